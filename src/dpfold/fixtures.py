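"""Seeded synthetic data and the brute-force oracles the DP strategies are tested against.

``enumerate_structures`` produces the complete set of valid structures for a
short sequence (unique partners, no crossings, minimum hairpin span,
chemistry); every folding strategy's optimum is checked against a direct
scan of this set.  ``enumerate_index_structures`` is the chemistry-blind
variant over bare positions, used to screen whole sequence batches.

All randomness flows through one explicitly seeded NumPy generator per call;
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Tuple, Union

import numpy as np

from .core import (
    BasePair,
    FoldConfig,
    RnaSequence,
    SecondaryStructure,
    can_pair,
    check_structure,
)
from .errors import DomainError, PerturbationError

#: Default refusal threshold for exhaustive enumeration.
ENUMERATION_CAP = 16


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for a reproducible batch of random sequences."""

    n_sequences: int
    length: Union[int, Tuple[int, int]]  # fixed length or inclusive (lo, hi) range
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise DomainError("n_sequences must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise DomainError(f"invalid length specification {self.length!r}")
        if not 0.0 <= self.gc_content <= 1.0:
            raise DomainError("gc_content must be in [0, 1]")

    @property
    def length_range(self) -> Tuple[int, int]:
        if isinstance(self.length, int):
            return self.length, self.length
        lo, hi = self.length
        return int(lo), int(hi)


def random_sequences(spec: SimulationSpec) -> List[RnaSequence]:
    """I.i.d. residues with P(G)=P(C)=gc/2 and P(A)=P(U)=(1-gc)/2."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, U
    alphabet = np.array(list("ACGU"))
    lo, hi = spec.length_range
    out: List[RnaSequence] = []
    width = len(str(spec.n_sequences))
    for idx in range(1, spec.n_sequences + 1):
        n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        residues = "".join(rng.choice(alphabet, size=n, p=probs))
        out.append(RnaSequence(id=f"sim_{idx:0{width}d}", residues=residues))
    return out


def _enumerate(
    n: int,
    admissible: callable,
    cfg: FoldConfig,
) -> List[FrozenSet[BasePair]]:
    """All valid pair sets over [1, n]; ``admissible(i, j)`` gates pairing."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> Tuple[FrozenSet[BasePair], ...]:
        if j - i < cfg.min_span:  # too short to hold any pair
            return (frozenset(),)
        out = list(rec(i, j - 1))  # j unpaired
        for k in range(i, j - cfg.min_span + 1):
            if not admissible(k, j):
                continue
            for left in rec(i, k - 1) if k > i else (frozenset(),):
                for inner in rec(k + 1, j - 1):
                    out.append(left | inner | {BasePair(k, j)})
        return tuple(out)

    result = rec(1, n)
    rec.cache_clear()
    return list(result)


def enumerate_structures(
    seq: RnaSequence, cfg: Optional[FoldConfig] = None, cap: int = ENUMERATION_CAP
) -> List[SecondaryStructure]:
    """The complete valid-structure space of ``seq`` (oracle for all strategies)."""
    cfg = cfg or FoldConfig()
    if seq.n > cap:
        raise DomainError(f"refusing to enumerate structures for n={seq.n} > cap={cap}")
    sets = _enumerate(
        seq.n,
        lambda i, j: can_pair(seq.base(i), seq.base(j), cfg.allowed_pairs),
        cfg,
    )
    return [SecondaryStructure(n=seq.n, pairs=p) for p in sets]


def enumerate_index_structures(
    n: int, cfg: Optional[FoldConfig] = None, cap: int = ENUMERATION_CAP
) -> List[FrozenSet[BasePair]]:
    """All nested pair sets over bare positions (chemistry ignored)."""
    cfg = cfg or FoldConfig()
    if n > cap:
        raise DomainError(f"refusing to enumerate index structures for n={n} > cap={cap}")
    return _enumerate(n, lambda i, j: True, cfg)


def perturb_structure(
    ref: SecondaryStructure,
    n_drop: int,
    n_add: int,
    seed: int,
    cfg: Optional[FoldConfig] = None,
    seq: Optional[RnaSequence] = None,
) -> SecondaryStructure:
    """Drop ``n_drop`` reference pairs and add ``n_add`` valid non-reference pairs.

    The result's confusion against ``ref`` has fn >= n_drop and fp == n_add.
    Raises :class:`PerturbationError` when the addition budget cannot be met.
    """
    cfg = cfg or FoldConfig()
    if n_drop > len(ref.pairs):
        raise PerturbationError(f"cannot drop {n_drop} of {len(ref.pairs)} pairs")
    rng = np.random.default_rng(seed)
    kept = ref.sorted_pairs()
    drop_idx = set(rng.choice(len(kept), size=n_drop, replace=False).tolist()) if n_drop else set()
    current = [p for t, p in enumerate(kept) if t not in drop_idx]

    def compatible(i: int, j: int) -> bool:
        for p in current:
            if i in (p.i, p.j) or j in (p.i, p.j):
                return False
            if p.i < i <= p.j < j or i < p.i <= j < p.j:
                return False
        return True

    for _ in range(n_add):
        candidates = [
            (i, j)
            for i in range(1, ref.n + 1)
            for j in range(i + cfg.min_span, ref.n + 1)
            if BasePair(i, j) not in ref.pairs
            and (seq is None or can_pair(seq.base(i), seq.base(j), cfg.allowed_pairs))
            and compatible(i, j)
        ]
        if not candidates:
            raise PerturbationError("no valid pair left to add")
        i, j = candidates[int(rng.integers(len(candidates)))]
        current.append(BasePair(i, j))

    out = SecondaryStructure(n=ref.n, pairs=frozenset(current))
    return check_structure(out, cfg, seq)
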