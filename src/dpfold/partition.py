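"""Boltzmann-ensemble mode: pair-level partition function, base-pair probabilities,
and a probability-threshold structure.

This is the pair-weighted (Nussinov-shaped) scheme: every admissible pair
(i, j) carries weight ``exp(-E_pair(i, j) / RT)`` and a structure's weight is
the product over its pairs, so with ``E_pair = 0`` the partition function
``Q(1, n)`` counts the valid structures exactly.  It is not a full
loop-decomposition partition function.

Inside recursion (rightmost-pair factorization)::

    Q(i, j)  = Q(i, j-1) + sum over k with can_pair(k, j), j-k >= min_span:
               Q(i, k-1) * Qb(k, j)
    Qb(k, j) = exp(-E_pair(k, j)/RT) * Q(k+1, j-1)

Outside completion, by the innermost pair (k, l) strictly enclosing (i, j)::

    P(i, j) = Qb(i, j) * [ Q(1, i-1) * Q(j+1, n) / Q(1, n)
              + sum over (k, l): P(k, l) * Q(k+1, i-1) * Q(j+1, l-1) / Q(k+1, l-1) ]

Numerical safety: tables hold ``Q(i, j) / eta**(j-i+1)`` for a rescale
factor ``eta >= 1``.  All probability ratios are scale-invariant; the
reported ``Q(1, n)`` is exposed both unscaled (when finite) and in log
space.  On overflow the fill raises :class:`PartitionOverflowError` and the
wrapper retries with a larger ``eta``.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

from .core import BasePair, FoldConfig, RnaSequence, SecondaryStructure, can_pair, check_structure
from .engine import AuxiliaryStorage, DpState, FoldStrategy, PredictionResult
from . import engine
from .errors import DpFoldError, PartitionOverflowError
from .zuker import EnergyModel, ToyEnergyModel


class PartitionState:
    """Scaled Q / Qb tables, the rescale factor, and (after the outside pass) P."""

    def __init__(self, n: int, em: EnergyModel, eta: float = 1.0, audit: bool = False):
        self.n = n
        self.em = em
        self.eta = eta
        self.Q = DpState(n, name="Q", audit=audit)
        self.Qb = DpState(n, name="Qb", audit=audit)
        self.aux = AuxiliaryStorage(kind="free_energy_op", payload=em)
        self.P: Optional[Dict[Tuple[int, int], float]] = None

    def q(self, i: int, j: int) -> float:
        """Scaled Q with the empty-interval convention Q = eta**0 = 1."""
        return 1.0 if j < i else self.Q.get(i, j)

    def q_unscaled(self, i: int, j: int) -> float:
        if j < i:
            return 1.0
        return self.Q.get(i, j) * self.eta ** (j - i + 1)

    @property
    def q_total(self) -> float:
        """Q(1, n), unscaled (may overflow to inf for very long sequences)."""
        return self.q_unscaled(1, self.n)

    @property
    def log_q_total(self) -> float:
        """ln Q(1, n), safe at any length."""
        return math.log(self.Q.get(1, self.n)) + self.n * math.log(self.eta)


class PartitionStrategy(FoldStrategy):
    name = "partition"
    aux_kind = "free_energy_op"
    scores_structure = False  # the threshold structure is an ensemble summary

    def __init__(self, em: Optional[EnergyModel] = None, eta: float = 1.0):
        self.em = em or ToyEnergyModel()
        self.eta = eta

    def allocate(self, seq: RnaSequence, cfg: FoldConfig, audit: bool = False) -> PartitionState:
        return PartitionState(seq.n, self.em, eta=self.eta, audit=audit)

    def init(self, state: PartitionState, seq: RnaSequence, cfg: FoldConfig) -> None:
        pass

    def _pair_weight(self, state: PartitionState, seq: RnaSequence, i: int, j: int, cfg) -> float:
        if j - i < cfg.min_span or not can_pair(seq.base(i), seq.base(j), cfg.allowed_pairs):
            return 0.0
        return math.exp(-state.em.pair_energy(seq, i, j) / state.em.rt)

    def fill_cell(
        self, state: PartitionState, i: int, j: int, seq: RnaSequence, cfg: FoldConfig
    ) -> None:
        eta = state.eta
        if i == j:
            state.Q.set(i, i, 1.0 / eta)
            state.Qb.set(i, i, 0.0)
            return
        w = self._pair_weight(state, seq, i, j, cfg)
        qb = w * state.q(i + 1, j - 1) / (eta * eta) if w else 0.0
        state.Qb.set(i, j, qb)
        total = state.Q.get(i, j - 1) / eta  # j unpaired
        for k in range(i, j - cfg.min_span + 1):
            qbkj = state.Qb.get(k, j) if k > i else qb
            if qbkj:
                total += state.q(i, k - 1) * qbkj
        state.Q.set(i, j, total)
        if not math.isfinite(total):
            raise PartitionOverflowError(eta)

    def final_score(self, state: PartitionState) -> float:
        return state.q_total

    def traceback(
        self, state: PartitionState, seq: RnaSequence, cfg: FoldConfig
    ) -> SecondaryStructure:
        probs = pair_probabilities(state)
        return threshold_structure(probs, cfg, state.n)

    def rescore(self, state, structure, seq, cfg) -> float:  # pragma: no cover
        raise NotImplementedError("ensemble mode has no per-structure score")


def partition_fill(
    seq: RnaSequence,
    cfg: Optional[FoldConfig] = None,
    em: Optional[EnergyModel] = None,
    eta: Optional[float] = None,
    max_retries: int = 12,
) -> PartitionState:
    """Fill Q/Qb, retrying with a growing rescale factor on overflow."""
    cfg = cfg or FoldConfig()
    current = eta if eta is not None else 1.0
    for _ in range(max_retries):
        try:
            return engine.fill(seq, PartitionStrategy(em, eta=current), cfg)
        except PartitionOverflowError:
            current *= 8.0
    raise DpFoldError(f"partition fill still overflows at eta={current}")


def pair_probabilities(state: PartitionState) -> Dict[Tuple[int, int], float]:
    """Outside completion: P(i, j) for every pair with nonzero Qb.

    Pairs are processed in decreasing span so every strictly enclosing
    pair's probability is already available.  O(n^4) over candidate pairs;
    exact (no sampling).  The result is cached on the state.
    """
    if state.P is not None:
        return state.P
    n = state.n
    q = state.q
    qtot = state.Q.get(1, n)
    cand: List[Tuple[int, int]] = [
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + 1, n + 1)
        if state.Qb.get(i, j) > 0.0
    ]
    cand.sort(key=lambda ij: ij[1] - ij[0], reverse=True)
    P: Dict[Tuple[int, int], float] = {}
    for i, j in cand:
        qb = state.Qb.get(i, j)
        total = qb * q(1, i - 1) * q(j + 1, n) / qtot
        for k, l in cand:
            if not (k < i and j < l):
                continue
            pkl = P[(k, l)]
            if pkl > 0.0:
                total += pkl * q(k + 1, i - 1) * qb * q(j + 1, l - 1) / q(k + 1, l - 1)
        P[(i, j)] = min(total, 1.0)
    state.P = P
    return P


def threshold_structure(
    probs: Dict[Tuple[int, int], float], cfg: FoldConfig, n: int
) -> SecondaryStructure:
    """Greedy selection of pairs with P above the threshold, most probable first.

    Candidates that would clash with an already selected pair (shared
    position or crossing) are skipped; at the default threshold 0.5 no
    clash can actually occur, since at most one partner per base can carry
    more than half the probability mass.
    """
    chosen: List[Tuple[int, int]] = []
    used: set = set()
    for (i, j), p in sorted(probs.items(), key=lambda kv: (-kv[1], kv[0])):
        if p <= cfg.pair_prob_threshold:
            continue
        if i in used or j in used:
            continue
        if any(g < i <= h < j or i < g <= j < h for g, h in chosen):
            continue
        chosen.append((i, j))
        used.update((i, j))
    s = SecondaryStructure(n=n, pairs=frozenset(BasePair(i, j) for i, j in chosen))
    return check_structure(s, cfg)


def predict_partition(
    seq: RnaSequence, cfg: Optional[FoldConfig] = None, em: Optional[EnergyModel] = None
) -> PredictionResult:
    """Fill (with overflow retry), compute probabilities, threshold-decode."""
    cfg = cfg or FoldConfig()
    state = partition_fill(seq, cfg, em)
    structure = PartitionStrategy(em or state.em).traceback(state, seq, cfg)
    check_structure(structure, cfg, seq)
    return PredictionResult(
        algorithm="partition",
        seq=seq,
        cfg=cfg,
        score=state.q_total,
        structure=structure,
        state=state,
    )
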