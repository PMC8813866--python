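"""Helix-based folding: enumerate stem regions into a pool, then DP over placements.

The recurrence on ``E(i, j)``:

1. ``j - i < 8``: the interval is too short for a stem, ``E = E_init = 0``.
2. A stem ``H(i, j, k)`` starting at i and ending at j contributes
   ``energy(H) + E(i + k, j - k)`` (the stem's k pairs consume the outer
   positions, the interior is solved recursively).
3. A split contributes ``E(i, k) + E(k+1, j)`` for ``i <= k < j`` (the
   ``k = i`` split skips a leading unpaired base; without it, stems not
   flush with the interval start would be unreachable).

Stem energies are sums of the energy model's stack terms over the stem's
``k - 1`` stacked steps (no initiation terms).  The default
``min_stem_len = 3`` is consistent with the base case: the smallest window
holding a 3-pair helix around a minimal hairpin is exactly ``j - i = 8``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .core import BasePair, FoldConfig, RnaSequence, SecondaryStructure, can_pair
from .engine import AuxiliaryStorage, DpState, FoldStrategy, PredictionResult
from . import engine
from .zuker import EnergyModel, default_energy_model

_EPS = 1e-9

#: Window-span threshold below which no stem placement is attempted (case 1).
E_INIT_SPAN = 8


@dataclass(frozen=True)
class StemRegion:
    """A run of k consecutively stacked pairs (i+t, j-t), t in [0, k-1]."""

    i: int
    j: int
    k: int
    energy: float

    def pairs(self) -> List[BasePair]:
        return [BasePair(self.i + t, self.j - t) for t in range(self.k)]


def enumerate_stems(
    seq: RnaSequence, cfg: Optional[FoldConfig] = None, em: Optional[EnergyModel] = None
) -> List[StemRegion]:
    """All stem regions with at least ``min_stem_len`` pairs, ordered by (i, j, k).

    For every outer pair (i, j) the helix is extended inward while residues
    keep pairing and the innermost span stays >= ``min_span``; each
    intermediate length from ``min_stem_len`` up to the maximal extension is
    emitted (maximal-and-shorter).
    """
    cfg = cfg or FoldConfig()
    em = em or default_energy_model()
    pool: List[StemRegion] = []
    n = seq.n
    for i in range(1, n + 1):
        for j in range(i + cfg.min_span, n + 1):
            if not can_pair(seq.base(i), seq.base(j), cfg.allowed_pairs):
                continue
            # extend inward; step t adds pair (i+t, j-t)
            kmax = 0
            t = 0
            while (
                i + t < j - t
                and (j - t) - (i + t) >= cfg.min_span
                and can_pair(seq.base(i + t), seq.base(j - t), cfg.allowed_pairs)
            ):
                kmax = t + 1
                t += 1
            energy = 0.0
            energies = []  # cumulative stack energy per helix length
            for k in range(1, kmax + 1):
                if k >= 2:
                    energy += em.stack(seq, i + k - 2, j - k + 2)
                energies.append(energy)
            for k in range(cfg.min_stem_len, kmax + 1):
                pool.append(StemRegion(i=i, j=j, k=k, energy=energies[k - 1]))
    pool.sort(key=lambda s: (s.i, s.j, s.k))
    return pool


class HelixState:
    """Score table E plus the stem pool auxiliary storage."""

    def __init__(self, n: int, em: EnergyModel, pool: List[StemRegion], audit: bool = False):
        self.n = n
        self.em = em
        self.E = DpState(n, name="E", audit=audit)
        self.pool = pool
        self.stems_by_ij: Dict[Tuple[int, int], List[StemRegion]] = {}
        for st in pool:
            self.stems_by_ij.setdefault((st.i, st.j), []).append(st)
        self.aux = AuxiliaryStorage(kind="stem_pool_op", payload=pool)
        self.selected_stems: List[StemRegion] = []

    def e(self, i: int, j: int) -> float:
        """E with the empty-interval convention E(i, j) = 0 for j < i."""
        return 0.0 if j < i else self.E.get(i, j)


class HelixStrategy(FoldStrategy):
    name = "helix"
    aux_kind = "stem_pool_op"

    def __init__(self, em: Optional[EnergyModel] = None):
        self.em = em or default_energy_model()

    def allocate(self, seq: RnaSequence, cfg: FoldConfig, audit: bool = False) -> HelixState:
        pool = enumerate_stems(seq, cfg, self.em)
        return HelixState(seq.n, self.em, pool, audit=audit)

    def init(self, state: HelixState, seq: RnaSequence, cfg: FoldConfig) -> None:
        pass

    def fill_cell(
        self, state: HelixState, i: int, j: int, seq: RnaSequence, cfg: FoldConfig
    ) -> None:
        if j - i < E_INIT_SPAN:
            state.E.set(i, j, 0.0)
            return
        best = None
        for st in state.stems_by_ij.get((i, j), ()):  # case 2
            cand = st.energy + state.e(i + st.k, j - st.k)
            if best is None or cand < best:
                best = cand
        # case 3; k = i is admitted so a leading unpaired base can be skipped
        # (E(i, i) = 0), otherwise stems not flush with the interval start
        # would be unreachable
        for k in range(i, j):
            cand = state.E.get(i, k) + state.E.get(k + 1, j)
            if best is None or cand < best:
                best = cand
        state.E.set(i, j, best)

    def final_score(self, state: HelixState) -> float:
        return state.E.get(1, state.n)

    def traceback(
        self, state: HelixState, seq: RnaSequence, cfg: FoldConfig
    ) -> SecondaryStructure:
        state.selected_stems = []
        pairs: List[BasePair] = []
        stack: List[Tuple[int, int]] = [(1, state.n)]
        while stack:
            i, j = stack.pop()
            if j - i < E_INIT_SPAN:
                continue
            target = state.E.get(i, j)
            if self._trace_cell(state, i, j, target, pairs, stack):
                continue
            raise AssertionError(f"no recurrence case reproduces E({i},{j})")
        return SecondaryStructure(n=state.n, pairs=frozenset(pairs))

    def _trace_cell(self, state, i, j, target, pairs, stack) -> bool:
        for st in state.stems_by_ij.get((i, j), ()):
            if abs(st.energy + state.e(i + st.k, j - st.k) - target) <= _EPS:
                state.selected_stems.append(st)
                pairs.extend(st.pairs())
                if i + st.k <= j - st.k:
                    stack.append((i + st.k, j - st.k))
                return True
        for k in range(i, j):
            if abs(state.E.get(i, k) + state.E.get(k + 1, j) - target) <= _EPS:
                stack.append((k + 1, j))
                stack.append((i, k))
                return True
        return False

    def rescore(
        self, state: HelixState, structure: SecondaryStructure, seq: RnaSequence, cfg: FoldConfig
    ) -> float:
        return sum(st.energy for st in state.selected_stems)


def helix_fill(
    seq: RnaSequence, cfg: Optional[FoldConfig] = None, em: Optional[EnergyModel] = None
) -> HelixState:
    cfg = cfg or FoldConfig()
    return engine.fill(seq, HelixStrategy(em), cfg)


def helix_traceback(
    state: HelixState, seq: RnaSequence, cfg: Optional[FoldConfig] = None
) -> SecondaryStructure:
    cfg = cfg or FoldConfig()
    return HelixStrategy(state.em).traceback(state, seq, cfg)


def predict_helix(
    seq: RnaSequence, cfg: Optional[FoldConfig] = None, em: Optional[EnergyModel] = None
) -> PredictionResult:
    cfg = cfg or FoldConfig()
    return engine.run(seq, HelixStrategy(em), cfg)
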