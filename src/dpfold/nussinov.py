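"""Maximum base-pairing dynamic programming with traceback.

The recurrence maximizes over four cases for cell (i, j):

1. i unpaired:            M(i+1, j)
2. j unpaired:            M(i, j-1)
3. i pairs j:             M(i+1, j-1) + theta(i, j)
4. bifurcation:           max_k M(i, k) + M(k+1, j),  i <= k < j

where ``theta(i, j) = 1`` only if the residues can pair chemically and
``j - i >= min_span``.  Ties are broken by case order then smallest split
point, so traceback is deterministic.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .core import FoldConfig, RnaSequence, SecondaryStructure, BasePair, can_pair
from .engine import DpState, FoldStrategy, PredictionResult
from . import engine


class NussinovState:
    """Fill state: the score table M plus the pairing indicator."""

    def __init__(self, n: int, audit: bool = False):
        self.M = DpState(n, name="M", audit=audit)
        self.n = n

    def m(self, i: int, j: int) -> int:
        """M with the empty-interval convention M(i, j) = 0 for j < i."""
        if j < i:
            return 0
        return int(self.M.get(i, j))


def _theta(seq: RnaSequence, i: int, j: int, cfg: FoldConfig) -> int:
    if j - i < cfg.min_span:
        return 0
    return 1 if can_pair(seq.base(i), seq.base(j), cfg.allowed_pairs) else 0


class NussinovStrategy(FoldStrategy):
    name = "nussinov"
    aux_kind = "none"

    def allocate(self, seq: RnaSequence, cfg: FoldConfig, audit: bool = False) -> NussinovState:
        return NussinovState(seq.n, audit=audit)

    def init(self, state: NussinovState, seq: RnaSequence, cfg: FoldConfig) -> None:
        pass  # base cells are spans 0, handled by fill_cell

    def fill_cell(
        self, state: NussinovState, i: int, j: int, seq: RnaSequence, cfg: FoldConfig
    ) -> None:
        if i == j:
            state.M.set(i, j, 0)
            return
        best = state.M.get(i + 1, j)  # case 1
        best = max(best, state.M.get(i, j - 1))  # case 2
        th = _theta(seq, i, j, cfg)
        if th:
            inner = state.M.get(i + 1, j - 1) if j - 1 >= i + 1 else 0
            best = max(best, inner + th)  # case 3
        for k in range(i, j):  # case 4
            best = max(best, state.m(i, k) + state.m(k + 1, j))
        state.M.set(i, j, best)

    def final_score(self, state: NussinovState) -> float:
        return float(state.M.get(1, state.n))

    def traceback(
        self, state: NussinovState, seq: RnaSequence, cfg: FoldConfig
    ) -> SecondaryStructure:
        pairs: List[BasePair] = []
        stack: List[Tuple[int, int]] = [(1, state.n)]
        while stack:
            i, j = stack.pop()
            if j <= i:
                continue
            v = state.m(i, j)
            if v == 0:
                continue
            if v == state.m(i + 1, j):  # case 1
                stack.append((i + 1, j))
                continue
            if v == state.m(i, j - 1):  # case 2
                stack.append((i, j - 1))
                continue
            th = _theta(seq, i, j, cfg)
            if th and v == state.m(i + 1, j - 1) + th:  # case 3
                pairs.append(BasePair(i, j))
                stack.append((i + 1, j - 1))
                continue
            for k in range(i, j):  # case 4, smallest split first
                if v == state.m(i, k) + state.m(k + 1, j):
                    stack.append((k + 1, j))
                    stack.append((i, k))
                    break
            else:  # pragma: no cover - unreachable on a consistent table
                raise AssertionError(f"no recurrence case reproduces M({i},{j})")
        return SecondaryStructure(n=state.n, pairs=frozenset(pairs))

    def rescore(
        self, state: NussinovState, structure: SecondaryStructure, seq: RnaSequence, cfg: FoldConfig
    ) -> float:
        return float(len(structure.pairs))


def nussinov_fill(seq: RnaSequence, cfg: Optional[FoldConfig] = None) -> NussinovState:
    """Fill the maximum-pairing table for ``seq``."""
    cfg = cfg or FoldConfig()
    return engine.fill(seq, NussinovStrategy(), cfg)


def nussinov_traceback(
    state: NussinovState, seq: RnaSequence, cfg: Optional[FoldConfig] = None
) -> SecondaryStructure:
    """Trace one maximum-pairing structure out of a filled table."""
    cfg = cfg or FoldConfig()
    return NussinovStrategy().traceback(state, seq, cfg)


def predict_nussinov(seq: RnaSequence, cfg: Optional[FoldConfig] = None) -> PredictionResult:
    cfg = cfg or FoldConfig()
    return engine.run(seq, NussinovStrategy(), cfg)


# ---------------------------------------------------------------------------
# Vectorized batch fill (for exhaustive screens over many sequences at once)
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_RESIDUES = "ACGU"


def encode_sequences(seqs: List[str]) -> np.ndarray:
    """Encode equal-length residue strings as a (B, n) uint8 matrix."""
    return np.array([[_CODE[c] for c in s] for s in seqs], dtype=np.uint8)


def all_sequences_encoded(n: int) -> np.ndarray:
    """All 4**n residue strings of length n, encoded, in lexicographic order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grids = np.meshgrid(*([np.arange(4, dtype=np.uint8)] * n), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def pairable_matrix(cfg: FoldConfig) -> np.ndarray:
    """4x4 boolean chemistry table in A,C,G,U code order."""
    mat = np.zeros((4, 4), dtype=bool)
    for a, b in cfg.allowed_pairs:
        mat[_CODE[a], _CODE[b]] = True
    return mat


def max_pairs_batch(codes: np.ndarray, cfg: Optional[FoldConfig] = None) -> np.ndarray:
    """Maximum pair count M(1, n) for every row of an encoded sequence batch.

    Same recurrence as :class:`NussinovStrategy` but computed for all B
    sequences simultaneously; used for exhaustive screens where a per-
    sequence Python loop would be too slow.
    """
    cfg = cfg or FoldConfig()
    pairable = pairable_matrix(cfg)
    B, n = codes.shape
    M = np.zeros((n + 2, n + 2, B), dtype=np.int16)
    for d in range(1, n):
        for i in range(1, n - d + 1):
            j = i + d
            best = np.maximum(M[i + 1, j], M[i, j - 1])
            if d >= cfg.min_span:
                theta = pairable[codes[:, i - 1], codes[:, j - 1]].astype(np.int16)
                np.maximum(best, M[i + 1, j - 1] + theta, out=best)
            for k in range(i, j):
                np.maximum(best, M[i, k] + M[k + 1, j], out=best)
            M[i, j] = best
    return M[1, n].copy()
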