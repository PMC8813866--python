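"""The generic DP-engine: triangular score tables, span-ordered fill, traceback dispatch.

Every folding strategy plugs into one audited fill schedule: cells are
visited in increasing span order (``d = j - i`` from 0 to ``n - 1``), so a
recurrence may only read cells of strictly smaller span.  Reading an unset
cell raises :class:`EngineInvariantError`; with ``audit=True`` every access
is logged so the schedule itself can be verified.

Minimization strategies mark unreachable cells with ``math.inf`` (the
"forbidden" sentinel); the partition strategy never touches it, its cells
are plain non-negative weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Tuple

from .core import FoldConfig, RnaSequence, SecondaryStructure, check_structure
from .core import write_ct, write_dotbracket
from .errors import DomainError, EngineInvariantError

#: Sentinel for cells that cannot host any structure under a minimization
#: objective.  Partition-function tables never use it.
FORBIDDEN = math.inf

AUX_KINDS = ("matrix_op", "stem_pool_op", "free_energy_op", "none")


class DpState:
    """Upper-triangular score table over cells (i, j), 1 <= i <= j <= n."""

    __slots__ = ("n", "name", "_values", "_audit", "audit_log")

    def __init__(self, n: int, name: str = "main", audit: bool = False):
        if n < 1:
            raise DomainError(f"table length must be >= 1, got {n}")
        self.n = n
        self.name = name
        self._values: Dict[Tuple[int, int], float] = {}
        self._audit = audit
        self.audit_log: List[Tuple[str, int, int]] = []

    def _check(self, i: int, j: int) -> None:
        if not (1 <= i <= j <= self.n):
            raise EngineInvariantError(
                f"cell ({i},{j}) not addressable in {self.name} table of size {self.n}"
            )

    def set(self, i: int, j: int, value: float) -> None:
        self._check(i, j)
        if self._audit:
            self.audit_log.append(("write", i, j))
        self._values[(i, j)] = value

    def get(self, i: int, j: int) -> float:
        self._check(i, j)
        if (i, j) not in self._values:
            raise EngineInvariantError(f"read of unset cell ({i},{j}) in {self.name} table")
        if self._audit:
            self.audit_log.append(("read", i, j))
        return self._values[(i, j)]

    def is_set(self, i: int, j: int) -> bool:
        self._check(i, j)
        return (i, j) in self._values

    @property
    def cell_count(self) -> int:
        """Number of addressable cells, n(n+1)/2."""
        return self.n * (self.n + 1) // 2


@dataclass
class AuxiliaryStorage:
    """Strategy-specific side table: auxiliary matrix, stem pool, or energy parameters."""

    kind: str
    payload: Any = None

    def __post_init__(self) -> None:
        if self.kind not in AUX_KINDS:
            raise DomainError(f"unknown auxiliary-storage kind {self.kind!r}")


def allocate(n: int) -> DpState:
    """Allocate an empty triangular table for a sequence of length ``n``."""
    return DpState(n)


@dataclass
class PredictionResult:
    """Outcome of one engine run: the optimum score and its traced structure."""

    algorithm: str
    seq: RnaSequence
    cfg: FoldConfig
    score: float
    structure: SecondaryStructure
    state: Any


class FoldStrategy:
    """Contract every DP strategy implements (the pluggable prediction component).

    ``allocate`` builds the strategy state (DpState tables + auxiliary
    storage); ``init`` seeds base cells; ``fill_cell`` computes cell (i, j)
    from strictly smaller spans; ``final_score`` reads the answer cell
    (1, n); ``traceback`` reconstructs a structure; ``rescore`` re-derives
    the objective value of a traced structure independently of the tables.
    """

    name: str = "abstract"
    aux_kind: str = "none"
    #: False for ensemble strategies whose emitted structure is a summary,
    #: not an optimum of the reported score.
    scores_structure: bool = True

    def allocate(self, seq: RnaSequence, cfg: FoldConfig, audit: bool = False) -> Any:
        raise NotImplementedError

    def init(self, state: Any, seq: RnaSequence, cfg: FoldConfig) -> None:
        raise NotImplementedError

    def fill_cell(self, state: Any, i: int, j: int, seq: RnaSequence, cfg: FoldConfig) -> None:
        raise NotImplementedError

    def final_score(self, state: Any) -> float:
        raise NotImplementedError

    def traceback(self, state: Any, seq: RnaSequence, cfg: FoldConfig) -> SecondaryStructure:
        raise NotImplementedError

    def rescore(
        self, state: Any, structure: SecondaryStructure, seq: RnaSequence, cfg: FoldConfig
    ) -> float:
        raise NotImplementedError


def fill(
    seq: RnaSequence, strategy: FoldStrategy, cfg: FoldConfig, audit: bool = False
) -> Any:
    """Allocate, init, and fill every cell in increasing span order."""
    state = strategy.allocate(seq, cfg, audit=audit)
    strategy.init(state, seq, cfg)
    n = seq.n
    for d in range(n):
        for i in range(1, n - d + 1):
            strategy.fill_cell(state, i, i + d, seq, cfg)
    return state


def run(
    seq: RnaSequence, strategy: FoldStrategy, cfg: FoldConfig, audit: bool = False
) -> PredictionResult:
    """Full prediction: fill, read the answer cell, trace back, verify.

    The traced structure must pass :func:`check_structure` and, for scoring
    strategies, re-score to ``final_score`` within 1e-9.
    """
    state = fill(seq, strategy, cfg, audit=audit)
    score = strategy.final_score(state)
    structure = strategy.traceback(state, seq, cfg)
    check_structure(structure, cfg, seq)
    if strategy.scores_structure:
        rescored = strategy.rescore(state, structure, seq, cfg)
        if not math.isclose(rescored, score, rel_tol=0.0, abs_tol=1e-9):
            raise EngineInvariantError(
                f"{strategy.name}: traced structure re-scores to {rescored}, "
                f"but final score is {score}"
            )
    return PredictionResult(
        algorithm=strategy.name, seq=seq, cfg=cfg, score=score, structure=structure, state=state
    )


def emit(result: PredictionResult, mode: Optional[str] = None, fmt: str = "pairs") -> str:
    """Render a prediction in the selected output mode.

    ``pair_count`` prints the number of pairs; ``pair_intervals`` prints the
    sorted pair list (``fmt="pairs"``), a dot-bracket record
    (``fmt="dotbracket"``), a CT table (``fmt="ct"``), or — for the
    partition strategy — (i, j, P) dot-plot triples (``fmt="dotplot"``).
    """
    mode = mode or result.cfg.output_mode
    s = result.structure
    if mode == "pair_count":
        return str(len(s.pairs))
    if mode != "pair_intervals":
        raise DomainError(f"unknown output mode {mode!r}")
    if fmt == "pairs":
        return " ".join(f"({p.i},{p.j})" for p in s.sorted_pairs())
    if fmt == "dotbracket":
        return write_dotbracket(result.seq, s)
    if fmt == "ct":
        return write_ct(result.seq, s)
    if fmt == "dotplot":
        probs = getattr(result.state, "P", None)
        if probs is None:
            raise DomainError("dot-plot output requires the partition strategy")
        lines = [
            f"{i}\t{j}\t{probs[(i, j)]:.6g}"
            for (i, j) in sorted(probs)
            if probs[(i, j)] > 0
        ]
        return "\n".join(lines)
    raise DomainError(f"unknown output format {fmt!r}")


def verify_access_order(tables: List[DpState]) -> None:
    """Assert no table logged a read before the first write of the same cell."""
    for t in tables:
        written = set()
        for event, i, j in t.audit_log:
            if event == "write":
                written.add((i, j))
            elif (i, j) not in written:
                raise EngineInvariantError(
                    f"{t.name}: cell ({i},{j}) read before write"
                )
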