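"""Base-pair-level prediction accuracy: sensitivity X, specificity Y, MCC.

X = TP / (TP + FN), Y = TP / (TP + FP), and the full Matthews coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

are computed at exact (i, j) pair identity — no slipped-pair credit.  The
widely used simplification MCC ~= sqrt(X * Y) is provided separately.

TN needs a pair universe: the default counts the admissible pairs
(span >= min_span, and chemically allowed when a sequence is supplied);
``universe="all"`` uses all C(n, 2) position pairs instead.  Undefined
metrics (zero denominators) are returned as None and rendered "NA".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .core import FoldConfig, RnaSequence, SecondaryStructure, can_pair
from .errors import DomainError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("confusion counts must be non-negative")


@dataclass(frozen=True)
class EvaluationReport:
    name: str
    n: int
    counts: ConfusionCounts
    x: Optional[float]
    y: Optional[float]
    mcc_full: Optional[float]
    mcc_simple: Optional[float]

    def row(self) -> str:
        def fmt(v: Optional[float]) -> str:
            return "NA" if v is None else f"{v:.4f}"

        return "\t".join(
            [self.name, str(self.n), fmt(self.x), fmt(self.y), fmt(self.mcc_full), fmt(self.mcc_simple)]
        )


def pair_universe_size(
    n: int,
    cfg: Optional[FoldConfig] = None,
    seq: Optional[RnaSequence] = None,
    universe: str = "admissible",
) -> int:
    """Size of the TN pair universe."""
    if universe == "all":
        return n * (n - 1) // 2
    if universe != "admissible":
        raise DomainError(f"unknown universe {universe!r}")
    cfg = cfg or FoldConfig()
    if seq is None:
        span = n - cfg.min_span  # number of d values from min_span to n-1
        return sum(n - d for d in range(cfg.min_span, n)) if span > 0 else 0
    return sum(
        1
        for i in range(1, n + 1)
        for j in range(i + cfg.min_span, n + 1)
        if can_pair(seq.base(i), seq.base(j), cfg.allowed_pairs)
    )


def confusion(
    pred: SecondaryStructure,
    ref: SecondaryStructure,
    cfg: Optional[FoldConfig] = None,
    seq: Optional[RnaSequence] = None,
    universe: str = "admissible",
) -> ConfusionCounts:
    """Exact-identity pair confusion counts between prediction and reference."""
    if pred.n != ref.n:
        raise DomainError(f"length mismatch: pred n={pred.n}, ref n={ref.n}")
    tp = len(pred.pairs & ref.pairs)
    fp = len(pred.pairs - ref.pairs)
    fn = len(ref.pairs - pred.pairs)
    u = pair_universe_size(pred.n, cfg, seq, universe)
    tn = max(u - tp - fp - fn, 0)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def sensitivity(c: ConfusionCounts) -> Optional[float]:
    """X = TP / (TP + FN); None when the reference has no pairs."""
    denom = c.tp + c.fn
    return None if denom == 0 else c.tp / denom


def specificity(c: ConfusionCounts) -> Optional[float]:
    """Y = TP / (TP + FP); None when the prediction has no pairs."""
    denom = c.tp + c.fp
    return None if denom == 0 else c.tp / denom


def mcc_full(c: ConfusionCounts, printed_variant: bool = False) -> Optional[float]:
    """Full Matthews coefficient; None when any marginal is zero.

    ``printed_variant`` swaps in the denominator (TP+FP)(TP+FN)(FN+FP)(TN+FN)
    occasionally seen in print (almost certainly a typo for the standard
    form); kept only for comparison.
    """
    if printed_variant:
        terms = [(c.tp + c.fp), (c.tp + c.fn), (c.fn + c.fp), (c.tn + c.fn)]
    else:
        terms = [(c.tp + c.fp), (c.tp + c.fn), (c.tn + c.fp), (c.tn + c.fn)]
    denom = 1.0
    for t in terms:
        denom *= t
    if denom == 0:
        return None
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def mcc_simple(x: float, y: float) -> float:
    """sqrt(X * Y), the common simplification of the Matthews coefficient."""
    if not (0 <= x <= 1 and 0 <= y <= 1):
        raise DomainError("x and y must lie in [0, 1]")
    return math.sqrt(x * y)


def evaluate(
    pred: SecondaryStructure,
    ref: SecondaryStructure,
    name: str = "seq",
    cfg: Optional[FoldConfig] = None,
    seq: Optional[RnaSequence] = None,
    universe: str = "admissible",
) -> EvaluationReport:
    """Full comparison report of a prediction against a reference structure."""
    c = confusion(pred, ref, cfg, seq, universe)
    x = sensitivity(c)
    y = specificity(c)
    simple = mcc_simple(x, y) if x is not None and y is not None else None
    return EvaluationReport(
        name=name, n=pred.n, counts=c, x=x, y=y, mcc_full=mcc_full(c), mcc_simple=simple
    )
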