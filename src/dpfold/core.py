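"""Sequence/structure domain types, validity rules, and FASTA / dot-bracket / CT I/O.

Coordinates are 1-based inclusive throughout: a sequence of length ``n`` is
indexed by ``i in [1, n]`` and a base pair ``(i, j)`` always has ``i < j``.

A note on the minimum hairpin span: the validity rule enforced here is
``j - i >= min_span`` with the default ``min_span = 4``, i.e. at least three
unpaired bases inside the innermost pair of a hairpin.  The alternative
"at least four unpaired bases" convention is reachable by setting
``min_span = 5`` in :class:`FoldConfig`.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple, Union

from Bio import SeqIO

from .errors import (
    ChemistryError,
    DomainError,
    EmptySequenceError,
    HairpinSpanError,
    InvalidResidueError,
    MultiplePairingError,
    ParseError,
    PseudoknotError,
)

RNA_ALPHABET = "ACGU"

#: Watson-Crick pairs plus the GU wobble, closed under symmetry.
DEFAULT_ALLOWED_PAIRS: FrozenSet[Tuple[str, str]] = frozenset(
    {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
)

ALGORITHMS = ("nussinov", "zuker", "helix", "partition")
OUTPUT_MODES = ("pair_count", "pair_intervals")


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over {A, C, G, U} with 1-based indexing."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptySequenceError("sequence is empty")
        for pos, r in enumerate(self.residues, start=1):
            if r not in RNA_ALPHABET:
                raise InvalidResidueError(r, pos)

    @property
    def n(self) -> int:
        return len(self.residues)

    def base(self, i: int) -> str:
        """Residue at 1-based position ``i``."""
        if not 1 <= i <= self.n:
            raise DomainError(f"position {i} outside [1, {self.n}]")
        return self.residues[i - 1]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class BasePair:
    """An ordered pair of 1-based positions with i < j."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if not (1 <= self.i < self.j):
            raise DomainError(f"base pair requires 1 <= i < j, got ({self.i}, {self.j})")


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs over a sequence of length ``n``.

    Construction only checks index ranges; the full validity rules
    (uniqueness, nestedness, hairpin span, chemistry) are enforced by
    :func:`check_structure`.
    """

    n: int
    pairs: FrozenSet[BasePair] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError(f"structure length must be >= 1, got {self.n}")
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        for p in self.pairs:
            if p.j > self.n:
                raise DomainError(f"pair {p} outside sequence of length {self.n}")

    def sorted_pairs(self) -> List[BasePair]:
        return sorted(self.pairs)

    def partner_map(self) -> Dict[int, int]:
        """Position -> partner map (both directions)."""
        out: Dict[int, int] = {}
        for p in self.pairs:
            out[p.i] = p.j
            out[p.j] = p.i
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class FoldConfig:
    """Assembly-time knobs shared by every folding strategy."""

    min_span: int = 4
    algorithm: str = "nussinov"
    output_mode: str = "pair_intervals"
    allowed_pairs: FrozenSet[Tuple[str, str]] = DEFAULT_ALLOWED_PAIRS
    energy_params: Optional[str] = None
    rt: float = 0.616
    pair_prob_threshold: float = 0.5
    min_stem_len: int = 3
    interior_loop_cap: Optional[int] = 30

    def __post_init__(self) -> None:
        if self.min_span < 1:
            raise DomainError(f"min_span must be >= 1, got {self.min_span}")
        if self.algorithm not in ALGORITHMS:
            raise DomainError(f"unknown algorithm {self.algorithm!r}")
        if self.output_mode not in OUTPUT_MODES:
            raise DomainError(f"unknown output mode {self.output_mode!r}")
        for a, b in self.allowed_pairs:
            if (b, a) not in self.allowed_pairs:
                raise DomainError(f"allowed_pairs not symmetric: ({a},{b}) without ({b},{a})")
        if self.rt <= 0:
            raise DomainError("rt must be positive")
        if not 0 < self.pair_prob_threshold <= 1:
            raise DomainError("pair_prob_threshold must be in (0, 1]")
        if self.min_stem_len < 1:
            raise DomainError("min_stem_len must be >= 1")
        if self.interior_loop_cap is not None and self.interior_loop_cap < 1:
            raise DomainError("interior_loop_cap must be >= 1 or None")


def validate_sequence(
    raw: str,
    normalize_t: bool = True,
    to_upper: bool = True,
    id: str = "seq",
) -> RnaSequence:
    """Check and normalize a raw residue string into an :class:`RnaSequence`.

    Whitespace is stripped, ``T``/``t`` rewritten to ``U`` when
    ``normalize_t`` is set, and lowercase accepted when ``to_upper`` is set.
    Any residue outside {A, C, G, U} after normalization (including IUPAC
    ambiguity codes) raises :class:`InvalidResidueError` with its 1-based
    position.
    """
    residues = "".join(raw.split())
    if not residues:
        raise EmptySequenceError("sequence is empty after whitespace stripping")
    if to_upper:
        residues = residues.upper()
    if normalize_t:
        residues = residues.replace("T", "U")
    return RnaSequence(id=id, residues=residues)


def can_pair(
    a: str,
    b: str,
    allowed_pairs: FrozenSet[Tuple[str, str]] = DEFAULT_ALLOWED_PAIRS,
) -> bool:
    """True iff the residue pair (in either order) is chemically allowed."""
    return (a, b) in allowed_pairs


def check_structure(
    s: SecondaryStructure,
    cfg: Optional[FoldConfig] = None,
    seq: Optional[RnaSequence] = None,
) -> SecondaryStructure:
    """Validate the three structure rules (and chemistry, when a sequence is given).

    Rule 1 — a base pairs at most once; rule 2 — no crossing pairs
    (pseudoknot-free); rule 3 — every pair satisfies ``j - i >= min_span``.
    Returns ``s`` unchanged on success.
    """
    cfg = cfg or FoldConfig()
    if seq is not None and seq.n != s.n:
        raise DomainError(f"structure length {s.n} != sequence length {seq.n}")
    seen: Dict[int, BasePair] = {}
    for p in s.pairs:
        for pos in (p.i, p.j):
            if pos in seen:
                raise MultiplePairingError(
                    f"position {pos} appears in both {seen[pos]} and {p}"
                )
            seen[pos] = p
        if p.j - p.i < cfg.min_span:
            raise HairpinSpanError(
                f"pair {p} has span {p.j - p.i} < min_span {cfg.min_span}"
            )
        if seq is not None and not can_pair(seq.base(p.i), seq.base(p.j), cfg.allowed_pairs):
            raise ChemistryError(
                f"pair {p} joins {seq.base(p.i)}-{seq.base(p.j)}, not an allowed pair"
            )
    ordered = s.sorted_pairs()
    for idx, p in enumerate(ordered):
        for q in ordered[idx + 1 :]:
            if q.i > p.j:
                break
            # q.i > p.i here; crossing iff p.i < q.i <= p.j < q.j
            if q.i <= p.j < q.j:
                raise PseudoknotError(f"pairs {p} and {q} cross")
    return s


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

PathOrHandle = Union[str, "os.PathLike[str]", io.TextIOBase]


def read_fasta(
    source: PathOrHandle,
    normalize_t: bool = True,
    to_upper: bool = True,
) -> List[RnaSequence]:
    """Read a (multi-record) FASTA file into validated sequences."""
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise ParseError("no FASTA records found")
    return [
        validate_sequence(str(rec.seq), normalize_t=normalize_t, to_upper=to_upper, id=rec.id)
        for rec in records
    ]


def write_fasta(seqs: Iterable[RnaSequence], width: int = 60) -> str:
    """Render sequences as FASTA text (deterministic, fixed line width)."""
    chunks: List[str] = []
    for s in seqs:
        chunks.append(f">{s.id}")
        for off in range(0, s.n, width):
            chunks.append(s.residues[off : off + width])
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# dot-bracket
# ---------------------------------------------------------------------------


def dotbracket_string(s: SecondaryStructure) -> str:
    chars = ["."] * s.n
    for p in s.pairs:
        chars[p.i - 1] = "("
        chars[p.j - 1] = ")"
    return "".join(chars)


def write_dotbracket(seq: RnaSequence, s: SecondaryStructure) -> str:
    """Three-line record: header, residues, bracket string."""
    if s.n != seq.n:
        raise DomainError(f"structure length {s.n} != sequence length {seq.n}")
    return f">{seq.id}\n{seq.residues}\n{dotbracket_string(s)}\n"


def read_dotbracket(text: str) -> SecondaryStructure:
    """Parse the first dot-bracket line found in ``text``.

    Header (``>``) and sequence lines are skipped; the structure line may
    contain only ``.``, ``(`` and ``)``. Unbalanced brackets raise
    :class:`ParseError`.
    """
    struct_line = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        if set(line) <= set(".()"):
            struct_line = line
            break
    if struct_line is None:
        raise ParseError("no dot-bracket line found")
    stack: List[int] = []
    pairs = set()
    for pos, ch in enumerate(struct_line, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {pos}")
            pairs.add(BasePair(stack.pop(), pos))
    if stack:
        raise ParseError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(n=len(struct_line), pairs=frozenset(pairs))


# ---------------------------------------------------------------------------
# CT (6-column connect table)
# ---------------------------------------------------------------------------


def write_ct(seq: RnaSequence, s: SecondaryStructure) -> str:
    """6-column CT text: index, residue, i-1, i+1 (0 at the end), partner, index."""
    if s.n != seq.n:
        raise DomainError(f"structure length {s.n} != sequence length {seq.n}")
    partner = s.partner_map()
    lines = [f"{seq.n}\t{seq.id}"]
    for i in range(1, seq.n + 1):
        nxt = i + 1 if i < seq.n else 0
        lines.append(
            f"{i}\t{seq.base(i)}\t{i - 1}\t{nxt}\t{partner.get(i, 0)}\t{i}"
        )
    return "\n".join(lines) + "\n"


def read_ct(text: str) -> Tuple[RnaSequence, SecondaryStructure]:
    """Parse CT text back into a sequence and structure.

    Partner asymmetry (row i says j but row j does not say i) raises
    :class:`ParseError`.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty CT input")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"bad CT header: {lines[0]!r}") from exc
    name = header[1] if len(header) > 1 else "seq"
    if len(lines) - 1 < n:
        raise ParseError(f"CT header says {n} rows, found {len(lines) - 1}")
    residues: List[str] = []
    partner: Dict[int, int] = {}
    for ln in lines[1 : n + 1]:
        cols = ln.split()
        if len(cols) < 6:
            raise ParseError(f"CT row has fewer than 6 columns: {ln!r}")
        idx, res, pj = int(cols[0]), cols[1], int(cols[4])
        if idx != len(residues) + 1:
            raise ParseError(f"CT rows out of order at index {idx}")
        residues.append(res)
        if pj:
            partner[idx] = pj
    for i, j in partner.items():
        if partner.get(j) != i:
            raise ParseError(f"CT partner asymmetry: {i} -> {j} but {j} -> {partner.get(j)}")
    pairs = frozenset(BasePair(i, j) for i, j in partner.items() if i < j)
    seq = validate_sequence("".join(residues), id=name)
    return seq, SecondaryStructure(n=n, pairs=pairs)
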