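"""Exception hierarchy shared by all dpfold modules."""


class DpFoldError(Exception):
    """Base class for all dpfold errors."""


class DomainError(DpFoldError):
    """An argument is outside its mathematical domain (e.g. n < 1)."""


class EmptySequenceError(DpFoldError):
    """Input sequence is empty after whitespace stripping."""


class InvalidResidueError(DpFoldError):
    """A residue outside {A, C, G, U} was found after normalization."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position  # 1-based
        super().__init__(f"invalid residue {residue!r} at position {position}")


class StructureError(DpFoldError):
    """A secondary-structure validity rule is violated."""


class MultiplePairingError(StructureError):
    """A base participates in more than one pair (rule 1)."""


class PseudoknotError(StructureError):
    """Two pairs cross (rule 2)."""


class HairpinSpanError(StructureError):
    """A pair (i, j) has j - i below the minimum span (rule 3)."""


class ChemistryError(StructureError):
    """A pair joins residues not in the allowed pair set."""


class ParseError(DpFoldError):
    """Malformed FASTA / dot-bracket / CT input."""


class EngineInvariantError(DpFoldError):
    """A DP-engine contract was violated (unset cell read, bad rescore...)."""


class PartitionOverflowError(DpFoldError):
    """Partition-function fill overflowed; retry with a larger rescale factor."""

    def __init__(self, eta: float):
        self.eta = eta
        super().__init__(
            f"partition function overflowed at rescale factor eta={eta}; "
            "retry with a larger eta"
        )


class PerturbationError(DpFoldError):
    """A structure perturbation request cannot be satisfied."""
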