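import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpfold.core import (
    DEFAULT_ALLOWED_PAIRS,
    BasePair,
    FoldConfig,
    RnaSequence,
    SecondaryStructure,
    can_pair,
    check_structure,
    dotbracket_string,
    read_ct,
    read_dotbracket,
    read_fasta,
    validate_sequence,
    write_ct,
    write_dotbracket,
    write_fasta,
)
from dpfold.errors import (
    ChemistryError,
    DomainError,
    EmptySequenceError,
    HairpinSpanError,
    InvalidResidueError,
    MultiplePairingError,
    ParseError,
    PseudoknotError,
)
from dpfold.fixtures import SimulationSpec, enumerate_structures, random_sequences


class TestValidateSequence:
    def test_identity(self):
        s = validate_sequence("ACGU")
        assert s.residues == "ACGU" and s.n == 4

    def test_normalization(self):
        assert validate_sequence("acgt", normalize_t=True, to_upper=True).residues == "ACGU"

    def test_invalid_residue_position(self):
        with pytest.raises(InvalidResidueError) as exc:
            validate_sequence("ACGX")
        assert exc.value.position == 4

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(InvalidResidueError):
            validate_sequence("ACGN")

    def test_empty(self):
        with pytest.raises(EmptySequenceError):
            validate_sequence("   \n ")

    def test_strict_mode_rejects_t(self):
        with pytest.raises(InvalidResidueError):
            validate_sequence("ACGT", normalize_t=False)

    def test_whitespace_stripped(self):
        assert validate_sequence(" AC\nGU ").residues == "ACGU"

    def test_one_based_indexing(self):
        s = validate_sequence("ACGU")
        assert s.base(1) == "A" and s.base(4) == "U"
        with pytest.raises(DomainError):
            s.base(0)


class TestCanPair:
    def test_gc(self):
        assert can_pair("G", "C")

    def test_wobble(self):
        assert can_pair("U", "G")

    def test_aa(self):
        assert not can_pair("A", "A")

    @given(st.sampled_from("ACGU"), st.sampled_from("ACGU"))
    def test_symmetry(self, a, b):
        assert can_pair(a, b) == can_pair(b, a)

    def test_custom_pair_set(self):
        pairs = frozenset({("A", "C"), ("C", "A")})
        assert can_pair("A", "C", pairs) and not can_pair("G", "C", pairs)


class TestCheckStructure:
    def test_valid_nested_helix(self, cfg):
        s = SecondaryStructure(10, {BasePair(1, 9), BasePair(2, 8), BasePair(3, 7)})
        assert check_structure(s, cfg) is s

    def test_pseudoknot(self, cfg):
        s = SecondaryStructure(9, {BasePair(1, 6), BasePair(4, 9)})
        with pytest.raises(PseudoknotError):
            check_structure(s, cfg)

    def test_short_hairpin(self, cfg):
        s = SecondaryStructure(4, {BasePair(1, 4)})
        with pytest.raises(HairpinSpanError):
            check_structure(s, cfg)

    def test_min_span_configurable(self):
        s = SecondaryStructure(4, {BasePair(1, 4)})
        assert check_structure(s, FoldConfig(min_span=3)) is s

    def test_multiple_pairing(self, cfg):
        s = SecondaryStructure(12, {BasePair(1, 8), BasePair(1, 12)})
        with pytest.raises(MultiplePairingError):
            check_structure(s, cfg)

    def test_chemistry(self, cfg):
        seq = validate_sequence("AAAAAAAAAA")
        s = SecondaryStructure(10, {BasePair(1, 10)})
        with pytest.raises(ChemistryError):
            check_structure(s, cfg, seq)

    def test_out_of_range_pair(self):
        with pytest.raises(DomainError):
            SecondaryStructure(5, {BasePair(1, 9)})

    def test_accepts_every_enumerated_structure(self, cfg):
        seqs = random_sequences(SimulationSpec(n_sequences=5, length=12, seed=21))
        for seq in seqs:
            for s in enumerate_structures(seq, cfg):
                check_structure(s, cfg, seq)

    def test_rejects_mutations(self, cfg):
        # crossing added to a valid structure
        s = SecondaryStructure(12, {BasePair(1, 8), BasePair(4, 12)})
        with pytest.raises(PseudoknotError):
            check_structure(s, cfg)


class TestDotBracket:
    def test_bracket_matching(self):
        s = read_dotbracket("(((....)))")
        assert {(p.i, p.j) for p in s.pairs} == {(1, 10), (2, 9), (3, 8)}

    def test_all_dots(self):
        assert read_dotbracket("..........").pairs == frozenset()

    def test_unbalanced(self):
        with pytest.raises(ParseError):
            read_dotbracket("((.)")
        with pytest.raises(ParseError):
            read_dotbracket(".))")

    def test_roundtrip(self):
        seq = validate_sequence("GGGAAAACCC")
        s = SecondaryStructure(10, {BasePair(1, 10), BasePair(2, 9), BasePair(3, 8)})
        assert read_dotbracket(write_dotbracket(seq, s)) == s

    def test_string_rendering(self):
        s = SecondaryStructure(10, {BasePair(1, 10), BasePair(2, 9), BasePair(3, 8)})
        assert dotbracket_string(s) == "(((....)))"


class TestCt:
    def test_roundtrip(self):
        seq = validate_sequence("GGGAAAACCC")
        s = SecondaryStructure(10, {BasePair(1, 10), BasePair(2, 9), BasePair(3, 8)})
        seq2, s2 = read_ct(write_ct(seq, s))
        assert seq2.residues == seq.residues and s2 == s

    def test_partner_asymmetry(self):
        seq = validate_sequence("GGGAAAACCC")
        s = SecondaryStructure(10, {BasePair(1, 10)})
        text = write_ct(seq, s).replace("\t10\t1", "\t0\t1")  # break row 1's partner
        with pytest.raises(ParseError):
            read_ct(text)

    def test_bad_header(self):
        with pytest.raises(ParseError):
            read_ct("notanumber seq\n")


class TestFasta:
    def test_roundtrip(self, tmp_path):
        seqs = random_sequences(SimulationSpec(n_sequences=4, length=(5, 80), seed=3))
        path = tmp_path / "x.fasta"
        path.write_text(write_fasta(seqs))
        back = read_fasta(str(path))
        assert [(s.id, s.residues) for s in back] == [(s.id, s.residues) for s in seqs]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ParseError):
            read_fasta(str(path))


@settings(max_examples=50, deadline=None)
@given(st.integers(5, 14), st.integers(0, 10_000))
def test_format_roundtrips_random(n, seed):
    """read(write(x)) = x for dot-bracket and CT on random valid instances."""
    cfg = FoldConfig()
    seq = random_sequences(SimulationSpec(n_sequences=1, length=n, seed=seed))[0]
    structs = enumerate_structures(seq, cfg)
    s = structs[seed % len(structs)]
    assert read_dotbracket(write_dotbracket(seq, s)) == s
    seq2, s2 = read_ct(write_ct(seq, s))
    assert (seq2.residues, s2) == (seq.residues, s)


class TestFoldConfig:
    def test_asymmetric_pairs_rejected(self):
        with pytest.raises(DomainError):
            FoldConfig(allowed_pairs=frozenset({("G", "C")}))

    def test_bad_min_span(self):
        with pytest.raises(DomainError):
            FoldConfig(min_span=0)

    def test_bad_algorithm(self):
        with pytest.raises(DomainError):
            FoldConfig(algorithm="mfold")

    def test_default_pairs_symmetric(self):
        for a, b in DEFAULT_ALLOWED_PAIRS:
            assert (b, a) in DEFAULT_ALLOWED_PAIRS
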