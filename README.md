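# dpfold

Composable dynamic-programming engines for pseudoknot-free RNA secondary
structure prediction. Four folding strategies plug into one generic,
audited DP engine (triangular tables, span-ordered fill, traceback,
output-mode dispatch):

| strategy    | objective                                   | auxiliary storage |
|-------------|---------------------------------------------|-------------------|
| `nussinov`  | maximum number of base pairs                | none              |
| `zuker`     | minimum free energy over a loop model       | energy parameters |
| `helix`     | minimum energy over stem-region placements  | stem pool         |
| `partition` | Boltzmann ensemble: pair probabilities      | energy parameters |

Shared components: validated sequence/structure domain types (unique
partners, no crossing pairs, minimum hairpin span), FASTA / dot-bracket /
CT readers and writers, base-pair-level evaluation metrics (sensitivity X,
specificity Y, full and simplified Matthews correlation coefficient), and a
seeded synthetic-data module whose exhaustive structure enumerator doubles
as the brute-force oracle for every engine.

## CLI

```sh
# fold a FASTA file (pairs, dot-bracket, CT, or dot-plot output)
dpfold predict --in seqs.fasta --algorithm zuker --format dotbracket
dpfold predict --in seqs.fasta --algorithm partition --format dotplot
dpfold predict --in seqs.fasta --algorithm nussinov --output-mode pair_count

# compare predicted vs reference structures (CT or dot-bracket)
dpfold evaluate --pred pred.ct --ref ref.ct

# generate seeded random sequences
dpfold simulate --n 10 --length 120 --gc 0.5 --seed 7 --out sim.fasta
```

Exit codes: 2 usage error (including illegal flag combinations such as
`--pair-prob-threshold` outside partition mode), 3 invalid input sequence,
4 I/O or parse failure.

## Library

```python
from dpfold import FoldConfig, predict, validate_sequence

seq = validate_sequence("GGGAAAACCC")
result = predict(seq, FoldConfig(algorithm="zuker"))
result.score, result.structure.sorted_pairs()
```

## Conventions & notes

- Coordinates are 1-based inclusive; a pair `(i, j)` has `i < j`.
- The minimum hairpin span is `j - i >= min_span`, default `min_span = 4`
  (three unpaired hairpin bases). Set `min_span = 5` for the stricter
  "at least four unpaired bases" convention.
- Allowed pairs default to Watson-Crick plus the GU wobble; ambiguity codes
  are rejected, `T -> U` normalization and lowercase acceptance are on by
  default and can be disabled.
- The Zuker-style energy model is pluggable. The shipped default is an
  ad-hoc, documented stand-in (pair-strength stacks, logarithmic loop
  penalties) — not a published thermodynamic parameter set. Override it
  with `--energy-params params.yaml`.
- The partition mode is the pair-weighted scheme: with all pair energies
  zero, `Q(1, n)` equals the number of valid structures exactly. Long
  inputs are handled by automatic rescaling; `log_q_total` is always safe.

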