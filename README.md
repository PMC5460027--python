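# misl — mutation-specific synthetic-lethal partner mining

`misl` predicts **synthetic-lethal (SL) partner genes of somatic
mutations** directly from primary-tumour genomics: per-cancer mutation
calls, segmented copy number and expression matrices.  The premise is that
selection in growing tumours leaves footprints of genetic interactions in
copy-number data — if losing gene *B* is lethal only in cells carrying
mutation *X*, then tumours with *X* should almost never carry a deletion
of *B*, and amplifications of *B* should concentrate in *X*-mutant
tumours.  The package also includes the reverse *biomarker* mode (from a
drug's inhibited genes to the alterations that predict sensitivity), the
validation statistics used to score predictions against pooled shRNA
screens and cell-line pharmacology, and a synthetic cohort generator with
planted ground truth so the entire pipeline is testable offline.

Intended users: computational cancer-biology groups prioritising drug
targets or genetic dependencies from cohort-scale tumour data.

## The statistic

All alteration calls are Boolean variables over samples (`X:mut`,
`B:amp`, `B:del`).  For a pair of variables the 2×2 cross-tabulation
(n₁₁, n₁₀, n₀₁, n₀₀) is tested with a two-part **Boolean implication**
test:

1. **Dependence** — two-sided Fisher exact p below a cutoff (always
   < 0.05; the working cutoff is tightened until a permutation-estimated
   FDR < 0.05).
2. **Sparseness** of the forbidden quadrant — with *a* the count in the
   quadrant the implication forbids, *r* and *c* the other counts in its
   row and column, the maximum-likelihood error rate

   e = ½ · ( a/(a+r) + a/(a+c) )

   must be < 0.1.

Two implication kinds are mined.  *Deletion arm*: `X:mut ⇒ NOT B:del`
(HI-LO; the (X=1, B_del=1) quadrant is sparse — mutual exclusion).
*Amplification arm*: `B:amp ⇒ X:mut` (HI-HI; the (B_amp=1, X=0) quadrant
is sparse), computed after appending *artificial normal* samples
(all-negative columns) so near-ubiquitous alterations keep a
non-degenerate margin.

A partner must additionally be (i) **not a copy-number passenger** in
every contributing cancer — its own expression must move concordantly
with the alteration (Welch t-test p < 0.05, fold > 1.2) — and (ii)
**overexpressed in mutant samples** of the cancer of interest (Welch
t-test p < 0.05, higher mean in mutants).  Genes surviving every gate are
the SL candidates of the mutation; a mutation with ≥ 1 candidate is
*targetable*.

## Worked example

Generate a synthetic three-cancer bundle with planted SL structure, then
mine the partner of one planted mutation:

```bash
misl synth --out bundle --seed 7
misl run --cohorts bundle --mutation G0024 --cancer C1 \
         --calibrate --permutations 10 --seed 1 --out run
```

`run/candidates.tsv` (one candidate found):

```
mutation  partner  cancer_type  arm       fisher_p    error_rate  sparse_count  passenger_p  passenger_fold  overexpression_p  overexpression_fold
G0024     G0122    C1           deletion  8.4067e-15  0.0         0             3.7962e-25   2.1915          3.5024e-34        2.0141
```

Reading the row: over the pooled cancers where `G0122`'s deletion is
expression-concordant, not one sample carries both the `G0024` mutation
and a `G0122` deletion (`sparse_count 0`, error rate 0); the mutual
exclusion is far beyond chance (Fisher p ≈ 8×10⁻¹⁵); deletion of `G0122`
halves its expression (fold 2.19 — a real dosage event, not a passenger);
and `G0122` is two-fold overexpressed in `G0024`-mutant samples of the
cancer of interest.  `bundle/truth.json` confirms (`G0024`, `G0122`) is
the planted pair.  The underlying implication is also available directly:

```bash
misl implications --cohorts bundle --anchor G0024:mut --kind hi_lo \
                  --fisher-cutoff 0.0001 --out imps
# antecedent  consequent  kind   fisher_p    error_rate  sparse_count  n    cancers
# G0024:mut   G0122:del   hi_lo  8.4067e-15  0.0         0             400  C2,C3
```

Other subcommands: `misl booleanize` (raw tables → Boolean matrices),
`misl biomarkers` / `misl evaluate-sensitivity` (reverse mode),
`misl screen-hits`, `misl rank-essentiality`, `misl gsea`,
`misl pathway-enrich`.  Every run writes a `manifest.json` with the
config snapshot, input digests and seed; reruns with the same seed and
inputs are byte-identical.

## Layout

```
src/misl/
  io.py            readers/writers (TSV, BED4, GMT) with fixed column contracts
  booleanize.py    segment filtering, normal subtraction, gene-level CNA calls,
                   passenger annotation, CancerCohort
  implications.py  contingency/Fisher/error-rate, implication scans,
                   artificial normals, permutation-FDR calibration
  core.py          the forward pipeline (recurrence gate, both arms,
                   overexpression filter), config, summaries
  biomarker.py     reverse mode and IC50-quartile sensitivity evaluation
  screen.py        dropout hit calling, essentiality ranking, preranked
                   enrichment, overlap/pathway tests
  synth.py         synthetic cohorts, screens and pharmacology with truth
  cli.py           `misl` command-line entry point
docs/methods.md    modelling notes, parameter choices, limitations
```
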