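# Methods notes

This note records the model assumptions, the parameter choices that
matter, what the synthetic data does and does not emulate, and the
numerical conventions, in the package's own terms.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Model and assumptions

The miner treats tumour cohorts as draws from a population shaped by
selection: a synthetic-lethal interaction between mutation *X* and gene
*B* depletes tumours carrying both *X* and a loss of *B*.  Two footprints
are mined over Boolean alteration variables:

* **mutual exclusion** of *X* and deletions of *B* (HI-LO implication,
  sparse (X=1, B_del=1) quadrant), and
* **containment** of *B* amplifications within *X*-mutant samples (HI-HI
  implication, sparse (B_amp=1, X=0) quadrant) — extra copies of *B* are
  tolerated or favoured only when *X* is present.

Assumptions this rests on: alteration calls are binary and comparable
across cohorts; samples are independent; somatic events only (germline
CNVs assumed removed upstream); a cohort is large enough that a 2×2
cross-tabulation is informative.  Pooling across cancer types assumes the
interaction is not private to one lineage; the passenger filter is what
keeps lineage-specific broad CNAs from contaminating the pool.

### The two-part implication test

Dependence is tested with a two-sided Fisher exact test — direction-free
on purpose, since direction is supplied by the sparse-quadrant gate.  The
sparseness gate uses the symmetric conditional error estimate
`e = 0.5*(a/(a+r) + a/(a+c))` — the average of P(violation | antecedent
row) and P(violation | consequent column).  `a = 0` gives `e = 0`; a
degenerate denominator (empty row or column) gives `e = 1` (fail), since
an implication with no support should never pass.  Gates: Fisher p below
the working cutoff and `e < 0.1`.

### Artificial normals

HI-HI extraction appends all-negative samples before testing.  An
alteration present in nearly all samples has a degenerate margin (Fisher
p = 1) even when the containment is perfect; all-negative samples restore
the margin and can never violate a HI-HI sparse quadrant, so they create
no false positives for that kind.  They are *never* applied to HI-LO,
where they would inflate the (0,0) quadrant.  The count `k` defaults to
the pooled tumour sample count — large enough to make a ubiquitous
alteration's margin balanced, and scale-free with cohort size.

### FDR calibration

The Fisher cutoff is not fixed at 0.05 but tightened until the estimated
false discovery rate is < 0.05.  The null permutes each variable's sample
labels independently (implemented by independently permuting every row of
both variable matrices; the induced pairing is a uniform relabelling) and
the FDR at a cutoff is the mean null count of passing pairs over the
observed count.  Default 100 permutations (minimum 10); the chosen cutoff
is the largest grid value below 0.05 with estimated FDR < 0.05.  On the
standard synthetic conditions this calibration is what separates planted
structure from marginal chance associations: the pipeline keeps perfect
plants (Fisher p ≈ 10⁻¹⁵ and below) while dropping p ≈ 10⁻³ noise.

### Passenger and overexpression gates

A copy-number event is a *passenger* in a cohort unless the gene's own
expression moves concordantly: Welch two-sided t-test p < 0.05 **and**
anti-logged fold difference 2^|Δ log₂ mean| > 1.2, with the direction
enforced by the sign of the mean difference (deletion → lower,
amplification → higher).  Welch is used everywhere a t-test appears:
group variances differ by construction (altered sets are small), and the
directionality-by-sign convention keeps all p-values two-sided and
comparable.  Genes with fewer than two samples on either side, or absent
from the expression matrix, are passengers by convention — an untestable
event should not contribute to a pooled implication.

The final gate requires the partner overexpressed in mutant versus
wild-type samples of the cancer of interest (Welch p < 0.05, higher mean
in mutants).  It is the mutation-specific filter: a partner whose
dependence is not elevated in the mutant context is discarded even if the
pan-cancer implication is strong.

### Pooling

Implications are computed on a single pooled 2×2 over the union of
samples from the eligible (mutation ≥ 2.5% of samples) cancer types in
which the partner's alteration is non-passenger; cohorts without
copy-number data contribute no samples to implications but can still be
the cancer of interest for the expression gate.  Pooling (rather than
per-cancer voting) maximises power for rare events and is what makes the
recurrence threshold meaningful as a gate rather than a weight.

## Reverse (biomarker) mode

For a drug inhibiting gene *Y*, the same two scans run with roles
swapped: alterations *X* with `X ⇒ NOT Y:del` or `Y:amp ⇒ X`, over
cancers where *Y*'s alteration is non-passenger, then the overexpression
gate on *Y* in *X*-altered samples per cancer.  Alterations on *Y*'s own
chromosome are excluded outright — their copy-number state co-segregates
with *Y*'s and the implication would be an artefact of linkage.
Sensitivity evaluation: a cell line is *truly sensitive* if its IC50 is
in the first quartile of tested lines (linear-interpolation quantile,
ties ≤ Q1 included); drug families are pooled by per-line minimum IC50
across member drugs; predicted-vs-true overlap is a two-sided Fisher
test.  A tissue-matched restriction is available as a parameter.

## Screen statistics

*Dropout hit calling* (barcode-count screens): constructs with baseline
reads < 100 are dropped; genes with < 3 surviving constructs are dropped;
a construct qualifies at > 20% read reduction (ratio < 0.8); a gene is a
hit when ≥ 2 constructs qualify **and** the mean ratio over its
qualifying constructs is < 0.6.  The two gates are separately switchable
parameters; the conjunction is the operative default.

*Essentiality ranking* (per-cell-line score screens): per construct a
Welch t-test of mutated vs wild-type lines; per gene the minimum-p
construct; score `-log10(p) × (mean_wt − mean_mut)`, so genes more
depleted in mutant lines score positive; descending order with
alphabetical tie-break.

*Preranked enrichment*: weighted Kolmogorov–Smirnov running sum (hit
steps ∝ |score|^weight, default weight 1; miss steps uniform), ES the
signed maximum deviation.  The null permutes gene-set labels.  The
nominal p is computed against the same-sign portion of the null — the
standard preranked convention, and the one under which null p-values are
uniform; NES divides ES by the mean |null ES| of the same sign.  The
≥ 25-gene overlap gate reflects the instability of the running-sum
statistic for small sets; it is a parameter (`min_overlap`) so toy
fixtures can exercise the machinery.

*Pathway enrichment*: hypergeometric tail over pathways that contain the
mutated gene and have ≤ 500 members; among pathways with identical
candidate-overlap sets only the smallest-p survives, and overlap sets
strictly contained in another's are dropped.

## Synthetic data: what it emulates, what it does not

The generator plants exactly the signals the miner assumes: subset/
mutual-exclusion structure between planted pairs (leak rate 0 by
default), dosage-concordant expression shifts for every non-passenger
CNA, passenger CNAs with no expression shift, and a mutant-
overexpression program for planted partners in the cancer of interest.
Planted partners receive the dosage shift only *outside* the cancer of
interest, so the final overexpression gate is fed by one signal and each
pipeline filter can be ablated independently — removing the
overexpression program zeroes recall without touching the implication or
passenger signals.

Parameter defaults define the standard study conditions (3 cancers × 200
samples, 500 genes, 10 HI-LO + 10 HI-HI plants, 50 passengers, effect
1.0 log₂, expression noise sd 0.4, seed 7).  Background rates — mutation
0.08, amplification/deletion 0.04 each per gene and sample, planted
anchor mutation frequency 0.30, planted partner alteration rate 0.30,
passenger rate 0.15, log₂ expression baseline 5.0 — were chosen once as
magnitudes typical of recurrent somatic events in cohort data and are
not tuned per experiment.

Not emulated: mutational signatures and hotspot structure, GISTIC-like
CNA length/recurrence distributions, count-level RNA-seq noise,
inter-gene expression correlation, tumour purity, subclonality.
Consequently, passing tests demonstrate the statistics recover the
structure they are designed for at realistic effect sizes and sample
counts — not that real-cohort confounders (broad co-amplification,
expression covariance along chromosomes) are overcome; on real data the
passenger filter and FDR calibration carry that burden.

## Numerical conventions and degenerate inputs

* Coordinates 0-based half-open everywhere; conversion happens only in
  readers.  Gene–segment assignment needs ≥ 1 bp overlap (configurable
  minimum fraction); a gene hit by both signs in one sample is set false
  in both matrices.
* A 2×2 with any zero margin has Fisher p = 1 (no evidence of
  dependence).
* Output ordering is fully deterministic: implications by (Fisher p,
  error rate, antecedent, consequent); rankings break ties
  alphabetically; all randomness flows from explicit seeds, with
  per-artifact child streams in the generator so adding an artifact never
  perturbs existing ones.
* Vectorised scans compute each distinct 2×2 table's Fisher p once
  (tables repeat heavily across gene pairs); the scalar and vectorised
  paths are checked for exact agreement in the test suite.

## Problem sizes used in the checks

The test suite and acceptance script run at the standard conditions
above, with: 1,000 random mini-cohorts (≤ 20 variables × ≤ 100 samples)
for the scan/brute-force equivalence; 10,000 random tables (total ≤ 60)
for the Fisher oracle; 200 null cohorts of 300 genes × 200 samples for
the calibration bound (cutoff calibrated once on an independent null
cohort, 20 permutations); 500 random gene sets at 300 permutations each
for null-p uniformity; 20 independent 1,000-gene screens for the ranking
check; FDR calibration in the recovery runs uses 10 permutations.  These
sizes are the package's fixed verification conditions.

## Known limitations

* Gene identity is the uppercased symbol string; no alias resolution.
* Only the HI-HI and HI-LO implication kinds are implemented (the kinds
  the miner needs), not the full implication taxonomy (LO-LO,
  equivalence) or implication networks over expression variables.
* Passenger annotation is per-gene marginal; it does not model joint
  segment structure, so a dense passenger region is tested gene by gene.
* The permutation FDR treats variables independently; correlated
  alterations (co-amplified neighbours) make the null slightly
  optimistic — another reason the calibrated cutoff, not 0.05, is the
  operating point.
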