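# Methods

## Design and data model

The unit of analysis is one tissue's genes × samples matrix of RPKM
values over three cohorts: young (1W), aged (4W) and aged-treated
(4W-IF). Tissues are never pooled: every statistic is computed within a
tissue over all of its cohorts. Cohorts are replicate groups —
triplicates for head-style designs, duplicates for thorax-style ones —
and duplicates are the supported minimum (the SD of a duplicate pair is
|x₁ − x₂|/√2 under the n−1 convention used everywhere; we use n−1
throughout because it is the unbiased default of every mainstream
statistics stack, and at n = 2 the choice is material).

Input files are plain TSV/CSV (matrix), TSV (sample sheet) and GMT
(gene sets). Missing cells are errors, never imputed: all statistics
assume complete replicate matrices. Outputs are full-precision TSV so
that runs diff cleanly; identical config + seed reproduce tables
byte-for-byte.

## Expression filter

A gene enters the tissue's universe iff its value exceeds `min_rpkm`
(default 1.0) in **every** sample of the tissue, all cohorts jointly —
a single low replicate removes the gene. The inequality is strict, as
are all cutoffs in the package. Filtering per tissue (not per cohort)
gives one gene universe per tissue on which fold changes, drift and
variance statistics are all computed; a per-cohort variant would make
the universes incomparable across contrasts.

## Fold-change classification

Fold change is the linear ratio of arithmetic cohort means,
FC = x̄(num)/x̄(den), applied symmetrically: a gene changes iff
FC > cutoff or FC < 1/cutoff (age cutoff 1.4 on 4W/1W, treatment cutoff
1.3 on 4W/4W-IF; both configurable). A geometric-mean variant
(2^(mean log2 difference)) is available via `fc_scale="geometric"`; the
linear ratio is the default because "1.4-fold" is only meaningful on
the linear scale. The treatment ratio keeps the aged cohort in the
numerator, so "IF up" — expression restored upward — corresponds to
FC < 1/1.3; this is the easiest sign to get wrong and is asserted by
dedicated tests. "IF more youthful" = (age down ∧ IF up) ∨ (age up ∧
IF down). "Change with IF" counts any gene past the 1.3 cutoff
independently of its age status; `require_age_change_for_if=True`
switches to the conjunctive reading.

Per-gene p-values come from a two-sided Welch (unequal-variance) t-test
on log2 values — the minimal defensible location test at 2–3
replicates. Classification uses only the fold-change cutoffs; p-values
and a Benjamini–Hochberg column are reported for reference. Note that
at n = 3 the Welch–Satterthwaite approximation is imperfect: under a
true null its p-value distribution deviates from uniform by an amount a
KS test detects once several thousand genes are pooled. The calibration
check therefore uses 1000 genes, where the approximation error sits
below the KS detection threshold; this is a property of the test, not
of the implementation.

## Drift and drift-variance

Drift is d(g, s) = log10[x(g, s)/x̄(g, young)] per gene and sample,
young-cohort replicates included. TD of a cohort is the sample variance
of d pooled over all genes and the cohort's replicates (the drift-plot
construction; `drift_pool="cohort_mean"` pools per-gene means of drift
instead).

Significance of a TD difference between cohorts a and b uses a
gene-level permutation test: genes are the exchangeable units (drift
values are dependent within a sample and heavy-tailed across genes),
each gene independently swaps its a- and b-replicate drift vectors with
probability ½, the statistic is |TD_a − TD_b|, and
p = (1 + #{permuted ≥ observed})/(1 + permutations) with a fixed seed.
The implementation is vectorised over permutations via per-gene
sums/sums-of-squares, so 999 permutations on 10⁴ genes cost a few
matrix products.

**Reference-cohort asymmetry.** Because young drift values are centred
by their own cohort mean, the young TD is deflated by construction
(within-gene variance shrunk by 1 − 1/n) while every other cohort's TD
is inflated by reference-mean noise (≈ 1/n of the young noise
variance). Two consequences, both deliberate and documented rather than
"corrected" away: (i) the young box of a drift-plot hugs zero partly by
construction; (ii) the permutation test is exactly calibrated only when
*neither* compared cohort is the reference — aged vs treated is the
clean null comparison, whereas aged vs young mixes genuine dispersion
change with the anchoring effect and should be read as a power-oriented
comparison in the spirit of the drift-plot stars.

## VZ, VC and scaled profiles

VZ(g, c) = SD/mean of replicates (coefficient of variation); VC is the
VZ ratio between two cohorts, regularised as (VZ_a + ε)/(VZ_b + ε) with
ε = 10⁻⁶ so zero-SD genes stay finite, and set to exactly 1 when both
VZ vanish. High-VC means VC > 3.75 strictly (3.5 is the documented
alternative for focussed gene-set profiles). The three reported
contrasts are 4W/1W, 4W/4W-IF and 1W/4W-IF, each with the first-named
cohort in the numerator as printed. Scaled VZ profiles divide each
gene's VZ by its maximum across the two compared cohorts, mapping every
gene into (0, 1] for scatter displays.

VC at 2–3 replicates is intrinsically noisy: a direct Monte Carlo bound
(reproduced in the test suite) shows that ranking genes by VC
distinguishes dispersion-inflated genes (CV 1.0 vs 0.3 after partial
treatment suppression) from stable ones (CV 0.2 both cohorts) with
AUROC ≈ 0.79 at n = 3 — no estimator can do better from the same three
numbers per cohort. Single-gene VC calls at this depth are screening
hypotheses, not measurements.

## Synthetic-data generator

The generator emulates the statistical skeleton of the targeted study
design, not its biology: per-gene baseline RPKM is log-normal
(ln-mean 2.5, ln-SD 1.5, putting ~90% of genes above the 1-RPKM filter);
a fraction of genes (6% up + 6% down by default, ≈ 1200 of 10⁴ —
matching the scale of age-responsive genes in the targeted design) have
their aged mean multiplied/divided by `age_effect_fold` (2.0); 20% of
those are "restored" (treated mean returns to the young mean); 15% of
genes are "drift" genes whose replicate CV is multiplied by 4 in the
aged cohort and 1.5 in the treated cohort from a base CV of 0.2. The
drift multipliers are calibration choices — no empirical magnitude for
the dispersion inflation is available — selected so the generated TD
ordering and drift-plots resemble the published pattern qualitatively.
Replicate noise is multiplicative log-normal with unit mean and the
target CV (σ² = ln(1 + CV²)), keeping RPKM positive and making CV and
log-ratio statistics exact on the noise law. Planted assignments slice
seeded permutations, so fractions give exact counts; identical
(spec, tissue, seed) give bit-identical output.

What the generator does **not** emulate: count-level (negative
binomial) noise, gene–gene correlation, length/GC biases,
heteroscedastic baseline CV, or compositional constraints of RPKM.
Passing recovery tests therefore demonstrates that the statistics
recover the planted structure under idealised replicate noise — not
that they would behave identically on real libraries.

## Problem sizes and numerical choices

Simulation-based checks run at 10⁴ genes × 3 replicates/cohort for
recovery and drift ordering (20 seeds, 999 permutations), 300 genes ×
200 seeds × 199 permutations for null calibration, and 2000 genes × 20
seeds for VC rank-recovery — sizes chosen to estimate each rate with
comfortable margins while keeping a full run in minutes on one CPU.
Degenerate inputs are handled explicitly: constant rows z-score to
zeros with a warning, single-replicate cohorts yield missing p-values
(warning) and are rejected for VZ, a cohort compared with itself gives
p = 1, and p = 0 is clamped to the smallest positive float before
−log10. Tie handling in the permutation test counts permuted
statistics within 10⁻¹⁵ of the observed value as exceedances
(conservative).

## Known limitations

- No between-sample normalisation (TMM/quantile): RPKM are taken as
  given, matching the upstream pipeline this package consumes.
- Raw p-values drive nothing, but they are reported unadjusted in the
  classification table by design; the BH column is advisory.
- The aged-vs-reference TD comparison conflates anchoring with
  dispersion change (see above); a reference-free dispersion contrast
  is available by comparing the two non-reference cohorts.
- The hypergeometric over-representation step is a generic stand-in for
  curated functional-annotation services; the shipped GMT fixture has
  random membership and exists to exercise the code path.
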