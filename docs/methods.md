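# Methods

This note documents the models, conventions and design choices behind
`bindsig`, in the spirit of a statistical-software methods appendix. No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` compute.

## Total Binding Affinity

A motif's position frequency matrix (PFM) of counts `c[b, j]` is converted
to probabilities with a Laplace pseudocount `a` (default 1.0 per cell):
`p[b, j] = (c[b, j] + a) / (Σ_b c[b, j] + 4a)`. With `a > 0` every
probability is strictly positive, so log-scores are finite.

TBA of a window is the sum over both strands and every full-length start
of the product of per-position probability/background ratios. Design
choices:

* **Window convention.** Coordinates are 0-based half-open throughout.
  The default promoter window is `[TSS − 756, TSS + 235)`, 991 bp, with
  the TSS at relative offset +756; the −756/+235 extent matches the
  experimentally mapped responsive promoter region that motivated the
  score. Because a "+1 base" convention is not uniquely defined for this
  kind of window, the half-open mapping was chosen so that window length
  is exactly `upstream + downstream`. On the − strand the window is
  `[TSS − downstream + 1, TSS + upstream + 1)` reverse-complemented, which
  is the exact mirror image of the + strand case (verified by a
  palindrome/mirror oracle test).
* **Background.** Default uniform (0.25 each); configurable as four
  probabilities. A genome-composition background can be supplied when the
  target genome is skewed.
* **Ambiguous bases.** Sub-windows containing `N` contribute 0 and are
  excluded from `n_windows`, avoiding background-dependent imputation bias
  in assembly gaps.
* **log TBA** is the natural log of the strand-summed TBA (not a sum of
  per-site logs), preserving the "total affinity" semantics in which many
  weak sites add up.
* **Ranking.** Motifs are ranked by raw log TBA by default. Raw TBA is not
  comparable across motifs of very different length/information content,
  so an optional mode re-ranks by an empirical z-score against
  `n_shuffles` mononucleotide-preserving shuffles of the window (seeded);
  it is off by default because the nominating analysis ranked raw TBA.

The implementation is a vectorized strided product; a brute-force
enumeration oracle (materializing every window and its reverse complement)
bounds it to 1e−10 relative error on random instances, and strand-reversal
invariance plus split-additivity are tested as exact invariants.

## Peak-to-gene assignment

* **Distance.** "Absolute distance 5 kb from the closest gene" is read as
  the edge-to-edge gap between the peak interval and the *gene body*
  (0 when overlapping), inclusive: retained iff gap ≤ 5000. TSS-anchored
  assignment is a defensible alternative; the gene-body reading follows
  the "closest gene" phrasing and is documented rather than resolved.
* **Uniqueness.** Each peak maps to exactly one gene; equidistant ties
  break by smaller gene start, then lexicographic gene id, making output
  deterministic.
* **TSS offsets** use the peak midpoint `⌊(start+end)/2⌋` (clustered peak
  tracks carry no summit column), sign-flipped on − strand genes so
  negative always means upstream.
* Pooling of per-cell-line tracks is left to the caller; `merge_beds`
  concatenates and sorts. A gene with several retained peaks counts once
  in the dual-bound set.

An all-pairs quadratic scan oracle checks closest gene and distance on
random instances; monotonicity (shrinking the distance cap never grows the
dual set) and reflection symmetry are property-tested.

## Enrichment and signature

* The universe defaults to all gene ids in the provided annotation.
  P-values depend strongly on this choice, so the universe size is
  reported in every result row.
* The test is the one-sided hypergeometric upper tail `P(X ≥ k)`
  (equivalently Fisher's exact test for enrichment); two-sided is
  available by flag. The odds ratio uses the standard 2×2 cross-product
  with `0/0 → NaN` and `x/0 → +inf`.
* Selection of the two top sets uses raw p < α (default 0.05) with ties
  broken by larger overlap percentage then name; BH q-values are computed
  and reported but deliberately do not drive selection, mirroring the
  original raw-p selection across 17 candidate sets.
* Gene ids are uppercased and whitespace-stripped on ingest. No
  ortholog/alias mapping is attempted; mixed-species symbol lists must be
  harmonized upstream.
* The signature is `(dual ∩ A) ∪ (dual ∩ B)`; its size is
  `|dual∩A| + |dual∩B| − |dual∩A∩B|`, which the tests pin with the
  published worked counts (32 and 113 overlapping in one gene → 144).

Exactness is bounded by a rational-arithmetic hypergeometric enumeration
oracle (1e−12 relative) on random small tables.

## Survival and GLMs

* **Score**: unweighted sum of signature-gene expression per sample;
  missing genes are skipped with a logged coverage fraction, and a zero
  overlap is an error.
* **Median split**: median is the 50th percentile (midpoint of the middle
  two for even n); "high" requires score *strictly above* the median, so
  ties go to "low" — deterministic and reported. For odd n with distinct
  scores this makes |low| = |high| + 1.
* **Kaplan-Meier**: product-limit over distinct event times; samples
  censored at an event time remain at risk there (censoring ordered after
  deaths at ties).
* **Log-rank**: unstratified two-sample form with the hypergeometric
  variance `V_j = d_j (n_1j/n_j)(1 − n_1j/n_j)(n_j − d_j)/(n_j − 1)`;
  χ² on 1 df. Zero total events yields p = 1 with a warning rather than an
  error.
* **GLMs**: the score is standardized (mean 0, SD 1) before fitting. For
  non-binary covariates a Gaussian linear model `score ~ feature` is fit
  in closed form (slope, SE, t, p). For binary covariates logistic
  regression `feature ~ score` is fit by IRLS (tolerance 1e−8 on
  coefficients, max 100 iterations) with a Wald z test. The direction
  (score as response vs predictor) is genuinely ambiguous in this class of
  univariate screens; the implemented default follows the
  "score vs clinical features" construction, and `binary=` lets callers
  force either family. Non-convergence or separation returns a flagged
  result with NaN SE instead of raising.
* No Cox model is included: the pipeline mirrors a KM + log-rank + GLM
  analysis exactly. Times are in days; no administrative truncation.

lifelines (KM/log-rank) and statsmodels (OLS/Logit) are used in the test
suite as independent oracles at 1e−6/1e−4 tolerances; the pipeline itself
never imports them.

## Synthetic-data generator

The generator emulates the statistical structure of the study's real
inputs (clustered ChIP-seq peak tracks for two TFs; curated pathway sets;
a breast-cancer cohort with expression and overall survival) at desk
scale. Per-generator RNG streams are derived from the master seed by fixed
offsets (`default_rng([stream, seed])`), so outputs are bit-reproducible
and mutually independent.

Defaults (one value each, chosen for a realistic, testable desk-scale
study; the cohort effect size is a testability choice because the
emulated cohort's hazard ratios are not published):

| parameter | default | rationale |
|---|---|---|
| n_genes / chrom_length | 300 / 6 Mb | ~20 kb gene pitch, ≥ 12 kb spacing so the 5 kb rule is unambiguous |
| n_peaks_per_tf | 200 | 70% genic (genic_peak_fraction), rest intergenic > 5 kb from any gene by construction |
| co_binding_fraction | 0.3 | 42 dual-bound genes at defaults |
| peak_width / tss_placement_sd | 200 bp / 300 bp | genic peaks centered Normal(TSS, sd): TSS-proximal like real promoter binding |
| n_gene_sets / gene_set_size | 17 / 60 | seventeen candidate sets, two planted |
| planted_set_overlap | 0.4 | planted sets draw 40% of members from the dual-bound truth |
| n_samples | 300 | log-rank power at hazard ratio 3 ≈ 1 |
| expression_log_mean / sd | 8.0 / 1.0 | log2-microarray-like scale |
| high_group_shift_sd | 1.0 | latent "high" shift on signature genes, in expression SDs; makes the median split concordant with truth at default n |
| hazard_ratio_high_vs_low | 3.0 | detectable planted effect |
| baseline_hazard | 5e-4 /day | median low-group survival ≈ 1400 days |
| censoring_rate | 2.5e-4 /day | independent exponential censoring, ~2/3 events observed |

Structural choices: one synthetic chromosome (the 5 kb rule and TSS
windows are intra-chromosomal); exponential survival with independent
exponential censoring (the simplest proportional-hazards model, matching
the log-rank stage's assumption); peaks simulated directly as intervals
(no read-level simulation or peak calling); no copy-number, subtype or
multi-omic structure. Clinical covariates (grade 1–3, binary ER and
chemotherapy, age, positive lymph nodes) are drawn with fixed dependence
on the latent high/low group so GLM recovery has a known sign.

What passing tests show — and do not show — about real data: the
generator's expression is homoscedastic Gaussian on the log scale with a
single latent group, peaks have uniform width, gene sets are exchangeable
draws, and censoring is independent. Real cohorts have batch structure,
correlated genes, informative censoring and probe-level summarization;
recovery of planted truth here validates the *code paths and statistics*,
not the biological robustness of any particular signature.

A note on null calibration: a null gene set must be drawn independently of
the dual-bound list from the whole universe for its Fisher p to be
approximately Uniform(0,1); a set constructed to avoid the dual list has
overlap 0 and p exactly 1. The calibration tests use wide table margins so
the discrete hypergeometric p-value is near-continuous before applying the
KS uniformity check.

## Problem sizes and numerical details

Tests and the acceptance script run at desk scale as the package's own
validation design: 200 random TBA instances (windows ≤ 50 bp, motifs
≤ 6 bp) against brute force; 500 random Fisher tables against rational
enumeration; 300 random peaks against an all-pairs scan; 50 random cohorts
against lifelines; 400 replicates for log-rank size at hazard ratio 1 and
100 for power at hazard ratio 3; 100 replicates for planted-set recovery
at overlap 0.8 (|set| = 100, |truth| = 200, universe 5000). Determinism:
all simulations are seeded; plots are rendered with a fixed SVG hash salt
and no date metadata so identical inputs give byte-identical files.

Known limitations: no probe→gene summarization (one expression row per
gene is assumed); no PAM50/subtype logic (sensitivity analyses are done by
pre-filtering the clinical table); no liftover, no signal-value weighting
of peaks, no GSEA-style ranked enrichment; the TBA stage scores one
promoter per invocation in the CLI (the library scores arbitrary windows).
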