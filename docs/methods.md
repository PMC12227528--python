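# Methods

`scburden` re-implements, as a reusable and tested pipeline, the statistical
machinery of case-control single-cell/single-nucleus RNA-seq studies in which
cells from the same donor are not independent: a two-part (hurdle)
differential-expression test wrapped in donor-balanced resampling, a
donor-label permutation null, fixed-size resampled DEG-burden comparison
between cell types, pseudotime differential-dynamics scoring, and gene-list
concordance statistics.  A synthetic generator with known ground truth is a
first-class component: every statistical guarantee the test suite asserts is
stated with respect to that generator.

## The hurdle test

Expression of gene *g* in cell *c* on the log-normalized scale
(`y = ln(1 + 10^4 · count / total UMI)`) is modelled in two parts on a shared
design `X` (intercept, diagnosis, detection rate `cngeneson`, age, sex,
capture/sequencing batch, optionally region or other covariates):

- detection: `1[y > 0] ~ Bernoulli(logit^-1(X β_det))`, fitted by IRLS;
- continuous: `y | y > 0 ~ Normal(X β_cont, σ²)`, fitted by least squares.

The test statistic for a term is the sum of the two components'
likelihood-ratio chi-squares, referred to χ² with df = number of estimable
components.  Degenerate components (all-detected, all-positive-equal, fewer
than 3 usable cells, collinear term) contribute zero with reduced df rather
than dropping the gene, keeping the gene universe stable for BH correction.

The combined fold change follows the two-part convention: predicted mean
expression is `detection probability × positive-component mean`, evaluated at
covariate means with the diagnosis term set to case resp. control, and the
difference is reported on the log2 scale.  Note the two consequences that
matter in practice and that the synthetic benchmarks make visible:

- detection noise enters the combined fold change multiplied by the mean
  expression level, so null genes have heavier-tailed fold-change estimates
  than the continuous component alone would suggest;
- the estimate is attenuated by the detection probability and by log1p
  curvature; at the generator's defaults (baseline negative-binomial means
  10–60 counts, detection 0.82–0.97 with a +1 logit shift for up-regulated
  genes) these effects approximately cancel and the median recovered log2 FC
  of true ±1 genes is 0.93–0.98.

The components are deliberately fixed-effect (no per-gene random intercept):
donor-level dependence is handled by the resampling routine and the
permutation null below, which are exact at the donor level, rather than by a
from-scratch logistic mixed model.  The IRLS/OLS fitters are written
in-package because the pipeline fits tens of thousands of small GLMs per run;
they are verified against statsmodels in the test suite.

## Donor-balanced resampling and calling rule

Per cell type: donors contributing fewer cells than `contributor_min_frac`
(default 0.25) times the per-donor average are removed; an equal number of
cells (the minimum over retained donors) is drawn from every retained donor;
the per-gene test runs on that subset; the routine repeats `n_repeats`
(default 10) times and the per-gene p and model log2 FC are the medians
across repeats (an unspecified aggregation in the source design; the median
is used for robustness).  A gene is *called* when BH q < 0.05, |model
log2 FC| ≥ log2(1.14), and the |log2 FC| of a covariate-free refit on the
full cell set ("raw" fold change) is ≥ 0.1.  The raw-refit filter removes
genes whose apparent fold change is carried by covariates.  The 0.1 cutoff is
interpreted on the log2 scale; region-restricted contrasts reuse the same
code path with the region covariate dropped and `fc_threshold = 1.10`.

## Donor-label permutation null

Diagnosis labels are permuted across donors (all cells of a donor move
together, group sizes preserved), the full pipeline statistic is recomputed,
and empirical per-gene p-values pool the permuted chi-squares of all genes —
with the conventional 10 permutations a per-gene null alone would have
resolution 1/11.  The empirical FDR at the calling threshold is the mean
permuted call count over the observed call count, capped at 1.  When fewer
distinct donor-label assignments exist than requested, all of them are used
and the count is recorded.  Permutations re-run the same balanced-resampling
routine as the observed statistic; `DEConfig.n_repeats = 1–2` is used for
permutations in the acceptance runs to keep the cost proportionate.

Pooling across genes calibrates the *average* rejection rate exactly under
exchangeability, not each gene's p individually; genes with atypical null
variance borrow an averaged null.  This is the intended trade-off at 10
permutations.

## DEG burden

Cluster sizes differ by orders of magnitude and DEG counts grow with cell
number, so cell types are compared on equal footing by drawing a fixed number
of cells (default 500) per diagnosis group, running the hurdle test with the
full covariate design (no donor balancing — the fixed draw is the
normalizer), counting called genes, and repeating (default 10 replicates).
Draws are stratified by diagnosis group only; donor composition is left
random, which is part of what the replicate spread measures.  Cell types are
compared by exact two-sided Mann-Whitney U tests on replicate DEG counts
(exact null for ≤ 20 per side without ties, tie-corrected normal
approximation otherwise), BH-adjusted over pairs.

## Trajectory differential dynamics

Lineages (ordered cells, pseudotime, 2D embedding) are inputs, not inferred.
Per condition:

1. *Dynamic screen*: Moran's I on covariate-residualized expression over a
   union-symmetrized, row-standardized kNN graph (k = 15) of the embedding,
   with randomization moments and a one-sided normal p.  Genes with BH
   q < 0.05 and z ≥ 10 are dynamic; the published rule "Moran's I ≥ 10" can
   only denote the z-statistic, since the coefficient is bounded near 1 — the
   threshold is therefore applied to z (configurable to I).  The union over
   conditions defines the candidate set.
2. *Meta-cells*: sliding windows along pseudotime, window length
   `max(2, ceil(n_cells/50))`, evenly spaced starts, up to 500 windows;
   meta-cell expression is the window mean, meta-cell pseudotime the window
   mean pseudotime.  The window rule is a package choice (unstated in the
   source design) sized so 500 meta-cells tile the lineage with ~50% overlap.
3. *Smoothing*: tricube-weighted local-linear regression, span 0.3 of
   meta-cells, evaluated on a 500-point grid over the intersection of the two
   conditions' pseudotime ranges.  Local-linear smoothing reproduces constants
   and linear trends exactly, which the tests assert.
4. *Score*: the differential expression score is |AUC_case − AUC_control| by
   the trapezoid rule, in pseudotime × log-expression units; genes scoring
   ≥ 50 are called.  The score is shift-invariant but scales with expression
   units; a scale-free variant (score / pseudotime range) is available.
5. *Pathways*: member genes are averaged per meta-cell and log(1+·)
   transformed; condition differences per gene are tested by permuting
   condition labels within pseudotime bins (statistic: integrated squared
   difference of smoothed curves; 200 permutations), BH-adjusted, and
   combined with the logit method
   (`C = -Σ logit(p_i)`, `t = C / sqrt(k π² (5k+2) / (3(5k+4)))`, upper tail
   of Student's t with 5k+4 df).  This permutation pattern test replaces a
   GAM-based per-gene test with the same null semantics; equivalence is not
   claimed.

## Concordance statistics

Hypergeometric enrichment uses the detected-gene universe as background with
exact log-combinatorics; Fisher overlap is the exact conditional two-sided
test; fold-change correlation is Pearson on log2 FC over either the union of
tested genes or the intersection of called genes, with a sign-concordance
fraction over shared calls; TF-target projection takes the union of a
TF→target map over differentially expressed TFs and reports coverage of a DEG
list plus unadjusted hypergeometric enrichment; cluster similarity correlates
per-cluster CPM-log profiles over the union of top-20 one-vs-rest markers
(mean log-expression difference ranking — a simple deterministic choice where
the source design names none).

## The synthetic generator

`simulate_dataset` draws hurdle-structured counts per donor and cell type:

- detection `~ Bernoulli(logit^-1(a_g + u_gd + x_c'γ_g + s_g Δ_det 1[case]))`,
  gene intercepts `a_g ~ U(1.5, 3.5)` (detection 0.82–0.97);
- positive counts `~` zero-truncated NB with
  `log mean = m_g + ct_offset + u_gd + x_c'β_g + s_g ln(2) f 1[case]`,
  `m_g` log-uniform over means 10–60 counts, dispersion θ = 2
  (variance = μ + μ²/θ);
- donor intercepts are *gene-specific*, `u_gd ~ N(0, donor_sd²)` (default
  0.05, the calibration scenarios set 0 or 0.5 explicitly): a donor effect
  shared by all genes would be removed by depth normalization and the
  detection-rate covariate and could not create the pseudoreplication the
  permutation null exists to absorb — gene-level donor variation is also what
  a per-gene random-intercept model targets;
- DE genes (fraction `frac_de` per cell type, optionally per-type) receive
  ±`log2fc_de` on the positive mean and ±`detection_shift_de` logits on
  detection, with the sign drawn at the *flux-balancing* probability
  `P(up) = w_dn / (w_up + w_dn)`, `w_up = 2^f r_up − 1`,
  `w_dn = 1 − 2^−f r_dn` (r = detection ratios): with symmetric signs a 2×
  up-gene adds more UMIs than a 0.5× down-gene removes, the case library
  composition shifts, and every null gene acquires a real relative-abundance
  change on the depth-normalized scale — i.e. the nominal truth (null
  log2 FC = 0) would be false on the scale the method estimates.  Balancing
  the expected flux keeps null genes at zero; the residual random shift is
  ≤ ~0.03 log2 units at the default design;
- covariates (age, sex, capture batch) act through per-gene coefficients with
  small sds and are emitted in the cell table.

`simulate_lineage` draws pseudotime uniformly, gives dynamic genes smooth
low-order cosine mean curves (amplitude 1) on the log-normalized scale around
baselines 3.5–5.5 (high enough that divergence excursions never clip at
zero, keeping the recorded truth exact), adds a condition-specific bump
(rectangle by default, raised cosine optionally) over the middle half of the
pseudotime range with exact analytic AUC gap recorded as truth, Gaussian
noise (default sd 0.2), and an embedding `(t, 0) + N(0, 0.2²)` so kNN
neighborhoods track pseudotime.  The `norm` layer carries the generated
values directly and counts are the inverted log1p transform at fixed depth,
so truth is stated on exactly the scale the scoring operates on.

What the generator does *not* emulate: gene-gene correlation, batch
integration artifacts, ambient RNA, doublets, cell-type proportion shifts,
or empirically calibrated mean-dispersion relationships.  Passing tests
demonstrate correctness of the statistical machinery under the declared
model, not performance on any real tissue.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale designs chosen as the package's
own benchmark sizes: 5+5 donors; 150 cells/donor (calibration; at 60
cells/donor the detection-component LRT's χ² approximation is visibly
anticonservative for ordinary GLM-asymptotic reasons) or 200 cells/donor
(recovery); 2,000 genes for calibration, 1,000 for recovery, 300 for burden
and trajectory runs; 20 donor-label permutations; 10 burden runs with 3
replicates of 500-cell draws.  The recovery scenario sets `donor_sd = 0` to
isolate estimation error: with donor effects present the analytic p-values
are anti-conservative by construction — that behavior is itself asserted,
separately, by the permutation-null scenario.

Other numerics: IRLS runs at most 50 iterations with step halving and treats
(quasi-)separated fits by their converged likelihood; empirical p-values use
the add-one rule `(1 + #{null ≥ obs}) / (1 + pool)`; BH is the standard
step-up; Mann-Whitney switches to the tie-corrected normal approximation
beyond n = 20 per side or under ties; all randomness flows through
`numpy.random.SeedSequence` keyed by (seed, cell type, repeat) with strings
hashed by crc32, so every result is reproducible cross-platform from a single
integer seed.

## Known limitations

- The analytic hurdle p-values assume independent cells; with donor effects
  they are anti-conservative and only the permutation quantities are
  calibrated.  This is by design and demonstrated in the tests.
- Pooled empirical p-values are average-calibrated, not per-gene calibrated.
- The combined fold change is unit-dependent (log-normalized scale) and
  attenuated at low detection; the DE-score threshold of 50 likewise carries
  pseudotime × expression units.
- The permutation null at 5+5 donors has only 252 distinct assignments; with
  fewer donors resolution degrades and the code falls back to full
  enumeration.
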