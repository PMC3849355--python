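# Methods

This note documents the statistical procedures `ionsig` implements, the
design choices made where the underlying method left them open, and what the
synthetic-data generator does and does not emulate.

## Preprocessing model

Cohorts are log2 expression matrices (genes × samples) with aligned clinical
records. Three filters mirror standard microarray practice:

- **Detection filter** — keep genes flagged present in at least one third of
  samples (inclusive bound). Requires an externally supplied presence
  matrix; computing detection calls from raw probe intensities is out of
  scope, and the filter refuses to run silently without the matrix.
- **Annotation collapse** — probes without a single unambiguous gene symbol
  are dropped, as are probes on chromosomes X/Y (sex confounding). When
  several probes remain for one gene, the probe with the highest mean
  expression represents it. This reconciliation rule is a documented choice:
  it is deterministic and common practice, but other conventions (e.g.
  highest variance) exist.
- **Catalog subset** — case-insensitive intersection with the 280-gene
  ion-channel catalog; catalog genes absent from a cohort are logged as
  unavailable and later skipped by the scorer.

Missing clinical values are an explicit unknown state (never zero) and are
excluded listwise per analysis.

## Screens

Differential expression uses Welch's unequal-variance *t*-test by default
(the pooled-variance variant is a switch; with group sizes of ~60 vs ~190
the two differ little, and Welch is the safer default when variances are
not known to be equal). BH adjustment runs over exactly the genes tested in
the call, so a panel-only analysis and a genome-wide analysis have different
adjustment universes, as they should. The DE criterion is adjusted *P* <
0.05 together with fold change above 1.25 **in magnitude** — the threshold
applies symmetrically (FC > 1.25 or FC < 0.8), since down-regulated genes
are reported with FC < 1.

The grade screen computes tie-aware Spearman correlations (Pearson on
midranks) with the *t*-approximation for the two-sided *P*-value,
*t* = ρ√((n−2)/(1−ρ²)) on n−2 df. With cohort sizes in the hundreds the
distinction from an exact test is immaterial; an exact permutation *P* is
available for n ≤ 9. Genes with zero expression variance are untestable and
excluded with a warning rather than poisoning the BH universe.

Enrichment uses the two-sided Fisher's exact convention that sums all table
probabilities no greater than the observed table's. Gene-list overlap
significance is the upper hypergeometric tail P(X ≥ observed).

## Risk score and dichotomization

The score is the ρ-weighted sum of per-gene z-scores. Numerical contracts:

- μᵢ, τᵢ use the scored cohort's own samples and the n−1 sample SD. Frozen
  discovery-cohort standardization is deliberately **not** offered: scoring
  each cohort internally is what makes cohort score distributions centered
  (mean exactly 0; median within 0.2 SD of 0 on simulated cohorts of
  n = 250) and the median threshold meaningful per cohort.
- Signature genes absent from a cohort are summed over without reweighting;
  `genes_used` records the subset, and a warning fires below 80% coverage.
  A zero-variance signature gene is dropped with a warning.
- The split is strict: positive ⇔ score > cohort median. Samples tied at
  the median are negative. All-equal scores raise a degenerate flag and
  label everyone negative.
- Scores are invariant to positive-slope affine transforms of any gene's
  expression (standardization absorbs them).

## Survival analysis

Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines. The Cox model is fit in-package by Newton–Raphson on the partial
likelihood with step-halving, converging at gradient norm < 1e−8, because
both Efron and Breslow tie conventions are needed (they agree exactly on
tie-free data — a test invariant — and Efron is the default as the less
biased of the two). Wald 95% intervals use z = 1.959964. Coefficients
drifting beyond |β| > 15 are reported as monotone-likelihood (complete
separation) errors naming the covariate, rather than returned with
meaningless standard errors. The implementation is cross-checked in the
test suite against lifelines and against a grid search of a directly coded
Efron likelihood.

Multivariate models encode the standard contrasts (signature +/−, age per
year, node +/−, size ≥T3/<T3, grade 3 vs 1–2, ER +/−, PR +/−, p53
mutant/wild-type) with listwise deletion of incomplete samples, counted in
the log. Subgroup analyses fit the signature indicator alone within six
standard strata (age <50/≥50, node, size, grade, ER, PR); strata without
events are skipped with a warning.

## Cluster support (AU)

Gene-pattern dendrograms use scipy's agglomerative clustering (correlation
or euclidean distance; average, complete or Ward linkage; Ward requires
euclidean). Merge order under tied heights follows scipy's deterministic
nearest-neighbor-chain ordering.

AU support follows the multiscale bootstrap: features are resampled at
scales r ∈ {0.5, 0.6, …, 1.4} (resample size ⌈r·n⌉, B = 1000 replicates per
scale by default), BP_r is the fraction of replicates in which a node's
exact item set reappears, and Φ⁻¹(1−BP_r) = v√r + c/√r is fit by weighted
least squares with binomial delta-method weights B·φ(ψ)²/(BP(1−BP)). Then
AU = 1−Φ(v−c) and the fitted scale-1 bootstrap probability is 1−Φ(v+c).
Numerical conventions: BP is clipped to [1/(B+1), B/(B+1)] to keep the
probit finite; scales where BP is exactly 0 or 1 carry no information and
are excluded from the fit; when fewer than two informative scales remain
the node reports AU = BP = 1 (or 0) directly with a low-confidence flag —
this is the ceiling case of a cluster reproduced in essentially every
replicate. The root always reproduces, so root AU = 1 identically. For a
genuinely supported cluster BP_r rises with r (v < 0 in the model), and AU
exceeds BP at scale 1, correcting the ordinary bootstrap's conservative
bias.

## Synthetic cohorts

The generator's defaults are the study conditions the tests measure under;
they were fixed once, as follows, and are not per-test dials.

Each tumor draws a standard-normal latent differentiation (aggressiveness)
value. Histological grade is its three-level quantile discretization with
prevalences (0.25, 0.45, 0.30), typical of unselected breast-tumor series.
Treating grade as a discretized continuum rather than three separated
point-masses matters: it keeps planted-gene expression continuous within
grade classes and the risk-score distribution symmetric, which is how real
cohort score distributions behave (medians near zero).

Thirty planted signature genes (the published grade-associated symbols,
with their published correlation signs — 11 positive, 19 negative) shift by
`grade_slope` = 0.25 log2 units per grade step against residual Gaussian
noise of 0.5 log2 units (signal-to-noise 0.5). The same genes shift 0.15
log2 units directly with p53-mutant and (oppositely) ER-positive status;
because both statuses are coupled to grade — P(mutant | grade) rising
(0.10, 0.20, 0.45), P(ER+ | grade) falling (0.95, 0.90, 0.70), with a
further 0.25 ER-positivity penalty for mutants — the aggregate status fold
change lands near 1.3–1.4, at the modest end of published effect sizes.

Survival: the latent prognostic risk is a standardized mixture of the
planted genes' shared clinical component (60% of variance,
`signal_fraction`) and independent unobserved heterogeneity (40%) — no real
expression panel is a perfect hazard proxy, and this split reproduces
dichotomized hazard ratios around 2, the center of the published per-cohort
range. Event times are exponential with hazard 0.12·exp(log 2 · risk) per
year, censored by the minimum of an independent exponential (rate 0.03) and
15 years of follow-up, giving ~68% observed events.

What the generator does **not** emulate: array-platform artifacts (probe
effects, batch structure, background), heavy-tailed expression noise,
gene–gene correlation beyond the shared clinical axis, non-proportional
hazards, and informative censoring. Tests passing on these cohorts
demonstrate that the pipeline's inference machinery is correct and
well-calibrated under its assumed model — not that the biological findings
would replicate on any particular real dataset.

## Problem sizes used in the test suite

Simulation-backed checks run at the generator's native scale: 280-gene
panels with n = 250 (screens, score algebra; 10–50 seeds), n = 300 (survival
recovery; 100 seeds), and an eight-cohort end-to-end study. Bootstrap
support checks use a 10-item, 100-feature two-blob fixture at B = 1000.
These sizes keep the full suite under a minute on one CPU while leaving the
Monte-Carlo assertions comfortably away from their thresholds.

## Known limitations

- The catalog is a nomenclature-based reconstruction of the 280-gene
  universe (the original supplementary list is not redistributed); two
  family counts differ by one from the published breakdown because human
  HGNC nomenclature provides only 19 GABA-A subunit genes.
- Cox confidence intervals are Wald-type; no profile-likelihood option.
- No time-varying covariates, competing risks, or proportionality
  diagnostics.
- The AU fallback for ceiling/floor BP reports a point value with a flag
  rather than an interval; extremely strong clusters are simply "supported
  at this B".
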