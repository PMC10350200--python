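# Methods

This note documents the statistical models implemented in `oncophylo`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions taken where several reasonable
conventions exist.

## Prevalence from necropsy records

The sampling unit is a necropsied animal. A record carries zero or more
diagnosis terms; a terminology dictionary maps each term to `benign`,
`malignant` or `non_neoplastic`. Classification is per animal and
severity-ordered: an animal is *malignant* if any term maps to malignant,
otherwise *benign* if any maps to benign, otherwise tumour-free;
non-neoplastic terms are ignored. Consequently an animal with several
neoplasms contributes once to the neoplasia numerator `k_neo` and once to
the malignancy numerator `k_mal` if any lesion is malignant, so benign
prevalence `p_ben = p_neo − p_mal` coincides with "fraction of animals whose
most severe lesion is benign".

Dictionary matching is exact on the case-folded, whitespace-normalized term.
No stemming or fuzzy matching is attempted: a term absent from the
dictionary excludes the record from both numerator and denominator and is
tallied in the exclusion report, so dictionary gaps surface instead of
silently deflating prevalence.

Record filters: neonates are excluded (an input flag, not inferred from age,
because no universal neonatal age cutoff exists across tetrapods); records
reporting a suspect neoplasm without histological confirmation are excluded;
records with no diagnosis terms are retained regardless of the histology
flag, since there was nothing to confirm. Species enter the analysis with at
least `min_n = 20` necropsies (configurable).

## Weighted phylogenetic regression with estimated λ

For species-level prevalence `y` (percent scale, untransformed) and design
`X` (intercept plus life-history predictors, log10-transformed where noted),
the model is

    y = Xβ + ε,   ε ~ N(0, σ² C(λ) + c · diag(1/n_i))

`C` is the Brownian covariance of the tree, used with branch lengths as-is
(λ and σ² absorb the time scale); `C(λ)` multiplies the off-diagonal by
Pagel's λ ∈ [0, 1]. The diagonal term models the sampling error of a species
mean estimated from `n_i` necropsies — standard error ∝ 1/√n_i, equivalently
√n_i weighting of species points. The error scale `c` is profiled by maximum
likelihood jointly with σ² rather than fixed, because the binomial sampling
variance also depends on the unknown prevalence level.

Numerics. Write `V = σ²·(C(λ) + g·D)` with `D = diag(1/n_i)` and
`g = c/σ²`. After whitening by `D^{-1/2}`, one symmetric eigendecomposition
of `D^{-1/2} C(λ) D^{-1/2}` per λ reduces every evaluation in `g` to O(N·p):
β̂ is the GLS estimator, σ̂² = RSS/N in closed form, and the profile over
`g` is a bounded scalar search on log₁₀ g ∈ [−8, 8] (C is normalized to unit
height internally, making these bounds scale-free). λ̂ is located on a
21-point grid over [0, 1], refined by bounded Brent search within one grid
step of the grid optimum, with both endpoints λ = 0 and λ = 1 evaluated
explicitly; the refinement tolerance (1e−5) is far below the 1e−3 resolution
at which λ̂ is verified against an independent 1001-point grid search.
Eigenvalues are clipped at zero to tolerate the exactly singular `C` that
duplicate-row trees produce at λ = 1 (the measurement-error diagonal keeps
`V` positive definite).

Inference: standard errors use the unbiased residual variance RSS/(N − p)
with t-tests at df = N − p, where p = rank(X); the estimated λ and variance
ratio are treated as known, matching common PGLS practice. R² is defined as
1 − RSS/TSS on `V(λ̂)^{-1/2}`-whitened response and design, with TSS from the
GLS intercept-only fit; since the published analyses report R² without a
definition, this whitened-R² convention is a package decision and is labeled
as such. Under a star covariance with equal weights the whole machinery
collapses exactly (to 1e−8) onto ordinary least squares, which the tests
verify against statsmodels.

The default analysis suite contains 28 regressions. The published work
states the total (28) but not the composition; the suite here is: 21
univariate fits (7 life-history predictors × 3 responses: neoplasia
prevalence, malignancy prevalence, malignant fraction), 4 mammal-only fits
(gestation time and litter size × the two prevalences), and 3 multivariate
models (weight + gestation for both prevalences; weight + longevity +
gestation for neoplasia). Transforms are recorded per model: adult weight
(g), maximum longevity (months), gestation (months), sexual maturity,
growth rate and BMR enter as log₁₀; litter size enters untransformed; two
multivariate models use gestation in raw months, mirroring the mixed
"per month" / "per log₁₀ month" slope conventions of the source analyses.
Species missing a predictor are listwise-deleted per analysis. Slope
p-values (intercepts excluded) are adjusted jointly by Benjamini–Hochberg at
q = 0.10; the original work names only "an FDR of 10%", and BH is the
default step-up procedure chosen here.

## Evolutionary models of prevalence

Prevalence (percent scale) is treated as a continuous trait with three
candidate covariance models: BM `V = σ²C`; OU (fixed root) `V_ij =
σ²/(2α)·e^{−α d_ij}(1 − e^{−2α t_ij})` with shared time `t_ij = C_ij` and
patristic distance `d_ij`; and EB with rate σ²e^{at}, giving
`V_ij = σ²(e^{a C_ij} − 1)/a`. Both non-BM models reduce continuously to BM
(α → 0, a → 0), and the implementation evaluates those limits exactly. Root
state and σ² are profiled analytically (GLS mean, scaled RSS); α is searched
on [0, 50/h] and a on [−10/h, 0] where h is tree height, with the boundary
(BM limit) preferred on ties so that model ranking is deterministic. Models
are ranked by AICc with k = 2 (BM) or 3 (OU, EB); ties break toward fewer
parameters, then alphabetically. OU is intended for ultrametric trees; a
non-ultrametric input triggers a warning and uses the same generalized
fixed-root covariance.

## Cohort statistics

Kruskal–Wallis (with tie correction, χ² p), the two-sample
Kolmogorov–Smirnov statistic (exhaustive ECDF scan; asymptotic Kolmogorov
tail at √(mn/(m+n))·D), the Pearson correlation (t-based p) and
Benjamini–Hochberg adjustment are implemented directly from their
definitions, with scipy/statsmodels serving as independent cross-checks in
the test-suite only. Asymptotic p-values are the default, appropriate at the
sample sizes of clade-level comparisons; full-enumeration permutation
p-values are available for small samples (pooled n ≤ 10 or so). The
benign-vs-malignant prevalence correlation uses species as unweighted units.

Age analysis: each aged record contributes the ratio age-at-death / species
reference lifespan, and within each clade the tumour-bearing and tumour-free
arms are compared by KS. The reference lifespan field defaults to the
life-history table's maximum longevity column and is configurable, because
the exact longevity field used by the source analyses is not stated. Clades
with fewer than 2 aged records per arm are skipped with a report.

## Assay processing

The DNA-damage response statistic is 100·AUC(treated)/AUC(untreated) on
cell-count-over-time curves (trapezoidal AUC), computed per species, agent
(radiation: 0/0.4/2/10 Gy over 5 days; doxorubicin: 0/0.11/0.33/1 μM with
DMSO vehicle over 3 days) and dose, after averaging replicates pointwise on
the shared 2-hour grid. Mean-then-ratio equals ratio-of-mean-AUCs on a
shared grid; the full recorded window per agent is integrated. Apoptosis
(Annexin V) counts are ingested and summarized but not modeled. Percent
growth and published somatic mutation rates (single-base substitutions per
genome per year) enter the PGLS as log₁₀ predictors of prevalence; fits with
fewer than 4 overlapping species are skipped with a report.

## The synthetic-data generator

The generator emulates the structure of the emulated study at its reported
scale: 292 species on a pure-birth ultrametric tree; necropsy counts
log-normal with median 35, floored at 20 (grand total ≈ 16–18k records);
clades assigned as contiguous monophyletic-like blocks with fractions
(0.34, 0.50, 0.16) and additive latent-prevalence offsets (+6.21, −2.67,
−4.91) around a grand mean of 9.07%, reproducing the mammals ≫ sauropsids >
amphibians gradient and the published clade means at the latent level; adult
weight, gestation and longevity evolved by Brownian motion on the log₁₀
scale (weight–gestation correlation ≈ 0.5); latent prevalence
η = 9.07 + clade offset + 2.1·(log₁₀ weight − mean) − 5.6·(log₁₀ gestation −
mean) + u with u drawn at λ = 0.46 and σ² = 36, clipped to [0, 100]; counts
binomial, with the malignant share of tumour-bearing animals Beta-distributed
around 0.65; 15 assay species and 9 mutation-rate species whose log₁₀ rates
couple to latent prevalence with slope 1/47.26.

The record-level generator reproduces the species counts exactly and then
injects contamination the ingest must remove: neonates (5% of a species'
count), tumour terms without histological confirmation (3%), and
unresolvable common names (2%). The round-trip
(records → resolve → filter → prevalence) is exact by construction and is
asserted exactly in the tests.

What the generator does not emulate: real taxonomies and allometries beyond
BM on the log scale; overdispersion of counts beyond binomial; diagnosis
drift between institutions; the truncation at 0% compresses realized clade
means toward each other relative to their latent targets (a linear-truncated
model is used, rather than logit, so that the generating model matches the
fitted linear PGLS and parameter recovery is a fair test; a low-mean clade's
realized mean is therefore biased upward). Passing tests demonstrate
correctness of the estimators under these generating conditions, not the
substantive biology of any real dataset.

Calibration experiments (slope recovery, type-I error, λ-grid agreement) are
run with zero clade offsets and a mid-scale latent mean (20–40%) so that the
generating model is exactly the latent-linear model those oracles prescribe
and truncation is negligible; simulation sizes are 200 taxa × 100 replicates
for recovery, 100 taxa × 200 replicates for the error-rate calibration, and
50 datasets of 50 taxa for the λ-grid comparison.

## Known limitations

* The measurement-error model `c/n_i` assumes a common error scale across
  species; the true binomial variance depends on each species' prevalence.
  The misfit is mild at the prevalence ranges involved and is absorbed by
  the profiled `c`.
* Inference treats λ̂ and ĝ as known; no small-sample correction for
  variance-parameter estimation is applied.
* The desk-scale summaries of the original published species table can only
  be recomputed when that (restricted) table is supplied locally; the
  corresponding check reports its absence rather than silently passing.
* Regression coefficients obtained on synthetic data are not expected to
  equal published coefficients numerically: those additionally depend on the
  external dated tree and the life-history database versions. When real
  inputs are supplied the package checks sign and significance patterns
  qualitatively.
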