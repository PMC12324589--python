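# Methods

## Model and estimation

The engine is single-response partial least squares (PLS1) fitted by
NIPALS with X-deflation. Features are centered and unit-variance scaled
(SD with ddof = 1) inside the fit and the parameters stored on the model;
the trait code −1/+1 is likewise centered and scaled. Scaling prevents the
largest block (functional couplings) or high-variance features from
dominating the covariance objective; a center-only mode (`scale=False`) is
available, and because residualized features are near-unit-scale anyway the
choice is rarely material. y-deflation is omitted: with a single response,
deflated X columns are orthogonal to earlier scores, so the extracted
components are identical either way (this is also why the engine agrees
with a standard reference implementation to machine precision).

Weights have unit norm; scores are mutually orthogonal by construction;
the rotation `R = W (P'W)⁻¹` satisfies `T = X_std R` on the training data
(checked at 1e−8) and is the only object needed for out-of-sample
projection. Component signs are arbitrary: `align_signs` flips
`(W, P, c, T)` columns jointly — and recomputes R — under either a
trait-positive or a largest-loading-positive convention, leaving all
magnitudes, reconstructions and p-values untouched.

Degenerate inputs: a constant trait or NaNs raise immediately; if X is
rank-exhausted before the requested number of components, extraction stops
early with a warning and the model carries the reduced K. Transform and
projection match columns by feature *name*, never position, so block
restriction cannot silently mis-align.

## Permutation inference

The trait vector is row-shuffled; each shuffle refits the full PLS at the
same K and records per-component |ρ(t_k, y_perm)|. The comparison is
two-sided on |ρ| because component signs carry no information. The add-one
estimator `p = (1 + b)/(1 + n_perm)` is used, and significance is declared
at **p ≤ α**: the estimator's floor `1/(n_perm + 1)` is exactly the event
"the observed association beats every null model", which is the intended
acceptance criterion at α = 1/(n_perm+1) (with the default 1000
permutations and α = 0.001 the distinction is invisible; with 999 it is
the difference between a usable and a vacuous test). All components are
compared simultaneously at fixed K; sequential component-wise re-testing
is deliberately not implemented.

The null refits matter: at desk scale the in-sample correlation of a PLS
component contains optimism of order √(p/n) even without any signal, and
the permutation null carries the same optimism, which is precisely what
makes the comparison valid. A corollary, visible in the examples: observed
in-sample ρ values overstate the planted latent correlation, and power at
α = 0.001 requires n/p comfortably in the tens.

## Bootstrap loading stability

Resamples with replacement keep the original n; each refit's components
are matched to the full-sample reference model (never chained) by Hungarian
assignment maximizing total |Pearson r| between loading columns, then
sign-aligned by the matched correlation's sign. Zero-variance columns get
zero similarity (matched last, with a warning). Per-entry CIs are empirical
percentiles across the matched loadings, default (5, 95) — kept as the
conventional two-sided 5–95% band even though it is a 90% interval; (2.5,
97.5) is a config switch. Percentile endpoints use the `lower`/`higher`
order-statistic convention rather than interpolation: the interval is never
narrower than the interpolated one and degenerates to min/max at
n_boot = 2. A resample with a constant trait is redrawn (logged); more than
10% redraws aborts, since that indicates a class imbalance too severe for
stable resampling.

## Cross-cohort projection

`restrict_model` subsets the rows of W and P by feature name and
**recomputes** the rotation from the restricted matrices — slicing the
parent rotation would apply the wrong inverse. The condition number of
`P_sub'W_sub` is stored and an error raised above 1e8 (a block smaller than
K is always singular). `project_cohort` standardizes the target with its
own mean/SD by default: source and target cohorts generally come from
different scanners, ages and preprocessing, so raw scales are
incomparable; reusing source parameters (`centering="source"`) is provided
for strict formula replication, and `centering="none"` for linearity
checks.

A structural note that shaped the validation design: a dichotomized trait
is a one-dimensional supervision signal. With two planted trait-linked
modes, the first component captures the single y-correlated combination of
them and later components are pinned only by the weak residual correlation
that survives the binarization's nonlinearity — per-mode recovery through
a two-mode fit therefore plateaus (≈0.7 at n ≤ 3000 in our Monte-Carlo)
no matter how clean the projection machinery is. The transfer recovery
test consequently plants a single strongly linked mode (binarized latent
r = 0.35, σ = 4, n = 1000), isolating what it is meant to validate: the
block-restricted rotation, not multi-mode separability.

## Phenome scans, contrasts, stratification

Scans compute pairwise-complete Pearson r per component × phenotype with
the two-sided p from the t transform (n_used − 2 df); 0/1 phenotypes are
treated numerically (point-biserial ≡ Pearson). The Bonferroni denominator
is the family's declared size (so thresholds like 0.05/977 are reproduced
even when fewer columns are supplied); `count_tested_only` switches to the
non-degenerate column count. Zero-variance phenotypes yield flagged records
with undefined r. p-values are floored at the smallest positive double
before the −log10 transform, with the flooring flagged.

Group differences use Student's pooled two-sample t by default (Welch
optional), signed as mean(group 1) − mean(group 0). Age stratification
uses closed-left/open-right brackets, so a shared printed endpoint
("40–50, 50–55") belongs to the upper bracket; participants outside every
bracket are tallied separately and counts are conserved.

## Synthetic cohorts

The generator emulates the statistical skeleton of a two-cohort
population-imaging study: `X = Σ_k σ_k t_k p_k' + noise_sd·E + C_z Γ` with
orthonormal planted loadings (QR of a Gaussian matrix — orthonormality
makes recovery unambiguous), standard-normal latent scores carrying
per-mode sex shifts and linear age trends, z-scored confounds with known
additive coefficients Γ (so residualization is checkable by recovery), and
a trait obtained by cutting `y* = Σ β_k t_k + ε` at the top-prevalence
quantile (default prevalence 0.334, the ~2:1 imbalance of the motivating
cohort; the +1 count is exactly `round(prevalence · n)`). The transfer
cohort reuses the planted loadings restricted to one block (GMV by
default), with negated age slopes and its own age range in months. Phenome
columns are `effect_r·z(t_k) + √(1−effect_r²)·noise`, optionally
thresholded to binary; names encode the ground truth.

Calibration: the binarized trait attenuates a latent correlation by
`φ(z_q)/√(q(1−q))` (≈0.77 at prevalence 0.334). The default trait noise is
solved from this closed form so mode 1's *binarized* latent correlation
lands near 0.1 — the regime the motivating study reports — and
`SyntheticTruth.for_latent_r` inverts the same formula for any target.
Default mode strengths (4, 3) against unit feature noise keep the planted
patterns recoverable at desk-scale n without making them trivial. The demo
dataset written by `make_demo` deliberately uses a stronger link (target
latent r 0.35) so both planted modes clear α = 0.001 at demo sample sizes;
at the default ~0.1 calibration, mode-1 detection sits at the α = 0.001
boundary below roughly n = 5000 and secondary modes are undetectable —
an instructive property, but not a useful demo.

What the generator does **not** emulate: spatial covariance structure of
real imaging features (atlas adjacency, hemispheric symmetry, block-wise
correlation), site/batch effects, non-Gaussian feature noise, missing-data
patterns, or longitudinal assessment beyond the two trait instances needed
by the concordance filter. Passing tests therefore certify the statistical
machinery — estimation, calibration, error control, transfer algebra — not
robustness to realistic imaging artifacts.

## Cohort preparation

The six raw trait levels map to −1 (two morning levels), +1 (two evening
levels) or missing (the two non-answers); undeclared strings raise with
the offending value. Participants are kept only when both assessment
instances agree after recoding, and dropped on any positive shift-work
flag ({sometimes, usually, always, yes}, case-insensitive); a missing flag
is no evidence and retains the participant. The two filters commute.
Residualization regresses each feature on an intercept plus the confound
design (categoricals one-hot with the reference level dropped; columns
z-scored for conditioning — residuals are invariant to this), raising on
rank deficiency. It is applied to brain features only, not the trait, and
is idempotent; residuals are orthogonal to every confound at 1e−10.

## Problem sizes and reproducibility

All Monte-Carlo work is desk-scale by design: calibration tests use 200
null datasets (n = 300, p = 100, K = 3, 199 permutations); power/recovery
uses 100 replicates at n = 1000 over blocks 20/8/22 (p = 50, preserving
the ~3:1:4 GMV:FA:FC ratio at n/p = 20); bootstrap calibration uses 50
replicates × 100 resamples; the acceptance script runs n = 5000 over
blocks 21/7/32 with 999 permutations and 200 resamples. A single master
seed fans out to fixed per-stage child seeds (SeedSequence keyed on stage
index, all below 2³¹), so any stage can be rerun independently and whole
runs are bit-reproducible; every output table carries the package version,
config hash and seed as comment headers.

## Known limitations

No sparse or multi-response PLS, no canonical correlation analysis, no FDR
alternatives beyond the Bonferroni hook, no imputation (complete-case
only), no harmonization of the target cohort beyond its own
standardization, and no attempt to pick K automatically — fit generously
and let the permutation test decide, which is the intended workflow.
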