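# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions, and the design choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The generative model (`methlung.simulate`)

Each cohort has `n_subjects` measured at two timepoints; the follow-up gap
is uniform on the configured interval (default 6–15 years). Per subject:
sex ~ Bernoulli(0.5); age at timepoint 1 ~ N(48, 8²) clipped to [25, 70];
height sex-specific normal; BMI, education (low/intermediate/high),
centre and spirometer (two levels each) categorical; smoking status
never/ex/current with prevalence (0.45, 0.30, 0.25); pack-years for ever-
smokers ~ Gamma(shape 2, scale 10) and exactly 0 for never-smokers;
current smokers accrue 0.75 packs/day over follow-up; cigarettes/day is
pack-years scaled by smoking duration.

**Effective smoking dose.** Current smokers: dose = pack-years.
Ex-smokers: dose = pack-years × 2^(−years-since-quitting / half-life),
half-life 10 years by default. This exponential decay encodes the
years-since-quitting gradient a methylation smoking signature shows;
the functional form is a modelling choice of this package.

**Methylation.** For non-reference CpG p and sample (subject i, time t):

```
logit(beta_pit) = mu_p + lambda_p' T_it + gamma_p' (w_it - 1/K)
                  + s_p * dose_it + u_pi + eps_pit
```

with probe baseline mu_p ~ N(0, 1.5²); latent technical factors
T ~ N(0, I) per sample, loading sparsely on CpGs (10% of probes per
factor, loadings N(0, 0.3²)) and densely on control probes
(intensities = base + 50·loadings·T + noise, floored at 1); cell-mixture
weights w ~ Dirichlet (neutrophil-dominated concentration, per sample);
smoking slope s_p nonzero for the configured fraction of CpGs (default
5%), drawn as −0.04 × U(0.5, 1.5) logit units per pack-year (negative =
smoking hypomethylation), with baselines of smoking CpGs drawn near
logit 0 so the dose effect is visible on the β scale; subject effect
u_pi ~ N(0, 0.3²) shared across timepoints (the within-subject
correlation knob — no canonical value exists, so it is a config
parameter); residual noise eps ~ N(0, 0.3²). The inverse logit guarantees
β ∈ [0, 1]. The first `n_ref_probes` rows are reference probes that mix
*linearly on the β scale*, `beta = panel · w + noise`, so deconvolution
has an exact target and a noiseless configuration reproduces the mixing
identity to machine precision.

**Lung function.** FVC follows a spirometry-style mean model in age,
height and sex with a shared subject effect; the FEV₁/FVC ratio is

```
ratio_it = 0.82 − 0.0012 (age−50) + c_d * dose_it
           + Σ_j b_j (beta_jit − expit(mu_j)) + v_i + e_it
```

clipped to (0.35, 0.97), and FEV₁ = ratio × FVC — so FEV₁ ≤ FVC holds by
construction. The mediated sum runs over the configured mediator CpGs
(default 20, a subset of the smoking CpGs) with slopes
b_j = 0.08 × U(0.75, 1.25) ratio units per β unit; the direct dose slope
is c_d = −0.0015 per pack-year. Defaults are chosen once so that a
desk-scale study (hundreds of subjects per cohort) has the discovery and
replication power the full-scale design would have with thousands;
consequently smoking explains a larger share of outcome variance here
than in field data, which matters when interpreting R² decompositions
but not sign/ordering/calibration behaviour.

**Ground truth.** Every run returns an effect table (probe, smoking
effect, outcome effect, mediator flag, null flag, baseline logit) and a
per-sample latent table (effective dose, cell fractions, technical
factors) used only by validation code.

**Array non-overlap.** Optionally each cohort drops a disjoint probe
slice (`disjoint_probe_fraction`), emulating meta-analysis across array
generations without restriction to shared markers; missing probes enter
the meta-analysis with direction '?' and zero weight.

## 2. Preprocessing

Control-probe PCA is computed on the column-centered, unscaled intensity
matrix (control probes share an intensity scale, so variance weighting is
meaningful), per cohort and per timepoint by default (pooling across
timepoints is available via a flag; which a study does is a design choice,
and the per-timepoint default matches the per-cohort, per-timepoint EWAS
structure). Requesting more components than min(samples−1, probes) is an
error naming the achievable maximum. Residualization fits, per probe, OLS
of β on an intercept plus all retained PC scores; probes with missing
values get a complete-case fit. Residuals are exactly orthogonal to the
scores and idempotent under re-residualization.

Cell fractions solve min‖panel·w − β‖² with w ≥ 0 (scipy NNLS) or, by
default, w ≥ 0 and Σw = 1, via an exact active-set iteration on the KKT
system (validated in the tests against exhaustive active-set enumeration
and recovering noiseless mixtures to machine precision). Because
sum-to-one fractions are collinear with the intercept, the design builder
drops one aliased cell column with a logged warning; this changes no
fitted value.

## 3. EWAS designs

The covariate models follow the base/smoking scheme described in the
README. Categorical references: education = low, smoking = never, sex
coded 0 (female, reference) / 1; the squared height deviation uses the
analysis-sample mean (computed per analysis subset; recorded in the
design metadata). Constant columns (e.g. a single-centre cohort) are
dropped silently as a structural zero; aliased columns are dropped with a
warning.

Per probe, the cross-sectional model is OLS of the outcome on
[covariates, methylation residual]; the implementation partials the
covariates out of both sides (Frisch–Waugh), which the tests verify is
identical to the full normal-equations solve to 1e−8. Reported p-values
use the normal approximation to the t statistic (the EWAS convention at
these sample sizes; exact t available via `use_t=True`). Probes with zero
residual variance or too few complete observations are skipped and
counted in the log, not reported as p = 1. Exact fits (zero residual)
report the underflow floor rather than erroring on a zero SE.

The prediction design regresses annualized change, (value₂ − value₁)/
follow-up years, on the timepoint-1 residuals, with baseline lung
function appended to the covariates exactly once; subjects missing a
timepoint are excluded here but contribute their single record to the
repeat design. The repeat design fits, per probe, a random-intercept
(subject) linear mixed model by REML (statsmodels MixedLM) with the
time-varying methylation residual as predictor, reporting the Wald z
test; non-converged probes are excluded with a log entry.

## 4. Meta-analysis and replication

Fixed-effect IVW only: weights 1/SE², pooled SE = (Σw)^(−1/2), Cochran's
Q with χ²(k−1) heterogeneity p, one direction character per cohort in the
declared cohort order. Genomic λ is the median observed χ²(1) statistic
over 0.4549364; it is reported for diagnosis and never used to rescale
(no genomic-control correction anywhere). Combining discovery and
replication runs IVW over the concatenated cohort-level results — by
weight additivity this equals a single IVW over all cohorts, which the
tests assert to 1e−12.

Sentinels are probes with discovery meta p strictly below 5×10⁻⁷. The
replication threshold is α divided by the number of sentinels for that
outcome; replication additionally requires sign concordance with
discovery by default (toggleable) — concordance is the stricter, more
defensible gate and costs nothing when effects are real.

## 5. Enrichment

GSEA-style weighted KS: walking down the ranking, set members add
|score|^exponent (normalized over the set), non-members subtract
1/(N − set size); the enrichment score is the signed maximum-magnitude
deviation (exponent 1 by default; exponent 0 recovers the classical KS
statistic, verified against a two-sample-ECDF oracle). The null permutes
membership labels: exhaustively when the arrangement count is ≤ 10⁶,
otherwise Monte-Carlo with the add-one correction
p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1). The comparison is two-sided on
the magnitude: that is the convention under which the permutation p is
uniform for a null ranking (a sign-conditional one-sided comparison is
not — its p cannot exceed ≈ 0.5), and the tests check this calibration
directly.

## 6. Mediation

Two OLS fits — mediator ~ treatment + covariates, outcome ~ treatment +
mediator + covariates (no interaction) — then quasi-Bayesian Monte
Carlo: parameter vectors drawn from the normal approximation at the
estimates, per draw ACME = a·b, ADE = c′, total = ACME + ADE (an exact
identity per draw), proportion = ACME/total with |total| < 1e−12 draws
excluded from the ratio. Point estimates are medians of draws (robust to
the ratio's heavy tails; the plug-in product is available as
`sobel_acme`, which also provides the delta-method SE used as the test
oracle), intervals are 2.5/97.5 percentiles, and
p = max(2·min(share ≤ 0, share ≥ 0), 2/n_sims) — so p-values are even
multiples of 2/n_sims with that floor.

The default treatment in the cohort-level wrapper is continuous
pack-years among never- plus current smokers: never-smokers anchor dose
zero and current smokers' effective dose equals pack-years exactly, so
the linear structural model holds up to the mild logit nonlinearity.
(Ex-smokers' decayed dose would misclassify exposure under a binary
ever/never coding, which remains available via `treatment="ever"`.)
Covariates default to the full base model.

For validation, the generator's structural truth is computed directly:
each mediator's path slope is the regression of its noise-free mean
expit(mu + s·dose) on dose over the analysis sample's latent doses; with
a single analyzed mediator, paths through the *other* mediators belong to
the direct pathway, so the true proportion is the analyzed path over the
direct-plus-all-paths total. Recovery is checked on single-mediator
configurations; with many simultaneous mediators, shared cell/technical
structure correlates mediators within treatment groups and single-CpG
ACMEs absorb part of that, a realistic caveat the analysis driver prints.

## 7. Smoking indices

An index is the equal-weight mean over a signed CpG set of z-scored
residuals, flipped for '−'-signed (smoking-hypomethylated) probes.
Orientation convention: **higher score = more smoking-like profile**, so
the index rises from never- to ex- to current smokers, rises with
pack-years, and associates negatively with lung function. The weights are
a package choice (no canonical weighting exists); a per-probe weight
vector can be supplied. Standardization parameters are stored so new
samples score consistently out of sample. At least half the set's probes
must be present; the rest are logged and skipped.

Associations are base-model-adjusted regressions (baseline-adjusted for
the prediction design), meta-analysed with the same IVW machinery.
Variance decomposition reports adjusted R² (1 − (1−R²)(n−1)/(n−p)) for
the nested chain base / base+index / base+smoking / base+smoking+index,
attributing each increment to the last-added block. Adjusted group
distributions residualize the index on the adjustment covariates
(grouping excluded), add back the grand mean, and summarize per group by
median, quartiles and 1.5-IQR whiskers.

## 8. Mendelian randomization

Per instrument, the Wald ratio by/bx with first-order delta-method SE
√(sy²/bx² + by²sx²/bx⁴) (second-order terms omitted — the standard
first-order practice); instruments pooled by IVW on the Wald SEs. No
pruning or clumping: instrument tables are assumed pre-selected.

## 9. Seeds, I/O, determinism

One global seed; per-stage seeds derive deterministically from
(seed, CRC32 of the stage name) through numpy's SeedSequence, kept below
2³¹, so stages are individually reproducible and two runs with the same
config and seed produce byte-identical TSVs (floats written with 17
significant digits; parsed with round-trip precision; 'NA' missing
token). Matrix readers reject duplicate probe ids and ragged rows with
the offending line number.

## 10. Problem sizes and limitations

The test suite and acceptance script run the study at desk scale: cohorts
of 150–500 subjects, 600–2000 CpGs, 20 seeds for the end-to-end
replication check, 5 seeds × 1000 quasi-Bayesian draws for mediation,
10⁵ p-values for λ calibration. These sizes are the package's chosen
operating point for fast, deterministic validation.

What the generator does *not* emulate — and hence what passing tests do
not establish about field data: probe-wise heteroscedasticity and
detection-p artefacts of real arrays; genomic correlation (co-methylation
blocks) beyond shared technical/cell structure; population stratification
and ancestry; selection and attrition between timepoints; spirometry
measurement protocol effects beyond a spirometer covariate; and
unmeasured confounding of the mediator–outcome relation, which the
sequential-ignorability assumption of the mediation model rules out by
fiat. Results on synthetic cohorts validate the statistical machinery and
its calibration, not the biology of any particular cohort.
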