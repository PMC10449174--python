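# Methods

## The scientific question and the model

The package implements the twin-design analysis of whether students'
educational expectations respond to prior school performance, and whether
that responsiveness differs by family socio-economic status (SES).  The
observed association between performance and expectations can be inflated
by factors that influence both — family-level environments and genetic
dispositions.  A classical twin design identifies those latent confounders
from the different genetic overlap of monozygotic (MZ) and dizygotic (DZ)
co-twins.

Three phenotypes per twin, in causal order: cognitive ability (a CFA score
over four Culture Fair Test subscales), academic performance (school-type-
residualized reverse-coded Math/German grade average) and educational
expectations (desired qualification level 1–3 weighted by the self-rated
probability of attaining it).  Each phenotype *i* loads on its own latent
additive-genetic (A_i), shared-environment (C_i) and non-shared-environment
(E_i) factors with free loadings `a_ii, c_ii, e_ii`; the factors have unit
variance and cross-twin correlations 1 (MZ) / ρ_DZ (DZ) for A, 1 for C, 0
for E.  ρ_DZ defaults to 0.5 (no assortative mating) and is exposed as a
knob for sensitivity analyses.  Downstream phenotypes additionally receive
cross-loadings from upstream A/C factors (`a_21, c_21, a_31, c_31, a_32,
c_32`) and directed regression paths `beta_21, beta_31, beta_32` — the
"ACE-beta" structure.  `beta_32` is the quantity of interest: the
responsiveness of expectations to performance net of the latent confounders.

The family-level moderator M (standardized parental years of education)
enters the means through main effects `b_1, b_2, b_3` and may moderate every
path into expectations: a moderated coefficient is `x + bx·M`.  `beta_32 +
gamma_32·M` is then the SES-specific responsiveness.  Because M is
continuous, the implied covariance is family-specific (a definition
variable).

### Reduced form and likelihood

The structural system is recursive, so with direct-loading matrix D and
strictly-lower regression matrix B the reduced form is exact:
`Λ = (I − B)⁻¹ D`, computed by forward substitution rather than numeric
inversion.  Within- and cross-twin covariance blocks are `Λ Λ'` and
`Λ K Λ'`, with K the diagonal of cross-twin latent correlations.  Each
family contributes the multivariate-normal density of its *observed*
phenotype sub-vector under its own implied moments (full-information
maximum likelihood): missing entries simply drop the corresponding rows
and columns.  Families are grouped by missingness pattern (and, when no
path is moderated, by zygosity — the covariance is then shared and
factorized once per group).  The analytic gradient of −2LL is propagated
through the reduced form, which is what makes the repeated-simulation
studies affordable on one core.

A univariate ADE variant (dominance instead of shared environment,
cross-twin correlations 1/0.25) is provided for the case where DZ
correlations fall below half the MZ correlations; the model-family rule
(`ADE iff r_DZ < r_MZ/2`, ties to ACE) is applied per phenotype from
double-entered twin correlations.  A model with all four components is not
identified in the classical twin design, hence the either/or choice.

### Estimation and model comparison

−2LL is minimized by L-BFGS-B with the analytic gradient, from a default of
10 jittered starts (N(0, 0.2) around 0.5 for diagonal loadings, 0
elsewhere, data means for intercepts; seed 20230824) because the likelihood
is sign-symmetric in every latent factor and occasionally flat.  e-paths
are bounded below at 1e-6.  Convergence requires a gradient infinity-norm
below 1e-4; when the line search stalls at machine precision of the
objective, one restart (resetting the quasi-Newton memory) is attempted.
After fitting, factor signs are canonicalized so diagonal loadings are
non-negative (cross-loadings and moderation coefficients on the same factor
flip together; the likelihood is unchanged).

Standard errors come from the observed information: `SE = sqrt(diag(2 H⁻¹))`
with H the Hessian of −2LL at the optimum, obtained by central differences
of the analytic gradient (step `1e-5·(1+|x|)`).

Nested models are compared by likelihood-ratio tests against chi-square
with df = number of newly fixed parameters.  For variance loadings tested
at zero the true reference is a chi-bar-square mixture; the plain chi-square
is used deliberately and is conservative (it over-accepts the restriction),
which matches common twin-modelling practice.  Backward selection
reproduces the "could be fixed to 0" reporting style deterministically: at
each round, eligible free paths (never e-paths, never intercepts, never a
main effect whose moderation coefficient is still free) are tried in
increasing |estimate|/SE order; the first fixation whose LRT p-value
exceeds α = 0.05 is kept, with refits warm-started at the parent solution;
selection stops when every candidate is rejected.  AIC is reported
alongside in the trail.

### Named models

`M1a/M1b/M1c` are univariate ACE decompositions of grades, expectations and
ability.  `M2a` estimates the responsiveness with no confounding control;
`M2b` adds the latent A/C cross-paths from performance; `M2c` adds
cognitive ability and its A/C cross-paths; `M2d` adds the SES main effects.
`M3a` moderates the paths into expectations originating from performance
and from the expectation-specific factors; `M3b` also moderates the
ability-related paths.  The presets encode the *best-fitting* versions as
published (already-pruned paths fixed to zero); `M3a_full`/`M3b_full` carry
the full moderation sets and are the intended starting points for backward
selection.

## Preprocessing

Pipeline order: expectation score → reversed-grade average → CFA ability
score → residualize grades on school type → residualize all three
phenotypes on sex and age (one pooled regression over all twins; only point
residuals are needed, so family clustering is irrelevant) → drop pairs with
a missing moderator (listwise, as the moderator enters the model structure)
→ drop pairs with zero observed phenotypes (FIML needs at least one) →
standardize phenotypes pooled over twins and the moderator over retained
pairs.  Standardizing *after* the drops keeps the mean-0/variance-1
contract exact on the analysis sample; with the observed drop rates the
difference from standardizing first is negligible.  Design choices that
were genuinely open:

* **Expectation weighting** — the aspiration level is multiplied by the
  success probability on [0, 1].  Multiplicative weighting is the minimal
  reading of "weighting by the probability of success", is monotone in both
  arguments, and is exposed as a config hook (`expectation_formula`).
* **Grade reversal** — `7 − g` on the German 1–6 scale.  Any
  order-reversing affine map is equivalent after standardization; this one
  keeps the 1–6 range.
* **School type** — dummy-coded with the modal category as reference
  (configurable); the original survey's exact coding scheme is not public.
* **CFA scoring** — a single-factor model (4 loadings, 4 unique variances)
  fitted by ML on the covariance of complete cases; regression-method
  factor scores for every twin with ≥1 observed indicator, then
  standardized.  In a one-factor model the scoring method changes scores
  only by a scalar, which standardization absorbs.  Heywood cases are
  bounded at 1e-6 with a warning.
* **Moderator scale** — the globally standardized M is used in every model
  (not re-centered per model).

## The synthetic cohort generator

`simulate_pairs` draws family-level M ~ N(0,1), latent factors with the
exact cross-twin correlation structure, and computes phenotypes from the
same reduced form the likelihood uses — so the empirical moments of a large
cohort are a direct Monte-Carlo oracle for the implied moments.  Default
conditions mirror the target survey: 1029 pairs, balanced MZ/DZ (the true
split is not public), item missingness 33% (expectations), 18% (grades),
1.3% (ability), and the published best-fitting moderated parameters as the
generating values (including `c33 = 0`, `ba33 = −0.09`, `gamma31 = −0.08`).
Missingness is MCAR by default — FIML is consistent under MAR, and MCAR
suffices for testing — with a MAR hook (per-phenotype logit shift in M)
available but off.

`simulate_raw_survey` maps latents back to raw survey items so the whole
preprocessing pipeline can be exercised: ability to four CFT sum scores
(fixed loadings, rounding, item maxima), grades to integer 1–6 Math/German
grades (subject-difficulty offsets stagger the rounding grids so the
two-subject average resolves half-grade steps; school-track grading offsets
±0.5), expectations to an aspiration level (thresholds at ±0.5 SD) and a
success probability chosen so that `aspiration × probability/100` is affine
in the latent score.  School track follows SES plus an independent lottery;
sex/age effects are added before mapping so residualization has real work
to do.  What the generator does *not* emulate: assortative mating in the
data-generating process (only the ρ_DZ knob), selection/attrition,
zygosity-specific missingness, ordinal measurement of expectations, or
passive gene-environment correlation.  Passing tests therefore validate
the estimator under the model's own assumptions, not robustness to their
violation.

## Calibration experiments and problem sizes

The `experiments` module runs the package's validation studies; the test
suite asserts their outcomes and `scripts/acceptance.py` reports them.
Sizes were chosen to give stable Monte-Carlo summaries on a single core:

* moment oracle — 5 random parameter draws × 2 zygosities × M ∈ {−1,0,1},
  250 000 pairs each; every moment discrepancy standardized by its MC
  standard error.  With ~800 simultaneous comparisons a few 3-SE
  exceedances are expected by chance (nominal 0.27%), so the criterion is
  the exceedance share, with a gross-error cap at 5 SE.
* likelihood oracle — FIML against an independent multivariate-normal
  density computation, complete and marginalized, tolerance 1e-8.
* parameter recovery — 100 cohorts of 4000 pairs (60% MZ, complete data)
  at the published moderated parameters; mean bias per parameter must stay
  below 0.03 (main paths) / 0.04 (moderation coefficients).
* LRT calibration — 400 replicates of a truly-zero, interior parameter
  (the SES main effect on grades) at n = 400 pairs; rejection rate 5% ± 2
  points, null median ≈ 0.455.
* selection consistency — 40 replicates of backward selection on a
  confounded bivariate structure whose `c33` is exactly zero (n = 2000);
  the zero path must be fixed in ≥90%.
* attenuation — one 4000-pair cohort from the confounded generating
  process; the no-control responsiveness estimate must exceed the
  fully-controlled one.

## Known limitations

* Chi-square (not chi-bar-square) reference for boundary loadings:
  conservative for fixation decisions.
* No bootstrap or cluster-robust standard errors.
* ADE is univariate-only; all multivariate models are ACE.
* No imputation and no measurement-invariance testing for the CFA.
* Triplets and higher multiples are out of scope for the data model.
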