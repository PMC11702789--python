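# Methods

## Absolute risk model

The package implements the literature-based absolute-risk synthesis used by
Gail-type / iCARE-type breast cancer models. Three ingredients are combined:

1. **A multiplicative relative-risk function.** Each covariate contributes
   `exp(β · z)` with categorical covariates contributing a per-level log
   relative risk (exactly 0 at the declared reference level) and continuous
   covariates a per-unit log relative risk centred at a declared reference
   value. The relative risks are configuration inputs, not fitted
   quantities: the package's scope starts where a literature synthesis ends.
   Separate models are configured for women younger and older than 50; a
   projection uses the single stratum selected by its entry age, with no
   blending across the boundary (the two strata are developed and validated
   separately, so mixing them inside one projection would create a hybrid
   model that belongs to neither).

2. **Baseline-hazard calibration.** Given a registry incidence table
   λ_m(a) and a representative reference population, the baseline hazard is
   λ₀(a) = λ_m(a) / W(a) with W(a) the reference-weighted mean relative risk
   under the stratum model applicable at age a. This is the rare-disease
   approximation: it ignores the differential depletion of high-risk women
   from the risk set with advancing age. At breast-cancer incidence levels
   (annual rates of a few per thousand) the depletion is negligible over a
   5-year horizon; an iterative attrition-adjusted refinement that re-weights
   survivors age by age is available via `attrition_adjusted=True` (default
   off, because the plain estimator satisfies the exact calibration identity
   Σ w λ₀(a) rr / Σ w = λ_m(a), which is testable to machine precision and
   is what the synthetic-truth recovery relies on). Competing mortality
   cancels from the attrition weights because it acts identically on every
   individual under this model.

3. **Discrete-time risk accumulation with competing mortality.** Age runs in
   integer years with at most one event per year, matching the granularity
   of registry rate tables and a 5-year horizon. The absolute risk is
   AR = Σ_t h(a+t) Π_{u<t} (1 − h(a+u) − μ(a+u)) with
   h = min(λ₀ · rr, 1 − μ); the clamp is degenerate-input safety (logged as
   a warning), never triggered at realistic rates. In-situ and invasive
   disease are treated as a single combined endpoint; the incidence table
   defines what counts as a case.

Rate tables are supplied as CSV with columns `age_lo, age_hi, rate`
(inclusive SEER-style bins) and expanded to annual rates by constant
interpolation within each bin. Model specifications round-trip losslessly
through YAML/JSON.

**Missing covariates** in a profile are marginalized, not guessed: because
the model factorizes multiplicatively, the effective relative risk is the
product of the observed covariates' contribution and the reference-weighted
mean contribution of the missing block among reference women who match the
observed categorical values exactly (continuous covariates do not restrict
the matching stratum; an empty stratum falls back to the full reference,
logged). With nothing missing this reduces to the plain relative risk; with
everything missing it reduces to the reference-mean relative risk, so
calibration-in-the-large is preserved.

## Reference-population augmentation

Questionnaire-based reference datasets typically lack density and PRS; both
are added by simulation.

**Density** follows a proportional-odds (cumulative-logit) model,
P(density ≤ k | x) = logistic(α_k − γ·x), chosen because the 4-level
category is ordinal; a multinomial alternative would spend extra parameters
on order violations the data cannot support at 4 levels. Fitting uses
maximum likelihood (statsmodels' ordinal regression); cut-point standard
errors are recovered from the threshold-increment parameterization by the
delta method. Default predictors are age (years), BMI (kg/m²), nulliparity,
postmenopausal status and current MHT use — established density correlates.
The default generating parameters (slopes −0.045/yr age, −0.12 per BMI unit,
+0.35 nulliparous, −0.40 postmenopausal, +0.30 current MHT; cut points
−8.40, −5.94, −3.48) were chosen once so that a US-like population aged
40–74 lands near the familiar 10/40/40/10 BI-RADS split, i.e. roughly half
of women with heterogeneously or extremely dense breasts. Imputation never
overwrites an observed density value.

**PRS** is drawn independently of the questionnaire covariates conditional
on family history. The family-history-positive stratum uses the
exponentially tilted normal p(x | FH=1) ∝ φ(x/σ) exp(θx) with
θ = b/σ, which is N(σb, σ²) in closed form (b = `fh_log_rr_per_sd`,
default 0.25; σ = 1 for a standardized score; FH prevalence 0.12). The
negative stratum draws from the complementary mixture component
(φ − p·f₁)/(1 − p) by rejection from φ, so the population marginal is
N(0, σ²) by construction. The exact complement is not a density in the
extreme upper tail (where p·f₁ > φ, beyond ~7–8 SD at the default
parameters); the sampler clamps the acceptance probability there, an error
many orders of magnitude below the Monte-Carlo resolution of any test in the
suite.

## Synthetic study populations

The generator emulates prospective mammography-cohort conditions: twelve
questionnaire risk factors with literature-plausible marginals and relative
risks (extreme-vs-fatty density RR within the established 2- to 4-fold
band), entry ages uniform on 40–49 (under-50 scenario) or 50–70 (over-50
scenario, matching the 50–70 census band used for stratification), US- and
Sweden-flavoured incidence and competing-mortality tables over ages 30–84,
and annual outcome competition in the fixed order cancer → death →
censoring (the ordering is a tie-break convention; at annual probabilities
of a few per thousand the order is immaterial, but fixing it makes cohorts
bit-reproducible). Censoring is uniform-hazard (default 0.02/year), the
simplest stand-in for registry-linkage attrition.

Follow-up mirrors registry-linkage practice: each woman is simulated for one
entry year plus five follow-up years; events in the entry year are recorded
but flagged excluded (screen-detection guard), and validation predicts from
`entry_age + 1` over τ = 5 so expected and observed cover exactly the same
window for exactly the risk set alive at the start of follow-up.

Nested case-control sampling keeps every eligible case at weight 1 and
samples controls without replacement, each carrying the inverse sampling
fraction as weight, so weighted control totals equal the cohort's. All
statistics treat weights with duplication semantics (doubling a weight
equals duplicating the row).

What the generator deliberately does **not** emulate: screening-detection
dynamics and length bias, tumour subtypes, staggered calendar entry,
measurement error in the questionnaire covariates, percent-density
misclassification around category thresholds, and real between-covariate
dependence beyond the built-in age→menopause→MHT and density/PRS couplings.
Passing tests therefore demonstrate the statistical machinery is correct
under the model's own assumptions — not that the bundled default relative
risks are externally valid for any real population.

## Validation statistics

- **E/O**: Σ w·predicted / Σ w·observed, log-normal 95% CI with Poisson SE
  1/√(unweighted observed cases). First-year-excluded rows are dropped from
  both numerator and denominator.
- **Decile calibration**: weighted empirical-quantile bin edges, bins
  upper-inclusive at edges with the lowest bin closed on the left; tied
  edges merge (logged). Observed-proportion CIs use the Kish effective
  sample size.
- **Slope/intercept**: OLS of decile observed proportions on decile mean
  predicted risk, CIs from the regression t distribution.
- **Goodness of fit**: Hosmer–Lemeshow-type Σ (O−E)²/(E(1−E/n)). The default
  reference distribution is χ² with **df = number of bins**: predictions are
  externally supplied, so no parameters are estimated on the validation
  data. (The development-data convention df = bins − 2 is available via the
  `df` argument; simulation at n = 10,000 over 500 replicates shows df =
  bins holds the nominal 5% level while bins − 2 more than doubles it.)
- **AUC**: weighted Wilcoxon statistic on the 5-year absolute risk, ties
  counted ½, deterministic given input order; Hanley–McNeil SE on Kish
  effective case/control counts. Rank-based, so any strictly monotone
  transform of the risks (e.g. the linear-predictor scale) gives the same
  value. Meta-analysis pools per-study AUCs by fixed-effect inverse
  variance on the AUC scale.
- Crude weighted proportions are the decile default; no Kaplan–Meier
  censoring adjustment is applied (censoring inflates E/O modestly —
  about the mean fraction of follow-up lost — which is visible in demo
  output at nonzero censoring rates and disappears at censoring 0).

## Stratification and reclassification

"Future cases" are expected cases, Σ w·r, not simulated events, because the
population-level quantities are projections from the reference risk
distribution; counts scale by census totals (US 2020: 43,718,160 women
50–70; Sweden 2016: 1,249,695), percentages display at one decimal and
counts round to the nearest integer. In reclassification,
`pct_additional_future_cases` evaluates expected cases under the fuller
model's risks (the better-calibrated reference when density truly carries
risk); `case_denominator="without"` switches conventions. Thresholds are
restricted to (0, 1) — a zero threshold is degenerate (everything is
"above") and excluded by the scenario invariant.

## Simulation sizes in the test suite

The large recovery tests use the over-50 scenario with incidence scaled ×3
(≈4,300 events at n = 100,000, so the calibration-recovery tolerances sit
well above Monte-Carlo noise), censoring 0 (E and O then cover identical
windows and E/O → 1 exactly in expectation), 500 replicates of n = 10,000
for the type-I error of the goodness-of-fit test, n = 20,000 for ordinal
parameter recovery and n = 200,000 for the PRS moment checks. The bundled
demo scenario runs n = 20,000 end to end.

## Known limitations

- The rare-disease calibration and the discrete annual grid are
  approximations; both matter only at hazards far above breast-cancer
  levels, where the attrition-adjusted option and the hazard clamp engage.
- Relative-risk configuration is taken at face value: no shrinkage, no
  uncertainty propagation from the literature estimates into the projected
  risks or their CIs.
- The density-imputation and PRS-coupling families are modelling choices
  (proportional odds; exponential tilt). Both are configurable, but no
  goodness-of-fit machinery is provided for choosing among alternatives.
- Weighted CIs use effective-sample-size approximations rather than design-
  based (e.g. DeLong or bootstrap) variance estimators; correlated-AUC
  contrasts between nested models are reported without a joint covariance.
- Non-European-ancestry transferability is out of scope: the machinery is
  population-agnostic, but every bundled default describes the European-
  ancestry populations the model family has been validated in.
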