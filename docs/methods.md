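# Methods

`hetiv` estimates heterogeneous comparative effectiveness from observational
admission data in four stages — expert-forced covariates, data-driven modifier
selection, local-instrumental-variable effect estimation, and clinician-facing
reporting — together with a synthetic cohort generator that carries an
analytic effect oracle. This note records the models, the parameters that
matter, the numerical choices, and the limits of what the verification suite
shows.

## The estimation problem

The motivating comparison is non-emergency surgery strategies (NES:
antibiotics and/or delayed surgery) versus emergency surgery (ES) for
emergency admissions with acute appendicitis in adults with multiple long-term
conditions (MLTC, at least 2 of 28 defined comorbidities). The outcome is
days alive and out of hospital over 90 days (DAOH, integer 0–90, deaths scored
0). Treatment choice is confounded by unrecorded physiology, so the analysis
is instrumental: the instrument is the hospital's tendency to operate (TTO),
the share of the hospital's eligible admissions in the prior period managed
with NES. Because unobserved factors that drive the choice can also modify
the effect (essential heterogeneity), a local-IV estimator is used rather
than two-stage least squares.

## Synthetic cohort generator (`hetiv.simulate`)

One row per admission under a generalized Roy model:

    D  = 1{ γ0 + γZ·Z + γX'X > V },          V ~ N(0, 1)
    Y(d) = μ0(X) + d·(τ0 + τ'X + ρσ·V) + ε,   ε ~ N(0, σ²)

`Z` is the hospital-period TTO (Beta(2, 11) by default, mean ≈ 0.15); the same
latent shock `V` enters choice and effect (single-factor essential
heterogeneity), giving the closed-form oracle

    MTE(x, u) = τ0 + τ'x + ρσ·Φ⁻¹(u).

Defaults reproduce the published marginals of the motivating national cohort
(N = 24,312; 15% NES; the printed comorbidity prevalences, age bands, sex and
frailty shares, which live in `hetiv.reference`). τ terms may be main effects
or pairwise interactions; the default pattern (τ0 = 2 DAOH; larger gains for
age ≥ 75, frailty, heart failure and kidney disease; losses for cancer;
ρσ = 3) emulates the scale of effects reported for this comparison without
asserting any specific published estimate.

Key mechanics:

- **MLTC rule.** Rows with fewer than two positive comorbidity indicators are
  redrawn. Naive rejection would enrich prevalent comorbidities
  (hypertension drifts from 0.54 to 0.64), so the Bernoulli draw
  probabilities are pre-calibrated by inverting the closed-form
  Poisson-binomial expression for the post-rejection marginal; realized
  prevalences then match the configured ones to binomial noise.
- **Bounded, zero-inflated outcome.** The latent outcome is clamped to
  [0, 90] and a logistic death model (in frailty and age) forces zeros. Both
  are switches: they reproduce the shape of DAOH but distort the linear
  oracle when effects push outcomes across the bounds, so estimator
  verification disables them.
- **γ0 calibration.** The treatment-index intercept is solved by root finding
  so the simulated NES share hits a target (default 15%).
- **Seeding.** One master seed; named substreams (hospitals, patients,
  comorbidities, choice, outcome, death) derived via `SeedSequence.spawn`, so
  cohorts are bit-reproducible.

`well_identified_config()` is the verification regime: uniform TTO on
(0.02, 0.98), balanced arms, no death mass or clamping. The propensity then
sweeps essentially the whole unit interval — the support condition under
which average effects are point identified from MTEs. The study-condition
defaults are deliberately harsher; see "Known limitations".

## Stage 1 — expert elicitation (`hetiv.elicitation`)

Ratings low/medium/high are coded 1/2/3; an item whose mean rating is at
least 2.0 (inclusive: "at least medium") is forced. Surveys with missing
cells are rejected, not imputed, matching the complete-panel design.
Agreement is ICC(2,1) — two-way random effects, absolute agreement, single
rater — with the averaged-rater ICC(2,k) as an option; the computation is
delegated to `pingouin.intraclass_corr` and cross-checked in the tests
against a from-scratch two-way ANOVA decomposition. A zero-variance table
returns NaN with a warning rather than a value.

## Stage 2 — candidate space and PDS LASSO (`hetiv.candidates`, `hetiv.lasso`)

Candidates comprise (a) age-band dummies (reference < 60), sex, frailty;
(b) forced comorbidities; (c) low-priority comorbidities; (d) all comorbidity
pairs plus each comorbidity × each base characteristic — with 28 comorbidities
and 4 base dummies, 490 interactions and 522 terms. A term survives the
volume filter only if each treatment arm has ≥ 50 patients **among its
carriers** (indicator = 1; both parents = 1 for interactions). The
carrier-only reading is the one consistent with a published 42-carrier
comorbidity failing the threshold; the stricter both-levels rule is available
via `rule="both_levels"`. Dropped terms stay in the report for audit.

Rigorous LASSO minimizes `(1/n)‖y − Xb‖² + (λ/n)Σ ψj|bj|` over the penalized
columns only, with the plug-in level `λ = 2c√n·Φ⁻¹(1 − γ/(2p))`, c = 1.1,
γ = 0.1/log n, and heteroskedasticity-robust loadings
`ψj = √(mean(xj²εi²))` iterated (15 rounds, early exit) from a forced-only
residual. Numerics: penalized columns are centered and standardized
internally (loadings are computed there, which is what makes selection
invariant to affine rescaling of inputs); user-supplied loadings are
interpreted on the raw column scale; the solver is covariance-update
coordinate descent on the Gram matrix (exact for this convex problem,
warm-started across loading rounds, convergence when the scale-weighted
coefficient change falls below 1e-10); zero-variance penalized columns are
dropped with a warning.

PDS runs two models: treatment on all candidate terms with the instrument
forced (linear-probability form — standard where the model's role is
selection, not prediction), and outcome on candidate terms plus
treatment×term interaction columns, with treatment and groups a–b forced.
The final modifier set is the union of everything selected with the forced
set. Forced covariates are never penalized and are retained regardless of
their fitted coefficient.

## Stage 3 — local IV (`hetiv.liv`)

The propensity is a probit of treatment on the modifier set, mandated
adjustments (ethnicity, deprivation quintile, age and age², period, teaching
status, hospital quality rates — dummies built internally) and the
instrument; logit is an option. Instrument strength is reported as the
squared HC1-robust t statistic of the instrument in the linear first stage.
Fitted propensities are clipped to [ε, 1−ε], ε = 1e-3 (derivative-based MTE
needs interior values); the clipped count is reported.

The outcome series is

    E[Y | X = x, p] = x'β + Σk αk p^k + Σj δj (xj·p),      k = 1…degree,

fit by least squares with rank-revealing QR to drop aliased columns. The MTE
is the analytic p-derivative, `Σk k·αk·u^(k−1) + δ'x`. Degree 3 is the
default; the basis is a config knob, and `basis="normal"` appends the column
−φ(Φ⁻¹(p)) — the exact selection-correction shape when choice shock and
effect heterogeneity are jointly normal — whose coefficient estimates ρσ.
The polynomial default is the generic series choice; the normal basis is the
better tool when the joint-normal model is credible (it removes the series'
endpoint approximation error, see limitations).

Individual effects integrate the MTE in closed form: over (0, p̂ᵢ] for
treated and (p̂ᵢ, 1) for untreated admissions (person-centred default), or
over (0, 1) for the x-conditional effect. Effects aggregate to one row per
selected term (comorbidity mains: carriers; interactions: joint carriers;
age/sex/frailty: each level), each with n and NES share; the n-weighted mean
of any partition's rows equals the overall mean by construction (asserted to
1e-10). Effects are not truncated to keep subgroup means inside [−90, 90];
a bounded outcome model is not imposed at this stage, and predictions outside
the range surface as such.

Uncertainty is a nonparametric percentile bootstrap. The default resamples
patients and re-estimates stage 3 with the selected modifier set held fixed —
PDS selection is designed to be robust to perturbation, and full re-selection
(`stages="stages23"`) plus hospital-cluster resampling (the instrument is
hospital-level) are exposed as conservative options. Replicates that fail
(degenerate resample) are dropped and counted. Bootstrap refits use a
warm-started Fisher-scoring probit written in-package (the statsmodels fit is
the cross-check in the tests); damped steps and a ridge fallback flag
quasi-separation.

## Stage 4 — reporting (`hetiv.reporting`)

Forest rows carry label, estimate, interval, n, NES share, group key and
indent level (interactions indent under their first parent in grouped mode).
Orderings: by effect size (ties broken by label), by grouping, or custom.
Filters are predicates or term substrings; filtering commutes with ordering.
The dynamic export is a single self-contained HTML file with the rows
embedded as JSON and vanilla-JS sorting/filtering — a shareable stand-in for
a hosted interactive tool; the static export is matplotlib. Writes are
atomic. No multiplicity adjustment is applied by default — the subgroup
estimates are hypothesis-raising, and blanket corrections such as Bonferroni
are conservative here — but `adjust_intervals` offers Bonferroni-style
widening for users who want it.

## Pipeline (`hetiv.pipeline`, CLI)

`run_pipeline` executes stages 1→4 from a `RunConfig` (YAML-loadable;
unknown keys and missing paths are schema errors — validation is by
dataclass-field checks rather than a formal JSON schema, which buys the same
guarantees without another dependency). Every artifact is written with a
SHA-256 recorded in a manifest along with seeds and timings; reruns with the
same seed are bit-identical. Stage failures raise a `StageError` carrying
the stage name and a machine-readable code (schema/data/instrument/
numerical), mapped to distinct CLI exit codes. The `hetiv` command exposes
simulate, validate, elicit, select, estimate, report and run verbs as a thin
layer over the library.

## Verification sizes

The test suite and acceptance script use: 25 random designs (n = 200,
p = 20) for solver-oracle agreement; 100 replicates of n = 5,000 × 200
candidates for selection recovery; n = 20,000 cohorts for MTE recovery
(RMSE tolerance 2.0 DAOH on an interior u-grid, registered before the
estimator was run) and a 20–50-replicate overall-effect bias check; 200 outer
replicates × 200 bootstrap draws at n = 2,000 for interval coverage. These
sizes make every stochastic check reproducible in minutes on one CPU while
keeping Monte-Carlo error well below the asserted margins.

## Known limitations

- **Support-driven extrapolation.** Under the study-condition defaults (15%
  treated, narrow TTO spread) the fitted propensity rarely approaches 1, so
  integrating the MTE over all of (0, 1) extrapolates the polynomial where
  there is no data; with essential heterogeneity (ρσ > 0) the overall-effect
  estimate is then unstable across seeds. This is an identification fact,
  not a solver artifact: average effects are only point identified when the
  propensity sweeps the unit interval. Recovery checks therefore run in the
  wide-support regime, and `basis="normal"` is the recommended setting when
  effects must be aggregated from a one-sided propensity distribution and
  joint normality is acceptable.
- **Oracle scale.** The effect oracle lives on the latent outcome scale;
  with clamping and the death mass enabled, the realized effect on observed
  DAOH is attenuated relative to the oracle. Tests that demand exact oracle
  agreement disable both switches.
- **What passing tests do not show.** The generator matches marginal
  prevalences and arm shares, not the dependence structure, coding noise or
  case-mix of real administrative data; ICD-coding behaviour, readmission
  dynamics and hospital case-mix are out of scope. Passing recovery tests
  demonstrates estimator correctness under the stated model, not robustness
  to misspecification of the choice equation or outcome series.
- The percentile bootstrap quantifies resampling variation given the fixed
  modifier set; re-selection uncertainty is only captured under the
  conservative `stages="stages23"` option.
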