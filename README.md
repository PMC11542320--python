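# hetiv

Heterogeneous comparative effectiveness from observational admission cohorts,
combining clinical judgment with machine-learning covariate selection and
instrumental-variable estimation.

## The problem

For emergency admissions — the motivating case is acute appendicitis in
adults with multiple long-term conditions (≥2 of 28 defined comorbidities) —
clinicians must choose between non-emergency surgery strategies (NES:
antibiotics and/or delayed surgery) and emergency surgery (ES). Randomized
evidence largely excludes these patients, and in administrative data the
choice is confounded by unrecorded physiology. `hetiv` implements a 4-stage
analysis that produces subgroup-level effect estimates a clinical user can
trust and interrogate:

1. **Expert elicitation** — a clinician panel rates each comorbidity
   low/medium/high; items with mean rating ≥ medium become *forced*
   covariates (never penalized away), and inter-rater agreement is summarised
   by an intraclass correlation.
2. **Data-driven selection** — a candidate space of >500 terms (mains, all
   comorbidity pairs, comorbidity × age/sex/frailty interactions) is screened
   by a 50-per-arm volume rule, then *rigorous LASSO* — plug-in penalty
   λ = 2c√n·Φ⁻¹(1 − γ/2p) with iterated heteroskedasticity-robust loadings —
   is run as post-double selection (PDS): treatment model and outcome model
   (with treatment×term interaction columns), keeping the union of selections.
3. **Local-IV estimation** — with the hospital tendency-to-operate (TTO,
   the prior-period NES share) as a continuous instrument, a probit
   propensity p̂ feeds the outcome series
   `E[Y|x, p] = x'β + Σₖ αₖ pᵏ + Σⱼ δⱼ(xⱼ·p)`, whose p-derivative is the
   marginal treatment effect `MTE(x, u) = Σₖ k·αₖ·u^{k−1} + δ'x` — the effect
   for patients at unobserved-resistance quantile u. Closed-form integration
   gives person-centred individual effects, aggregated to subgroups with
   percentile-bootstrap intervals.
4. **Reporting** — forest plots ordered by effect size or by grouping, focal
   subgroup views, and a self-contained interactive HTML export showing
   estimate, CI, n and NES rate per row.

The outcome throughout is DAOH: days alive and out of hospital over 90 days
(deaths score 0). A synthetic cohort generator reproduces the published
marginals of the motivating national cohort (N = 24,312, 15% NES) under a
generalized Roy model whose analytic oracle `MTE(x,u) = τ₀ + τ'x + ρσ·Φ⁻¹(u)`
makes every stage verifiable end to end.

## Worked example

`examples/04_mte_estimation.py` fits the local-IV model on a simulated cohort
with known effects (τ₀ = 5, τ_frailty = 4, τ_CHF = 5, ρσ = 3, n = 20,000):

```
first-stage F for the instrument: 11689
MTE(x-bar, u=0.2): estimated   3.72   true   3.16
MTE(x-bar, u=0.5): estimated   5.28   true   5.69
MTE(x-bar, u=0.8): estimated   8.26   true   8.21
overall effect: 5.94 DAOH (oracle ATE 5.67)
                label  estimate     n  nes_share
            not frail  5.527230 17681   0.492959
                frail  9.079707  2319   0.561018
chronic heart failure 10.488031   892   0.571749
```

Reading this: the instrument is strongly relevant (F ≫ 100); the estimated
MTE rises in u because the unobserved factor that makes surgery more likely
also lowers the benefit of avoiding it (ρσ > 0), tracking the closed-form
truth across quantiles; the overall mean effect lands within sampling error
of the oracle ATE; and frail and heart-failure subgroups show the larger
gains built into the generator. Each example in `examples/` is a short
narrative script for one capability (simulation, elicitation, selection,
estimation, reporting, full pipeline).

A thin CLI wraps the same functions:

```bash
hetiv simulate --n 24312 --seed 0 --out cohort.csv
hetiv validate cohort.csv
hetiv run --config run.yaml        # stages 1-4 + provenance manifest
```

## Documentation

`docs/methods.md` describes the models and their assumptions, the defaults
and why, the numerical choices (penalty constants, clipping, tie-breaks,
degenerate inputs), what the synthetic generator does and does not emulate,
and known limitations — in particular the propensity-support requirement for
aggregating marginal effects, and the optional joint-normal control-function
basis (`basis="normal"`) for one-sided propensity distributions.
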