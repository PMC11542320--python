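"""Synthetic admission cohorts under a generalized Roy model with known effects.

The generator emulates the structure of a hospital administrative extract:
one row per emergency admission with a binary treatment (1 = non-emergency
surgery strategy, NES; 0 = emergency surgery, ES), an integer outcome DAOH
(days alive and out of hospital over 90 days, deaths scored 0), a continuous
hospital-level instrument TTO (tendency to operate: the share of the
hospital's admissions in the prior period managed with NES), patient
characteristics, and 28 binary comorbidity indicators with every patient
carrying at least two (the MLTC inclusion rule).

Treatment choice follows a latent-index (generalized Roy) model

    D = 1{ gamma_0 + gamma_Z * Z + gamma_X' X > V },   V ~ N(0, 1),

and potential outcomes have a single-factor essentially heterogeneous effect

    Y(d) = mu_0(X) + d * (tau_0 + tau' X + rho_sigma * V) + eps.

Because the same latent shock V drives both choice and effect, the marginal
treatment effect at unobserved-resistance quantile u has the closed form

    MTE(x, u) = tau_0 + tau' x + rho_sigma * Phi^{-1}(u),

which is exposed as :func:`true_mte` and is the oracle every estimation stage
is verified against.  Death is a separate logistic mass (in frailty and age)
that forces the outcome to zero, and the latent outcome is clamped to
[0, 90]; both are switches, since they distort the linear oracle when the
effect pushes outcomes across the bounds.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import reference

BASE_CHARS = ("age_60_74", "age_75_plus", "sex", "frailty")

#: default heterogeneous effect pattern (DAOH units).  Chosen once to emulate
#: the scale of the motivating comparison: modest average benefit of NES with
#: larger gains for older, frail patients and for cardiac/renal disease and
#: losses for cancer, including two pairwise interactions.
DEFAULT_MODIFIERS: dict[str, float] = {
    "age_60_74": 2.0,
    "age_75_plus": 6.0,
    "frailty": 4.0,
    "chronic_heart_failure": 5.0,
    "chronic_kidney_disease": 4.0,
    "diabetes": 2.0,
    "cancer": -5.0,
    "chronic_heart_failure:chronic_kidney_disease": 6.0,
    "cancer:hypertension": -7.0,
}

DEFAULT_TREATMENT_COEFS: dict[str, float] = {
    "age_60_74": 0.3,
    "age_75_plus": 0.8,
    "frailty": 0.3,
    "chronic_heart_failure": 0.4,
    "chronic_kidney_disease": 0.2,
    "dementia": 0.6,
    "cancer": 0.3,
    "diabetes": 0.1,
}

DEFAULT_BASELINE_COEFS: dict[str, float] = {
    "age_60_74": -4.0,
    "age_75_plus": -10.0,
    "frailty": -8.0,
    "chronic_heart_failure": -5.0,
    "chronic_kidney_disease": -3.0,
    "cancer": -6.0,
    "dementia": -5.0,
    "hosp_mortality": -20.0,
    "hosp_readmission": -10.0,
}

#: logistic model for 90-day death (outcome mass at zero)
DEFAULT_DEATH_MODEL: dict[str, float] = {
    "intercept": -4.5,
    "frailty": 1.2,
    "age_60_74": 0.3,
    "age_75_plus": 0.8,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the published marginals of the motivating cohort
    (N = 24,312 admissions, 15% NES, the printed comorbidity prevalences and
    age/sex/frailty shares) with a heterogeneous effect pattern on the DAOH
    scale.
    """

    n_patients: int = reference.N_TOTAL
    n_hospitals: int = 150
    n_periods: int = 10
    #: hospital-period TTO distribution: ("beta", a, b) or ("uniform", lo, hi)
    tto_distribution: tuple = ("beta", 2.0, 11.0)
    comorbidity_prevalences: dict[str, float] = field(
        default_factory=reference.comorbidity_prevalences
    )
    age_band_probs: tuple[float, float, float] = field(
        default_factory=reference.age_band_probs
    )
    sex_prob: float = field(default_factory=reference.female_prob)
    frailty_prob: float = field(default_factory=reference.frailty_prob)
    ethnicity_probs: tuple = field(default_factory=reference.ethnicity_probs)
    imd_probs: tuple = field(default_factory=reference.imd_probs)
    #: IV relevance gamma_Z; with the default TTO spread this yields a very
    #: strong first stage at the study's n.
    iv_strength: float = 3.0
    treatment_index_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_COEFS)
    )
    #: treatment-index intercept gamma_0; if None it is calibrated so the
    #: treated (NES) share matches ``target_treated_share``.
    gamma_0: float | None = None
    target_treated_share: float = field(default_factory=reference.nes_share)
    baseline_intercept: float = 72.0
    baseline_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_COEFS)
    )
    baseline_effect: float = 2.0  # tau_0
    modifier_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODIFIERS)
    )
    unobserved_slope: float = 3.0  # rho_sigma
    outcome_noise_sd: float = 12.0
    death_prob_model: dict[str, float] | None = field(
        default_factory=lambda: dict(DEFAULT_DEATH_MODEL)
    )
    clamp_outcome: bool = True
    round_outcome: bool = True
    enforce_mltc: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_hospitals <= 0 or self.n_periods <= 0:
            raise ValueError("n_hospitals and n_periods must be positive")
        probs = list(self.comorbidity_prevalences.values()) + [
            self.sex_prob,
            self.frailty_prob,
            *self.age_band_probs,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.age_band_probs) - 1.0) > 1e-9:
            raise ValueError("age_band_probs must sum to 1")
        kind = self.tto_distribution[0]
        if kind not in ("beta", "uniform"):
            raise ValueError(f"unknown tto distribution {kind!r}")
        if kind == "uniform":
            lo, hi = self.tto_distribution[1:]
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError("uniform TTO support must be within [0, 1]")
        if self.enforce_mltc:
            positive = sum(p > 0 for p in self.comorbidity_prevalences.values())
            if positive < 2:
                raise ValueError(
                    "MLTC rule (>=2 comorbidities) is unattainable: fewer than "
                    "2 comorbidities have positive prevalence"
                )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                json.loads(json.dumps(dataclasses.asdict(self), default=list)),
                fh, sort_keys=False,
            )


@dataclass
class OracleEffects:
    """Ground truth attached to a generated cohort."""

    person_effect: np.ndarray  # tau_0 + tau'x_i + rho_sigma * V_i
    conditional_effect: np.ndarray  # tau_0 + tau'x_i
    ate: float  # mean of person effects (Monte-Carlo ATE)
    tau_0: float
    modifier_effects: dict[str, float]
    unobserved_slope: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "ate": self.ate,
                    "tau_0": self.tau_0,
                    "modifier_effects": self.modifier_effects,
                    "unobserved_slope": self.unobserved_slope,
                    "person_effect": self.person_effect.tolist(),
                    "conditional_effect": self.conditional_effect.tolist(),
                },
                fh,
            )


def _rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Named substreams derived deterministically from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw_tto(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    kind, *params = config.tto_distribution
    size = (config.n_hospitals, config.n_periods)
    if kind == "beta":
        return rng.beta(params[0], params[1], size=size)
    lo, hi = params
    return rng.uniform(lo, hi, size=size)


def _mltc_adjusted_prevalences(targets: np.ndarray, max_iter: int = 500,
                               tol: float = 1e-10) -> np.ndarray:
    """Draw probabilities q such that marginals AFTER the >=2 rule hit targets.

    Rejection sampling (redraw rows with fewer than 2 positive indicators)
    enriches every indicator, most strongly the prevalent ones.  Under
    independent Bernoulli(q) draws the post-rejection marginal has the closed
    form r_c = q_c (1 - prod_{j != c}(1 - q_j)) / (1 - P0 - P1), with P0, P1
    the Poisson-binomial probabilities of 0 and 1 positives; this fixed-point
    iteration inverts that map.  Falls back to the unadjusted probabilities
    (with a warning) if no feasible q exists.
    """
    t = np.asarray(targets, float)
    q = t.copy()
    pos = t > 0
    for _ in range(max_iter):
        one_minus = 1.0 - q
        prod_all = np.prod(one_minus)
        with np.errstate(divide="ignore", invalid="ignore"):
            prod_wo = np.where(one_minus > 0, prod_all / one_minus, 0.0)
        p0 = prod_all
        p1 = float(np.sum(np.where(one_minus > 0, q / one_minus, 0.0)) * prod_all)
        accept = 1.0 - p0 - p1
        if accept <= 0:
            break
        r = q * (1.0 - prod_wo) / accept
        if np.max(np.abs(r[pos] - t[pos])) < tol:
            return q
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(pos & (r > 0), np.clip(q * t / np.where(r > 0, r, 1.0),
                                                0.0, 0.999), q * 0.0)
    warnings.warn("could not calibrate prevalences to the MLTC rule; "
                  "using unadjusted draw probabilities", stacklevel=2)
    return t


def _draw_comorbidities(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli comorbidity matrix; rows with <2 positives are redrawn.

    Draw probabilities are pre-adjusted so that the post-rejection marginal
    prevalences match the configured ones.
    """
    names = list(config.comorbidity_prevalences)
    prev = np.array([config.comorbidity_prevalences[c] for c in names])
    n = config.n_patients
    if not config.enforce_mltc:
        return (rng.random((n, len(names))) < prev).astype(np.int8)
    q = _mltc_adjusted_prevalences(prev)
    mat = (rng.random((n, len(names))) < q).astype(np.int8)
    for _ in range(1000):
        bad = mat.sum(axis=1) < 2
        if not bad.any():
            return mat
        mat[bad] = (rng.random((bad.sum(), len(names))) < q).astype(np.int8)
    raise RuntimeError("MLTC rejection sampling did not terminate")


def term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    """Evaluate a (possibly interaction) term name on cohort columns.

    Interaction terms are colon-joined parent names; the column is the
    product of the parents.
    """
    parts = term.split(":")
    col = np.ones(len(df))
    for p in parts:
        col = col * df[p].to_numpy(dtype=float)
    return col


def _effect_terms(df: pd.DataFrame, modifiers: Mapping[str, float]) -> np.ndarray:
    out = np.zeros(len(df))
    for term, coef in modifiers.items():
        out += coef * term_column(df, term)
    return out


def _calibrate_gamma0(index_wo_g0: np.ndarray, target: float) -> float:
    """Solve mean(Phi(g0 + index)) = target for g0."""

    def f(g0: float) -> float:
        return stats.norm.cdf(g0 + index_wo_g0).mean() - target

    return optimize.brentq(f, -12.0, 12.0, xtol=1e-10)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, OracleEffects]:
    """Simulate an admission cohort and its effect oracle.

    Returns the cohort as a DataFrame (one row per admission, booleans coded
    0/1) and an :class:`OracleEffects` with the per-patient true effects.
    Reproducible for a fixed ``config.seed``.
    """
    config.validate()
    rngs = _rngs(
        config.seed,
        ["hospital", "patient", "comorbidity", "choice", "outcome", "death"],
    )
    n = config.n_patients

    # hospitals: TTO per hospital-period plus hospital-level quality covariates
    hosp_rng = rngs["hospital"]
    tto_grid = _draw_tto(config, hosp_rng)
    teaching = (hosp_rng.random(config.n_hospitals) < 0.25).astype(np.int8)
    mort = np.clip(hosp_rng.normal(0.10, 0.02, config.n_hospitals), 0.01, 0.30)
    readm = np.clip(hosp_rng.normal(0.15, 0.03, config.n_hospitals), 0.01, 0.40)

    pr = rngs["patient"]
    hospital_id = pr.integers(0, config.n_hospitals, n)
    period = pr.integers(0, config.n_periods, n)
    tto = tto_grid[hospital_id, period]

    age_band = pr.choice(3, size=n, p=np.asarray(config.age_band_probs))
    age_lo = np.array([18.0, 60.0, 75.0])[age_band]
    age_hi = np.array([60.0, 75.0, 95.0])[age_band]
    age = age_lo + pr.random(n) * (age_hi - age_lo)
    sex = (pr.random(n) < config.sex_prob).astype(np.int8)
    frailty = (pr.random(n) < config.frailty_prob).astype(np.int8)
    ethnicity = pr.choice(len(config.ethnicity_probs), size=n,
                          p=np.asarray(config.ethnicity_probs))
    imd = 1 + pr.choice(len(config.imd_probs), size=n,
                        p=np.asarray(config.imd_probs))

    comorb = _draw_comorbidities(config, rngs["comorbidity"])
    comorb_names = list(config.comorbidity_prevalences)

    df = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "hospital_id": hospital_id,
            "period": period,
            "tto": tto,
            "age": age,
            "age_band": age_band,
            "age_60_74": (age_band == 1).astype(np.int8),
            "age_75_plus": (age_band == 2).astype(np.int8),
            "sex": sex,
            "frailty": frailty,
            "ethnicity": ethnicity,
            "imd_quintile": imd,
            "teaching_hospital": teaching[hospital_id],
            "hosp_mortality": mort[hospital_id],
            "hosp_readmission": readm[hospital_id],
        }
    )
    for j, name in enumerate(comorb_names):
        df[name] = comorb[:, j]

    # treatment choice
    index_wo_g0 = config.iv_strength * tto + _effect_terms(
        df, config.treatment_index_coefs
    )
    if config.gamma_0 is not None:
        gamma_0 = config.gamma_0
    else:
        gamma_0 = _calibrate_gamma0(index_wo_g0, config.target_treated_share)
    v = rngs["choice"].standard_normal(n)
    treatment = (gamma_0 + index_wo_g0 > v).astype(np.int8)
    df["treatment"] = treatment

    # effects and outcomes
    cond_effect = config.baseline_effect + _effect_terms(
        df, config.modifier_effects
    )
    person_effect = cond_effect + config.unobserved_slope * v

    mu0 = config.baseline_intercept + _effect_terms(df, config.baseline_coefs)
    eps = rngs["outcome"].normal(0.0, config.outcome_noise_sd, n)
    y = mu0 + treatment * person_effect + eps
    if config.clamp_outcome:
        y = np.clip(y, 0.0, 90.0)

    died = np.zeros(n, dtype=np.int8)
    if config.death_prob_model:
        dm = dict(config.death_prob_model)
        lin = dm.pop("intercept", -5.0) + _effect_terms(df, dm)
        p_death = 1.0 / (1.0 + np.exp(-lin))
        died = (rngs["death"].random(n) < p_death).astype(np.int8)
        y = np.where(died == 1, 0.0, y)
    df["died"] = died
    df["outcome"] = np.rint(y).astype(int) if config.round_outcome else y

    _assert_cohort_invariants(df, config)

    oracle = OracleEffects(
        person_effect=person_effect,
        conditional_effect=cond_effect,
        ate=float(person_effect.mean()),
        tau_0=config.baseline_effect,
        modifier_effects=dict(config.modifier_effects),
        unobserved_slope=config.unobserved_slope,
    )
    return df, oracle


def _assert_cohort_invariants(df: pd.DataFrame, config: SimulationConfig) -> None:
    out = df["outcome"].to_numpy()
    if config.clamp_outcome and (out.min() < 0 or out.max() > 90):
        raise AssertionError("outcome outside [0, 90]")
    if ((df["died"] == 1) & (df["outcome"] != 0)).any():
        raise AssertionError("death must imply zero DAOH")
    if config.enforce_mltc:
        counts = df[list(config.comorbidity_prevalences)].sum(axis=1)
        if (counts < 2).any():
            raise AssertionError("MLTC rule violated (<2 comorbidities)")
    if df["tto"].min() < 0 or df["tto"].max() > 1:
        raise AssertionError("tto outside [0, 1]")


def true_mte(
    config: SimulationConfig, x: Mapping[str, float], u: float | np.ndarray
) -> float | np.ndarray:
    """Closed-form marginal treatment effect MTE(x, u).

    ``x`` maps covariate names to values; interaction terms in the config are
    evaluated as products of the named parents.  ``u`` is the
    unobserved-resistance quantile and must lie strictly inside (0, 1).
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0.0) or np.any(u_arr >= 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    val = config.baseline_effect
    for term, coef in config.modifier_effects.items():
        prod = 1.0
        for p in term.split(":"):
            prod *= float(x.get(p, 0.0))
        val += coef * prod
    out = val + config.unobserved_slope * stats.norm.ppf(u_arr)
    return float(out) if np.isscalar(u) else out


def true_subgroup_effect(
    config: SimulationConfig,
    subgroup: Callable[[pd.DataFrame], np.ndarray] | None = None,
    n_draws: int = 200_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo oracle for the average effect within a subgroup.

    ``subgroup`` is a predicate mapping a cohort frame to a boolean mask
    (``None`` selects everyone).  Since the latent choice shock is independent
    of covariates, the subgroup mean of the person-level effect equals
    ``tau_0 + tau' E[x | subgroup]``, estimated here by simulating covariates
    from the configured distribution.  Returns (estimate, standard error).
    """
    mc = dataclasses.replace(
        config,
        n_patients=n_draws,
        seed=config.seed + 1_000_003 if seed is None else seed,
        gamma_0=config.gamma_0 if config.gamma_0 is not None else 0.0,
    )
    df, oracle = generate_cohort(mc)
    mask = np.ones(len(df), bool) if subgroup is None else np.asarray(subgroup(df))
    if mask.sum() == 0:
        raise ValueError("subgroup is empty in the covariate distribution")
    vals = oracle.conditional_effect[mask]
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(mask.sum()))


def well_identified_config(
    n_patients: int = 20_000,
    seed: int = 0,
    baseline_effect: float = 5.0,
    modifier_effects: Mapping[str, float] | None = None,
    unobserved_slope: float = 3.0,
    outcome_noise_sd: float = 10.0,
) -> SimulationConfig:
    """A configuration in which the local-IV estimand is point identified.

    Full-support instrument variation (uniform hospital TTO on (0.02, 0.98)),
    balanced treatment arms, no death mass and no outcome clamping: the
    propensity then sweeps essentially the whole unit interval, which is the
    textbook support requirement for recovering average effects from marginal
    treatment effects.  Used for estimator verification; the study-condition
    defaults of :class:`SimulationConfig` are deliberately harsher (15%
    treated share, narrow TTO spread, zero-inflated bounded outcome).
    """
    if modifier_effects is None:
        modifier_effects = {"frailty": 4.0, "chronic_heart_failure": 5.0}
    treat_coefs = {t.split(":")[0]: 0.3 for t in modifier_effects}
    base_coefs = {t: -6.0 for t in treat_coefs}
    return SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        tto_distribution=("uniform", 0.02, 0.98),
        iv_strength=3.0,
        target_treated_share=0.5,
        treatment_index_coefs=treat_coefs,
        baseline_intercept=45.0,
        baseline_coefs=base_coefs,
        baseline_effect=baseline_effect,
        modifier_effects=dict(modifier_effects),
        unobserved_slope=unobserved_slope,
        outcome_noise_sd=outcome_noise_sd,
        death_prob_model=None,
        clamp_outcome=False,
        round_outcome=False,
    )


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort with the documented header (booleans as 0/1)."""
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
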