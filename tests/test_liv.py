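"""Local-IV stage: instrument, propensity, MTE, effects, bootstrap."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hetiv
from hetiv.liv import (
    BootstrapSpec,
    InstrumentError,
    MTEModel,
    _probit_mle,
    aggregate_subgroups,
    bootstrap_ci,
    compute_tto,
    fit_mte,
    fit_propensity,
    person_effects,
)
from hetiv.simulate import well_identified_config

from conftest import toy_cohort


# ---------------------------------------------------------------- instrument
def test_compute_tto_hand_fixtures():
    df = pd.DataFrame(
        {
            "hospital_id": [1] * 6 + [2] * 4,
            "period": [0, 0, 0, 1, 1, 1, 0, 0, 1, 1],
            "treatment": [1, 1, 1, 0, 1, 0, 1, 0, 0, 0],
        }
    )
    tto = compute_tto(df)
    # hospital 1, period 1: prior period was all NES -> 1.0
    assert tto[3] == pytest.approx(1.0)
    # hospital 2, period 1: prior period 1 of 2 NES -> 0.5
    assert tto[8] == pytest.approx(0.5)
    # period-0 admissions have no prior volume
    assert tto[[0, 1, 2, 6, 7]].isna().all()


def test_compute_tto_fraction():
    df = pd.DataFrame(
        {
            "hospital_id": [5] * 11,
            "period": [0] * 10 + [1],
            "treatment": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
        }
    )
    assert compute_tto(df)[10] == pytest.approx(0.3)  # 3 NES of 10


def test_compute_tto_matches_brute_force():
    df = toy_cohort(n=500, seed=2)
    tto = compute_tto(df)
    for i in np.random.default_rng(0).choice(500, 40, replace=False):
        h, p = df.loc[i, "hospital_id"], df.loc[i, "period"]
        prior = df[(df["hospital_id"] == h) & (df["period"] == p - 1)]
        if len(prior) == 0:
            assert np.isnan(tto[i])
        else:
            assert tto[i] == pytest.approx(prior["treatment"].mean())


def test_compute_tto_single_period_warns():
    df = toy_cohort(n=50, seed=0, n_periods=1)
    with pytest.warns(UserWarning, match="prior-period"):
        tto = compute_tto(df)
    assert tto.isna().all()


# ---------------------------------------------------------------- propensity
def test_probit_newton_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(800), rng.standard_normal((800, 3))])
    y = (X @ np.array([-0.3, 0.8, -0.5, 0.2])
         > rng.standard_normal(800)).astype(float)
    beta, converged, _ = _probit_mle(X, y)
    ref = sm.Probit(y, X).fit(disp=0)
    assert converged
    assert np.allclose(beta, ref.params, atol=1e-6)


def test_propensity_instrument_sign_and_strength(simple_selection):
    hits = 0
    for seed in range(20):
        cfg = well_identified_config(n_patients=10_000, seed=seed)
        cohort, _ = hetiv.generate_cohort(cfg)
        prop = fit_propensity(cohort, simple_selection, adjustments=None)
        if prop.coef["tto"] > 0:
            hits += 1
        assert prop.f_stat > 100  # strong first stage by construction
    assert hits == 20


def test_propensity_null_instrument_f_near_one(simple_selection):
    fs = []
    for seed in range(20):
        cfg = dataclasses.replace(
            well_identified_config(n_patients=4_000, seed=seed),
            iv_strength=0.0, gamma_0=0.0,
        )
        cohort, _ = hetiv.generate_cohort(cfg)
        fs.append(fit_propensity(cohort, simple_selection,
                                 adjustments=None).f_stat)
    assert np.median(fs) < 3.0


def test_constant_instrument_raises(simple_selection):
    cfg = well_identified_config(n_patients=500, seed=0)
    cohort, _ = hetiv.generate_cohort(cfg)
    cohort["tto"] = 0.4
    with pytest.raises(InstrumentError):
        fit_propensity(cohort, simple_selection, adjustments=None)


def test_propensity_clipping_reported(simple_selection):
    cfg = well_identified_config(n_patients=5_000, seed=1)
    cohort, _ = hetiv.generate_cohort(cfg)
    prop = fit_propensity(cohort, simple_selection, adjustments=None, eps=0.2)
    assert prop.n_clipped == int(
        ((prop.phat <= 0.2) | (prop.phat >= 0.8)).sum()
    ) > 0
    assert prop.phat.min() >= 0.2 and prop.phat.max() <= 0.8


# ----------------------------------------------------------------------- MTE
def test_degree_one_no_modifiers_equals_2sls(identified_cohort):
    _, cohort, _ = identified_cohort
    sel = hetiv.SelectionResult(x_forced=[], x_selected_d=[],
                                x_selected_y=[], selected_interactions=[])
    prop = fit_propensity(cohort, sel, adjustments=None)
    model = fit_mte(cohort, prop, sel, degree=1, adjustments=None)
    # MTE constant in x and u, equal to the fitted p coefficient
    assert model.mte(np.empty((1, 0)), 0.3) == pytest.approx(model.poly_coef[0])
    assert model.mte(np.empty((1, 0)), 0.7) == pytest.approx(model.poly_coef[0])
    # direct 2SLS with phat as the instrument for the treatment indicator
    y = cohort["outcome"].to_numpy(float)
    d = cohort["treatment"].to_numpy(float)
    W = np.column_stack([np.ones(len(d)), d])
    Z = np.column_stack([np.ones(len(d)), prop.phat])
    beta_2sls = np.linalg.solve(Z.T @ W, Z.T @ y)
    # the probit MLE fitted values satisfy the OLS orthogonality only
    # approximately, so the match is close but not exact ...
    assert model.poly_coef[0] == pytest.approx(beta_2sls[1], rel=1e-3)
    # ... whereas with the linear projection of d on phat as the propensity,
    # degree-1 LIV and 2SLS coincide to machine precision
    proj = np.linalg.lstsq(Z, d, rcond=None)[0]
    prop_lin = dataclasses.replace(prop, phat=Z @ proj)
    model_lin = fit_mte(cohort, prop_lin, sel, degree=1, adjustments=None)
    assert model_lin.poly_coef[0] == pytest.approx(beta_2sls[1], rel=1e-9)


def test_mte_recovery_against_closed_form(identified_cohort, simple_selection):
    cfg, cohort, _ = identified_cohort
    prop = fit_propensity(cohort, simple_selection, adjustments=None)
    model = fit_mte(cohort, prop, simple_selection, adjustments=None)
    xbar = cohort[simple_selection.x_selected].mean()
    lo = max(0.10, prop.phat.min() + 0.02)
    hi = min(0.90, prop.phat.max() - 0.02)
    ug = np.linspace(lo, hi, 33)
    est = model.mte(xbar.to_numpy()[None, :], ug).ravel()
    tru = np.array([hetiv.true_mte(cfg, xbar.to_dict(), float(u)) for u in ug])
    rmse = float(np.sqrt(np.mean((est - tru) ** 2)))
    assert rmse < 2.0  # pre-registered tolerance, DAOH units


def test_flat_mte_when_no_essential_heterogeneity(simple_selection):
    cfg = dataclasses.replace(
        well_identified_config(n_patients=20_000, seed=8), unobserved_slope=0.0
    )
    cohort, _ = hetiv.generate_cohort(cfg)
    prop = fit_propensity(cohort, simple_selection, adjustments=None)
    model = fit_mte(cohort, prop, simple_selection, adjustments=None)
    xbar = cohort[simple_selection.x_selected].mean().to_numpy()[None, :]
    ug = np.linspace(prop.phat.min() + 0.02, prop.phat.max() - 0.02, 21)
    dev = np.abs(model.mte(xbar, ug).ravel()
                 - float(model.mte(xbar, 0.5)))
    # analytic SE of the deviation via the OLS covariance of the p-polynomial
    se = _mte_dev_se(cohort, prop, model, simple_selection, ug)
    assert np.all(dev <= 3.0 * se + 1e-9)


def _mte_dev_se(cohort, prop, model, sel, ug):
    """Delta-method SE of MTE(u) - MTE(0.5) from the outcome OLS fit."""
    from hetiv.liv import _stage3_design_names

    p = prop.phat
    mat, names = _stage3_design_names(cohort, sel, None)
    cols = [np.ones(len(cohort))] + [mat[c].to_numpy(float) for c in names]
    for k in range(1, model.degree + 1):
        cols.append(p**k)
    for m in model.modifier_names:
        cols.append(mat[m].to_numpy(float) * p)
    X = np.column_stack(cols)
    y = cohort["outcome"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    XtX_inv = np.linalg.pinv(X.T @ X)
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    V = XtX_inv * sigma2
    npoly = model.degree
    off = 1 + len(names)
    ses = []
    for u in ug:
        g = np.zeros(X.shape[1])
        for k in range(1, npoly + 1):
            g[off + k - 1] = k * (u ** (k - 1) - 0.5 ** (k - 1))
        ses.append(np.sqrt(g @ V @ g))
    return np.asarray(ses)


def test_mte_extrapolation_warns(identified_cohort, simple_selection):
    _, cohort, _ = identified_cohort
    prop = fit_propensity(cohort, simple_selection, adjustments=None)
    model = fit_mte(cohort, prop, simple_selection, adjustments=None)
    bad_u = (prop.phat.min() / 2.0) if prop.phat.min() > 2e-3 else 1e-4
    with pytest.warns(UserWarning, match="support"):
        model.mte(np.zeros((1, 2)), bad_u)
    with pytest.raises(ValueError):
        model.mte(np.zeros((1, 2)), 0.0)


# ------------------------------------------------------------ person effects
def test_person_effect_integrals_match_numeric_quadrature():
    # hand-built model: closed-form integrals vs trapezoid quadrature
    model = MTEModel(
        baseline_names=["const"], modifier_names=["frailty"],
        poly_coef=np.array([4.0, -3.0, 2.0]),
        baseline_coef=np.array([1.0]), modifier_coef=np.array([2.5]),
        degree=3, support=(0.01, 0.99),
    )
    rng = np.random.default_rng(0)
    n = 50
    cohort = pd.DataFrame({
        "frailty": rng.integers(0, 2, n),
        "treatment": rng.integers(0, 2, n),
    })
    phat = rng.uniform(0.05, 0.95, n)
    prop = hetiv.PropensityFit(
        coef={}, names=[], phat=phat, f_stat=np.nan, n_clipped=0, eps=1e-3,
        link="probit", converged=True, separation=False, instrument_col="tto",
    )
    eff = person_effects(model, prop, cohort, mode="person")
    ug = np.linspace(1e-6, 1 - 1e-6, 20_001)
    for i in range(0, n, 7):
        x = cohort[["frailty"]].iloc[[i]].to_numpy(float)
        mte_u = model.mte(x, ug).ravel()
        p = phat[i]
        if cohort["treatment"].iloc[i] == 1:
            mask = ug <= p
        else:
            mask = ug > p
        expected = np.trapezoid(mte_u[mask], ug[mask]) / (
            ug[mask][-1] - ug[mask][0]
        )
        assert eff["effect"].iloc[i] == pytest.approx(expected, abs=5e-3)
    cond = person_effects(model, prop, cohort, mode="conditional")
    full = np.trapezoid(model.mte(np.array([[1.0]]), ug).ravel(), ug)
    assert cond.loc[cohort["frailty"] == 1, "effect"].iloc[0] == pytest.approx(
        full, abs=5e-3
    )


def test_conditional_effects_recover_analytic_values(identified_cohort,
                                                     simple_selection):
    cfg, cohort, oracle = identified_cohort
    prop = fit_propensity(cohort, simple_selection, adjustments=None)
    model = fit_mte(cohort, prop, simple_selection, adjustments=None)
    eff = person_effects(model, prop, cohort, mode="conditional")
    # x-conditional effect equals tau_0 + tau'x since Phi^{-1} integrates to 0
    assert eff["effect"].mean() == pytest.approx(
        oracle.conditional_effect.mean(), abs=1.0
    )


def test_treated_high_propensity_person_effect_approaches_conditional():
    model = MTEModel(
        baseline_names=["const"], modifier_names=[],
        poly_coef=np.array([4.0, -3.0, 2.0]), baseline_coef=np.array([0.0]),
        modifier_coef=np.empty(0), degree=3, support=(0.001, 0.999),
    )
    cohort = pd.DataFrame({"treatment": [1, 1]})
    for p, tol in ((0.999, 0.02), (0.9999, 0.002)):
        prop = hetiv.PropensityFit(
            coef={}, names=[], phat=np.array([p, 0.5]), f_stat=np.nan,
            n_clipped=0, eps=1e-6, link="probit", converged=True,
            separation=False, instrument_col="tto",
        )
        person = person_effects(model, prop, cohort, mode="person")
        cond = person_effects(model, prop, cohort, mode="conditional")
        assert abs(person["effect"].iloc[0] - cond["effect"].iloc[0]) < tol


def test_support_limited_flag():
    model = MTEModel(
        baseline_names=[], modifier_names=[], poly_coef=np.array([1.0]),
        baseline_coef=np.empty(0), modifier_coef=np.empty(0), degree=1,
        support=(0.001, 0.999),
    )
    prop = hetiv.PropensityFit(
        coef={}, names=[], phat=np.array([1e-3, 0.5]), f_stat=np.nan,
        n_clipped=1, eps=1e-3, link="probit", converged=True,
        separation=False, instrument_col="tto",
    )
    cohort = pd.DataFrame({"treatment": [0, 1]})
    eff = person_effects(model, prop, cohort)
    assert bool(eff["support_limited"].iloc[0]) and not bool(
        eff["support_limited"].iloc[1]
    )


# ---------------------------------------------------------------- aggregation
def test_homogeneous_effects_give_identical_subgroups(simple_selection):
    cfg = well_identified_config(n_patients=4_000, seed=4, modifier_effects={},
                                 unobserved_slope=0.0, baseline_effect=5.0)
    cfg = dataclasses.replace(
        cfg,
        treatment_index_coefs={"frailty": 0.3, "chronic_heart_failure": 0.4},
        baseline_coefs={"frailty": -6.0},
    )
    cohort, _ = hetiv.generate_cohort(cfg)
    eff = pd.DataFrame({"effect": np.full(len(cohort), 5.0),
                        "support_limited": False})
    est = aggregate_subgroups(eff, cohort, simple_selection)
    assert est.overall["estimate"] == 5.0
    assert (est.table["estimate"] == 5.0).all()


def test_partition_identity(identified_cohort, simple_selection):
    _, cohort, _ = identified_cohort
    sel = hetiv.SelectionResult(
        x_forced=["age_60_74", "age_75_plus", "sex", "frailty",
                  "chronic_heart_failure"],
        x_selected_d=[], x_selected_y=[],
        selected_interactions=["frailty:chronic_heart_failure"],
    )
    prop = fit_propensity(cohort, sel, adjustments=None)
    model = fit_mte(cohort, prop, sel, adjustments=None)
    eff = person_effects(model, prop, cohort)
    est = aggregate_subgroups(eff, cohort, sel)
    assert est.overall["estimate"] == pytest.approx(
        eff["effect"].mean(), abs=1e-12
    )
    for term in ("age_band", "sex", "frailty"):
        rows = est.table[est.table["term"] == term]
        w = (rows["estimate"] * rows["n"]).sum() / rows["n"].sum()
        assert w == pytest.approx(est.overall["estimate"], abs=1e-10)
        assert rows["n"].sum() == est.overall["n"]


def test_subgroup_ordering_matches_oracle():
    mods = {"chronic_heart_failure": 15.0, "cancer": -12.0}
    cfg = well_identified_config(n_patients=20_000, seed=12,
                                 modifier_effects=mods)
    cohort, oracle = hetiv.generate_cohort(cfg)
    sel = hetiv.SelectionResult(
        x_forced=["chronic_heart_failure", "cancer"], x_selected_d=[],
        x_selected_y=[], selected_interactions=[],
    )
    prop = fit_propensity(cohort, sel, adjustments=None)
    model = fit_mte(cohort, prop, sel, adjustments=None)
    eff = person_effects(model, prop, cohort)
    est = aggregate_subgroups(eff, cohort, sel)
    tab = est.table.set_index("term")["estimate"]
    assert tab["chronic_heart_failure"] > est.overall["estimate"] > tab["cancer"]
    true_chf = oracle.conditional_effect[
        cohort["chronic_heart_failure"] == 1].mean()
    true_can = oracle.conditional_effect[cohort["cancer"] == 1].mean()
    # rare-carrier subgroups (cancer ~3% prevalence) carry sizable sampling
    # noise in their modifier-by-p coefficient
    assert tab["chronic_heart_failure"] == pytest.approx(true_chf, abs=5.0)
    assert tab["cancer"] == pytest.approx(true_can, abs=5.0)


# ------------------------------------------------------------------ bootstrap
def test_bootstrap_deterministic_and_interval_sane(simple_selection):
    cfg = well_identified_config(n_patients=2_000, seed=6)
    cohort, _ = hetiv.generate_cohort(cfg)
    spec = BootstrapSpec(n_replicates=40, seed=99)
    a = bootstrap_ci(cohort, simple_selection, spec, adjustments=None)
    b = bootstrap_ci(cohort, simple_selection, spec, adjustments=None)
    assert a.overall == b.overall  # bit-identical under the same seed
    pd.testing.assert_frame_equal(a.table, b.table)
    assert a.overall["ci_low"] <= a.overall["estimate"] <= a.overall["ci_high"]
    assert a.meta["bootstrap"]["failures"] == 0


def test_bootstrap_width_degenerates_without_noise(simple_selection):
    # with zero outcome noise and no essential heterogeneity the only
    # resampling variation left is the binomial treatment draw, so intervals
    # are narrow and shrink with n (the percentile width estimates sampling
    # spread, which vanishes as information grows)
    widths = {}
    for n in (1_000, 8_000):
        cfg = well_identified_config(
            n_patients=n, seed=2, modifier_effects={}, unobserved_slope=0.0,
            baseline_effect=5.0, outcome_noise_sd=0.0,
        )
        cfg = dataclasses.replace(
            cfg, treatment_index_coefs={"frailty": 0.3}, baseline_coefs={}
        )
        cohort, _ = hetiv.generate_cohort(cfg)
        sel = hetiv.SelectionResult(x_forced=["frailty"], x_selected_d=[],
                                    x_selected_y=[], selected_interactions=[])
        est = bootstrap_ci(cohort, sel, BootstrapSpec(n_replicates=60, seed=1),
                           adjustments=None)
        widths[n] = est.overall["ci_high"] - est.overall["ci_low"]
        assert est.overall["estimate"] == pytest.approx(5.0, abs=1.0)
    assert widths[8_000] < widths[1_000]
    assert widths[8_000] < 1.5


def test_bootstrap_hospital_cluster_unit(simple_selection):
    cfg = well_identified_config(n_patients=2_000, seed=13)
    cohort, _ = hetiv.generate_cohort(cfg)
    spec = BootstrapSpec(n_replicates=20, seed=5, unit="hospital")
    est = bootstrap_ci(cohort, simple_selection, spec, adjustments=None)
    assert est.meta["bootstrap"]["unit"] == "hospital"
    assert np.isfinite(est.overall["ci_low"])
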