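"""Rigorous LASSO solver and post-double selection."""

import numpy as np
import pandas as pd
import pytest

import hetiv
from hetiv.candidates import CandidateSet, Term
from hetiv.elicitation import PrioritySet
from hetiv.lasso import PenalizedDesign, pds_select, plugin_lambda, rigorous_lasso


def random_design(n, p, seed, sigma=1.0, beta=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    b = np.zeros(p) if beta is None else beta
    y = X @ b + sigma * rng.standard_normal(n)
    return X, y


def qp_oracle(X, y, lam, loadings, forced_idx=(), fit_intercept=True):
    """Generic convex-solver solution of the same penalized least squares.

    Split b = b+ - b- with nonnegativity; the objective is smooth in
    (b+, b-), solved by L-BFGS-B with box constraints.  Entirely independent
    of the coordinate-descent path.  The intercept is handled by centering;
    loadings apply on the raw column scale.
    """
    from scipy.optimize import minimize

    n, p = X.shape
    yc = y - y.mean() if fit_intercept else y
    Xc = X - X.mean(axis=0) if fit_intercept else X
    pen_idx = [j for j in range(p) if j not in forced_idx]
    weights = np.zeros(p)
    for k, j in enumerate(pen_idx):
        weights[j] = lam * loadings[k] / (2.0 * n)

    def fun(z):
        bp, bm = z[:p], z[p:]
        b = bp - bm
        r = yc - Xc @ b
        grad_b = -2.0 * (Xc.T @ r) / n
        f = float(r @ r / n + 2.0 * weights @ (bp + bm))
        g = np.concatenate([grad_b + 2.0 * weights, -grad_b + 2.0 * weights])
        return f, g

    res = minimize(fun, np.zeros(2 * p), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * p),
                   options={"maxiter": 20000, "ftol": 1e-18, "gtol": 1e-12})
    coef = res.x[:p] - res.x[p:]
    return coef, res.fun


def test_full_shrinkage_at_huge_lambda():
    X, y = random_design(100, 8, 0, beta=np.ones(8))
    design = PenalizedDesign(y=y, X=X, names=[f"x{j}" for j in range(8)],
                             forced=[], penalized=list(range(8)))
    fit = rigorous_lasso(design, lam=1e9)
    assert np.allclose(fit.coef, 0.0)
    assert fit.active == []


def test_zero_lambda_recovers_least_squares():
    X, y = random_design(60, 5, 1, beta=np.arange(5, dtype=float))
    design = PenalizedDesign(y=y, X=X, names=[f"x{j}" for j in range(5)],
                             forced=[], penalized=list(range(5)))
    fit = rigorous_lasso(design, lam=0.0)
    Xi = np.column_stack([np.ones(60), X])
    ols = np.linalg.lstsq(Xi, y, rcond=None)[0]
    assert np.allclose(fit.coef, ols[1:], atol=1e-7)
    assert fit.intercept == pytest.approx(ols[0], abs=1e-7)


def test_matches_convex_solver_oracle_with_forced_columns():
    n, p = 200, 20
    X, y = random_design(n, p, 5, beta=np.r_[np.array([2.0, -1.5]), np.zeros(18)])
    names = [f"x{j}" for j in range(p)]
    forced, penal = [0], list(range(1, p))
    lam = plugin_lambda(n, len(penal))
    loadings = np.ones(len(penal))
    fit = rigorous_lasso(
        PenalizedDesign(y=y, X=X, names=names, forced=forced, penalized=penal,
                        loadings=loadings),
        lam=lam,
    )
    coef_o, f_o = qp_oracle(X, y, lam, loadings, forced_idx=forced)
    f_cd = _objective(X, y, fit.coef, lam, loadings, penal)
    assert abs(f_cd - f_o) < 1e-6
    active_cd = {names[j] for j in penal if abs(fit.coef[j]) > 1e-6}
    active_o = {names[j] for j in penal if abs(coef_o[j]) > 1e-6}
    assert active_cd == active_o
    assert names[0] not in fit.active  # forced never counted as "selected"


def _objective(X, y, coef, lam, loadings, penal):
    n = len(y)
    inter = y.mean() - X.mean(0) @ coef
    r = y - inter - X @ coef
    pen = sum(loadings[k] * abs(coef[j]) for k, j in enumerate(penal))
    return float(r @ r / n + lam * pen / n)


def test_orthonormal_design_soft_thresholding():
    # on X with X'X/n = I the lasso is soft-thresholding of the OLS solution
    n, p = 400, 6
    rng = np.random.default_rng(2)
    Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
    X = Q * np.sqrt(n)  # columns orthonormal under the 1/n inner product
    beta = np.array([3.0, -2.0, 1.0, 0.5, 0.0, 0.0])
    y = X @ beta + 0.1 * rng.standard_normal(n)
    lam = 0.8 * n  # threshold lam/(2n) = 0.4
    loadings = np.ones(p)
    fit = rigorous_lasso(
        PenalizedDesign(y=y, X=X, names=list("abcdef"), forced=[],
                        penalized=list(range(p)), loadings=loadings),
        lam=lam, fit_intercept=False,
    )
    ols = X.T @ y / n
    thresh = lam / (2 * n)
    expected = np.sign(ols) * np.maximum(np.abs(ols) - thresh, 0.0)
    assert np.allclose(fit.coef, expected, atol=1e-7)


def test_selection_invariant_to_column_order_and_rescaling():
    n, p = 300, 12
    beta = np.zeros(p)
    beta[[1, 4]] = [1.5, -2.0]
    X, y = random_design(n, p, 7, beta=beta)
    names = [f"x{j}" for j in range(p)]
    base = rigorous_lasso(PenalizedDesign(
        y=y, X=X, names=names, forced=[], penalized=list(range(p))))
    # rescale penalized columns
    scale = np.linspace(0.2, 5.0, p)
    fit_s = rigorous_lasso(PenalizedDesign(
        y=y, X=X * scale, names=names, forced=[], penalized=list(range(p))))
    assert set(base.active) == set(fit_s.active)
    assert np.allclose(fit_s.coef * scale, base.coef, atol=1e-6)
    # permute columns
    perm = np.random.default_rng(0).permutation(p)
    fit_p = rigorous_lasso(PenalizedDesign(
        y=y, X=X[:, perm], names=[names[j] for j in perm], forced=[],
        penalized=list(range(p))))
    assert set(base.active) == set(fit_p.active)


def test_input_validation_and_degenerate_columns():
    X, y = random_design(50, 3, 0)
    with pytest.raises(ValueError, match="non-finite"):
        PenalizedDesign(y=np.r_[y[:-1], np.nan], X=X, names=list("abc"),
                        forced=[], penalized=[0, 1, 2])
    with pytest.raises(ValueError, match="overlap"):
        PenalizedDesign(y=y, X=X, names=list("abc"), forced=[0],
                        penalized=[0, 1])
    Xz = X.copy()
    Xz[:, 2] = 7.0  # zero variance
    with pytest.warns(UserWarning, match="zero-variance"):
        fit = rigorous_lasso(PenalizedDesign(
            y=y, X=Xz, names=list("abc"), forced=[], penalized=[0, 1, 2]))
    assert fit.dropped == ["c"]
    assert fit.coef[2] == 0.0


def _toy_candidates(names):
    return CandidateSet(group_a=[], group_b=[],
                        group_c=[Term(n, (n,), "c") for n in names],
                        group_d=[])


def test_pds_selects_true_confounders_and_forces_forced():
    rng = np.random.default_rng(1)
    n, p = 4000, 60
    names = [f"v{j:02d}" for j in range(p)]
    X = rng.standard_normal((n, p))
    z = rng.random(n)
    conf = [0, 1, 2]  # affect both treatment and outcome
    d = (0.8 * z + X[:, conf] @ np.array([0.6, -0.6, 0.6])
         + rng.standard_normal(n) > 0.4).astype(float)
    y = 2.0 * d + X[:, conf] @ np.array([3.0, 3.0, -3.0]) + rng.standard_normal(n)
    cohort = pd.DataFrame(X, columns=names)
    cohort["treatment"] = d
    cohort["outcome"] = y
    cohort["tto"] = z
    cands = _toy_candidates(names)
    sel = pds_select(cohort, cands, None)
    for j in conf:
        assert names[j] in sel.x_selected
    # union rule
    assert set(sel.x_selected_d) | set(sel.x_selected_y) <= set(sel.x_selected)

    # a forced term with zero coefficient is still retained
    cands_f = CandidateSet(
        group_a=[], group_b=[Term("v59", ("v59",), "b")],
        group_c=[Term(n, (n,), "c") for n in names[:-1]], group_d=[],
    )
    sel_f = pds_select(cohort, cands_f, None)
    assert "v59" in sel_f.x_forced and "v59" in sel_f.x_selected


def test_pds_false_selection_rate_is_controlled():
    # pure-noise candidates under a null DGP: the plug-in penalty keeps the
    # average number of false selections small
    counts = []
    for seed in range(15):
        rng = np.random.default_rng(seed)
        n, p = 600, 50
        names = [f"v{j:02d}" for j in range(p)]
        cohort = pd.DataFrame(rng.standard_normal((n, p)), columns=names)
        cohort["tto"] = rng.random(n)
        cohort["treatment"] = (rng.random(n) < 0.3).astype(float)
        cohort["outcome"] = rng.standard_normal(n)
        sel = pds_select(cohort, _toy_candidates(names), None)
        counts.append(len(sel.x_selected))
    assert np.mean(counts) < 2.0


def test_pds_empty_candidates_returns_forced_with_warning():
    rng = np.random.default_rng(0)
    cohort = pd.DataFrame({
        "treatment": rng.integers(0, 2, 100).astype(float),
        "outcome": rng.standard_normal(100),
        "tto": rng.random(100),
    })
    empty = CandidateSet(group_a=[], group_b=[], group_c=[], group_d=[])
    with pytest.warns(UserWarning, match="empty"):
        sel = pds_select(cohort, empty, None)
    assert sel.x_selected == []
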