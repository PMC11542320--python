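"""Stage 3: local-IV estimation of marginal, individual and subgroup effects.

The estimator follows the separate-effects (local instrumental variable)
approach for a binary treatment with a continuous preference-based
instrument.  A probit propensity p(x, z) = Phi(x'b + g z) is fitted with the
hospital tendency-to-operate (TTO) as the instrument; the conditional mean
outcome is then modelled as a series in the propensity,

    E[Y | X = x, p] = x' beta + sum_k alpha_k p^k + sum_j delta_j (x_j p),

so that the marginal treatment effect at unobserved-resistance quantile u is
the analytic derivative

    MTE(x, u) = sum_k k alpha_k u^{k-1} + sum_j delta_j x_j .

Individual effects integrate the MTE over u: over (0, p_i] for treated
patients and (p_i, 1) for untreated ones (person-centred, the default), or
over (0, 1) for the x-conditional effect; both integrals are closed-form
polynomial expressions.  Individual effects are aggregated to subgroups
defined by the selected modifier terms, with percentile bootstrap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .candidates import design_matrix
from .lasso import SelectionResult

DEFAULT_ADJUSTMENTS = (
    "ethnicity",
    "imd_quintile",
    "age",
    "age_sq",
    "period",
    "teaching_hospital",
    "hosp_mortality",
    "hosp_readmission",
)
_CATEGORICAL = {"ethnicity", "imd_quintile", "period"}

AGE_LEVELS = {
    "age under 60": lambda df: (df["age_60_74"] == 0) & (df["age_75_plus"] == 0),
    "age 60-74": lambda df: df["age_60_74"] == 1,
    "age 75+": lambda df: df["age_75_plus"] == 1,
}


class InstrumentError(ValueError):
    """The instrument is degenerate or absent."""


def compute_tto(cohort: pd.DataFrame,
                treatment_col: str = "treatment") -> pd.Series:
    """Instrument from raw admissions: prior-period NES share per hospital.

    For each admission, the share of the same hospital's admissions in the
    immediately preceding period that were managed non-operatively.  The index
    admission belongs to the current period so it never enters its own
    instrument.  Admissions with no prior-period volume get NaN (flagged).
    """
    for col in ("hospital_id", "period"):
        if col not in cohort.columns:
            raise KeyError(f"cohort lacks required column {col!r}")
    grp = cohort.groupby(["hospital_id", "period"])[treatment_col].agg(
        ["sum", "size"]
    )
    share = (grp["sum"] / grp["size"]).rename("tto_hat")
    key = pd.MultiIndex.from_arrays(
        [cohort["hospital_id"], cohort["period"] - 1]
    )
    out = pd.Series(
        share.reindex(key).to_numpy(), index=cohort.index, name="tto_hat"
    )
    if out.isna().all():
        warnings.warn(
            "no admission has prior-period volume (single-period data?); "
            "all instrument values are flagged missing",
            stacklevel=2,
        )
    return out


def build_adjustments(
    cohort: pd.DataFrame, names: tuple[str, ...] | list[str] = DEFAULT_ADJUSTMENTS
) -> pd.DataFrame:
    """Mandated adjustment columns: categoricals as dummies, age-squared derived."""
    out = {}
    for name in names:
        if name == "age_sq":
            out["age_sq"] = cohort["age"].to_numpy(float) ** 2
        elif name in _CATEGORICAL:
            col = cohort[name]
            levels = sorted(col.unique())
            for lv in levels[1:]:  # first level is the reference
                out[f"{name}_{lv}"] = (col == lv).astype(float).to_numpy()
        else:
            out[name] = cohort[name].to_numpy(float)
    return pd.DataFrame(out, index=cohort.index)


def _probit_mle(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray | None = None,
    maxiter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, bool, bool]:
    """Probit MLE by Fisher scoring; returns (beta, converged, separation_flag).

    On an ill-conditioned information matrix (e.g., quasi-separation) a small
    ridge is added and the fit is flagged.
    """
    n, k = X.shape
    beta = np.zeros(k) if start is None else start.copy()
    separation = False
    converged = False
    for _ in range(maxiter):
        xb = np.clip(X @ beta, -8.0, 8.0)
        p = stats.norm.cdf(xb)
        pdf = stats.norm.pdf(xb)
        denom = np.clip(p * (1.0 - p), 1e-12, None)
        score = X.T @ (pdf * (y - p) / denom)
        W = pdf**2 / denom
        H = X.T @ (X * W[:, None])
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            separation = True
            delta = np.linalg.solve(H + 1e-6 * np.eye(k), score)
        # dampen huge steps (quasi-separation)
        step = np.max(np.abs(delta))
        if step > 10.0:
            delta *= 10.0 / step
            separation = True
        beta = beta + delta
        if step < tol:
            converged = True
            break
    return beta, converged, separation


def _logit_mle(X, y, start=None, maxiter=100, tol=1e-10):
    n, k = X.shape
    beta = np.zeros(k) if start is None else start.copy()
    separation = False
    converged = False
    for _ in range(maxiter):
        p = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30)))
        score = X.T @ (y - p)
        W = np.clip(p * (1 - p), 1e-12, None)
        H = X.T @ (X * W[:, None])
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            separation = True
            delta = np.linalg.solve(H + 1e-6 * np.eye(k), score)
        step = np.max(np.abs(delta))
        if step > 10.0:
            delta *= 10.0 / step
            separation = True
        beta = beta + delta
        if step < tol:
            converged = True
            break
    return beta, converged, separation


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove linearly dependent columns (rank-revealing QR)."""
    if X.shape[1] == 0:
        return X, names, []
    _, R, piv = _qr_pivot(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [names[j] for j in sorted(piv[rank:])]
    return X[:, keep], [names[j] for j in keep], dropped


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


@dataclass
class PropensityFit:
    coef: dict[str, float]
    names: list[str]
    phat: np.ndarray  # clipped to [eps, 1-eps]
    f_stat: float  # first-stage (robust) F for the instrument
    n_clipped: int
    eps: float
    link: str
    converged: bool
    separation: bool
    instrument_col: str
    dropped: list[str] = field(default_factory=list)


def _stage3_design_names(
    cohort: pd.DataFrame,
    selection: SelectionResult,
    adjustments: tuple[str, ...] | list[str] | None,
) -> tuple[pd.DataFrame, list[str]]:
    """Modifier + adjustment columns used by both stage-3 models."""
    mod = design_matrix(cohort, selection.x_selected)
    if adjustments:
        adj = build_adjustments(cohort, adjustments)
        adj = adj[[c for c in adj.columns if c not in mod.columns]]
        mat = pd.concat([mod, adj], axis=1)
    else:
        mat = mod
    return mat, list(mat.columns)


def fit_propensity(
    cohort: pd.DataFrame,
    selection: SelectionResult,
    adjustments: tuple[str, ...] | list[str] | None = DEFAULT_ADJUSTMENTS,
    instrument_col: str = "tto",
    treatment_col: str = "treatment",
    link: str = "probit",
    eps: float = 1e-3,
    start: np.ndarray | None = None,
) -> PropensityFit:
    """Probit (or logit) treatment model with the instrument, plus first-stage F.

    The instrument-strength F statistic is the squared HC1-robust t statistic
    of the instrument in the linear first stage on the same covariates.
    """
    z = cohort[instrument_col].to_numpy(float)
    if np.ptp(z) < 1e-12:
        raise InstrumentError("instrument has zero variance")
    if np.isnan(z).any():
        raise InstrumentError("instrument contains missing values")
    mat, names = _stage3_design_names(cohort, selection, adjustments)
    X = np.column_stack([np.ones(len(cohort)), mat.to_numpy(float), z])
    all_names = ["const"] + names + [instrument_col]
    X, kept_names, dropped = _drop_aliased(X, all_names)
    if instrument_col not in kept_names:
        raise InstrumentError("instrument aliased with covariates")
    if dropped:
        warnings.warn(f"dropping aliased propensity columns: {dropped}",
                      stacklevel=2)
    d = cohort[treatment_col].to_numpy(float)

    mle = _probit_mle if link == "probit" else _logit_mle
    if start is not None and len(start) != X.shape[1]:
        start = None
    beta, converged, separation = mle(X, d, start=start)
    xb = X @ beta
    p_raw = stats.norm.cdf(xb) if link == "probit" else 1 / (1 + np.exp(-xb))
    phat = np.clip(p_raw, eps, 1.0 - eps)
    n_clipped = int(((p_raw < eps) | (p_raw > 1.0 - eps)).sum())

    # robust first-stage F for the instrument (linear probability first stage)
    zi = kept_names.index(instrument_col)
    XtX_inv = np.linalg.pinv(X.T @ X)
    bhat = XtX_inv @ (X.T @ d)
    resid = d - X @ bhat
    n, k = X.shape
    meat = (X * resid[:, None]).T @ (X * resid[:, None])
    vcov = XtX_inv @ meat @ XtX_inv * (n / max(n - k, 1))
    f_stat = float(bhat[zi] ** 2 / vcov[zi, zi])

    return PropensityFit(
        coef=dict(zip(kept_names, beta)),
        names=kept_names,
        phat=phat,
        f_stat=f_stat,
        n_clipped=n_clipped,
        eps=eps,
        link=link,
        converged=converged,
        separation=separation,
        instrument_col=instrument_col,
        dropped=dropped,
    )


@dataclass
class MTEModel:
    """Outcome series in the propensity; MTE is its analytic p-derivative.

    With ``basis="polynomial"`` (default) the control function is the pure
    power series in p.  ``basis="normal"`` appends the inverse-Mills-type
    column -phi(Phi^{-1}(p)), the exact selection-correction shape when the
    latent choice shock and the effect heterogeneity are jointly normal; its
    coefficient is the loading of the unobserved heterogeneity, and the MTE
    gains the term mills_coef * Phi^{-1}(u).
    """

    baseline_names: list[str]  # x columns (incl. const)
    modifier_names: list[str]  # x columns interacted with p
    poly_coef: np.ndarray  # alpha_1..alpha_degree
    baseline_coef: np.ndarray
    modifier_coef: np.ndarray
    degree: int
    support: tuple[float, float]  # observed range of phat
    basis: str = "polynomial"
    mills_coef: float = 0.0
    dropped: list[str] = field(default_factory=list)

    def mte(self, x_mod: np.ndarray | pd.DataFrame, u) -> np.ndarray | float:
        """MTE(x, u) for modifier rows x_mod (columns = modifier_names).

        Returns an (n_rows, n_u) array, squeezed to a vector or scalar when a
        single row and/or scalar u is given.
        """
        u_arr = np.atleast_1d(np.asarray(u, float))
        if np.any(u_arr <= 0.0) or np.any(u_arr >= 1.0):
            raise ValueError("u must lie strictly inside (0, 1)")
        if np.any(u_arr < self.support[0] - 1e-9) or np.any(
            u_arr > self.support[1] + 1e-9
        ):
            warnings.warn("evaluating MTE outside the observed propensity "
                          "support (extrapolation)", stacklevel=2)
        x = np.atleast_2d(np.asarray(x_mod, float))
        ks = np.arange(1, self.degree + 1)
        dpoly = (self.poly_coef * ks) @ np.power.outer(u_arr, ks - 1).T
        if self.basis == "normal":
            dpoly = dpoly + self.mills_coef * stats.norm.ppf(u_arr)
        xi = x @ self.modifier_coef if x.shape[1] else np.zeros(x.shape[0])
        res = xi[:, None] + dpoly[None, :]
        if res.shape[0] == 1:
            res = res[0]
            if np.isscalar(u):
                return float(res[0])
        return res


def fit_mte(
    cohort: pd.DataFrame,
    propensity: PropensityFit,
    selection: SelectionResult,
    degree: int = 3,
    adjustments: tuple[str, ...] | list[str] | None = DEFAULT_ADJUSTMENTS,
    outcome_col: str = "outcome",
    basis: str = "polynomial",
) -> MTEModel:
    """Least-squares fit of the outcome series in the propensity.

    Baseline terms are the modifier set plus mandated adjustments; the
    polynomial basis in p has the configured degree; modifier x p interaction
    columns carry the observable heterogeneity.  basis="normal" appends the
    joint-normal selection-correction column -phi(Phi^{-1}(p)).
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if basis not in ("polynomial", "normal"):
        raise ValueError("basis must be 'polynomial' or 'normal'")
    p = propensity.phat
    y = cohort[outcome_col].to_numpy(float)
    mat, names = _stage3_design_names(cohort, selection, adjustments)
    modifier_names = list(selection.x_selected)
    Xmod = mat[modifier_names].to_numpy(float) if modifier_names else np.empty(
        (len(cohort), 0)
    )
    cols = [np.ones(len(cohort))] + [mat[c].to_numpy(float) for c in names]
    col_names = ["const"] + names
    for k in range(1, degree + 1):
        cols.append(p**k)
        col_names.append(f"p^{k}")
    if basis == "normal":
        cols.append(-stats.norm.pdf(stats.norm.ppf(p)))
        col_names.append("mills(p)")
    for j, m in enumerate(modifier_names):
        cols.append(Xmod[:, j] * p)
        col_names.append(f"{m}:p")
    X = np.column_stack(cols)
    X, kept, dropped = _drop_aliased(X, col_names)
    if dropped:
        warnings.warn(f"dropping aliased outcome columns: {dropped}",
                      stacklevel=2)
    missing_poly = [f"p^{k}" for k in range(1, degree + 1) if f"p^{k}" not in kept]
    if missing_poly:
        raise ValueError(f"propensity polynomial aliased: {missing_poly}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coef = dict(zip(kept, beta))
    mod_kept = [m for m in modifier_names if f"{m}:p" in kept]
    base_names = [
        c for c in kept
        if not c.endswith(":p") and not c.startswith("p^") and c != "mills(p)"
    ]
    return MTEModel(
        baseline_names=base_names,
        modifier_names=mod_kept,
        poly_coef=np.array([coef[f"p^{k}"] for k in range(1, degree + 1)]),
        baseline_coef=np.array([coef[c] for c in base_names]),
        modifier_coef=np.array([coef[f"{m}:p"] for m in mod_kept]),
        degree=degree,
        support=(float(p.min()), float(p.max())),
        basis=basis,
        mills_coef=float(coef.get("mills(p)", 0.0)),
        dropped=dropped,
    )


def person_effects(
    model: MTEModel,
    propensity: PropensityFit,
    cohort: pd.DataFrame,
    mode: str = "person",
    treatment_col: str = "treatment",
) -> pd.DataFrame:
    """Individual-level effects by closed-form integration of the MTE.

    mode="person" integrates MTE(x_i, u) over u in (0, p_i] for treated and
    (p_i, 1) for untreated admissions; mode="conditional" integrates over the
    full (0, 1), giving the x-conditional average effect.  Returns a frame
    with columns effect, mode, support_limited.
    """
    if mode not in ("person", "conditional"):
        raise ValueError("mode must be 'person' or 'conditional'")
    p = propensity.phat
    xi = (
        design_matrix(cohort, model.modifier_names).to_numpy(float)
        @ model.modifier_coef
        if model.modifier_names
        else np.zeros(len(cohort))
    )
    alpha = model.poly_coef
    ks = np.arange(1, model.degree + 1)
    if mode == "conditional":
        eff = xi + alpha.sum()  # integral of mills_coef * Phi^{-1}(u) over (0,1) is 0
    else:
        d = cohort[treatment_col].to_numpy()
        pk = np.power.outer(p, ks)  # p^k
        treated_part = (pk / p[:, None]) @ alpha  # sum alpha_k p^{k-1}
        untreated_part = ((1.0 - pk) @ alpha) / (1.0 - p)
        if model.basis == "normal" and model.mills_coef != 0.0:
            mills = stats.norm.pdf(stats.norm.ppf(p))
            treated_part = treated_part - model.mills_coef * mills / p
            untreated_part = untreated_part + model.mills_coef * mills / (1.0 - p)
        eff = xi + np.where(d == 1, treated_part, untreated_part)
    limited = (p <= propensity.eps) | (p >= 1.0 - propensity.eps)
    return pd.DataFrame(
        {"effect": eff, "support_limited": limited}, index=cohort.index
    ).assign(mode=mode)


@dataclass
class EffectEstimates:
    """Per-subgroup effect estimates with intervals and context counts."""

    overall: dict
    table: pd.DataFrame  # label, term, estimate, ci_low, ci_high, n, nes_share, suppressed
    person: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "overall": self.overall,
                    "subgroups": self.table.to_dict(orient="records"),
                    "meta": self.meta,
                },
                fh,
                indent=2,
                default=float,
            )


def _subgroup_masks(
    cohort: pd.DataFrame, selection: SelectionResult
) -> list[tuple[str, str, np.ndarray]]:
    """(label, term, mask) for every reportable subgroup.

    Age/sex/frailty base characteristics contribute one row per level;
    comorbidity mains contribute their carrier set; interaction terms the
    joint-carrier set.
    """
    out: list[tuple[str, str, np.ndarray]] = []
    terms = selection.x_selected
    age_done = sex_done = frail_done = False
    for t in terms:
        if t in ("age_60_74", "age_75_plus"):
            if not age_done and "age_60_74" in cohort.columns:
                for label, pred in AGE_LEVELS.items():
                    out.append((label, "age_band", pred(cohort).to_numpy()))
                age_done = True
        elif t == "sex":
            if not sex_done:
                out.append(("male", "sex", (cohort["sex"] == 0).to_numpy()))
                out.append(("female", "sex", (cohort["sex"] == 1).to_numpy()))
                sex_done = True
        elif t == "frailty":
            if not frail_done:
                out.append(("not frail", "frailty", (cohort["frailty"] == 0).to_numpy()))
                out.append(("frail", "frailty", (cohort["frailty"] == 1).to_numpy()))
                frail_done = True
        else:
            label = t.replace(":", " & ").replace("_", " ")
            mask = design_matrix(cohort, [t]).to_numpy(float).ravel() == 1
            out.append((label, t, mask))
    return out


def aggregate_subgroups(
    effects: pd.DataFrame,
    cohort: pd.DataFrame,
    selection: SelectionResult,
    reporting_floor: int = 10,
    treatment_col: str = "treatment",
) -> EffectEstimates:
    """Aggregate individual effects to the reportable subgroups.

    The overall estimate is the mean of per-patient effects; each subgroup row
    carries its size and NES share.  Rows below the reporting floor are
    emitted with a suppression flag rather than dropped.
    """
    eff = effects["effect"].to_numpy(float)
    if len(eff) != len(cohort):
        raise ValueError("effects are not aligned with the cohort")
    d = cohort[treatment_col].to_numpy()
    rows = []
    for label, term, mask in _subgroup_masks(cohort, selection):
        n = int(mask.sum())
        rows.append(
            {
                "label": label,
                "term": term,
                "estimate": float(eff[mask].mean()) if n else float("nan"),
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "n": n,
                "nes_share": float(d[mask].mean()) if n else float("nan"),
                "suppressed": n < reporting_floor,
            }
        )
    overall = {
        "estimate": float(eff.mean()),
        "ci_low": float("nan"),
        "ci_high": float("nan"),
        "n": int(len(eff)),
        "nes_share": float(d.mean()),
    }
    return EffectEstimates(
        overall=overall, table=pd.DataFrame(rows), person=effects,
        meta={"reporting_floor": reporting_floor},
    )


@dataclass
class BootstrapSpec:
    n_replicates: int = 200
    seed: int = 0
    unit: str = "patient"  # or "hospital"
    stages: str = "stage3"  # or "stages23" (re-run selection per replicate)
    interval: str = "percentile"
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one bootstrap replicate")
        if self.unit not in ("patient", "hospital"):
            raise ValueError("unit must be 'patient' or 'hospital'")
        if self.stages not in ("stage3", "stages23"):
            raise ValueError("stages must be 'stage3' or 'stages23'")


def _stage3_estimates(
    cohort: pd.DataFrame,
    selection: SelectionResult,
    adjustments,
    degree: int,
    mode: str,
    eps: float,
    start: np.ndarray | None = None,
    reporting_floor: int = 10,
    basis: str = "polynomial",
) -> tuple[EffectEstimates, PropensityFit]:
    prop = fit_propensity(cohort, selection, adjustments, eps=eps, start=start)
    model = fit_mte(cohort, prop, selection, degree=degree,
                    adjustments=adjustments, basis=basis)
    eff = person_effects(model, prop, cohort, mode=mode)
    est = aggregate_subgroups(eff, cohort, selection, reporting_floor=reporting_floor)
    return est, prop


def bootstrap_ci(
    cohort: pd.DataFrame,
    selection: SelectionResult,
    spec: BootstrapSpec,
    adjustments: tuple[str, ...] | list[str] | None = DEFAULT_ADJUSTMENTS,
    degree: int = 3,
    mode: str = "person",
    eps: float = 1e-3,
    reporting_floor: int = 10,
    candidates=None,
    priorities=None,
    min_per_arm: int = 50,
    basis: str = "polynomial",
) -> EffectEstimates:
    """Nonparametric bootstrap percentile intervals for all subgroup estimates.

    The default re-estimates stage 3 (propensity, outcome series, effects) on
    each resample with the selected modifier set held fixed; stages="stages23"
    additionally re-runs the volume filter and PDS selection per replicate
    (requires ``candidates`` and ``priorities``).  Resampling is by patient or
    by hospital cluster.  Failed replicates (degenerate resamples) are dropped
    and counted.
    """
    from .candidates import apply_volume_threshold
    from .lasso import pds_select

    point, prop0 = _stage3_estimates(
        cohort, selection, adjustments, degree, mode, eps,
        reporting_floor=reporting_floor, basis=basis,
    )
    start = np.array([prop0.coef[n] for n in prop0.names])
    labels = list(point.table["label"])
    rng = np.random.default_rng(spec.seed)
    n = len(cohort)
    hospitals = cohort["hospital_id"].unique() if spec.unit == "hospital" else None

    overall_draws = np.full(spec.n_replicates, np.nan)
    sub_draws = np.full((spec.n_replicates, len(labels)), np.nan)
    failures = 0
    for b in range(spec.n_replicates):
        if spec.unit == "patient":
            idx = rng.integers(0, n, n)
            boot = cohort.iloc[idx].reset_index(drop=True)
        else:
            picked = rng.choice(hospitals, size=len(hospitals), replace=True)
            boot = pd.concat(
                [cohort[cohort["hospital_id"] == h] for h in picked],
                ignore_index=True,
            )
        try:
            sel_b = selection
            if spec.stages == "stages23":
                kept, _ = apply_volume_threshold(boot, candidates, min_per_arm)
                sel_b = pds_select(boot, kept, priorities)
            est_b, _ = _stage3_estimates(
                boot, sel_b, adjustments, degree, mode, eps, start=start,
                reporting_floor=reporting_floor, basis=basis,
            )
        except (np.linalg.LinAlgError, ValueError, InstrumentError):
            failures += 1
            continue
        overall_draws[b] = est_b.overall["estimate"]
        tb = est_b.table.set_index("label")["estimate"]
        sub_draws[b] = [tb.get(lb, np.nan) for lb in labels]

    lo_q, hi_q = (1 - spec.level) / 2, 1 - (1 - spec.level) / 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        point.overall["ci_low"] = float(np.nanquantile(overall_draws, lo_q))
        point.overall["ci_high"] = float(np.nanquantile(overall_draws, hi_q))
        point.table["ci_low"] = np.nanquantile(sub_draws, lo_q, axis=0)
        point.table["ci_high"] = np.nanquantile(sub_draws, hi_q, axis=0)
    point.meta.update(
        {
            "bootstrap": {
                "n_replicates": spec.n_replicates,
                "seed": spec.seed,
                "unit": spec.unit,
                "stages": spec.stages,
                "interval": spec.interval,
                "level": spec.level,
                "failures": failures,
                "failure_rate": failures / spec.n_replicates,
            },
            "first_stage_f": prop0.f_stat,
            "n_clipped": prop0.n_clipped,
        }
    )
    return point
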