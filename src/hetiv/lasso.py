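"""Stage 2: rigorous LASSO and post-double selection (PDS).

"Rigorous" LASSO solves

    min_b  (1/n) ||y - X b||^2  +  (lambda/n) * sum_{j in penalized} psi_j |b_j|

with the plug-in penalty level

    lambda = 2 c sqrt(n) Phi^{-1}(1 - gamma / (2 p)),   c = 1.1, gamma = 0.1/log(n),

and heteroskedasticity-robust penalty loadings psi_j = sqrt(mean(x_j^2 e_i^2))
computed on standardized columns and iterated from an initial forced-only
residual.  Forced columns (clinically mandated covariates, the treatment
indicator, the instrument, the intercept) are never penalized.  The solver is
covariance-update coordinate descent, exact for this convex objective.

PDS runs this machinery three ways on an admission cohort: the treatment on
all candidate terms (instrument forced), the outcome on candidates plus
treatment (patient characteristics, clinically forced comorbidities and the
treatment forced), with treatment x term interaction columns entering the
outcome model as penalized candidates.  The union of everything selected,
together with the forced set, is the final modifier set for effect
estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .candidates import CandidateSet, design_matrix
from .elicitation import PrioritySet

TREAT_PREFIX = "treatment:"


def plugin_lambda(n: int, p: int, c: float = 1.1, gamma: float | None = None) -> float:
    """Plug-in penalty level 2c sqrt(n) Phi^{-1}(1 - gamma/(2p))."""
    if gamma is None:
        gamma = 0.1 / np.log(max(n, 3))
    return 2.0 * c * np.sqrt(n) * stats.norm.ppf(1.0 - gamma / (2.0 * max(p, 1)))


@dataclass
class PenalizedDesign:
    """Design for a penalized regression with a forced/penalized partition."""

    y: np.ndarray
    X: np.ndarray
    names: list[str]
    forced: list[int]
    penalized: list[int]
    loadings: np.ndarray | None = None  # per penalized column, standardized scale

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float).ravel()
        self.X = np.asarray(self.X, float)
        if not (np.isfinite(self.y).all() and np.isfinite(self.X).all()):
            raise ValueError("non-finite entries in y or X")
        if set(self.forced) & set(self.penalized):
            raise ValueError("forced and penalized sets overlap")
        if self.loadings is not None and np.any(np.asarray(self.loadings) <= 0):
            raise ValueError("penalty loadings must be strictly positive")


@dataclass
class LassoFit:
    coef: np.ndarray  # original scale, including intercept last
    intercept: float
    names: list[str]
    active: list[str]  # penalized columns with nonzero coefficient
    lam: float
    loadings: np.ndarray
    n_iter: int
    converged: bool
    dropped: list[str] = field(default_factory=list)

    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.coef))


def _coordinate_descent(
    G: np.ndarray,
    c_vec: np.ndarray,
    thresh: np.ndarray,
    b0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_passes: int = 2000,
) -> tuple[np.ndarray, int, bool]:
    """Solve min (1/n)||y-Xb||^2 + 2*sum thresh_j |b_j| via covariance updates.

    G = X'X/n, c_vec = X'y/n; thresh_j = lambda*psi_j/(2n) (0 for forced).
    """
    p = len(c_vec)
    b = np.zeros(p) if b0 is None else b0.copy()
    gb = G @ b
    diag = np.diag(G).copy()
    scale = np.sqrt(np.maximum(diag, 1e-30))
    converged = False
    it = 0
    for it in range(1, max_passes + 1):
        max_delta = 0.0
        for j in range(p):
            if diag[j] <= 0.0:
                continue
            rho = c_vec[j] - gb[j] + diag[j] * b[j]
            t = thresh[j]
            if t > 0.0:
                new = np.sign(rho) * max(abs(rho) - t, 0.0) / diag[j]
            else:
                new = rho / diag[j]
            delta = new - b[j]
            if delta != 0.0:
                gb += G[:, j] * delta
                b[j] = new
                max_delta = max(max_delta, abs(delta) * scale[j])
        if max_delta < tol:
            converged = True
            break
    return b, it, converged


def rigorous_lasso(
    design: PenalizedDesign,
    c: float = 1.1,
    gamma: float | None = None,
    lam: float | None = None,
    n_loading_iter: int = 15,
    tol: float = 1e-10,
    fit_intercept: bool = True,
) -> LassoFit:
    """Fit the rigorous LASSO with plug-in penalty and iterated loadings.

    If ``design.loadings`` or ``lam`` are given they are used as-is (no
    iteration); otherwise loadings are initialized from the residuals of a
    forced-only least-squares fit and iterated ``n_loading_iter`` times (with
    early exit on convergence).  Coefficients are returned on the original
    scale of the columns.
    """
    y, X = design.y, design.X
    n, p_all = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    forced = list(design.forced)
    penal = list(design.penalized)

    # center everything (intercept handled analytically), standardize penalized
    y_mean = y.mean() if fit_intercept else 0.0
    yc = y - y_mean
    x_mean = X.mean(axis=0) if fit_intercept else np.zeros(p_all)
    Xc = X - x_mean
    sd = Xc.std(axis=0)

    dropped = [design.names[j] for j in penal if sd[j] <= 1e-12]
    if dropped:
        warnings.warn(
            f"dropping zero-variance penalized columns: {dropped}", stacklevel=2
        )
        penal = [j for j in penal if sd[j] > 1e-12]
    cols = forced + penal
    scale = np.ones(len(cols))
    for k, j in enumerate(cols):
        if j in penal and sd[j] > 0:
            scale[k] = sd[j]
    Xw = Xc[:, cols] / scale
    n_forced, n_pen = len(forced), len(penal)

    G = (Xw.T @ Xw) / n
    c_vec = (Xw.T @ yc) / n

    if lam is None:
        lam_val = plugin_lambda(n, n_pen, c=c, gamma=gamma)
    else:
        lam_val = float(lam)

    sd_pen = np.array([sd[j] if sd[j] > 0 else 1.0 for j in penal])
    if design.loadings is not None:
        # user loadings are on the raw column scale; convert to the
        # standardized coordinates used internally
        raw = np.asarray(design.loadings, float)
        lut = {j: raw[k] for k, j in enumerate(design.penalized)}
        load_list = [np.array([lut[j] for j in penal]) / sd_pen]
    else:
        # initial loadings from forced-only residuals
        if n_forced:
            bf, *_ = np.linalg.lstsq(Xw[:, :n_forced], yc, rcond=None)
            resid = yc - Xw[:, :n_forced] @ bf
        else:
            resid = yc.copy()
        load_list = None

    Xp = Xw[:, n_forced:]
    b = None
    it_total = 0
    converged = False
    psi = None
    for k in range(max(n_loading_iter, 1)):
        if load_list is not None:
            psi = load_list[0]
        else:
            new_psi = np.sqrt(np.mean(Xp**2 * resid[:, None] ** 2, axis=0))
            new_psi = np.maximum(new_psi, 1e-10)
            if psi is not None and np.max(np.abs(new_psi - psi)) < 1e-8:
                break
            psi = new_psi
        thresh = np.concatenate([np.zeros(n_forced), lam_val * psi / (2.0 * n)])
        b, it, converged = _coordinate_descent(G, c_vec, thresh, b0=b, tol=tol)
        it_total += it
        if load_list is not None:
            break
        resid = yc - Xw @ b

    # back to original scale
    coef = np.zeros(p_all)
    for k, j in enumerate(cols):
        coef[j] = b[k] / scale[k]
    intercept = float(y_mean - x_mean @ coef) if fit_intercept else 0.0
    active = [
        design.names[j]
        for k, j in enumerate(cols[n_forced:])
        if abs(b[n_forced + k]) > 0.0
    ]
    return LassoFit(
        coef=coef,
        intercept=intercept,
        names=list(design.names),
        active=active,
        lam=lam_val,
        loadings=psi * sd_pen if psi is not None else np.empty(0),
        n_iter=it_total,
        converged=converged,
        dropped=dropped,
    )


def lasso_objective(fit_coef: np.ndarray, intercept: float, design: PenalizedDesign,
                    lam: float, loadings: np.ndarray) -> float:
    """Objective (1/n)RSS + (lam/n) sum psi_j |b_j| with raw-scale loadings."""
    y, X = design.y, design.X
    n = len(y)
    resid = y - intercept - X @ fit_coef
    pen = 0.0
    for k, j in enumerate(design.penalized):
        pen += loadings[k] * abs(fit_coef[j])
    return float(resid @ resid / n + lam * pen / n)


@dataclass
class SelectionResult:
    """Outcome of post-double selection over the candidate term space."""

    x_forced: list[str]  # group-a characteristics + stage-1 forced comorbidities
    x_selected_d: list[str]  # penalized terms active in the treatment model
    x_selected_y: list[str]  # penalized main terms active in the outcome model
    selected_interactions: list[str]  # terms whose treatment x term column was kept
    lambdas: dict[str, float] = field(default_factory=dict)
    audit: dict = field(default_factory=dict)

    @property
    def x_selected(self) -> list[str]:
        out = list(self.x_forced)
        for name in (
            self.x_selected_d + self.x_selected_y + self.selected_interactions
        ):
            if name not in out:
                out.append(name)
        return out

    def __post_init__(self) -> None:
        sel = set(self.x_selected)
        assert set(self.x_forced) <= sel
        assert set(self.x_selected_d) | set(self.x_selected_y) <= sel

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "x_forced": self.x_forced,
                    "x_selected_d": self.x_selected_d,
                    "x_selected_y": self.x_selected_y,
                    "selected_interactions": self.selected_interactions,
                    "x_selected": self.x_selected,
                    "lambdas": self.lambdas,
                },
                fh,
                indent=2,
            )


def pds_select(
    cohort: pd.DataFrame,
    candidates: CandidateSet,
    priorities: PrioritySet | None = None,
    outcome_col: str = "outcome",
    treatment_col: str = "treatment",
    instrument_col: str = "tto",
    c: float = 1.1,
    gamma: float | None = None,
    n_loading_iter: int = 15,
) -> SelectionResult:
    """Post-double selection of effect modifiers on a (volume-filtered) cohort.

    Runs the treatment model (treatment on all candidate terms, instrument
    forced), and the outcome model (outcome on candidate terms plus
    treatment x term interaction columns, with the treatment indicator and
    groups a-b forced).  The treatment model uses the linear-probability form,
    standard where selection rather than prediction is the goal.  Returns the
    union of selections with the forced set.
    """
    terms = candidates.names
    forced_terms = [t.name for t in candidates.group_a + candidates.group_b]
    penal_terms = [t.name for t in candidates.group_c + candidates.group_d]
    X_terms = design_matrix(cohort, candidates.terms) if terms else pd.DataFrame(
        index=cohort.index
    )
    d = cohort[treatment_col].to_numpy(float)
    y = cohort[outcome_col].to_numpy(float)
    z = cohort[instrument_col].to_numpy(float)
    lambdas: dict[str, float] = {}
    audit: dict = {}

    if not terms:
        warnings.warn("candidate set empty after filtering; "
                      "selection reduces to the forced set", stacklevel=2)
        return SelectionResult(
            x_forced=forced_terms, x_selected_d=[], x_selected_y=[],
            selected_interactions=[], lambdas=lambdas,
        )

    # 1) treatment model: instrument forced, all candidate terms penalized
    names_d = [instrument_col] + terms
    Xd = np.column_stack([z, X_terms.to_numpy()])
    fit_d = rigorous_lasso(
        PenalizedDesign(
            y=d, X=Xd, names=names_d, forced=[0],
            penalized=list(range(1, len(names_d))),
        ),
        c=c, gamma=gamma, n_loading_iter=n_loading_iter,
    )
    x_selected_d = [t for t in fit_d.active]
    lambdas["treatment_model"] = fit_d.lam
    audit["treatment_model"] = {"active": fit_d.active, "n_iter": fit_d.n_iter}

    # 2) outcome model: treatment + groups a-b forced; groups c-d and all
    #    treatment x term interactions penalized
    inter_names = [TREAT_PREFIX + t for t in terms]
    Xy = np.column_stack(
        [d[:, None], X_terms.to_numpy(), d[:, None] * X_terms.to_numpy()]
    )
    names_y = [treatment_col] + terms + inter_names
    forced_idx = [0] + [1 + terms.index(t) for t in forced_terms]
    penal_idx = [1 + terms.index(t) for t in penal_terms] + list(
        range(1 + len(terms), 1 + 2 * len(terms))
    )
    fit_y = rigorous_lasso(
        PenalizedDesign(y=y, X=Xy, names=names_y, forced=forced_idx,
                        penalized=penal_idx),
        c=c, gamma=gamma, n_loading_iter=n_loading_iter,
    )
    x_selected_y = [t for t in fit_y.active if not t.startswith(TREAT_PREFIX)]
    selected_inter = [
        t[len(TREAT_PREFIX):] for t in fit_y.active if t.startswith(TREAT_PREFIX)
    ]
    lambdas["outcome_model"] = fit_y.lam
    audit["outcome_model"] = {"active": fit_y.active, "n_iter": fit_y.n_iter}

    return SelectionResult(
        x_forced=forced_terms,
        x_selected_d=x_selected_d,
        x_selected_y=x_selected_y,
        selected_interactions=selected_inter,
        lambdas=lambdas,
        audit=audit,
    )
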