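"""Incident/static and longitudinal-marker ROC methods.

* ``is2_auc`` — incident sensitivity as in the Cox incident/dynamic method
  but with a static control set (event-free beyond a fixed horizon t*);
  works with a baseline marker or the last value before a landmark.
* ``ecd2_roc`` — the nearest-neighbour cumulative/dynamic estimator applied
  to the most recent marker value before a landmark.
* ``ad1_*`` — induced binormal ROC from case/control linear mixed-effects
  trajectory models (random intercept + visit-time slope per subject; the
  case mean additionally depends on the time before event and its
  interaction with visit time).
* ``ad2_*`` — direct binormal ROC-GLM on case/control placement values with
  a probit link and a linear time-before-event effect.

Binormal convention throughout: ROC(p) = Phi(a0 + a1 Phi^-1(p)) with
a0 = (mu_D - mu_Dbar)/s_D, a1 = s_Dbar/s_D, AUC = Phi(a0/sqrt(1+a1^2)).

Censored subjects are retained as controls for the AD methods (which do not
themselves model censoring); the fit records this convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.special import ndtr, ndtri

from .cohorts import BaselineCohort, LongitudinalCohort, last_value_cohort
from .curves import AUCResult, ROCCurve
from .cd import UndefinedAUCError, _weighted_frac_above, cd2_roc
from .curves import threshold_grid
from .incident import _require_event_time
from .primitives import FittingError, NNEConfig, TimeVaryingCoef, ph_fit, smooth_time_varying_gamma

__all__ = [
    "ISConfig",
    "is2_roc",
    "is2_auc",
    "ecd2_roc",
    "MixedModelFit",
    "ad1_fit",
    "ad1_moments",
    "InducedROC",
    "binormal_auc",
    "ad1_roc",
    "ad1_auc",
    "ROCGLMFit",
    "ad2_fit",
    "ad2_roc",
]


@dataclass(frozen=True)
class ISConfig:
    """Incident/static configuration.

    ``t_star`` is the fixed follow-up horizon defining static controls
    (event-free beyond t*); ``marker_source`` selects the baseline marker
    or the last value before ``landmark``.
    """

    t_star: float
    marker_source: str = "baseline"
    landmark: float | None = None

    def __post_init__(self):
        if self.t_star <= 0:
            raise ValueError("t_star must be > 0")
        if self.marker_source not in ("baseline", "last-value"):
            raise ValueError(f"unknown marker_source {self.marker_source!r}")
        if self.marker_source == "last-value" and self.landmark is None:
            raise ValueError("last-value marker source needs a landmark")


def _is2_cohort(data, cfg: ISConfig) -> BaselineCohort:
    if isinstance(data, BaselineCohort):
        return data
    if cfg.marker_source == "last-value":
        return last_value_cohort(data, cfg.landmark)
    # baseline source from a longitudinal cohort: first visit value
    X = np.array([data.visits_of(i)[1][0] for i in range(data.n)])
    return BaselineCohort(data.subject_id, data.Z, data.delta, X, data.time_unit)


def is2_roc(data, t: float, cfg: ISConfig,
            tv: TimeVaryingCoef | None = None, bandwidth: float | None = None) -> ROCCurve:
    """Incident/static ROC: incident cases at event time ``t``, static
    controls event-free beyond ``cfg.t_star``.

    The sensitivity uses the exponentially tilted weights of the Cox
    incident/dynamic method over the redefined riskset (incident cases plus
    static controls); the specificity is empirical over static controls.
    """
    if t >= cfg.t_star:
        raise ValueError(f"need t < t_star, got t={t}, t_star={cfg.t_star}")
    cohort = _is2_cohort(data, cfg)
    _require_event_time(cohort, t)
    cases = (cohort.Z == t) & (cohort.delta == 1)
    static = cohort.Z > cfg.t_star
    if not static.any():
        raise UndefinedAUCError(f"no static control beyond t_star={cfg.t_star}")
    if tv is None:
        tv = smooth_time_varying_gamma(ph_fit(cohort), bandwidth)
    gamma_t = float(tv(t))
    pool = cases | static
    Xp = cohort.X[pool]
    w = np.exp(np.clip(gamma_t * Xp - np.max(gamma_t * Xp), -700, 0))
    grid = threshold_grid(Xp)
    sens = _weighted_frac_above(Xp, w, grid)
    Xs = cohort.X[static]
    fpr = _weighted_frac_above(Xs, np.ones(len(Xs)), grid)
    return ROCCurve(t, grid, sens, fpr, "is2",
                    metadata={"t_star": cfg.t_star, "gamma_t": gamma_t,
                              "marker_source": cfg.marker_source,
                              "landmark": cfg.landmark,
                              "time_axis": "original"})


def is2_auc(data, t, cfg, tv=None, bandwidth=None) -> AUCResult:
    return is2_roc(data, t, cfg, tv, bandwidth).auc_result()


def ecd2_roc(lc: LongitudinalCohort, landmark: float, t: float,
             cfg: NNEConfig | None = None) -> ROCCurve:
    """Nearest-neighbour C/D estimator on the last marker value before the
    landmark; subjects must be at risk past the landmark, and the time axis
    stays on the original scale."""
    if t <= landmark:
        raise ValueError(f"horizon t={t} must exceed the landmark {landmark}")
    cohort = last_value_cohort(lc, landmark)
    curve = cd2_roc(cohort, t, cfg)
    meta = {**curve.metadata, "landmark": landmark, "time_axis": "original",
            "n_at_risk": cohort.n}
    return ROCCurve(curve.t, curve.thresholds, curve.sens, curve.fpr, "ecd2",
                    metadata=meta)


# ---------------------------------------------------------------------------
# AD1: induced binormal ROC from case/control linear mixed models


@dataclass(frozen=True)
class MixedModelFit:
    """Case/control linear mixed-effects fits for marker trajectories.

    Case fixed effects are (b0, b_s, b_tbe, b_s:tbe) on [1, s, tbe, s*tbe];
    control fixed effects are (b0, b_s) on [1, s]. ``case_V``/``control_V``
    are the 2x2 random-effect covariances over (intercept, visit slope) and
    ``*_sigma`` the residual SDs.
    """

    case_beta: np.ndarray
    case_V: np.ndarray
    case_sigma: float
    control_beta: np.ndarray
    control_V: np.ndarray
    control_sigma: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for V in (self.case_V, self.control_V):
            V = np.asarray(V, float)
            if V.shape != (2, 2) or abs(V[0, 1] - V[1, 0]) > 1e-10:
                raise ValueError("random-effect covariance must be symmetric 2x2")
            if np.linalg.eigvalsh(V).min() < -1e-8:
                raise ValueError("random-effect covariance must be PSD")
        if self.case_sigma <= 0 or self.control_sigma <= 0:
            raise ValueError("residual SDs must be > 0")


def _fit_mixed(df: pd.DataFrame, formula: str, scale: float) -> tuple:
    df = df.copy()
    df["s_"] = df["s"] / scale
    if "tbe" in df:
        df["tbe_"] = df["tbe"] / scale
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["sid"], re_formula="~s_")
        try:
            fit = model.fit(reml=True, method=["lbfgs", "powell"])
        except Exception as exc:
            raise FittingError(f"mixed-model fit failed: {exc}") from exc
    if not np.all(np.isfinite(fit.fe_params.to_numpy())):
        raise FittingError(f"mixed-model fit diverged: {fit.fe_params.to_dict()}")
    return fit


def ad1_fit(lc: LongitudinalCohort, time_scale: float | None = None) -> MixedModelFit:
    """Fit the case and control trajectory mixed models by ML/REML.

    Cases are subjects with an observed event (time before event is
    ``Z - s`` at each visit); censored subjects serve as controls. Visit
    time and time-before-event are internally rescaled to order one before
    optimisation (day-scale slopes otherwise give badly conditioned
    variance components) and estimates are mapped back to the input units.
    """
    case_rows, ctrl_rows = [], []
    for i in range(lc.n):
        s, y = lc.visits_of(i)
        if lc.delta[i] == 1:
            case_rows.append(pd.DataFrame(
                {"sid": lc.subject_id[i], "s": s, "tbe": lc.Z[i] - s, "y": y}))
        else:
            ctrl_rows.append(pd.DataFrame({"sid": lc.subject_id[i], "s": s, "y": y}))
    if len(case_rows) < 2 or len(ctrl_rows) < 2:
        raise FittingError("need at least 2 cases and 2 controls with visits")
    case_df = pd.concat(case_rows, ignore_index=True)
    ctrl_df = pd.concat(ctrl_rows, ignore_index=True)
    tau = float(time_scale or max(case_df["s"].max(), case_df["tbe"].max(),
                                  ctrl_df["s"].max(), 1.0))

    cfit = _fit_mixed(case_df, "y ~ s_ * tbe_", tau)
    gfit = _fit_mixed(ctrl_df, "y ~ s_", tau)

    def unscale_V(V):
        V = np.asarray(V, float)
        return np.array([[V[0, 0], V[0, 1] / tau], [V[1, 0] / tau, V[1, 1] / tau ** 2]])

    case_cols = ["Intercept", "s_", "tbe_", "s_:tbe_"]
    case_scale = np.array([1.0, tau, tau, tau ** 2])
    case_beta = cfit.fe_params.reindex(case_cols).to_numpy() / case_scale
    case_se = cfit.bse_fe.reindex(case_cols).to_numpy() / case_scale
    ctrl_scale = np.array([1.0, tau])
    control_beta = gfit.fe_params.reindex(["Intercept", "s_"]).to_numpy() / ctrl_scale
    control_se = gfit.bse_fe.reindex(["Intercept", "s_"]).to_numpy() / ctrl_scale
    return MixedModelFit(
        case_beta, unscale_V(cfit.cov_re.to_numpy()), float(np.sqrt(cfit.scale)),
        control_beta, unscale_V(gfit.cov_re.to_numpy()), float(np.sqrt(gfit.scale)),
        meta={
            "case_beta_se": case_se, "control_beta_se": control_se,
            "n_cases": len(case_rows), "n_controls": len(ctrl_rows),
            "time_scale": tau, "converged": bool(cfit.converged and gfit.converged),
            "control_definition": "censored subjects retained as controls",
        },
    )


def ad1_moments(fit: MixedModelFit, s: float, t: float):
    """Model-implied marker means and SDs at visit time ``s`` and time
    before event ``t``.

    The mean uses the full fixed-effect design ([1, s, t, st] for cases,
    [1, s] for controls); the variance uses only the random-effect columns
    [1, s] plus the residual variance, since the random effects are an
    intercept and a visit-time slope.
    """
    if s < 0 or t < 0:
        raise ValueError("visit time and time before event must be >= 0")
    u_case = np.array([1.0, s, t, s * t])
    u_re = np.array([1.0, s])
    mu_D = float(u_case @ fit.case_beta)
    mu_Dbar = float(np.array([1.0, s]) @ fit.control_beta)
    s_D = float(np.sqrt(fit.case_sigma ** 2 + u_re @ fit.case_V @ u_re))
    s_Dbar = float(np.sqrt(fit.control_sigma ** 2 + u_re @ fit.control_V @ u_re))
    return mu_D, mu_Dbar, s_D, s_Dbar


def binormal_auc(a0: float, a1: float) -> float:
    """AUC of the binormal curve Phi(a0 + a1 Phi^-1(p))."""
    return float(ndtr(a0 / np.sqrt(1.0 + a1 ** 2)))


@dataclass(frozen=True)
class InducedROC:
    """Location-scale induced ROC (Gaussian family): Phi(a0 + a1 Phi^-1(p))."""

    a0: float
    a1: float
    family: str = "gaussian"

    def __post_init__(self):
        if self.a1 <= 0:
            raise ValueError("slope a1 must be > 0")

    def roc(self, p):
        return ndtr(self.a0 + self.a1 * ndtri(np.asarray(p, float)))

    @property
    def auc(self) -> float:
        return binormal_auc(self.a0, self.a1)


def _binormal_curve(induced: InducedROC, t: float, method: str,
                    mu_ctrl: float, s_ctrl: float,
                    p_grid: np.ndarray | None = None, meta: dict | None = None) -> ROCCurve:
    p = np.linspace(0, 1, 201) if p_grid is None else np.asarray(p_grid, float)
    p = np.unique(np.concatenate(([0.0], p, [1.0])))
    inner = p[(p > 0) & (p < 1)]
    sens = np.concatenate(([0.0], induced.roc(inner), [1.0]))
    fpr = np.concatenate(([0.0], inner, [1.0]))
    # implied marker cutoffs from the control distribution (descending)
    thr = np.concatenate(([np.inf], mu_ctrl - s_ctrl * ndtri(inner), [-np.inf]))
    md = {"a0": induced.a0, "a1": induced.a1, "auc_closed_form": induced.auc}
    md.update(meta or {})
    return ROCCurve(t, thr, sens, fpr, method, metadata=md)


def ad1_roc(fit: MixedModelFit, s: float, t: float,
            p_grid: np.ndarray | None = None) -> ROCCurve:
    """Induced Gaussian ROC at visit time ``s`` and time before event ``t``."""
    mu_D, mu_Dbar, s_D, s_Dbar = ad1_moments(fit, s, t)
    induced = InducedROC((mu_D - mu_Dbar) / s_D, s_Dbar / s_D)
    return _binormal_curve(induced, t, "ad1", mu_Dbar, s_Dbar, p_grid,
                           {"visit_time": s})


def ad1_auc(fit: MixedModelFit, s: float, t: float) -> AUCResult:
    mu_D, mu_Dbar, s_D, s_Dbar = ad1_moments(fit, s, t)
    induced = InducedROC((mu_D - mu_Dbar) / s_D, s_Dbar / s_D)
    return AUCResult(t=t, auc=induced.auc, method="ad1",
                     metadata={"visit_time": s, "a0": induced.a0, "a1": induced.a1})


# ---------------------------------------------------------------------------
# AD2: ROC-GLM with probit link on placement values


@dataclass(frozen=True)
class ROCGLMFit:
    """Binormal ROC-GLM parameters: ROC(t, p) = Phi(g0 + g1 Phi^-1(p) + alpha t)."""

    gamma0: float
    gamma1: float
    alpha: float
    flagged: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.gamma1 <= 0:
            raise ValueError("binormal slope gamma1 must be > 0")


def ad2_fit(lc: LongitudinalCohort, time_effect: bool = True,
            max_pairs: int = 200_000, seed: int = 0) -> ROCGLMFit:
    """Fit the ROC-GLM: all case-control visit pairs, the pair indicator
    I(Y_case >= Y_control) regressed on the probit of the control placement
    value and (optionally) the case's time before event, with a probit link.

    Placement values use the pooled control empirical CDF with midranks.
    Pair sets larger than ``max_pairs`` are subsampled reproducibly.
    """
    y_case, tbe_case, y_ctrl = [], [], []
    for i in range(lc.n):
        s, y = lc.visits_of(i)
        if lc.delta[i] == 1:
            y_case.append(y)
            tbe_case.append(lc.Z[i] - s)
        else:
            y_ctrl.append(y)
    if not y_case or not y_ctrl:
        raise FittingError("need at least one case and one control with visits")
    y_case = np.concatenate(y_case)
    tbe_case = np.concatenate(tbe_case)
    y_ctrl = np.concatenate(y_ctrl)
    from scipy.stats import rankdata

    # placement = false-positive rate at the control value as threshold
    # (survivor fraction of the pooled control sample, midrank ties)
    p_ctrl = 1.0 - (rankdata(y_ctrl, method="average") - 0.5) / len(y_ctrl)
    q_ctrl = ndtri(p_ctrl)

    i_idx, j_idx = np.meshgrid(np.arange(len(y_case)), np.arange(len(y_ctrl)),
                               indexing="ij")
    i_idx, j_idx = i_idx.ravel(), j_idx.ravel()
    if len(i_idx) > max_pairs:
        keep = np.random.default_rng(seed).choice(len(i_idx), max_pairs, replace=False)
        i_idx, j_idx = i_idx[keep], j_idx[keep]
    D = (y_case[i_idx] >= y_ctrl[j_idx]).astype(float)
    cols = [np.ones(len(D)), q_ctrl[j_idx]]
    if time_effect:
        cols.append(tbe_case[i_idx])
    Xmat = np.column_stack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(D, Xmat, family=sm.families.Binomial(sm.families.links.Probit()))
        try:
            res = glm.fit(maxiter=200)
        except Exception as exc:
            raise FittingError(f"ROC-GLM fit failed: {exc}") from exc
    flagged = bool(D.min() == D.max()) or not np.all(np.isfinite(res.params))
    g0, g1 = float(res.params[0]), float(res.params[1])
    alpha = float(res.params[2]) if time_effect else 0.0
    return ROCGLMFit(g0, max(g1, 1e-8), alpha, flagged=flagged,
                     meta={"n_pairs": len(D), "time_effect": time_effect})


def ad2_roc(fit: ROCGLMFit, t: float, p_grid: np.ndarray | None = None) -> ROCCurve:
    """Binormal ROC at time before event ``t`` from a fitted ROC-GLM."""
    induced = InducedROC(fit.gamma0 + fit.alpha * t, fit.gamma1)
    return _binormal_curve(induced, t, "ad2", 0.0, 1.0, p_grid,
                           {"alpha": fit.alpha, "flagged": fit.flagged})
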