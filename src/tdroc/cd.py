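"""Cumulative/dynamic (C/D) time-dependent ROC estimators.

Cases at horizon ``t`` are subjects with events in (0, t]; controls are
subjects event-free beyond ``t``. Estimators:

naive   observed-proportion estimator dropping subjects censored before t
cd1     conditional Kaplan-Meier (Bayes) plug-in; unbounded, non-monotone
cd2     Akritas nearest-neighbour bivariate-survival estimator
cd3     Kaplan-Meier-like estimator with event-time increments (revised
        closed form); sensitivity monotone and bounded
cd4     proportional-hazards model plug-in over sample means
cd5     inverse-probability-of-censoring weighted (marginal weights)
cd6     conditional IPCW (marker-conditional censoring weights)
cd7     interval-weighted average AUC with Kaplan-Meier increment weights
cd8     Viallon-Latouche conditional-absolute-risk plug-in AUC family
        (Cox / Aalen / nearest-neighbour KM)

All curve estimators share the threshold grid (unique marker values with
±inf sentinels) and compute AUC by trapezoidal integration; pairwise tie
handling is the half-weight convention.
"""

from __future__ import annotations

import numpy as np

from .cohorts import BaselineCohort
from .curves import AUCResult, ROCCurve, threshold_grid
from .primitives import (
    NNEConfig,
    additive_fit,
    censoring_km,
    default_lambda_n,
    km,
    nne_bivariate,
    nne_conditional_at,
    ph_fit,
    _ecdf_values,
    _product_limit,
)

__all__ = [
    "UndefinedAUCError",
    "naive_roc",
    "cd1_roc",
    "cd2_roc",
    "cd3_roc",
    "cd4_roc",
    "cd5_roc",
    "cd6_roc",
    "cd7_weighted_auc",
    "cd8_auc",
    "cd_roc",
    "cd_auc",
    "CD_METHODS",
]


class UndefinedAUCError(ValueError):
    """Case or control set (or a required weight) is empty/degenerate."""


def _weighted_frac_above(X, w, grid):
    """sum of w over X > c, per grid threshold c, normalised by sum(w)."""
    X = np.asarray(X, float)
    w = np.asarray(w, float)
    order = np.argsort(X, kind="mergesort")
    Xs, ws = X[order], w[order]
    suffix = np.concatenate((np.cumsum(ws[::-1])[::-1], [0.0]))
    idx = np.searchsorted(Xs, grid, side="right")
    tot = ws.sum()
    if tot <= 0:
        raise UndefinedAUCError("all weights vanished")
    return suffix[idx] / tot


def _masks(cohort: BaselineCohort, t: float):
    cases = (cohort.Z <= t) & (cohort.delta == 1)
    controls = cohort.Z > t
    return cases, controls


def naive_roc(cohort: BaselineCohort, t: float) -> ROCCurve:
    """Empirical estimator over observed events and survivors only."""
    cases, controls = _masks(cohort, t)
    if not cases.any():
        raise UndefinedAUCError(f"no observed event at or before t={t}")
    if not controls.any():
        raise UndefinedAUCError(f"no subject at risk beyond t={t}")
    grid = threshold_grid(cohort.X)
    sens = _weighted_frac_above(cohort.X[cases], np.ones(cases.sum()), grid)
    fpr = _weighted_frac_above(cohort.X[controls], np.ones(controls.sum()), grid)
    return ROCCurve(t, grid, sens, fpr, "naive")


def cd1_roc(cohort: BaselineCohort, t: float) -> ROCCurve:
    """Conditional Kaplan-Meier (Bayes-theorem) plug-in estimator.

    Values may exit [0, 1] and need not be monotone (the quadrant
    probability plug-in is not a valid bivariate distribution under
    censoring); raw values are returned, flagged via ``out_of_bounds``.
    """
    S = km(cohort)
    St = S(t)
    if not 0 < St < 1:
        raise UndefinedAUCError(f"marginal survival at t={t} is {St}; estimator undefined")
    grid = threshold_grid(cohort.X)
    Fx = _ecdf_values(cohort.X, grid)
    sens = np.empty(len(grid))
    fpr = np.empty(len(grid))
    for k, c in enumerate(grid):
        above = cohort.X > c
        if above.any():
            S_above = _product_limit(cohort.Z[above], cohort.delta[above] == 1)(t)
            sens[k] = (1 - S_above) * (1 - Fx[k]) / (1 - St)
        else:
            sens[k] = 0.0
        below = ~above
        if below.any():
            S_below = _product_limit(cohort.Z[below], cohort.delta[below] == 1)(t)
            fpr[k] = 1 - S_below * Fx[k] / St
        else:
            fpr[k] = 1.0
    return ROCCurve(t, grid, sens, fpr, "cd1", bounded=False)


def cd2_roc(cohort: BaselineCohort, t: float, cfg: NNEConfig | None = None) -> ROCCurve:
    """Nearest-neighbour bivariate survival estimator (Akritas weighted KM).

    Monotone, bounded in [0, 1] and invariant to strictly increasing
    marker transformations (the kernel acts on the ECDF scale).
    """
    cfg = cfg or NNEConfig.for_n(cohort.n)
    surface = nne_bivariate(cohort, cfg)
    s_i = surface.conditional_at(t)
    S_marg = float(s_i.mean())
    if not 0 < S_marg < 1:
        raise UndefinedAUCError(f"smoothed marginal survival at t={t} is {S_marg}")
    grid = threshold_grid(cohort.X)
    # S_lambda(c, t) as suffix means of conditional survival over X > c
    order = np.argsort(cohort.X, kind="mergesort")
    Xs = cohort.X[order]
    suffix = np.concatenate((np.cumsum(s_i[order][::-1])[::-1], [0.0]))
    idx = np.searchsorted(Xs, grid, side="right")
    S_ct = suffix[idx] / cohort.n
    frac_above = (cohort.n - idx) / cohort.n  # 1 - F_X(c)
    sens = np.clip((frac_above - S_ct) / (1 - S_marg), 0.0, 1.0)
    fpr = np.clip(S_ct / S_marg, 0.0, 1.0)
    return ROCCurve(t, grid, sens, fpr, "cd2", metadata={"lambda_n": cfg.lambda_n})


def cd3_roc(cohort: BaselineCohort, t: float) -> ROCCurve:
    """Kaplan-Meier-like estimator distributing KM increments over event
    markers (revised closed form). Sensitivity is monotone and bounded;
    specificity may be non-monotone, so the raw curve is not clipped.
    """
    S = km(cohort)
    ev = cohort.event_times()
    ev = ev[ev <= t]
    if len(ev) == 0:
        raise UndefinedAUCError(f"no observed event time at or before t={t}")
    S_prev = np.concatenate(([1.0], S(ev)[:-1]))
    dS = S_prev - S(ev)  # P(t_{k-1} < T <= t_k)
    S_tm = S(ev[-1])
    grid = threshold_grid(cohort.X)
    sens = np.zeros(len(grid))
    below = np.zeros(len(grid))
    for k, tk in enumerate(ev):
        Xk = cohort.X[(cohort.Z == tk) & (cohort.delta == 1)]
        share_above = _weighted_frac_above(Xk, np.ones(len(Xk)), grid)
        sens += share_above * dS[k]
        below += (1 - share_above) * dS[k]
    sens /= 1 - S_tm
    Fx = _ecdf_values(cohort.X, grid)
    if S_tm <= 0:
        raise UndefinedAUCError(f"no probability mass beyond last event time <= {t}")
    sp = (Fx - below) / S_tm
    return ROCCurve(t, grid, sens, 1 - sp, "cd3", bounded=False)


def cd4_roc(cohort: BaselineCohort, t: float, fit=None) -> ROCCurve:
    """Proportional-hazards plug-in with expectations replaced by sample
    means. Monotone and bounded, but not invariant to increasing marker
    transformations (the Cox score changes with the transform)."""
    fit = fit if fit is not None else ph_fit(cohort)
    S_i = np.asarray(fit.survival(t, cohort.X), float)
    F_i = 1 - S_i
    if F_i.sum() <= 0 or S_i.sum() <= 0:
        raise UndefinedAUCError(f"degenerate model risks at t={t}")
    grid = threshold_grid(cohort.X)
    sens = _weighted_frac_above(cohort.X, F_i, grid)
    fpr = _weighted_frac_above(cohort.X, S_i, grid)
    return ROCCurve(t, grid, sens, fpr, "cd4")


def _ipcw_event_weights(cohort: BaselineCohort, t: float, sc_left: np.ndarray) -> np.ndarray:
    """delta / S_c(Z-) for events at or before t, else 0."""
    w = np.zeros(cohort.n)
    ev = (cohort.delta == 1) & (cohort.Z <= t)
    if not ev.any():
        raise UndefinedAUCError(f"no observed event at or before t={t}")
    if np.any(sc_left[ev] <= 0):
        raise UndefinedAUCError(
            f"zero censoring-survival weight before t={t}; truncate the horizon"
        )
    w[ev] = 1.0 / sc_left[ev]
    return w


def cd5_roc(cohort: BaselineCohort, t: float) -> ROCCurve:
    """Inverse-probability-of-censoring weighted estimator: IPCW
    sensitivity (marginal censoring KM), empirical specificity."""
    Sc = censoring_km(cohort)
    w = _ipcw_event_weights(cohort, t, Sc.value_at_left(cohort.Z))
    _, controls = _masks(cohort, t)
    if not controls.any():
        raise UndefinedAUCError(f"no subject at risk beyond t={t}")
    grid = threshold_grid(cohort.X)
    sens = _weighted_frac_above(cohort.X, w, grid)
    fpr = _weighted_frac_above(cohort.X[controls], np.ones(controls.sum()), grid)
    return ROCCurve(t, grid, sens, fpr, "cd5")


def cd6_roc(
    cohort: BaselineCohort, t: float,
    censoring_model: str = "nne", cfg: NNEConfig | None = None,
) -> ROCCurve:
    """Conditional IPCW: weights use the censoring survival given the
    marker, making the estimator robust to marker-dependent censoring.

    The default censoring model is the nearest-neighbour weighted KM on
    censoring times; a proportional-hazards censoring model is available
    with ``censoring_model="ph"``.
    """
    if censoring_model not in ("nne", "ph"):
        raise ValueError(f"unknown censoring model {censoring_model!r}")
    if censoring_model == "ph":
        flipped = BaselineCohort(
            cohort.subject_id, cohort.Z, 1 - cohort.delta, cohort.X, cohort.time_unit
        )
        cfit = ph_fit(flipped)
        eps = 1e-9 * max(1.0, float(np.max(cohort.Z)))
        sc_left = np.asarray(cfit.survival(cohort.Z - eps, cohort.X), float)
        sc_t = np.asarray(cfit.survival(t, cohort.X), float)
    else:
        cfg = cfg or NNEConfig.for_n(cohort.n)
        cens = 1 - cohort.delta
        F = _ecdf_values(cohort.X, cohort.X)
        sc_left = np.empty(cohort.n)
        sc_t = np.empty(cohort.n)
        for i in range(cohort.n):
            m = np.abs(F - F[i]) < cfg.lambda_n
            curve = _product_limit(cohort.Z[m], cens[m] == 1)
            sc_left[i] = curve.value_at_left(cohort.Z[i])
            sc_t[i] = curve(t)
    w = _ipcw_event_weights(cohort, t, sc_left)
    _, controls = _masks(cohort, t)
    if not controls.any():
        raise UndefinedAUCError(f"no subject at risk beyond t={t}")
    if np.any(sc_t[controls] <= 0):
        raise UndefinedAUCError(f"zero conditional censoring survival at t={t}")
    grid = threshold_grid(cohort.X)
    sens = _weighted_frac_above(cohort.X, w, grid)
    fpr = _weighted_frac_above(cohort.X[controls], 1.0 / sc_t[controls], grid)
    return ROCCurve(t, grid, sens, fpr, "cd6", metadata={"censoring_model": censoring_model})


CD_METHODS = {}


def cd_roc(cohort: BaselineCohort, t: float, method: str, **kw) -> ROCCurve:
    """Dispatch a C/D curve estimator by tag."""
    try:
        fn = CD_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown C/D method {method!r}; choose from {sorted(CD_METHODS)}")
    return fn(cohort, t, **kw)


def cd_auc(cohort: BaselineCohort, t: float, method: str, **kw) -> AUCResult:
    """Scalar C/D AUC by tag (curve methods integrate; vl_* are plug-in)."""
    if method in ("vl_cox", "vl_aalen", "vl_km"):
        return cd8_auc(cohort, t, variant=method, **kw)
    return cd_roc(cohort, t, method, **kw).auc_result()


def cd7_weighted_auc(
    cohort: BaselineCohort, tau1: float, tau2: float,
    base="cd5", **base_kw,
) -> AUCResult:
    """Interval-weighted average of a base C/D AUC over (tau1, tau2].

    Event-time AUC values are averaged with weights proportional to the
    Kaplan-Meier drop at each distinct event time (increments taken in
    absolute value so the weights form a distribution summing to 1).
    ``base`` is a C/D method tag or any callable ``(cohort, t) -> AUCResult``.
    """
    if not tau1 < tau2 <= float(np.max(cohort.Z)):
        raise ValueError("need tau1 < tau2 <= max observed time")
    S = km(cohort)
    if not S(tau1) > S(tau2):
        raise UndefinedAUCError("no survival drop inside the interval")
    ev = cohort.event_times()
    ev = ev[(ev > tau1) & (ev <= tau2)]
    if len(ev) == 0:
        raise UndefinedAUCError(f"no event time in ({tau1}, {tau2}]")
    S_prev = np.concatenate(([S(tau1)], S(ev)[:-1]))
    wts = np.abs(S_prev - S(ev))
    wts = wts / wts.sum()
    if callable(base):
        auc_fn, tag = base, getattr(base, "__name__", "custom")
    else:
        auc_fn, tag = (lambda c, tk: cd_auc(c, tk, base, **base_kw)), base
    aucs = np.array([auc_fn(cohort, tk).auc for tk in ev])
    return AUCResult(
        t=tau2, auc=float(np.dot(wts, aucs)), method=f"cd7[{tag}]",
        metadata={"tau1": tau1, "tau2": tau2, "event_times": ev, "weights": wts},
    )


def _pairwise_auc_from_risks(X: np.ndarray, F: np.ndarray) -> float:
    """Rank-form concordance of risks: sum_{i!=j} w_ij F_i (1-F_j) over
    sum_{i!=j} F_i (1-F_j), with w_ij = I(X_i>X_j) + I(X_i=X_j)/2.

    Computed with group prefix sums; algebraically identical to the
    explicit double sum.
    """
    order = np.argsort(X, kind="mergesort")
    Xs, Fs = np.asarray(X, float)[order], np.asarray(F, float)[order]
    Gs = 1.0 - Fs
    uniq, start = np.unique(Xs, return_index=True)
    sumF = np.add.reduceat(Fs, start)
    sumG = np.add.reduceat(Gs, start)
    sumFG = np.add.reduceat(Fs * Gs, start)
    prefixG = np.concatenate(([0.0], np.cumsum(sumG)))[:-1]  # controls strictly below
    num = float(np.dot(sumF, prefixG)) + 0.5 * float(np.sum(sumF * sumG - sumFG))
    den = float(Fs.sum() * Gs.sum() - np.sum(Fs * Gs))
    if den <= 0:
        raise UndefinedAUCError("degenerate conditional risks (all 0 or all 1)")
    return num / den


def cd8_auc(cohort: BaselineCohort, t: float, variant: str = "vl_cox",
            l_n: float | None = None) -> AUCResult:
    """Conditional-absolute-risk plug-in AUC (Viallon-Latouche family).

    ``variant`` selects the risk model: ``vl_cox`` (Breslow-baseline Cox),
    ``vl_aalen`` (Aalen additive) or ``vl_km`` (nearest-neighbour
    conditional KM with half-width ``l_n``, default 0.25 n^(-1/5)).
    """
    if variant == "vl_cox":
        F = np.asarray(ph_fit(cohort).risk(t, cohort.X), float)
    elif variant == "vl_aalen":
        F = np.asarray(additive_fit(cohort).risk(t, cohort.X), float)
    elif variant == "vl_km":
        lam = l_n if l_n is not None else min(0.25 * cohort.n ** (-1 / 5), 0.499)
        F = 1.0 - nne_conditional_at(cohort, NNEConfig(lam), t)
    else:
        raise ValueError(f"unknown CD8 variant {variant!r}")
    return AUCResult(t=t, auc=_pairwise_auc_from_risks(cohort.X, F), method=variant)


CD_METHODS.update(
    {
        "naive": naive_roc,
        "cd1": cd1_roc,
        "cd2": cd2_roc,
        "cd3": cd3_roc,
        "cd4": cd4_roc,
        "cd5": cd5_roc,
        "cd6": cd6_roc,
    }
)
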