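"""Survival-analysis building blocks shared by all ROC estimators.

Contents: the product-limit (Kaplan–Meier) curve and its censoring-time
counterpart, the Akritas nearest-neighbour weighted Kaplan–Meier on the
marker's empirical-CDF scale, proportional-hazards and Aalen additive fits
(lifelines-backed) with a Breslow baseline evaluated at marker 0, scaled
Schoenfeld residual smoothing for time-varying hazard coefficients, and
subject-level bootstrap resampling.

Conventions: at tied times events precede censorings (standard KM risk-set
convention); inverse-probability-of-censoring weights evaluate the censoring
survival at the left limit Z- for event records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from lifelines import AalenAdditiveFitter, CoxPHFitter
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohorts import BaselineCohort
from .curves import AUCResult

logger = logging.getLogger(__name__)

__all__ = [
    "StepSurvival",
    "NNEConfig",
    "PHFit",
    "AdditiveFit",
    "TimeVaryingCoef",
    "FittingError",
    "km",
    "censoring_km",
    "default_lambda_n",
    "nne_weighted_km",
    "nne_conditional_at",
    "nne_bivariate",
    "ph_fit",
    "additive_fit",
    "smooth_time_varying_gamma",
    "bootstrap_ci",
]


class FittingError(RuntimeError):
    """A model fit failed to converge or was ill-posed."""


@dataclass(frozen=True)
class StepSurvival:
    """Right-continuous non-increasing step function with S(0) = 1.

    ``times`` are the ascending jump times; ``values`` hold S just after
    each jump.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if np.any(np.diff(self.values) > 1e-12):
            raise ValueError("survival values must be non-increasing")
        if len(self.values) and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("survival values must lie in [0,1]")

    def __call__(self, t):
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right") - 1
        vals = np.concatenate(([1.0], self.values))
        return vals[idx + 1] if np.ndim(t) else float(vals[idx + 1])

    def value_at_left(self, t):
        """Left limit S(t-)."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="left") - 1
        vals = np.concatenate(([1.0], self.values))
        return vals[idx + 1] if np.ndim(t) else float(vals[idx + 1])


def _product_limit(Z: np.ndarray, events: np.ndarray, w: np.ndarray | None = None) -> StepSurvival:
    """(Weighted) product-limit estimate; jumps only at times with events."""
    Z = np.asarray(Z, float)
    events = np.asarray(events, float)
    w = np.ones_like(Z) if w is None else np.asarray(w, float)
    order = np.argsort(Z, kind="mergesort")
    Z, events, w = Z[order], events[order], w[order]
    t_uniq, start = np.unique(Z, return_index=True)
    # weighted deaths per distinct time and weighted number at risk
    dN = np.add.reduceat(w * events, start)
    at_risk = np.cumsum((w)[::-1])[::-1][start]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = 1.0 - np.where(at_risk > 0, dN / at_risk, 0.0)
    S = np.cumprod(frac)
    keep = dN > 0
    return StepSurvival(t_uniq[keep], np.clip(S[keep], 0.0, 1.0))


def km(cohort: BaselineCohort) -> StepSurvival:
    """Kaplan–Meier estimate of the event-time survival function."""
    return _product_limit(cohort.Z, cohort.delta == 1)


def censoring_km(cohort: BaselineCohort) -> StepSurvival:
    """Kaplan–Meier estimate for the censoring time (indicator 1 - delta)."""
    return _product_limit(cohort.Z, cohort.delta == 0)


def default_lambda_n(n: int) -> float:
    """Default nearest-neighbour half-width, 0.25 n^(-1/3), capped below 0.5."""
    return min(0.25 * n ** (-1 / 3), 0.499)


@dataclass(frozen=True)
class NNEConfig:
    """Half-width of the 0/1 nearest-neighbour kernel on the ECDF scale.

    ``2 * lambda_n`` is the fraction of subjects inside each neighbourhood.
    """

    lambda_n: float

    def __post_init__(self):
        if not 0 < self.lambda_n < 0.5:
            raise ValueError(f"lambda_n must be in (0, 0.5), got {self.lambda_n}")

    @classmethod
    def for_n(cls, n: int) -> "NNEConfig":
        return cls(default_lambda_n(n))


def _ecdf_values(X: np.ndarray, at: np.ndarray) -> np.ndarray:
    sx = np.sort(np.asarray(X, float))
    return np.searchsorted(sx, np.asarray(at, float), side="right") / len(sx)


def _nne_mask(X: np.ndarray, x0: float, lam: float) -> np.ndarray:
    F = _ecdf_values(X, X)
    F0 = float(_ecdf_values(X, np.asarray([x0]))[0])
    return np.abs(F - F0) < lam


def nne_weighted_km(cohort: BaselineCohort, x0: float, cfg: NNEConfig) -> StepSurvival:
    """Akritas weighted Kaplan–Meier estimate of S(t | X = x0).

    The 0/1 kernel acts on the marker's empirical-CDF scale, so the result
    is invariant to strictly increasing marker transformations. Anchors
    drawn from the cohort always fall inside their own neighbourhood.
    """
    mask = _nne_mask(cohort.X, x0, cfg.lambda_n)
    if not mask.any():  # anchor outside the cohort support with a tiny window
        mask = np.abs(cohort.X - x0) == np.min(np.abs(cohort.X - x0))
    return _product_limit(cohort.Z[mask], cohort.delta[mask] == 1)


def nne_conditional_at(
    cohort: BaselineCohort, cfg: NNEConfig, t: float,
    anchors: np.ndarray | None = None,
    events: np.ndarray | None = None,
) -> np.ndarray:
    """S_lambda(t | x) for each anchor x (default: every cohort marker).

    ``events`` overrides the event indicator (pass ``1 - delta`` to estimate
    the conditional censoring survival).
    """
    X = cohort.X
    d = cohort.delta if events is None else np.asarray(events)
    anchors = X if anchors is None else np.asarray(anchors, float)
    F = _ecdf_values(X, X)
    Fa = _ecdf_values(X, anchors)
    out = np.empty(len(anchors))
    for k, f0 in enumerate(Fa):
        m = np.abs(F - f0) < cfg.lambda_n
        if not m.any():
            m = np.abs(X - anchors[k]) == np.min(np.abs(X - anchors[k]))
        out[k] = _product_limit(cohort.Z[m], d[m] == 1)(t)
    return out


class NNEBivariateSurface:
    """Nearest-neighbour estimate of the bivariate survival S(c, t) of (X, T).

    ``S(c, t) = n^-1 sum_i I(X_i > c) S_lambda(t | X_i)``; the marginal is
    ``S(-inf, t)``. Non-increasing in both arguments.
    """

    def __init__(self, cohort: BaselineCohort, cfg: NNEConfig):
        self.cohort = cohort
        self.cfg = cfg
        self._curves: list[StepSurvival] | None = None

    def _conditional_curves(self) -> list[StepSurvival]:
        if self._curves is None:
            c, cfg = self.cohort, self.cfg
            F = _ecdf_values(c.X, c.X)
            self._curves = []
            for f0 in F:
                m = np.abs(F - f0) < cfg.lambda_n
                self._curves.append(_product_limit(c.Z[m], c.delta[m] == 1))
        return self._curves

    def conditional_at(self, t: float) -> np.ndarray:
        """S_lambda(t | X_i) for every subject i."""
        return np.array([s(t) for s in self._conditional_curves()])

    def __call__(self, c, t: float) -> np.ndarray | float:
        s_i = self.conditional_at(t)
        cs = np.atleast_1d(np.asarray(c, float))
        out = np.array([s_i[self.cohort.X > cc].sum() / self.cohort.n for cc in cs])
        return out if np.ndim(c) else float(out[0])

    def marginal(self, t: float) -> float:
        return float(self.conditional_at(t).mean())


def nne_bivariate(cohort: BaselineCohort, cfg: NNEConfig) -> NNEBivariateSurface:
    return NNEBivariateSurface(cohort, cfg)


@dataclass(frozen=True)
class PHFit:
    """Cox proportional-hazards fit for a single scalar marker.

    The baseline cumulative hazard is the Breslow estimate at marker 0;
    ``scaled_schoenfeld`` holds gamma + m * var(gamma) * s_k per event
    record (the standard scaled residuals whose smooth estimates a
    time-varying coefficient).
    """

    gamma: float
    se: float
    event_grid: np.ndarray          # per-event observed times, ascending
    schoenfeld: np.ndarray
    scaled_schoenfeld: np.ndarray
    baseline_times: np.ndarray      # distinct event times
    baseline_cumhaz: np.ndarray     # Breslow Lambda_0 at those times

    @property
    def var(self) -> float:
        return self.se ** 2

    def cumhaz(self, t, x):
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        lam0 = np.concatenate(([0.0], self.baseline_cumhaz))[np.asarray(idx) + 1]
        return lam0 * np.exp(self.gamma * np.asarray(x, float))

    def survival(self, t, x):
        return np.exp(-self.cumhaz(t, x))

    def risk(self, t, x):
        """Conditional absolute risk F(t; x) = 1 - exp(-Lambda(t; x))."""
        return 1.0 - self.survival(t, x)


def ph_fit(cohort: BaselineCohort) -> PHFit:
    """Fit lambda_0(t) exp(gamma X) by partial likelihood (Breslow baseline)."""
    if cohort.n_events < 1:
        raise FittingError("proportional-hazards fit needs at least one event")
    if np.ptp(cohort.X) == 0:
        raise FittingError("marker is constant; hazard coefficient unidentifiable")
    df = pd.DataFrame({"T": cohort.Z, "E": cohort.delta, "x": cohort.X})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
    except Exception as exc:  # pragma: no cover - lifelines diagnostics pass through
        raise FittingError(f"Cox partial-likelihood fit failed: {exc}") from exc
    gamma = float(cph.params_.iloc[0])
    se = float(cph.standard_errors_.iloc[0])

    Z, d, X = cohort.Z, cohort.delta, cohort.X
    exb = np.exp(gamma * X)
    ev_times = np.unique(Z[d == 1])
    # Breslow baseline and risk-set weighted marker means at distinct event times
    lam0 = np.empty(len(ev_times))
    xbar = np.empty(len(ev_times))
    for k, tk in enumerate(ev_times):
        at_risk = Z >= tk
        denom = exb[at_risk].sum()
        lam0[k] = (d[Z == tk] == 1).sum() / denom
        xbar[k] = (X[at_risk] * exb[at_risk]).sum() / denom
    cumhaz = np.cumsum(lam0)

    ev_mask = d == 1
    order = np.argsort(Z[ev_mask], kind="mergesort")
    grid = Z[ev_mask][order]
    x_ev = X[ev_mask][order]
    res = x_ev - xbar[np.searchsorted(ev_times, grid)]
    m = len(grid)
    scaled = gamma + m * se ** 2 * res
    return PHFit(gamma, se, grid, res, scaled, ev_times, cumhaz)


@dataclass(frozen=True)
class AdditiveFit:
    """Aalen additive-hazards fit: cumulative intercept B0 and slope B1."""

    times: np.ndarray
    B0: np.ndarray
    B1: np.ndarray

    def _interp(self, vals, t):
        idx = np.searchsorted(self.times, t, side="right") - 1
        padded = np.concatenate(([0.0], vals))
        return padded[np.asarray(idx) + 1]

    def b0(self, t):
        return self._interp(self.B0, t)

    def b1(self, t):
        return self._interp(self.B1, t)

    def risk(self, t, x):
        """F(t; x) = 1 - exp(-B0(t) - B1(t) x), clipped to [0, 1]."""
        cum = self.b0(t) + self.b1(t) * np.asarray(x, float)
        return 1.0 - np.exp(-np.clip(cum, 0.0, None))


def additive_fit(cohort: BaselineCohort) -> AdditiveFit:
    """Least-squares cumulative coefficients for hazard b0(t) + b1(t) X."""
    if cohort.n_events < 2:
        raise FittingError("additive fit needs at least two events")
    if np.ptp(cohort.X) == 0:
        # degenerate design: slope is zero and the intercept reduces to the
        # marginal Nelson-Aalen cumulative hazard
        Z, d = cohort.Z, cohort.delta
        ev = np.unique(Z[d == 1])
        dn = np.array([((Z == tk) & (d == 1)).sum() for tk in ev], float)
        y = np.array([(Z >= tk).sum() for tk in ev], float)
        return AdditiveFit(ev, np.cumsum(dn / y), np.zeros(len(ev)))
    df = pd.DataFrame({"T": cohort.Z, "E": cohort.delta, "x": cohort.X})
    aaf = AalenAdditiveFitter(fit_intercept=True, coef_penalizer=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aaf.fit(df, duration_col="T", event_col="E")
    ch = aaf.cumulative_hazards_
    times = ch.index.to_numpy(float)
    keep = times > 0
    times = times[keep]

    def _accumulate(cum):
        inc = np.diff(np.concatenate(([0.0], cum)))
        bad = ~np.isfinite(inc)
        if bad.any():
            logger.warning("additive fit: dropped %d singular increment(s)", int(bad.sum()))
            inc[bad] = 0.0
        return np.cumsum(inc)

    return AdditiveFit(times, _accumulate(ch["Intercept"].to_numpy(float)[keep]),
                       _accumulate(ch["x"].to_numpy(float)[keep]))


@dataclass(frozen=True)
class TimeVaryingCoef:
    """Smoothed time-varying log-hazard coefficient gamma(t)."""

    grid: np.ndarray
    gamma_t: np.ndarray
    bandwidth: float

    def __call__(self, t):
        return np.interp(t, self.grid, self.gamma_t)


def smooth_time_varying_gamma(fit: PHFit, bandwidth: float | None = None) -> TimeVaryingCoef:
    """Estimate gamma(t) by locally weighted linear (lowess) smoothing of the
    scaled Schoenfeld residuals over the event-time grid.

    Smoothing distances use the rank of the event time (the "rank" time
    transform customary for scaled-residual diagnostics): late event times
    are sparse and their residuals noisy, and rank spacing keeps those
    points from dominating the boundary fit. ``bandwidth`` is the smoother
    span: the fraction of events entering each local fit (default 0.6).
    Spans covering fewer than five events are widened with a warning.
    """
    m = len(fit.event_grid)
    if m < 5:
        raise FittingError("time-varying coefficient needs at least 5 events")
    frac = 0.6 if bandwidth is None else float(bandwidth)
    if frac * m < 5:
        frac = min(1.0, 5.0 / m)
        logger.warning("smoother span widened to %.3f (needs >= 5 events per window)", frac)
    frac = min(frac, 1.0)
    rank = np.arange(m, dtype=float)
    sm = lowess(fit.scaled_schoenfeld, rank, frac=frac, it=0, return_sorted=False)
    return TimeVaryingCoef(fit.event_grid, np.asarray(sm, float), frac)


def bootstrap_ci(
    estimator: Callable[[BaselineCohort], float | AUCResult],
    cohort,
    B: int = 200,
    level: float = 0.95,
    seed: int | None = None,
    method: str | None = None,
) -> AUCResult:
    """Percentile bootstrap interval from B whole-subject resamples.

    Deterministic given ``seed``. An estimator failure on a resample causes
    a redraw (count logged); more than 10% failed draws is a hard error.
    """
    if B < 50:
        raise ValueError("bootstrap needs B >= 50 replicates")
    rng = np.random.default_rng(seed)

    def value(c):
        r = estimator(c)
        return (r.auc, r.t, r.method) if isinstance(r, AUCResult) else (float(r), np.nan, None)

    point, t, tag = value(cohort)
    tag = method or tag or getattr(estimator, "__name__", "estimator")
    n = cohort.n
    stats, failures = [], 0
    while len(stats) < B:
        idx = rng.integers(0, n, n)
        try:
            stats.append(value(cohort.resample(idx))[0])
        except Exception:
            failures += 1
            if failures > 0.1 * B:
                raise FittingError(
                    f"bootstrap: {failures} resample failures exceeded 10% of B={B}"
                )
    if failures:
        logger.warning("bootstrap: %d failed resample(s) redrawn", failures)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(stats, [alpha, 1 - alpha])
    return AUCResult(
        t=t, auc=point, method=tag,
        ci_low=float(min(lo, point)), ci_high=float(max(hi, point)),
        n_boot=B, seed=seed,
    )
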