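"""Synthetic cohorts with known truth for every estimator family.

Baseline cohorts carry a standard-Gaussian marker with an exponential,
Weibull or additive hazard effect, and censoring that is absent,
independent exponential, or marker-dependent (censoring hazard
``rate * exp(eta X)`` — the structure that breaks estimators assuming
censoring independent of the marker). Each simulated cohort comes with an
oracle exposing the true conditional risk and the true cumulative/dynamic
and incident/dynamic AUC at any time by quadrature over the marker law.

Longitudinal cohorts follow case/control linear mixed-effects trajectory
models (random intercept + visit-time slope; the case mean also carries
time-before-event and interaction terms). The default trajectory
parameters are of the magnitude reported for the Mayo PBC serum-bilirubin
style score fits, with visits on a yearly schedule in days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import norm

from .cohorts import BaselineCohort, LongitudinalCohort

__all__ = [
    "BaselineScenario",
    "LongitudinalScenario",
    "TrueModelOracle",
    "simulate_baseline",
    "simulate_longitudinal",
    "true_cd_auc",
    "true_id_auc",
]


@dataclass(frozen=True)
class BaselineScenario:
    """Generator settings for a single-marker censored cohort.

    ``event_model``: ``exponential`` (hazard rate * exp(gamma X)),
    ``weibull`` (cumulative hazard rate * t^shape * exp(gamma X)) or
    ``additive`` (hazard b0 + b1 X, floored at ``additive_floor``).
    ``censoring``: ``none``, ``independent`` (exponential at
    ``censoring_rate``) or ``marker`` (rate * exp(censoring_eta * X)).
    """

    n: int
    gamma: float = 1.0
    event_model: str = "exponential"
    baseline_rate: float = 1.0
    shape: float = 1.5
    b0: float = 1.0
    b1: float = 0.3
    additive_floor: float = 1e-3
    censoring: str = "independent"
    censoring_rate: float = 0.5
    censoring_eta: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.event_model not in ("exponential", "weibull", "additive"):
            raise ValueError(f"unknown event model {self.event_model!r}")
        if self.censoring not in ("none", "independent", "marker"):
            raise ValueError(f"unknown censoring model {self.censoring!r}")
        if self.baseline_rate <= 0 or self.censoring_rate <= 0 or self.shape <= 0:
            raise ValueError("rates and shape must be > 0")


class TrueModelOracle:
    """True conditional law of (T, C) given the marker, with quadrature AUCs."""

    def __init__(self, sc: BaselineScenario, grid_n: int = 4001, span: float = 8.0):
        self.sc = sc
        self.x = np.linspace(-span, span, grid_n)
        self.phi = norm.pdf(self.x)

    def _event_rate(self, x):
        sc = self.sc
        if sc.event_model == "additive":
            return np.maximum(sc.b0 + sc.b1 * np.asarray(x, float), sc.additive_floor)
        return sc.baseline_rate * np.exp(sc.gamma * np.asarray(x, float))

    def cumhaz(self, t, x):
        r = self._event_rate(x)
        if self.sc.event_model == "weibull":
            return r * t ** self.sc.shape
        return r * t

    def risk(self, t, x):
        """F(t | x) = P(T <= t | X = x)."""
        return 1.0 - np.exp(-self.cumhaz(t, x))

    def density(self, t, x):
        """f(t | x)."""
        r = self._event_rate(x)
        if self.sc.event_model == "weibull":
            lam = r * self.sc.shape * t ** (self.sc.shape - 1)
        else:
            lam = r
        return lam * np.exp(-self.cumhaz(t, x))

    def _auc(self, numer_fn, t: float) -> float:
        """P(X_i > X_j | case weight(i), T_j > t) by quadrature over the
        Gaussian marker law (tie set has measure zero)."""
        Sv = 1.0 - self.risk(t, self.x)
        g = numer_fn(t, self.x)
        H = cumulative_trapezoid(Sv * self.phi, self.x, initial=0.0)  # mass below x
        num = np.trapezoid(g * H * self.phi, self.x)
        den = np.trapezoid(g * self.phi, self.x) * np.trapezoid(Sv * self.phi, self.x)
        if den <= 0:
            raise ValueError(f"degenerate case/control mass at t={t}")
        return float(num / den)

    def cd_auc(self, t: float) -> float:
        """True AUC^{C,D}(t) = P(X_i > X_j | T_i <= t, T_j > t)."""
        if self.sc.gamma == 0 and self.sc.event_model != "additive":
            return 0.5
        return self._auc(self.risk, t)

    def id_auc(self, t: float) -> float:
        """True AUC^{I,D}(t) = P(X_i > X_j | T_i = t, T_j > t)."""
        if self.sc.gamma == 0 and self.sc.event_model != "additive":
            return 0.5
        return self._auc(self.density, t)

    def event_fraction(self) -> float:
        """P(delta = 1) under the scenario (quadrature over t and x)."""
        sc = self.sc
        if sc.censoring == "none":
            return 1.0
        rc = (sc.censoring_rate if sc.censoring == "independent"
              else sc.censoring_rate * np.exp(sc.censoring_eta * self.x))
        if sc.event_model == "exponential":
            re = self._event_rate(self.x)
            frac = re / (re + rc)
            return float(np.trapezoid(frac * self.phi, self.x))
        # numeric inner integral over t for non-exponential event models
        tmax = 20.0 / min(float(np.min(np.atleast_1d(rc))), 1.0)
        tg = np.linspace(1e-9, tmax, 4000)
        inner = np.empty(len(self.x))
        for k, xv in enumerate(self.x):
            rck = rc if np.isscalar(rc) else rc[k]
            inner[k] = np.trapezoid(self.density(tg, xv) * np.exp(-rck * tg), tg)
        return float(np.trapezoid(inner * self.phi, self.x))

    def median_event_time(self) -> float:
        """Median of the marginal event-time distribution (no censoring)."""
        from scipy.optimize import brentq

        marg = lambda t: np.trapezoid(self.risk(t, self.x) * self.phi, self.x) - 0.5
        return float(brentq(marg, 1e-9, 1e6))


def simulate_baseline(sc: BaselineScenario) -> tuple[BaselineCohort, TrueModelOracle]:
    """Draw a cohort under the scenario; reproducible given ``sc.seed``."""
    rng = np.random.default_rng(sc.seed)
    X = rng.standard_normal(sc.n)
    oracle = TrueModelOracle(sc)
    E = rng.exponential(size=sc.n)
    rate = oracle._event_rate(X)
    if sc.event_model == "weibull":
        T = (E / rate) ** (1.0 / sc.shape)
    else:
        T = E / rate
    if sc.censoring == "none":
        C = np.full(sc.n, np.inf)
    elif sc.censoring == "independent":
        C = rng.exponential(1.0 / sc.censoring_rate, sc.n)
    else:
        C = rng.exponential(size=sc.n) / (sc.censoring_rate * np.exp(sc.censoring_eta * X))
    Z = np.minimum(T, C)
    delta = (T <= C).astype(int)
    ids = np.array([f"s{k}" for k in range(sc.n)], dtype=object)
    return BaselineCohort(ids, np.maximum(Z, 1e-12), delta, X), oracle


def true_cd_auc(oracle: TrueModelOracle, t: float) -> float:
    return oracle.cd_auc(t)


def true_id_auc(oracle: TrueModelOracle, t: float) -> float:
    return oracle.id_auc(t)


# ---------------------------------------------------------------------------
# longitudinal trajectories

#: trajectory defaults: magnitudes of the PBC-style mixed-model fits, days
_CASE_BETA = (1.139, -4.813e-4, 2.283e-4, -1.083e-7)
_CTRL_BETA = (-0.569, 2.906e-4)


def _cov(sd_int, sd_slope, rho):
    off = rho * sd_int * sd_slope
    return ((sd_int ** 2, off), (off, sd_slope ** 2))


@dataclass(frozen=True)
class LongitudinalScenario:
    """Generator settings for case/control marker trajectories.

    Visit times follow ``n_visits`` on a regular ``spacing`` grid with
    uniform ``jitter`` (first visit at time 0, jitter-free). Case event
    times are uniform on ``case_event_window`` (default: from just past the
    first scheduled visit to two spacings beyond the last) and visits at or
    after the event are discarded, so the time before event is defined at
    every retained visit; controls keep the full schedule and are censored
    ``control_followup`` after their last visit.
    """

    n_case: int = 100
    n_control: int = 100
    n_visits: int = 5
    spacing: float = 365.0
    jitter: float = 30.0
    case_beta: tuple = _CASE_BETA
    control_beta: tuple = _CTRL_BETA
    case_V: tuple = _cov(0.593, 3.448e-4, -0.378)
    control_V: tuple = _cov(0.550, 2.615e-4, 0.209)
    case_sigma: float = 0.293
    control_sigma: float = 0.220
    case_event_window: tuple | None = None
    control_followup: float = 365.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_visits < 1:
            raise ValueError("need at least one visit")
        for V in (self.case_V, self.control_V):
            if np.linalg.eigvalsh(np.asarray(V, float)).min() < -1e-12:
                raise ValueError("random-effect covariance must be PSD")


def simulate_longitudinal(sc: LongitudinalScenario) -> LongitudinalCohort:
    """Draw case/control trajectories; reproducible given ``sc.seed``.

    Case trajectories include the time-before-event terms (every case's
    event time exceeds its last visit, so the lag is defined at each
    visit); control trajectories depend on visit time only.
    """
    rng = np.random.default_rng(sc.seed)
    window = sc.case_event_window or (0.6 * sc.spacing, sc.n_visits * sc.spacing + 2 * sc.spacing)
    ids, Z, delta, vs, vt, vv = [], [], [], [], [], []

    def visit_times():
        base = np.arange(sc.n_visits) * sc.spacing
        jit = rng.uniform(-sc.jitter, sc.jitter, sc.n_visits)
        jit[0] = 0.0
        s = np.sort(base + jit)
        s[0] = max(s[0], 0.0)
        return s

    k = 0
    for grp, ng in (("case", sc.n_case), ("ctrl", sc.n_control)):
        beta = np.asarray(sc.case_beta if grp == "case" else sc.control_beta)
        V = np.asarray(sc.case_V if grp == "case" else sc.control_V, float)
        sig = sc.case_sigma if grp == "case" else sc.control_sigma
        # PSD square root via eigendecomposition (exact for singular V)
        evals, evecs = np.linalg.eigh(V)
        L = evecs * np.sqrt(np.clip(evals, 0.0, None))
        for _ in range(ng):
            s = visit_times()
            b = L @ rng.standard_normal(2)
            if grp == "case":
                T = rng.uniform(*window)
                s = s[s < T]
                if len(s) == 0:
                    s = np.array([0.0])
                tbe = T - s
                mean = beta[0] + beta[1] * s + beta[2] * tbe + beta[3] * s * tbe
                Z.append(T)
                delta.append(1)
            else:
                mean = beta[0] + beta[1] * s
                Z.append(s[-1] + sc.control_followup)
                delta.append(0)
            y = b[0] + b[1] * s + mean + sig * rng.standard_normal(len(s))
            ids.append(f"{grp}{k}")
            vs.append(np.full(len(s), k))
            vt.append(s)
            vv.append(y)
            k += 1
    return LongitudinalCohort(
        np.array(ids, object), np.array(Z), np.array(delta),
        np.concatenate(vs), np.concatenate(vt), np.concatenate(vv),
    )
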