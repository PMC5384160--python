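"""Incident/dynamic (I/D) time-dependent ROC estimators and concordance.

At an event time ``t`` the riskset (subjects with Z >= t) splits into
incident cases (Z = t with an observed event) and dynamic controls
(Z > t). Estimators:

id1  Cox-model sensitivity with exponentially tilted riskset weights and a
     time-varying coefficient from smoothed scaled Schoenfeld residuals;
     empirical specificity over controls
id2  weighted mean rank: kernel-local average of per-riskset concordance
     U-statistics A(t)
id3  fractional-polynomial model for AUC(t) fitted by pseudo
     partial-likelihood over riskset concordant/discordant pair counts

plus the concordance summary C^tau, a Kaplan-Meier-weighted average of the
incident/dynamic AUC over (0, tau].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr, ndtri

from .cohorts import BaselineCohort
from .curves import AUCResult, ROCCurve, threshold_grid
from .cd import UndefinedAUCError, _weighted_frac_above
from .primitives import TimeVaryingCoef, km, ph_fit, smooth_time_varying_gamma

__all__ = [
    "Riskset",
    "riskset_at",
    "id1_roc",
    "id1_auc",
    "concordance_tau",
    "riskset_concordance",
    "id2_wmr",
    "FracPolyModel",
    "id3_fit",
    "id3_auc",
    "id3_integrated_auc",
    "FP_POWERS",
]

#: Royston-Altman candidate powers for fractional polynomials
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class Riskset:
    """Incident cases and dynamic controls at an event time."""

    t: float
    case_idx: np.ndarray
    control_idx: np.ndarray

    @property
    def d_t(self) -> int:
        return len(self.case_idx)

    @property
    def n_t(self) -> int:
        return len(self.control_idx)


def riskset_at(cohort: BaselineCohort, t: float) -> Riskset:
    cases = np.flatnonzero((cohort.Z == t) & (cohort.delta == 1))
    controls = np.flatnonzero(cohort.Z > t)
    return Riskset(t, cases, controls)


def _require_event_time(cohort: BaselineCohort, t: float) -> None:
    ev = cohort.event_times()
    if t not in ev:
        near = ev[np.argsort(np.abs(ev - t))][:5]
        raise UndefinedAUCError(
            f"t={t} is not an observed event time; nearest event times: {np.sort(near)}"
        )


def _gamma_at(cohort: BaselineCohort, t: float, tv: TimeVaryingCoef | None,
              bandwidth: float | None = None) -> float:
    if tv is None:
        tv = smooth_time_varying_gamma(ph_fit(cohort), bandwidth)
    return float(tv(t))


def id1_roc(
    cohort: BaselineCohort, t: float,
    tv: TimeVaryingCoef | None = None, bandwidth: float | None = None,
) -> ROCCurve:
    """Cox-regression incident/dynamic ROC at event time ``t``.

    Sensitivity is the exp-tilted riskset survivor function of the marker
    with weights pi_i proportional to exp(X_i * gamma(t)) over the riskset;
    specificity is empirical over dynamic controls.
    """
    _require_event_time(cohort, t)
    rs = riskset_at(cohort, t)
    if rs.n_t == 0:
        raise UndefinedAUCError(f"empty control set beyond t={t}")
    gamma_t = _gamma_at(cohort, t, tv, bandwidth)
    at_risk = cohort.Z >= t
    Xr = cohort.X[at_risk]
    w = np.exp(np.clip(gamma_t * Xr - np.max(gamma_t * Xr), -700, 0))
    grid = threshold_grid(Xr)
    sens = _weighted_frac_above(Xr, w, grid)
    Xc = cohort.X[rs.control_idx]
    fpr = _weighted_frac_above(Xc, np.ones(len(Xc)), grid)
    return ROCCurve(t, grid, sens, fpr, "id1", metadata={"gamma_t": gamma_t})


def id1_auc(cohort, t, tv=None, bandwidth=None) -> AUCResult:
    return id1_roc(cohort, t, tv, bandwidth).auc_result()


def concordance_tau(cohort: BaselineCohort, auc_at, tau: float) -> float:
    """Concordance summary C^tau: weighted average of AUC^{I,D}(t) over
    distinct event times in (0, tau].

    ``auc_at`` maps an event time to its incident/dynamic AUC (a callable
    or a dict). The weight at t_k is the Kaplan-Meier mass 2 f(t_k) S(t_k)
    normalised by 1 - S(tau)^2, discretised as
    (S(t_{k-1})^2 - S(t_k)^2) / (1 - S(tau)^2) so the weights telescope to
    exactly 1.
    """
    if tau > float(np.max(cohort.Z)):
        raise ValueError("tau must not exceed the largest observed time")
    S = km(cohort)
    if S(tau) >= 1.0:
        raise UndefinedAUCError(f"no event mass in (0, {tau}]; concordance undefined")
    ev = cohort.event_times()
    ev = ev[ev <= tau]
    S_prev = np.concatenate(([1.0], S(ev)[:-1]))
    wts = (S_prev ** 2 - S(ev) ** 2) / (1.0 - S(tau) ** 2)
    lookup = auc_at if callable(auc_at) else (lambda tk: auc_at[tk])
    aucs = np.array([float(lookup(tk)) for tk in ev])
    return float(np.dot(wts, aucs))


def riskset_concordance(cohort: BaselineCohort, t: float) -> float:
    """A(t): fraction of case-control marker pairs correctly ordered in the
    riskset at event time ``t`` (strict inequality, as the rank statistic
    is defined)."""
    rs = riskset_at(cohort, t)
    if rs.d_t == 0 or rs.n_t == 0:
        raise UndefinedAUCError(f"riskset at t={t} lacks cases or controls")
    Xcase = cohort.X[rs.case_idx]
    Xctrl = np.sort(cohort.X[rs.control_idx])
    below = np.searchsorted(Xctrl, Xcase, side="left")
    return float(below.sum() / (rs.d_t * rs.n_t))


def id2_wmr(
    cohort: BaselineCohort, t: float,
    bandwidth: float | None = None, kernel: str = "uniform",
) -> AUCResult:
    """Weighted-mean-rank estimator: local average of riskset concordances.

    ``bandwidth`` is the half-width h of the event-time neighbourhood
    |t - t_j| < h; the default spans the nearest 10% of event times.
    ``kernel`` is ``"uniform"`` (plain mean over the neighbourhood) or
    ``"standardized"`` (Gaussian kernel weights normalised to sum to 1).
    """
    ev = np.array([tk for tk in cohort.event_times()
                   if riskset_at(cohort, tk).n_t > 0])
    if len(ev) == 0:
        raise UndefinedAUCError("no usable event times")
    if bandwidth is None:
        k = max(1, int(np.ceil(0.1 * len(ev))))
        bandwidth = float(np.sort(np.abs(ev - t))[min(k, len(ev) - 1)]) + 1e-12
    if kernel == "uniform":
        near = ev[np.abs(ev - t) < bandwidth]
        if len(near) == 0:
            raise UndefinedAUCError(
                f"no event time within h={bandwidth} of t={t}; increase the bandwidth"
            )
        wts = np.full(len(near), 1.0 / len(near))
        times = near
    elif kernel == "standardized":
        raw = np.exp(-0.5 * ((ev - t) / bandwidth) ** 2)
        if raw.sum() <= 0:
            raise UndefinedAUCError("kernel weights vanished; increase the bandwidth")
        wts = raw / raw.sum()
        times = ev
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    a = np.array([riskset_concordance(cohort, tk) for tk in times])
    return AUCResult(t=t, auc=float(np.dot(wts, a)), method="id2",
                     metadata={"bandwidth": bandwidth, "kernel": kernel,
                               "n_times": len(times)})


@dataclass(frozen=True)
class FracPolyModel:
    """Fractional-polynomial model for AUC(t): link(AUC) = b0 + sum_g b_g u^(p_g)
    with u = t / time_scale and u^(0) meaning ln(u)."""

    powers: tuple
    beta: np.ndarray
    link: str
    time_scale: float
    loglik: float
    flagged: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def G(self) -> int:
        return len(self.powers)

    def _eta(self, t):
        u = np.asarray(t, float) / self.time_scale
        eta = np.full(np.shape(u), self.beta[0], dtype=float)
        for g, p in enumerate(self.powers, start=1):
            eta = eta + self.beta[g] * (np.log(u) if p == 0 else u ** p)
        return eta

    def auc(self, t):
        eta = self._eta(t)
        return expit(eta) if self.link == "logistic" else ndtr(eta)


def _pair_counts(cohort: BaselineCohort):
    """Per distinct event time: concordant (case > control) and discordant
    (case <= control) pair counts over the riskset controls."""
    times, n1, n2 = [], [], []
    for tk in cohort.event_times():
        rs = riskset_at(cohort, tk)
        if rs.d_t == 0 or rs.n_t == 0:
            continue
        Xcase = cohort.X[rs.case_idx]
        Xctrl = np.sort(cohort.X[rs.control_idx])
        below = np.searchsorted(Xctrl, Xcase, side="left").sum()
        times.append(tk)
        n1.append(int(below))
        n2.append(int(rs.d_t * rs.n_t - below))
    return np.array(times), np.array(n1, float), np.array(n2, float)


def id3_fit(cohort: BaselineCohort, G: int = 1, link: str = "logistic") -> FracPolyModel:
    """Fit the fractional-polynomial AUC model by maximising the pseudo
    partial-likelihood prod_k AUC(t_k)^{n1_k} (1-AUC(t_k))^{n2_k}.

    The power set is searched exhaustively (distinct powers from the
    Royston-Altman candidates); the time axis is rescaled by the median
    event time before powers are applied, so t^2 stays numerically tame on
    day-scale data. Complete separation (all pairs concordant or all
    discordant) pins the AUC to the boundary and flags the fit.
    """
    if link not in ("logistic", "probit"):
        raise ValueError(f"unknown link {link!r}")
    times, n1, n2 = _pair_counts(cohort)
    if len(times) < G + 2:
        raise UndefinedAUCError(f"need at least G+2={G + 2} usable event times, got {len(times)}")
    scale = float(np.median(times))
    u = times / scale
    inv = expit if link == "logistic" else ndtr
    fwd = logit if link == "logistic" else ndtri

    if n2.sum() == 0 or n1.sum() == 0:
        eta0 = fwd(0.999) if n2.sum() == 0 else fwd(0.001)
        return FracPolyModel((), np.array([eta0]), link, scale, 0.0, flagged=True)

    abar = n1.sum() / (n1.sum() + n2.sum())

    def nll(beta, powers):
        eta = np.full(len(u), beta[0])
        for g, p in enumerate(powers, start=1):
            eta = eta + beta[g] * (np.log(u) if p == 0 else u ** p)
        a = np.clip(inv(eta), 1e-12, 1 - 1e-12)
        return -(n1 * np.log(a) + n2 * np.log(1 - a)).sum()

    best = None
    for powers in itertools.combinations(FP_POWERS, G):
        x0 = np.concatenate(([fwd(abar)], np.zeros(G)))
        res = minimize(nll, x0, args=(powers,), method="BFGS")
        if best is None or res.fun < best[0]:
            best = (res.fun, powers, res.x)
    fun, powers, beta = best
    return FracPolyModel(tuple(powers), np.asarray(beta), link, scale, -fun,
                         meta={"n_event_times": len(times)})


def id3_auc(model: FracPolyModel, t: float) -> AUCResult:
    return AUCResult(t=t, auc=float(np.clip(model.auc(t), 0, 1)), method="id3",
                     metadata={"powers": model.powers, "flagged": model.flagged})


def id3_integrated_auc(model: FracPolyModel, tau: float, n_grid: int = 512) -> float:
    """Uniform-weight integrated AUC over (0, tau] from the analytic curve."""
    t = np.linspace(tau / n_grid, tau, n_grid)
    return float(np.trapezoid(model.auc(t), t) / (tau - t[0]))
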