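"""ROC-curve and AUC result containers shared by every estimator.

A curve is stored as sensitivity / false-positive-rate pairs over a
descending threshold grid (unique marker values plus ±inf sentinels, so the
limiting points (0,0) and (1,1) are always present). The scalar AUC is the
trapezoidal integral of the curve, which on empirical step curves equals the
corresponding pairwise statistic with tied markers counted with weight 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ROCCurve", "AUCResult", "threshold_grid", "trapezoid_auc"]


def threshold_grid(X: np.ndarray) -> np.ndarray:
    """Descending grid of unique marker values with ±inf sentinels."""
    u = np.unique(np.asarray(X, float))
    return np.concatenate(([np.inf], u[::-1], [-np.inf]))


def trapezoid_auc(fpr: np.ndarray, sens: np.ndarray) -> float:
    order = np.argsort(fpr, kind="mergesort")
    return float(np.trapezoid(np.asarray(sens)[order], np.asarray(fpr)[order]))


@dataclass(frozen=True)
class ROCCurve:
    """Time-dependent ROC curve at evaluation time ``t``.

    ``bounded`` records whether the estimator guarantees values inside
    [0, 1]; estimators without that guarantee (the conditional Kaplan–Meier
    plug-in) report raw values, flagged via ``out_of_bounds``.
    """

    t: float
    thresholds: np.ndarray
    sens: np.ndarray
    fpr: np.ndarray
    method: str
    bounded: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "thresholds", np.asarray(self.thresholds, float))
        object.__setattr__(self, "sens", np.asarray(self.sens, float))
        object.__setattr__(self, "fpr", np.asarray(self.fpr, float))
        if not (len(self.thresholds) == len(self.sens) == len(self.fpr)):
            raise ValueError("thresholds, sens, fpr must align")
        if np.any(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be non-increasing")
        if self.bounded:
            eps = 1e-9
            if np.any(self.sens < -eps) or np.any(self.sens > 1 + eps):
                raise ValueError(f"{self.method}: sensitivity outside [0,1]")
            if np.any(self.fpr < -eps) or np.any(self.fpr > 1 + eps):
                raise ValueError(f"{self.method}: 1-specificity outside [0,1]")

    @property
    def out_of_bounds(self) -> bool:
        return bool(
            np.any(self.sens < 0) or np.any(self.sens > 1)
            or np.any(self.fpr < 0) or np.any(self.fpr > 1)
        )

    @property
    def auc(self) -> float:
        return trapezoid_auc(self.fpr, self.sens)

    def auc_result(self, **kw) -> "AUCResult":
        return AUCResult(t=self.t, auc=self.auc, method=self.method, **kw)


@dataclass(frozen=True)
class AUCResult:
    """Scalar AUC at time ``t`` with optional bootstrap interval."""

    t: float
    auc: float
    method: str
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not -1e-9 <= self.auc <= 1 + 1e-9:
            raise ValueError(f"AUC {self.auc} outside [0,1] for {self.method}")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.auc + 1e-12 and self.auc - 1e-12 <= self.ci_high):
                raise ValueError("bootstrap interval must bracket the point estimate")
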