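# tdroc

Time-dependent ROC curve and AUC estimation for right-censored event-time
data and longitudinal biomarkers.

## The problem

In prognostic studies the disease status of a subject is not fixed: a
subject event-free at two years may fail at five, and a biomarker measured
at baseline loses discriminating power as the prediction horizon recedes.
A classical ROC analysis that freezes case/control status at a single
look therefore misstates a marker's accuracy. With censored follow-up
(Z_i = min(T_i, C_i), event indicator δ_i, marker X_i), sensitivity and
specificity become functions of time,

    Se(c, t) = P(X_i > c | D_i(t) = 1),   Sp(c, t) = P(X_i ≤ c | D_i(t) = 0),

and the time-dependent AUC(t) is the area under the induced curve —
equivalently the probability that a randomly chosen case at time t has a
higher marker value than a randomly chosen control. `tdroc` implements the
full family of estimators for the three case/control conventions:

* **Cumulative/dynamic** (cases failed in (0, t], controls beyond t):
  the naive estimator, conditional-KM (`cd1`), Akritas nearest-neighbour
  (`cd2`), KM-increment (`cd3`), Cox plug-in (`cd4`), marginal and
  marker-conditional inverse-probability-of-censoring weighting
  (`cd5`, `cd6`), interval-weighted AUC (`cd7`), and the
  conditional-absolute-risk plug-in family (`cd8`: Cox / Aalen additive /
  nearest-neighbour KM).
* **Incident/dynamic** (cases fail exactly at t): Cox risk-set tilting
  with a time-varying coefficient from smoothed Schoenfeld residuals
  (`id1`), the weighted-mean-rank local U-statistic (`id2`), the
  fractional-polynomial pseudo-likelihood model (`id3`), and the
  concordance summary C^τ = ∫ AUC(t)·2f(t)S(t)/(1−S(τ)²) dt.
* **Incident/static and longitudinal markers**: static-control extension
  of the Cox method (`is2`), landmark ("last value") nearest-neighbour
  estimation (`ecd2`), the induced binormal ROC from case/control linear
  mixed trajectory models (`ad1`, with AUC = Φ(a₀/√(1+a₁²))), and the
  probit ROC-GLM on placement values (`ad2`).

Percentile bootstrap confidence intervals (whole-subject resampling) are
available for every scalar estimate, and a synthetic-cohort module
generates censored cohorts and marker trajectories with known truth —
including quadrature oracles for the true C/D and I/D AUC — so every
estimator can be validated without external data.

## Worked example

```python
import numpy as np
from tdroc import (BaselineScenario, simulate_baseline,
                   cd2_roc, cd5_roc, cd6_roc, cd8_auc, bootstrap_ci)

sc = BaselineScenario(n=500, gamma=1.0, censoring="independent",
                      censoring_rate=0.4, seed=7)
cohort, oracle = simulate_baseline(sc)      # marker ~ N(0,1), hazard e^{X}
t = 0.7
print("true AUC:", round(oracle.cd_auc(t), 3))
for name, auc in [("cd2", cd2_roc(cohort, t).auc),
                  ("cd5", cd5_roc(cohort, t).auc),
                  ("cd6", cd6_roc(cohort, t).auc),
                  ("vl_cox", cd8_auc(cohort, t, "vl_cox").auc)]:
    print(f"{name:7s} AUC(0.7) = {auc:.3f}")
r = bootstrap_ci(lambda c: cd5_roc(c, t).auc, cohort, B=200, seed=1)
print(f"cd5 95% CI: ({r.ci_low:.3f}, {r.ci_high:.3f})")
```

prints

```
true AUC: 0.809
cd2     AUC(0.7) = 0.794
cd5     AUC(0.7) = 0.796
cd6     AUC(0.7) = 0.797
vl_cox  AUC(0.7) = 0.793
cd5 95% CI: (0.750, 0.840)
```

Under this generator (standard-normal marker, exponential hazard e^{γX}
with γ = 1, 30% independent censoring) the cumulative/dynamic AUC at
t = 0.7 is 0.809; all four censoring-aware estimators land within 0.016
of it at n = 500, and the bootstrap interval covers the truth.

The same estimators are available from a shell:

```sh
tdroc simulate --scenario scenario.txt --out cohort.csv --seed 7
tdroc cd --method cd5 --time 0.7 --input cohort.csv --out auc.csv --boot 200 --seed 1
tdroc id --method id2 --time 0.6 --input cohort.csv --out id.csv
tdroc ad1 --visit-time 3650 --time-before-event 1825 --input visits.csv --out ad1.csv
```

Each run writes a long-format AUC table
(`method,t,auc,ci_low,ci_high,n_boot,seed`) and a JSON sidecar from which
the invocation can be reproduced exactly.

## Layout

| module | contents |
|---|---|
| `tdroc.cohorts` | cohort containers, validation, CSV/TSV IO, landmark reduction |
| `tdroc.curves` | `ROCCurve` / `AUCResult` containers, trapezoidal AUC |
| `tdroc.primitives` | KM and censoring KM, nearest-neighbour weighted KM, Cox/Aalen fits, Schoenfeld smoothing, bootstrap |
| `tdroc.cd` | cumulative/dynamic estimators (naive, cd1–cd8) |
| `tdroc.incident` | incident/dynamic estimators (id1–id3), concordance C^τ |
| `tdroc.longitudinal` | is2, ecd2, induced binormal (ad1), ROC-GLM (ad2) |
| `tdroc.synth` | scenario generators and quadrature truth oracles |
| `tdroc.cli` | `tdroc` command-line entry point |

See `docs/methods.md` for the models, defaults, numerical choices and
limitations.
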