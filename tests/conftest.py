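import numpy as np
import pytest
from hypothesis import settings

from tdroc import BaselineCohort, BaselineScenario, simulate_baseline

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_cohort(Z, delta, X):
    ids = [f"s{k}" for k in range(len(Z))]
    return BaselineCohort(ids, Z, delta, X)


def random_cohort(seed, n=60, censor_rate=0.7, gamma=1.0):
    """Seeded censored cohort with a standard-normal marker under an
    exponential proportional-hazards event model."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal(n)
    T = rng.exponential(size=n) / np.exp(gamma * X)
    C = rng.exponential(1.0 / censor_rate, n)
    Z = np.minimum(T, C)
    return make_cohort(np.maximum(Z, 1e-12), (T <= C).astype(int), X)


def rank_biased_cohort(n, seed):
    """Sequential-removal cohort whose true incident/dynamic AUC is exactly
    2/3 at every event time.

    At each event time the case is drawn from the current riskset with
    probability proportional to its marker rank (ascending, 1-based); then
    P(X_case > X_control | riskset of size m) = 2/3 independently of m.
    """
    rng = np.random.default_rng(seed)
    X = rng.permutation(n).astype(float)  # distinct markers
    remaining = list(range(n))
    Z = np.empty(n)
    for step in range(1, n + 1):
        ranks = np.argsort(np.argsort(X[remaining])) + 1.0
        probs = ranks / ranks.sum()
        pick = rng.choice(len(remaining), p=probs)
        Z[remaining[pick]] = step
        remaining.pop(pick)
    return make_cohort(Z, np.ones(n, int), X)


def pairwise_weighted_auc(X_case, w_case, X_ctrl, w_ctrl):
    """Brute-force weighted Mann-Whitney with half-weight ties."""
    num = 0.0
    for xi, wi in zip(X_case, w_case):
        for xj, wj in zip(X_ctrl, w_ctrl):
            if xi > xj:
                num += wi * wj
            elif xi == xj:
                num += 0.5 * wi * wj
    return num / (np.sum(w_case) * np.sum(w_ctrl))


@pytest.fixture
def toy_uncensored():
    """Four uncensored subjects; naive AUC at t=2.5 enumerates to 0.75."""
    return make_cohort([1, 2, 3, 4], [1, 1, 1, 1], [2, 4, 1, 3])


@pytest.fixture(scope="session")
def ph2000():
    """n=2000 exponential proportional-hazards cohort (gamma=1, independent
    censoring) with its quadrature oracle; shared across recovery tests."""
    sc = BaselineScenario(n=2000, gamma=1.0, censoring="independent",
                          censoring_rate=0.4, seed=11)
    return simulate_baseline(sc)


@pytest.fixture(scope="session")
def ph2000_median_t(ph2000):
    cohort, oracle = ph2000
    return float(oracle.median_event_time())
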