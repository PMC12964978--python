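"""Shared fixtures and independent oracle implementations.

The oracles here (exhaustive pairing enumeration, explicitly summed Cox
partial likelihood, trapezoid quadrature of the utility path) are kept
deliberately naive and separate from the package code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pneumocea import cohort


@pytest.fixture(scope="session")
def calibrated_cohort() -> pd.DataFrame:
    """A mid-sized cohort under the calibrated (confounded) study conditions."""
    return cohort.generate_cohort(cohort.CohortConfig(n_per_arm=500, seed=20240901))


@pytest.fixture(scope="session")
def large_cohort() -> pd.DataFrame:
    """Large cohort for marginal-calibration checks."""
    return cohort.generate_cohort(cohort.CohortConfig(n_per_arm=50_000, seed=7031))


# ---------------------------------------------------------------------------
# oracles


def optimal_matching_total(treated_logits, control_logits, caliper, n_pairs):
    """Minimum total |logit| distance over all caliper-feasible pairings of
    exactly ``n_pairs`` pairs, by exhaustive enumeration (tiny inputs only)."""
    t = list(treated_logits)
    c = list(control_logits)
    best = math.inf
    for t_sub in itertools.combinations(range(len(t)), n_pairs):
        for c_perm in itertools.permutations(range(len(c)), n_pairs):
            ds = [abs(t[i] - c[j]) for i, j in zip(t_sub, c_perm)]
            if all(d <= caliper for d in ds):
                best = min(best, sum(ds))
    return best


def max_matching_cardinality(treated_logits, control_logits, caliper):
    """Maximum number of caliper-feasible pairs, by exhaustive enumeration."""
    for k in range(min(len(treated_logits), len(control_logits)), 0, -1):
        if math.isfinite(optimal_matching_total(treated_logits, control_logits, caliper, k)):
            return k
    return 0


def cox_partial_loglik(beta, times, events, x):
    """Explicitly summed Breslow log partial likelihood (no ties assumed)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = times >= times[i]
            ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


def quadrature_qaly(recurrence, t_rec_months, utilities, episodes, annual_rate, horizon_months=60.0, n=100_000):
    """Trapezoid quadrature (n steps per smooth piece) of the discounted
    utility path, with the path semantics restated independently here."""
    T = horizon_months / 12.0
    di = episodes.d_initial_days / 365.0
    rho = math.log1p(annual_rate)
    if recurrence:
        tr = t_rec_months / 12.0
        end_rec = min(tr + episodes.d_recurrence_days / 365.0, T)
        pieces = [
            (0.0, min(di, tr), utilities.u_pneumothorax),
            (min(di, tr), tr, utilities.u_stable),
            (tr, end_rec, utilities.u_pneumothorax),
            (end_rec, T, utilities.u_post_recovery),
        ]
    else:
        pieces = [(0.0, min(di, T), utilities.u_pneumothorax), (min(di, T), T, utilities.u_stable)]
    total = 0.0
    for a, b, u in pieces:
        if b <= a:
            continue
        ts = np.linspace(a, b, n + 1)
        total += float(np.trapezoid(u * np.exp(-rho * ts), ts))
    return total


def empirical_survivor(times, t):
    """Empirical survivor fraction P(T > t) with no censoring."""
    times = np.asarray(times, float)
    return float(np.mean(times > t))
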