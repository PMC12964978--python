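"""Recurrence effect measures, matched-pair tests, time-to-event analysis
and the two-proportion sample-size calculation.

Effect measures follow the standard epidemiological definitions: absolute
risk reduction ARR = p_control − p_treated, number needed to treat
NNT = 1/ARR, relative risk RR = p_treated/p_control.  Time-to-event analysis
uses the Kaplan–Meier product-limit estimator, the two-group log-rank test
and a single-covariate Cox proportional-hazards model (Breslow tie handling
by default, Efron selectable).  The intention-to-treat convention is fixed:
crossover never changes a patient's analysis arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times
from scipy import stats

from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    DegenerateInputError,
    EmptyInputError,
)


@dataclass(frozen=True)
class TwoByTwo:
    events_treated: int
    n_treated: int
    events_control: int
    n_control: int

    def __post_init__(self):
        if self.n_treated <= 0 or self.n_control <= 0:
            raise ConfigurationError("group sizes must be positive")
        if not (0 <= self.events_treated <= self.n_treated):
            raise ConfigurationError("events_treated must lie in [0, n_treated]")
        if not (0 <= self.events_control <= self.n_control):
            raise ConfigurationError("events_control must lie in [0, n_control]")


@dataclass(frozen=True)
class EffectSummary:
    """Raw-precision effect measures; presentation rounding is separate."""

    rate_treated: float
    rate_control: float
    arr: float
    nnt: float  # inf marks undefined (ARR <= 0); see nnt_note
    rr: float
    nnt_note: str = ""

    def as_presentation(self) -> dict:
        """1 dp on percentages, 2 dp on NNT — rendering only."""
        return {
            "rate_treated_pct": round(100.0 * self.rate_treated, 1),
            "rate_control_pct": round(100.0 * self.rate_control, 1),
            "arr_pct": round(100.0 * self.arr, 1),
            "nnt": round(self.nnt, 2) if math.isfinite(self.nnt) else None,
            "rr": round(self.rr, 3) if math.isfinite(self.rr) else None,
        }


def effect_summary(t: TwoByTwo) -> EffectSummary:
    """Rates, ARR, NNT and RR from a matched 2x2 of recurrence counts."""
    rt = t.events_treated / t.n_treated
    rc = t.events_control / t.n_control
    arr = rc - rt
    if arr > 0:
        nnt, note = 1.0 / arr, ""
    else:
        nnt = math.inf
        note = "undefined (ARR = 0)" if arr == 0 else "undefined (ARR < 0: treated arm worse)"
    rr = rt / rc if rc > 0 else (math.nan if rt == 0 else math.inf)
    return EffectSummary(rt, rc, arr, nnt, rr, note)


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    mode: str
    degenerate: bool = False


def mcnemar_test(
    discordant_tc: int,
    discordant_ct: int,
    mode: Literal["exact", "chi_square"] = "exact",
    continuity: bool = True,
) -> McNemarResult:
    """McNemar's test on the discordant-pair counts of a matched 2x2.

    exact: two-sided binomial tail doubling, ``p = min(1, 2 P(X <= min(b,c)))``
    with ``X ~ Binomial(b+c, 1/2)``; chi_square: ``(|b-c|-cc)²/(b+c)`` on one
    degree of freedom (continuity correction cc=1 unless disabled).
    """
    b, c = discordant_tc, discordant_ct
    if b < 0 or c < 0:
        raise ConfigurationError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return McNemarResult(0.0, 1.0, mode, degenerate=True)
    if mode == "exact":
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
        return McNemarResult(float(min(b, c)), float(p), mode)
    if mode == "chi_square":
        cc = 1.0 if continuity else 0.0
        stat = max(abs(b - c) - cc, 0.0) ** 2 / n
        return McNemarResult(float(stat), float(stats.chi2.sf(stat, df=1)), mode)
    raise ConfigurationError(f"unknown mode {mode!r}")


@dataclass
class SurvFit:
    """Kaplan–Meier product-limit fit (log–log survival CI)."""

    event_times: np.ndarray  # distinct observed times in the step function
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # inf marks "not reached"
    median_ci: tuple

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.event_times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_fit(times: Sequence[float], event_flags: Sequence[int]) -> SurvFit:
    """Kaplan–Meier estimate of the recurrence-free survivor function."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=int)
    if len(t) == 0:
        raise EmptyInputError("km_fit requires at least one subject")
    if np.any(t <= 0):
        raise ConfigurationError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_["KM_estimate"]
    timeline = sf.index.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    ci_df = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
    return SurvFit(
        event_times=timeline,
        survival=sf.to_numpy(dtype=float),
        at_risk=at_risk,
        median=median,
        median_ci=(lo, hi),
    )


def survival_at(fit: SurvFit, time: float) -> float:
    """Step-function evaluation of the KM estimate at a time point."""
    idx = np.searchsorted(fit.event_times, time, side="right") - 1
    return 1.0 if idx < 0 else float(fit.survival[idx])


def logrank_test(times_a, flags_a, times_b, flags_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    fa = np.asarray(flags_a, dtype=int)
    fb = np.asarray(flags_b, dtype=int)
    if fa.sum() + fb.sum() == 0:
        raise DegenerateInputError("log-rank test requires at least one event")
    res = _ll_logrank(
        np.asarray(times_a, float), np.asarray(times_b, float), event_observed_A=fa, event_observed_B=fb
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxFit:
    log_hr: float
    se: float
    hr: float
    ci95: tuple
    ties_method: str
    p_value: float


def _cox_ll_grad_hess(
    beta: float, x: np.ndarray, order_times: np.ndarray, events: np.ndarray, ties_method: str
):
    """Log partial likelihood, score and information for a scalar covariate.

    Subjects must be sorted by ascending time; risk-set sums are reverse
    cumulative sums.  Breslow treats tied events with a common denominator;
    Efron down-weights tied subjects' own contribution within the tie.
    """
    ex = np.exp(beta * x)
    # reverse cumulative risk-set sums at each subject's position
    s0 = np.cumsum(ex[::-1])[::-1]
    s1 = np.cumsum((x * ex)[::-1])[::-1]
    s2 = np.cumsum((x * x * ex)[::-1])[::-1]
    ll = grad = hess = 0.0
    i = 0
    n = len(x)
    while i < n:
        j = i
        while j < n and order_times[j] == order_times[i]:
            j += 1
        tied = np.arange(i, j)[events[i:j] == 1]
        d = len(tied)
        if d > 0:
            xs = x[tied].sum()
            ll += beta * xs
            if ties_method == "breslow" or d == 1:
                r0, r1, r2 = s0[i], s1[i], s2[i]
                mu = r1 / r0
                ll -= d * math.log(r0)
                grad += xs - d * mu
                hess += d * (r2 / r0 - mu * mu)
            else:  # efron
                t0 = ex[tied].sum()
                t1 = (x[tied] * ex[tied]).sum()
                t2 = (x[tied] ** 2 * ex[tied]).sum()
                grad += xs
                for k in range(d):
                    f = k / d
                    r0 = s0[i] - f * t0
                    r1 = s1[i] - f * t1
                    r2 = s2[i] - f * t2
                    mu = r1 / r0
                    ll -= math.log(r0)
                    grad -= mu
                    hess += r2 / r0 - mu * mu
        i = j
    return ll, grad, hess


def cox_fit(
    times: Sequence[float],
    event_flags: Sequence[int],
    group_indicator: Sequence[int],
    ties_method: Literal["breslow", "efron"] = "breslow",
) -> CoxFit:
    """Single-covariate Cox proportional-hazards fit (group = 1 for VATS).

    Damped Newton maximization of the log partial likelihood; convergence
    when |update| < 1e-9.  Breslow tie handling by default, Efron selectable.
    Standard error from the observed information.  A monotone partial
    likelihood (the estimate running away) raises :class:`ConvergenceError`.
    """
    t = np.asarray(times, float)
    e = np.asarray(event_flags, int)
    x = np.asarray(group_indicator, float)
    if e.sum() == 0:
        raise DegenerateInputError("cox_fit requires at least one event")
    if len(np.unique(x)) < 2:
        raise ConfigurationError("cox_fit requires both groups present")
    if ties_method not in ("breslow", "efron"):
        raise ConfigurationError(f"unknown ties_method {ties_method!r}")
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]

    beta = 0.0
    ll, grad, hess = _cox_ll_grad_hess(beta, x, t, e, ties_method)
    for _ in range(100):
        if hess <= 0:
            raise ConvergenceError("non-positive observed information in Cox fit")
        step = grad / hess
        # dampen: halve the step until the likelihood does not decrease
        for _ in range(30):
            new_beta = beta + step
            new = _cox_ll_grad_hess(new_beta, x, t, e, ties_method)
            if new[0] >= ll - 1e-12:
                break
            step /= 2.0
        beta, (ll, grad, hess) = new_beta, new
        if abs(beta) > 50:
            raise ConvergenceError(
                "monotone partial likelihood: log HR diverged (all events in one "
                "group before any in the other)"
            )
        if abs(step) < 1e-9:
            break
    else:
        raise ConvergenceError("Cox Newton iteration did not converge in 100 steps")
    se = 1.0 / math.sqrt(hess)
    z975 = 1.959963984540054
    z = beta / se
    return CoxFit(
        log_hr=beta,
        se=se,
        hr=math.exp(beta),
        ci95=(math.exp(beta - z975 * se), math.exp(beta + z975 * se)),
        ties_method=ties_method,
        p_value=float(2.0 * stats.norm.sf(abs(z))),
    )


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def rank_tests(sample_a, sample_b, paired: bool = False) -> RankTestResult:
    """Mann–Whitney U (unpaired) or Wilcoxon signed-rank (paired) comparison.

    Both use the normal approximation with tie correction; zero differences
    are dropped in the paired test, and an all-zero difference vector yields
    the degenerate result p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise EmptyInputError("rank tests require non-empty samples")
    if paired:
        if len(a) != len(b):
            raise ConfigurationError("paired test requires equal-length samples")
        d = a - b
        if np.all(d == 0):
            return RankTestResult(0.0, 1.0, degenerate=True)
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=False, method="approx")
        return RankTestResult(float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankTestResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# sample size


def sample_size_two_props(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    variant: Literal["pooled", "unpooled"] = "unpooled",
) -> int:
    """Per-group n for a two-sided two-independent-proportions comparison.

    pooled:   n = (z_{a/2} sqrt(2 p̄ q̄) + z_b sqrt(p1 q1 + p2 q2))² / (p1-p2)²
    unpooled: n = (z_{a/2} + z_b)² (p1 q1 + p2 q2) / (p1-p2)²
    """
    if not (0 < p2 < 1 and 0 < p1 < 1):
        raise ConfigurationError("proportions must lie in (0, 1)")
    if p1 == p2:
        raise ConfigurationError("p1 must differ from p2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ConfigurationError("alpha and power must lie in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    q1, q2 = 1 - p1, 1 - p2
    delta2 = (p1 - p2) ** 2
    if variant == "pooled":
        pbar = (p1 + p2) / 2
        n = (za * math.sqrt(2 * pbar * (1 - pbar)) + zb * math.sqrt(p1 * q1 + p2 * q2)) ** 2 / delta2
    elif variant == "unpooled":
        n = (za + zb) ** 2 * (p1 * q1 + p2 * q2) / delta2
    else:
        raise ConfigurationError(f"unknown variant {variant!r}")
    return math.ceil(n - 1e-9)


def inflate_sample_size(n: int, factor: float) -> int:
    """Attrition/matching-loss inflation: ceil(n * factor)."""
    if factor < 1:
        raise ConfigurationError("inflation factor must be >= 1")
    return math.ceil(n * factor - 1e-9)


def power_two_props(
    n: int, p1: float, p2: float, alpha: float = 0.05, variant: str = "unpooled"
) -> float:
    """Normal-approximation power of the two-proportion test at per-group n."""
    za = stats.norm.ppf(1 - alpha / 2)
    q1, q2 = 1 - p1, 1 - p2
    sd_alt = math.sqrt(p1 * q1 + p2 * q2)
    if variant == "pooled":
        pbar = (p1 + p2) / 2
        sd_null = math.sqrt(2 * pbar * (1 - pbar))
        z = (abs(p1 - p2) * math.sqrt(n) - za * sd_null) / sd_alt
    else:
        z = abs(p1 - p2) * math.sqrt(n) / sd_alt - za
    return float(stats.norm.cdf(z))
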