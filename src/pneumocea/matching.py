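"""Propensity-score estimation, greedy caliper matching and covariate
balance diagnostics.

The propensity score is the modeled probability of undergoing VATS given the
seven baseline covariates (age ≥45, sex, smoking, laterality, degree of lung
collapse, maximum bleb diameter, number of blebs).  Matching is 1:1 greedy
nearest-neighbor on the logit of the score without replacement, with a
caliper expressed either in absolute logit units or (default) as a multiple
of the standard deviation of the logit — 0.02 SD by default.  Balance is
reported as standardized mean differences (SMD), with SMD < 0.1
conventionally regarded as negligible imbalance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import (
    CollinearityError,
    ConfigurationError,
    ConvergenceError,
    DegenerateVarianceError,
    SeparationError,
)

#: design columns of the propensity model: indicator name -> (covariate, level)
DESIGN_LEVELS: list[tuple[str, str, str]] = [
    ("sex_male", "sex", "male"),
    ("age_ge45", "age_ge45", 1),
    ("smoker_yes", "smoker", "yes"),
    ("laterality_left", "laterality", "left"),
    ("collapse_gt50", "collapse_cat", "gt50"),
    ("bleb_diam_cm1_5", "bleb_diam_cat", "cm1_5"),
    ("bleb_diam_gt5cm", "bleb_diam_cat", "gt5cm"),
    ("bleb_count_n3_5", "bleb_count_cat", "n3_5"),
    ("bleb_count_gt5", "bleb_count_cat", "gt5"),
]

#: one-vs-rest indicator levels entering the balance report (reference levels
#: of multi-category covariates included, continuous age excluded)
BALANCE_LEVELS: list[tuple[str, str, str]] = [
    ("sex=male", "sex", "male"),
    ("age_ge45", "age_ge45", 1),
    ("smoker=yes", "smoker", "yes"),
    ("laterality=left", "laterality", "left"),
    ("collapse=gt50", "collapse_cat", "gt50"),
    ("bleb_diam=lt1cm", "bleb_diam_cat", "lt1cm"),
    ("bleb_diam=cm1_5", "bleb_diam_cat", "cm1_5"),
    ("bleb_diam=gt5cm", "bleb_diam_cat", "gt5cm"),
    ("bleb_count=n1_2", "bleb_count_cat", "n1_2"),
    ("bleb_count=n3_5", "bleb_count_cat", "n3_5"),
    ("bleb_count=gt5", "bleb_count_cat", "gt5"),
]


def design_matrix(cohort: pd.DataFrame, drop_constant: bool = True):
    """Dummy-coded design matrix (with intercept) for the propensity model.

    Constant indicator columns (a level absent or universal in the cohort)
    carry no information and are dropped, with their names recorded, so that
    reduced test cohorts remain full rank.
    """
    cols = {"intercept": np.ones(len(cohort))}
    dropped = []
    for name, cov, level in DESIGN_LEVELS:
        x = (cohort[cov] == level).astype(float).to_numpy()
        if drop_constant and (x.min() == x.max()):
            dropped.append(name)
            continue
        cols[name] = x
    X = pd.DataFrame(cols, index=cohort.index)
    return X, dropped


@dataclass
class PropensityFit:
    """Fitted propensity model with per-patient linear predictors (logits)."""

    coefficients: pd.Series
    linear_predictor: np.ndarray
    converged: bool
    n_iterations: int
    patient_ids: np.ndarray
    treated: np.ndarray  # boolean, True = vats
    dropped_columns: list = field(default_factory=list)

    @property
    def propensity(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor))

    @property
    def sd_logit(self) -> float:
        return float(np.std(self.linear_predictor, ddof=1))


def fit_propensity(cohort: pd.DataFrame) -> PropensityFit:
    """Logistic regression of treatment (vats=1) on the seven covariates.

    Newton–Raphson via statsmodels; convergence tolerance 1e-8 on the
    coefficient update, at most 100 iterations.  Fitted probabilities within
    1e-10 of 0 or 1 indicate (quasi-)complete separation and raise
    :class:`SeparationError`; a rank-deficient design raises
    :class:`CollinearityError`.
    """
    arms = set(cohort["arm"].unique())
    if arms != {"chest_tube", "vats"}:
        raise ConfigurationError(f"both arms required for propensity fit, got {sorted(arms)}")
    y = (cohort["arm"] == "vats").to_numpy(dtype=float)
    X, dropped = design_matrix(cohort)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise CollinearityError(
            f"design matrix rank {rank} < {X.shape[1]} columns: {list(X.columns)}"
        )
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise SeparationError(f"propensity fit failed, likely separation: {exc}") from exc
    eta = np.asarray(res.fittedvalues, dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    if np.any(p < 1e-10) or np.any(p > 1.0 - 1e-10):
        # name the covariate pattern driving the extreme fits
        worst = X.columns[np.argmax(np.abs(res.params.to_numpy()))]
        raise SeparationError(
            f"fitted propensities within 1e-10 of 0/1 — complete or quasi-complete "
            f"separation (largest coefficient on '{worst}')"
        )
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("propensity logistic regression did not converge")
    return PropensityFit(
        coefficients=res.params,
        linear_predictor=eta,
        converged=True,
        n_iterations=int(res.mle_retvals.get("iterations", 0)),
        patient_ids=cohort["patient_id"].to_numpy(),
        treated=(cohort["arm"] == "vats").to_numpy(),
        dropped_columns=dropped,
    )


@dataclass
class MatchResult:
    """1:1 matched pairs on the propensity logit."""

    pairs: list  # (treated_id, control_id, logit_distance)
    caliper_value: float  # effective caliper on the logit scale
    caliper_mode: str
    n_unmatched_treated: int
    n_unmatched_control: int

    def __post_init__(self):
        ids = [i for p in self.pairs for i in p[:2]]
        assert len(ids) == len(set(ids)), "an id appears in more than one pair"
        assert all(d <= self.caliper_value + 1e-12 for *_, d in self.pairs)

    def treated_ids(self) -> list:
        return [t for t, _, _ in self.pairs]

    def control_ids(self) -> list:
        return [c for _, c, _ in self.pairs]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["treated_id", "control_id", "logit_distance"])


def match_greedy(
    fit: PropensityFit,
    caliper: float = 0.02,
    caliper_mode: Literal["absolute", "sd_scaled"] = "sd_scaled",
    order_rule: Literal["descending", "data", "random"] = "random",
    seed: int = 0,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching on the propensity logit.

    Treated units are visited in the configured order; each takes the
    nearest still-unmatched control within the effective caliper
    (``caliper × SD(logit)`` in ``sd_scaled`` mode).  Ties between
    equidistant controls break to the lower control id.  Matching is without
    replacement and deterministic given ``(order_rule, seed)``.

    The default order is a seeded random permutation of the treated units:
    processing in propensity order makes each greedy mismatch drift in one
    direction along the logit axis and leaves systematic covariate
    imbalance, whereas a random order lets mismatches cancel.
    """
    if caliper <= 0:
        raise ConfigurationError("caliper must be positive")
    if not fit.converged:
        raise ConfigurationError("propensity fit must have converged before matching")
    eff = caliper * fit.sd_logit if caliper_mode == "sd_scaled" else caliper
    if caliper_mode not in ("absolute", "sd_scaled"):
        raise ConfigurationError(f"unknown caliper_mode {caliper_mode!r}")

    t_mask = fit.treated
    t_ids, t_logit = fit.patient_ids[t_mask], fit.linear_predictor[t_mask]
    c_ids, c_logit = fit.patient_ids[~t_mask], fit.linear_predictor[~t_mask]

    if order_rule == "descending":
        order = np.argsort(-t_logit, kind="stable")
    elif order_rule == "data":
        order = np.arange(len(t_ids))
    elif order_rule == "random":
        order = np.random.default_rng(seed).permutation(len(t_ids))
    else:
        raise ConfigurationError(f"unknown order_rule {order_rule!r}")

    available = np.ones(len(c_ids), dtype=bool)
    pairs = []
    for i in order:
        if not available.any():
            break
        d = np.abs(c_logit - t_logit[i])
        d[~available] = np.inf
        dmin = d.min()
        if dmin <= eff:
            cands = np.flatnonzero(d == dmin)
            j = cands[np.argmin(c_ids[cands])] if len(cands) > 1 else cands[0]
            pairs.append((t_ids[i], c_ids[j], float(dmin)))
            available[j] = False
    return MatchResult(
        pairs=pairs,
        caliper_value=float(eff),
        caliper_mode=caliper_mode,
        n_unmatched_treated=len(t_ids) - len(pairs),
        n_unmatched_control=len(c_ids) - len(pairs),
    )


def smd(values_a: Sequence[float], values_b: Sequence[float], kind: str = "continuous") -> float:
    """Standardized mean difference between two samples.

    continuous: ``|m_a - m_b| / sqrt((s²_a + s²_b)/2)`` with sample (ddof=1)
    variances; binary: ``|p_a - p_b| / sqrt((p_a q_a + p_b q_b)/2)``.
    Returns 0 when numerator and denominator are both 0; raises
    :class:`DegenerateVarianceError` when only the denominator is.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigurationError("smd requires non-empty groups")
    if kind == "binary":
        if not (np.isin(a, (0.0, 1.0)).all() and np.isin(b, (0.0, 1.0)).all()):
            raise ConfigurationError("binary smd requires 0/1 values")
        pa, pb = a.mean(), b.mean()
        num = abs(pa - pb)
        den = math.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
    elif kind == "continuous":
        num = abs(a.mean() - b.mean())
        va = a.var(ddof=1) if len(a) > 1 else 0.0
        vb = b.var(ddof=1) if len(b) > 1 else 0.0
        den = math.sqrt((va + vb) / 2.0)
    else:
        raise ConfigurationError(f"unknown smd kind {kind!r}")
    if den == 0.0:
        if num == 0.0:
            return 0.0
        raise DegenerateVarianceError("zero pooled variance with non-zero mean difference")
    return num / den


@dataclass
class BalanceReport:
    """Per-level and mean SMDs before and after matching.

    Post-match entries are NaN (undefined) when the match is empty; the mean
    SMD is the unweighted arithmetic mean over the reported one-vs-rest
    levels (metadata records the averaging set).
    """

    per_covariate_smd_pre: pd.Series
    per_covariate_smd_post: pd.Series
    mean_smd_pre: float
    mean_smd_post: float
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"smd_pre": self.per_covariate_smd_pre, "smd_post": self.per_covariate_smd_post}
        )
        df.index.name = "level"
        return df


def _level_smds(df_t: pd.DataFrame, df_c: pd.DataFrame) -> pd.Series:
    out = {}
    for name, cov, level in BALANCE_LEVELS:
        a = (df_t[cov] == level).astype(float).to_numpy()
        b = (df_c[cov] == level).astype(float).to_numpy()
        out[name] = smd(a, b, kind="binary")
    return pd.Series(out)


def balance_report(cohort: pd.DataFrame, fit: PropensityFit, match: MatchResult) -> BalanceReport:
    """SMD balance diagnostics before and after matching.

    Multi-category covariates are expanded to one-vs-rest indicators; the
    post-match columns are computed on matched records only.
    """
    t_all = cohort[cohort["arm"] == "vats"]
    c_all = cohort[cohort["arm"] == "chest_tube"]
    pre = _level_smds(t_all, c_all)
    if match.n_pairs == 0:
        post = pd.Series(np.nan, index=pre.index)
        mean_post = float("nan")
    else:
        t_m = cohort[cohort["patient_id"].isin(match.treated_ids())]
        c_m = cohort[cohort["patient_id"].isin(match.control_ids())]
        post = _level_smds(t_m, c_m)
        mean_post = float(post.mean())
    return BalanceReport(
        per_covariate_smd_pre=pre,
        per_covariate_smd_post=post,
        mean_smd_pre=float(pre.mean()),
        mean_smd_post=mean_post,
        n_pairs=match.n_pairs,
    )


def matched_cohort(cohort: pd.DataFrame, match: MatchResult) -> pd.DataFrame:
    """Subset of the cohort containing only matched patients."""
    keep = set(match.treated_ids()) | set(match.control_ids())
    return cohort[cohort["patient_id"].isin(keep)].copy()
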