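"""Probabilistic sensitivity analysis (PSA), cost-effectiveness plane and
acceptability curve, plus the deterministic one-way scenario grid.

Parameter uncertainty is propagated by Monte Carlo: utilities and
probabilities are drawn from beta distributions (method-of-moments from mean
and SE, or direct shape parameters), incremental cost from a gamma or
log-normal law.  Each iteration recomputes the incremental cost and QALY
gain through the QALY accrual model; the decision rule is net monetary
benefit, NMB = lambda * dQALY - dCost > 0 (ties count as not
cost-effective).  Each parameter draws from its own named substream, so
adding a parameter does not perturb the others' draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cea import DiscountSpec, EpisodeSpec, UtilitySet, qaly_trajectory
from .exceptions import ConfigurationError
from .outcomes import TwoByTwo

DEFAULT_WTP_GRID = tuple(
    sorted(set(np.arange(0, 400_001, 10_000).tolist()) | {95_749, 287_247})
)


@dataclass(frozen=True)
class ParameterSpec:
    """One PSA parameter distribution.

    kind: 'beta' (mean+se), 'beta_ab' (alpha/beta shapes), 'gamma' (mean+se),
    'lognormal' (mean+se) or 'fixed'.  se=0 with a moment-based kind is a
    degenerate spec: every draw equals the mean.
    """

    kind: str
    mean: float = math.nan
    se: float = math.nan
    alpha: float = math.nan
    beta: float = math.nan

    def validate(self, name: str) -> None:
        if self.kind == "fixed":
            return
        if self.kind == "beta_ab":
            if not (self.alpha > 0 and self.beta > 0):
                raise ConfigurationError(f"parameter '{name}': beta shapes must be positive")
            return
        if self.kind not in ("beta", "gamma", "lognormal"):
            raise ConfigurationError(f"parameter '{name}': unknown kind {self.kind!r}")
        if not math.isfinite(self.mean):
            raise ConfigurationError(f"parameter '{name}': mean required")
        if self.se < 0:
            raise ConfigurationError(f"parameter '{name}': se must be >= 0")
        if self.kind == "beta":
            if not 0.0 < self.mean < 1.0:
                raise ConfigurationError(f"parameter '{name}': beta mean must lie in (0, 1)")
            if self.se > 0 and self.se**2 >= self.mean * (1.0 - self.mean):
                raise ConfigurationError(
                    f"parameter '{name}': infeasible beta moments "
                    f"(se² = {self.se**2:.4g} >= m(1-m) = {self.mean * (1 - self.mean):.4g})"
                )
        elif self.mean <= 0:
            raise ConfigurationError(f"parameter '{name}': mean must be positive")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        m, s = self.mean, self.se
        if self.kind == "fixed" or (self.kind != "beta_ab" and s == 0.0):
            return np.full(n, m)
        if self.kind == "beta_ab":
            return rng.beta(self.alpha, self.beta, size=n)
        if self.kind == "beta":
            v = m * (1.0 - m) / s**2 - 1.0
            return rng.beta(m * v, (1.0 - m) * v, size=n)
        if self.kind == "gamma":
            shape = m**2 / s**2
            return rng.gamma(shape, s**2 / m, size=n)
        # lognormal, moment-matched
        sigma2 = math.log1p(s**2 / m**2)
        return rng.lognormal(math.log(m) - sigma2 / 2.0, math.sqrt(sigma2), size=n)


@dataclass
class PSAConfig:
    n_iterations: int = 10_000
    seed: int = 0
    distributions: dict = field(default_factory=dict)
    wtp_grid: tuple = DEFAULT_WTP_GRID

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        grid = np.asarray(self.wtp_grid, dtype=float)
        if grid.size == 0:
            raise ConfigurationError("wtp_grid must be non-empty")
        if np.any(np.diff(grid) <= 0):
            raise ConfigurationError("wtp_grid must be strictly ascending")
        for name, spec in self.distributions.items():
            spec.validate(name)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent of every other parameter's draws."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def draw_parameter_matrix(config: PSAConfig) -> pd.DataFrame:
    """All iterations' draws, one column per parameter (reproducible)."""
    config.validate()
    cols = {
        name: spec.draw(_substream(config.seed, name), config.n_iterations)
        for name, spec in config.distributions.items()
    }
    return pd.DataFrame(cols)


def draw_parameters(config: PSAConfig, iteration: int) -> dict:
    """Parameter set for one iteration; depends only on (seed, iteration)."""
    if not 0 <= iteration < config.n_iterations:
        raise ConfigurationError("iteration out of range")
    config.validate()
    return {
        name: float(spec.draw(_substream(config.seed, name), config.n_iterations)[iteration])
        for name, spec in config.distributions.items()
    }


@dataclass(frozen=True)
class CEABaseInputs:
    """Base-case decision-model inputs for the matched cohort."""

    n_pairs: int = 33
    two_by_two: TwoByTwo = TwoByTwo(4, 33, 16, 33)
    delta_cost_per_patient: float = 17_813.0
    utilities: UtilitySet = UtilitySet()
    episodes: EpisodeSpec = EpisodeSpec()
    discount: DiscountSpec = DiscountSpec()
    horizon_months: float = 60.0
    #: representative recurrence time for expectation-based QALY accrual
    t_recurrence_months: float = 15.0
    gdp_per_capita: float = 95_749.0


def default_distributions(base: CEABaseInputs, cost_se_frac: float = 0.2, utility_se_frac: float = 0.1) -> dict:
    """Standard PSA parameterization: utilities beta (SE = 10% of mean),
    incremental cost gamma (SE = 20% of mean), recurrence probabilities beta
    with shapes (events + 1, non-events + 1) per arm."""
    t = base.two_by_two
    return {
        "u_pneumothorax": ParameterSpec(
            "beta", mean=base.utilities.u_pneumothorax, se=utility_se_frac * base.utilities.u_pneumothorax
        ),
        "u_post_recovery": ParameterSpec(
            "beta", mean=base.utilities.u_post_recovery, se=utility_se_frac * base.utilities.u_post_recovery
        ),
        "p_rec_treated": ParameterSpec(
            "beta_ab", alpha=t.events_treated + 1, beta=t.n_treated - t.events_treated + 1
        ),
        "p_rec_control": ParameterSpec(
            "beta_ab", alpha=t.events_control + 1, beta=t.n_control - t.events_control + 1
        ),
        "delta_cost_per_patient": ParameterSpec(
            "gamma", mean=base.delta_cost_per_patient, se=cost_se_frac * base.delta_cost_per_patient
        ),
    }


def _expected_delta_qaly_per_patient(
    p_treated: float,
    p_control: float,
    utilities: UtilitySet,
    episodes: EpisodeSpec,
    discount: DiscountSpec,
    horizon_months: float,
    t_recurrence_months: float,
) -> float:
    q_rec = qaly_trajectory(
        True, t_recurrence_months, utilities, episodes, discount, horizon_months
    ).qaly
    q_norec = qaly_trajectory(False, None, utilities, episodes, discount, horizon_months).qaly
    return (p_control - p_treated) * (q_norec - q_rec)


def base_case_deltas(base: CEABaseInputs) -> tuple[float, float]:
    """(cohort ΔCost, cohort ΔQALY) at the point estimates."""
    t = base.two_by_two
    dq_pp = _expected_delta_qaly_per_patient(
        t.events_treated / t.n_treated,
        t.events_control / t.n_control,
        base.utilities,
        base.episodes,
        base.discount,
        base.horizon_months,
        base.t_recurrence_months,
    )
    return base.delta_cost_per_patient * base.n_pairs, dq_pp * base.n_pairs


@dataclass
class PSAResult:
    draws: pd.DataFrame  # columns delta_cost, delta_qaly (cohort scale)
    quadrant_counts: dict
    ceac: np.ndarray
    wtp_grid: np.ndarray
    prob_ce_at: dict
    n_faulted: int = 0

    @property
    def ne_fraction(self) -> float:
        return self.quadrant_counts["NE"] / len(self.draws)


def ceac_curve(delta_cost: np.ndarray, delta_qaly: np.ndarray, wtp_grid) -> np.ndarray:
    """P(cost-effective) over the WTP grid under the NMB rule (ties → not CE)."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ConfigurationError("wtp_grid must be non-empty")
    return np.array([np.mean(lam * delta_qaly - delta_cost > 0) for lam in grid])


def run_psa(base: CEABaseInputs, config: PSAConfig | None = None) -> PSAResult:
    """Monte Carlo PSA: recompute (ΔCost, ΔQALY) per iteration through the
    QALY accrual model with drawn parameters.

    Deterministic given the config seed.  Non-finite iterations are excluded
    from the CEAC and counted in ``n_faulted``."""
    if config is None:
        config = PSAConfig()
    if not config.distributions:
        config = replace_distributions(config, default_distributions(base))
    config.validate()
    draws = draw_parameter_matrix(config)
    n = config.n_iterations

    u_pn = draws.get("u_pneumothorax", pd.Series(np.full(n, base.utilities.u_pneumothorax)))
    u_pr = draws.get("u_post_recovery", pd.Series(np.full(n, base.utilities.u_post_recovery)))
    p_t = draws.get(
        "p_rec_treated",
        pd.Series(np.full(n, base.two_by_two.events_treated / base.two_by_two.n_treated)),
    )
    p_c = draws.get(
        "p_rec_control",
        pd.Series(np.full(n, base.two_by_two.events_control / base.two_by_two.n_control)),
    )
    dc_pp = draws.get("delta_cost_per_patient", pd.Series(np.full(n, base.delta_cost_per_patient)))

    dq = np.empty(n)
    for i in range(n):
        util = UtilitySet(
            u_stable=base.utilities.u_stable,
            u_pneumothorax=float(np.clip(u_pn.iloc[i], 0.0, 1.0)),
            u_post_recovery=float(np.clip(u_pr.iloc[i], 0.0, 1.0)),
        )
        dq[i] = (
            _expected_delta_qaly_per_patient(
                float(p_t.iloc[i]),
                float(p_c.iloc[i]),
                util,
                base.episodes,
                base.discount,
                base.horizon_months,
                base.t_recurrence_months,
            )
            * base.n_pairs
        )
    dc = dc_pp.to_numpy(dtype=float) * base.n_pairs

    finite = np.isfinite(dc) & np.isfinite(dq)
    n_faulted = int(n - finite.sum())
    dcv, dqv = dc[finite], dq[finite]
    quadrants = {
        "NE": int(np.sum((dqv > 0) & (dcv > 0))),
        "NW": int(np.sum((dqv <= 0) & (dcv > 0))),
        "SE": int(np.sum((dqv > 0) & (dcv <= 0))),
        "SW": int(np.sum((dqv <= 0) & (dcv <= 0))),
    }
    grid = np.asarray(config.wtp_grid, dtype=float)
    curve = ceac_curve(dcv, dqv, grid)
    prob_at = {
        "1x_gdp": float(np.mean(base.gdp_per_capita * dqv - dcv > 0)),
        "3x_gdp": float(np.mean(3.0 * base.gdp_per_capita * dqv - dcv > 0)),
    }
    return PSAResult(
        draws=pd.DataFrame({"delta_cost": dcv, "delta_qaly": dqv}),
        quadrant_counts=quadrants,
        ceac=curve,
        wtp_grid=grid,
        prob_ce_at=prob_at,
        n_faulted=n_faulted,
    )


def replace_distributions(config: PSAConfig, distributions: dict) -> PSAConfig:
    return PSAConfig(
        n_iterations=config.n_iterations,
        seed=config.seed,
        distributions=distributions,
        wtp_grid=config.wtp_grid,
    )


# ---------------------------------------------------------------------------
# one-way deterministic scenarios


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    overrides: dict = field(default_factory=dict)


_VALID_OVERRIDES = {
    "u_pneumothorax",
    "u_post_recovery",
    "d_recurrence_days",
    "cost_multiplier",
    "annual_rate",
}


def _apply_overrides(base: CEABaseInputs, overrides: dict) -> CEABaseInputs:
    unknown = set(overrides) - _VALID_OVERRIDES
    if unknown:
        raise ConfigurationError(f"unknown scenario override keys: {sorted(unknown)}")
    utilities = base.utilities
    if "u_pneumothorax" in overrides or "u_post_recovery" in overrides:
        utilities = UtilitySet(
            u_stable=utilities.u_stable,
            u_pneumothorax=overrides.get("u_pneumothorax", utilities.u_pneumothorax),
            u_post_recovery=overrides.get("u_post_recovery", utilities.u_post_recovery),
        )
    episodes = base.episodes
    if "d_recurrence_days" in overrides:
        episodes = EpisodeSpec(
            d_recurrence_days=overrides["d_recurrence_days"],
            d_initial_days=episodes.d_initial_days,
        )
    discount = base.discount
    if "annual_rate" in overrides:
        discount = DiscountSpec(annual_rate=overrides["annual_rate"], method=discount.method)
    dc = base.delta_cost_per_patient * overrides.get("cost_multiplier", 1.0)
    return replace(
        base,
        utilities=utilities,
        episodes=episodes,
        discount=discount,
        delta_cost_per_patient=dc,
    )


def default_scenarios() -> list[ScenarioSpec]:
    """The standard one-way grid: utility, episode-duration, cost and
    discount-rate variations around the base case."""
    return [
        ScenarioSpec("base_case", {}),
        ScenarioSpec("u_pneumothorax_0.5", {"u_pneumothorax": 0.5}),
        ScenarioSpec("u_pneumothorax_0.8", {"u_pneumothorax": 0.8}),
        ScenarioSpec("recurrence_7d", {"d_recurrence_days": 7.0}),
        ScenarioSpec("recurrence_21d", {"d_recurrence_days": 21.0}),
        ScenarioSpec("cost_plus_20pct", {"cost_multiplier": 1.2}),
        ScenarioSpec("cost_minus_20pct", {"cost_multiplier": 0.8}),
        ScenarioSpec("discount_0pct", {"annual_rate": 0.0}),
        ScenarioSpec("discount_3pct", {"annual_rate": 0.03}),
        ScenarioSpec("discount_6pct", {"annual_rate": 0.06}),
    ]


def one_way_scenarios(
    base: CEABaseInputs,
    scenarios: list[ScenarioSpec] | None = None,
    psa_config: PSAConfig | None = None,
) -> pd.DataFrame:
    """Deterministic scenario grid: ΔCost, ΔQALY, ICER per scenario, plus the
    probability of cost-effectiveness at 3x GDP from a PSA re-run with the
    overridden parameters held fixed."""
    if scenarios is None:
        scenarios = default_scenarios()
    if psa_config is None:
        psa_config = PSAConfig(n_iterations=2_000)
    rows = []
    for sc in scenarios:
        b = _apply_overrides(base, sc.overrides)
        dc, dq = base_case_deltas(b)
        icer = dc / dq if dq != 0 else math.nan
        dists = default_distributions(b)
        # hold the varied parameters fixed at their scenario values
        for key in sc.overrides:
            if key in ("u_pneumothorax", "u_post_recovery"):
                dists[key] = ParameterSpec("fixed", mean=getattr(b.utilities, key))
            elif key == "cost_multiplier":
                dists["delta_cost_per_patient"] = ParameterSpec(
                    "fixed", mean=b.delta_cost_per_patient
                )
        res = run_psa(b, replace_distributions(psa_config, dists))
        rows.append(
            {
                "scenario": sc.name,
                "delta_cost_cny": dc,
                "delta_qaly": dq,
                "icer_per_qaly_cny": icer,
                "ce_probability_3x_gdp": res.prob_ce_at["3x_gdp"],
            }
        )
    return pd.DataFrame(rows)
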