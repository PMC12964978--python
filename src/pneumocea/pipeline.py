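"""End-to-end pipeline: cohort (simulated or CSV) → propensity matching →
recurrence outcomes → cost-effectiveness → sensitivity analyses, written as
a reproducible artifact bundle of CSV report files plus a run manifest.

A single run seed fans out to per-stage substreams (stage-name keyed), so
each stage is individually reproducible and adding a stage does not perturb
earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cea, cohort, matching, outcomes, psa
from .exceptions import ConfigurationError

log = logging.getLogger("pneumocea")


def stage_seed(seed: int, stage: str) -> int:
    """Derived per-stage seed (stable, < 2^31)."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31)
    )


@dataclass
class RunConfig:
    mode: str = "simulate"  # or "csv"
    csv_path: str | None = None
    seed: int = 0
    n_per_arm: int = 500
    confounding_multiplier: float = 1.0
    caliper: float = 0.02
    caliper_mode: str = "sd_scaled"
    order_rule: str = "random"
    utilities: cea.UtilitySet = field(default_factory=cea.UtilitySet)
    episodes: cea.EpisodeSpec = field(default_factory=cea.EpisodeSpec)
    discount: cea.DiscountSpec = field(default_factory=cea.DiscountSpec)
    gdp_per_capita: float = cea.GDP_PER_CAPITA_CNY
    psa_iterations: int = 10_000
    scenario_psa_iterations: int = 2_000
    allow_extra_columns: bool = False

    def validate(self) -> None:
        if self.mode not in ("simulate", "csv"):
            raise ConfigurationError(f"unknown input mode {self.mode!r}")
        if self.mode == "csv" and not self.csv_path:
            raise ConfigurationError("csv mode requires csv_path")
        if self.mode == "simulate" and self.csv_path:
            raise ConfigurationError("exactly one input mode: simulate does not take csv_path")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("utilities", cea.UtilitySet), ("episodes", cea.EpisodeSpec), ("discount", cea.DiscountSpec)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def canonical_json(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return {k: getattr(o, k) for k in o.__dataclass_fields__}
            raise TypeError(type(o))

        return json.dumps(self.__dict__, sort_keys=True, default=default)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the artifact bundle; returns the manifest.

    Bundle: cohort.csv (+ generating config, simulate mode), pairs.csv,
    balance.csv, effects.csv, km_curve.csv, cea_table.csv, scenarios.csv,
    ce_plane.csv, ceac.csv, manifest.json.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    files = []

    # --- cohort -----------------------------------------------------------
    if config.mode == "simulate":
        ccfg = cohort.CohortConfig(
            n_per_arm=config.n_per_arm,
            seed=stage_seed(config.seed, "cohort"),
            confounding_multiplier=config.confounding_multiplier,
        )
        df = cohort.generate_cohort(ccfg)
        cohort.write_cohort(df, out / "cohort.csv", ccfg)
        files += ["cohort.csv", "cohort.csv.config.json"]
    else:
        df = cohort.read_cohort(config.csv_path, allow_extra=config.allow_extra_columns)
    log.info("cohort stage: %d records (%.2fs)", len(df), time.time() - t0)

    # --- matching ---------------------------------------------------------
    t1 = time.time()
    fit = matching.fit_propensity(df)
    match = matching.match_greedy(
        fit,
        caliper=config.caliper,
        caliper_mode=config.caliper_mode,
        order_rule=config.order_rule,
        seed=stage_seed(config.seed, "matching"),
    )
    balance = matching.balance_report(df, fit, match)
    _write_csv(match.to_frame(), out / "pairs.csv")
    bal = balance.to_frame().reset_index()
    bal.loc[len(bal)] = ["mean", balance.mean_smd_pre, balance.mean_smd_post]
    _write_csv(bal, out / "balance.csv")
    files += ["pairs.csv", "balance.csv"]
    log.info(
        "matching stage: %d pairs, mean SMD %.3f -> %.3f (%.2fs)",
        match.n_pairs,
        balance.mean_smd_pre,
        balance.mean_smd_post,
        time.time() - t1,
    )
    mdf = matching.matched_cohort(df, match)

    # --- outcomes ---------------------------------------------------------
    t2 = time.time()
    arms = {arm: sub for arm, sub in mdf.groupby("arm")}
    tt = outcomes.TwoByTwo(
        int(arms["vats"]["recurrence"].sum()),
        len(arms["vats"]),
        int(arms["chest_tube"]["recurrence"].sum()),
        len(arms["chest_tube"]),
    )
    eff = outcomes.effect_summary(tt)
    # matched-pair discordance from the pair list
    rec = df.set_index("patient_id")["recurrence"]
    b = sum(
        1 for t_id, c_id, _ in match.pairs if rec[t_id] == 1 and rec[c_id] == 0
    )
    c = sum(
        1 for t_id, c_id, _ in match.pairs if rec[t_id] == 0 and rec[c_id] == 1
    )
    mcn = outcomes.mcnemar_test(b, c, mode="exact")
    lr_stat, lr_p = outcomes.logrank_test(
        arms["vats"]["time_months"],
        arms["vats"]["recurrence"],
        arms["chest_tube"]["time_months"],
        arms["chest_tube"]["recurrence"],
    )
    cox = outcomes.cox_fit(
        mdf["time_months"], mdf["recurrence"], (mdf["arm"] == "vats").astype(int)
    )
    pres = eff.as_presentation()
    effrows = [
        ("n_pairs", match.n_pairs),
        ("recurrence_rate_vats_pct", pres["rate_treated_pct"]),
        ("recurrence_rate_chest_tube_pct", pres["rate_control_pct"]),
        ("arr_pct", pres["arr_pct"]),
        ("nnt", pres["nnt"]),
        ("rr", pres["rr"]),
        ("mcnemar_exact_p", mcn.p_value),
        ("logrank_chi2", lr_stat),
        ("logrank_p", lr_p),
        ("cox_hr", cox.hr),
        ("cox_hr_ci_low", cox.ci95[0]),
        ("cox_hr_ci_high", cox.ci95[1]),
        ("cox_p", cox.p_value),
    ]
    _write_csv(pd.DataFrame(effrows, columns=["metric", "value"]), out / "effects.csv")
    km_frames = []
    for arm, sub in arms.items():
        sf = outcomes.km_fit(sub["time_months"], sub["recurrence"])
        f = sf.to_frame()
        f.insert(0, "arm", arm)
        km_frames.append(f)
    _write_csv(pd.concat(km_frames, ignore_index=True), out / "km_curve.csv")
    files += ["effects.csv", "km_curve.csv"]
    log.info("outcomes stage: ARR %.1f%%, HR %.3f (%.2fs)", pres["arr_pct"], cox.hr, time.time() - t2)

    # --- CEA --------------------------------------------------------------
    t3 = time.time()
    delta_cost_pp = float(
        arms["vats"]["total_cost_cny"].mean() - arms["chest_tube"]["total_cost_cny"].mean()
    )
    effects_by_arm = cea.cohort_effects(
        mdf, config.utilities, config.episodes, config.discount
    )
    delta_qaly = effects_by_arm["vats"]["qaly"] - effects_by_arm["chest_tube"]["qaly"]
    result = cea.compute_cea(
        delta_cost_pp, match.n_pairs, tt, delta_qaly, gdp_per_capita=config.gdp_per_capita
    )
    _write_csv(result.to_frame(), out / "cea_table.csv")
    files += ["cea_table.csv"]
    log.info("cea stage: ICER %.0f CNY/QALY (%.2fs)", result.icer_per_qaly or float("nan"), time.time() - t3)

    # --- PSA + scenarios --------------------------------------------------
    t4 = time.time()
    base = psa.CEABaseInputs(
        n_pairs=match.n_pairs,
        two_by_two=tt,
        delta_cost_per_patient=delta_cost_pp,
        utilities=config.utilities,
        episodes=config.episodes,
        discount=config.discount,
        gdp_per_capita=config.gdp_per_capita,
    )
    pcfg = psa.PSAConfig(n_iterations=config.psa_iterations, seed=stage_seed(config.seed, "psa"))
    pres_psa = psa.run_psa(base, pcfg)
    plane = pres_psa.draws.copy()
    plane.insert(0, "iteration", np.arange(len(plane)))
    quad = np.where(
        (plane["delta_qaly"] > 0) & (plane["delta_cost"] > 0),
        "NE",
        np.where(
            plane["delta_cost"] > 0, "NW", np.where(plane["delta_qaly"] > 0, "SE", "SW")
        ),
    )
    plane["quadrant"] = quad
    _write_csv(plane, out / "ce_plane.csv")
    _write_csv(
        pd.DataFrame({"wtp_cny_per_qaly": pres_psa.wtp_grid, "probability": pres_psa.ceac}),
        out / "ceac.csv",
    )
    scen_cfg = psa.PSAConfig(
        n_iterations=config.scenario_psa_iterations, seed=stage_seed(config.seed, "scenarios")
    )
    scen = psa.one_way_scenarios(base, psa_config=scen_cfg)
    _write_csv(scen, out / "scenarios.csv")
    files += ["ce_plane.csv", "ceac.csv", "scenarios.csv"]
    log.info(
        "psa stage: NE fraction %.3f, P(CE|3xGDP) %.3f (%.2fs)",
        pres_psa.ne_fraction,
        pres_psa.prob_ce_at["3x_gdp"],
        time.time() - t4,
    )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        "files": sorted(files),
        "n_pairs": match.n_pairs,
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
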