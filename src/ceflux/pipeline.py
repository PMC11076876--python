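"""Pipeline configuration, orchestration and report generation.

A single YAML (or dict) configuration drives the full chain: obtain a time
series (read a tidy CSV, or simulate a named preset), compute per-interval
conversion rates, derive metrics, flag steady-state windows, average phase
tails and render summary tables.  Outputs are plain CSV/JSON with units in
the column names; identical config + seed gives byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compounds import NormalConditions, default_registry
from .metrics import compute_metrics, phase_average
from .rates import CO2Equilibrium, compute_rates, rates_frame
from .simulate import STUDY_FEED, build_preset
from .steady import SteadyStateCriteria, steady_flags
from .timeseries import (
    FeedDefinition,
    PhaseDefinition,
    ReactorTimeSeries,
    assign_phases,
    read_timeseries,
)

__all__ = ["PipelineConfig", "run_pipeline", "render_summary_tables"]

log = logging.getLogger("ceflux")

_KNOWN_KEYS = {
    "output_dir",
    "seed",
    "input",
    "reactor",
    "feed",
    "phases",
    "eeo_strategy",
    "steady_state",
    "phase_average_n_last",
    "aliases",
}


class ConfigError(ValueError):
    """Configuration failed schema validation; message names the field."""


@dataclass
class PipelineConfig:
    """Validated pipeline settings; see ``from_dict`` for the schema."""

    output_dir: Path
    seed: int = 0
    input_csv: Path | None = None
    preset: str | None = None
    noise_cv: float = 0.0
    volume_l: float = 1.0
    equilibrium: CO2Equilibrium = field(default_factory=CO2Equilibrium)
    conditions: NormalConditions = field(default_factory=NormalConditions)
    default_base_molarity: float = 2.0
    feed: FeedDefinition = field(default_factory=lambda: STUDY_FEED)
    phases: list[PhaseDefinition] = field(default_factory=list)
    eeo_strategy: str = "acceptor_routing"
    steady: SteadyStateCriteria = field(default_factory=SteadyStateCriteria)
    phase_average_n_last: int = 5
    aliases: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ConfigError("missing required field: output_dir")
        inp = raw.get("input", {})
        if not isinstance(inp, dict):
            raise ConfigError("field 'input' must be a mapping")
        if ("timeseries_csv" in inp) == ("preset" in inp):
            raise ConfigError(
                "field 'input' needs exactly one of: timeseries_csv, preset"
            )
        reactor = raw.get("reactor", {})
        eq = CO2Equilibrium(
            kh=float(reactor.get("kh", 0.026)),
            pka1=float(reactor.get("pka1", 6.31)),
            speciation=bool(reactor.get("speciation", True)),
        )
        cond = NormalConditions(
            temperature_K=float(reactor.get("normal_temperature_K", 273.15)),
            pressure_kPa=float(reactor.get("normal_pressure_kPa", 101.325)),
        )
        feed_raw = raw.get("feed")
        if feed_raw is None:
            feed = STUDY_FEED
        else:
            if "composition" not in feed_raw:
                raise ConfigError("field 'feed' needs a 'composition' mapping")
            feed = FeedDefinition(
                composition={k: float(v) for k, v in feed_raw["composition"].items()},
                yeast_extract_g_l=float(feed_raw.get("yeast_extract_g_l", 0.0)),
            )
        phases = []
        for p in raw.get("phases", []):
            try:
                phases.append(
                    PhaseDefinition(
                        name=str(p["name"]),
                        start_day=float(p["start_day"]),
                        end_day=float(p["end_day"]),
                        co2_load=float(p.get("co2_load", 0.0)),
                        n2_load=float(p.get("n2_load", 0.0)),
                    )
                )
            except KeyError as err:
                raise ConfigError(f"phase entry missing field {err}") from err
        ss_raw = raw.get("steady_state", {})
        steady = SteadyStateCriteria(
            window_span=float(ss_raw.get("window_span", 3.0)),
            max_cv=float(ss_raw.get("max_cv", 0.10)),
            tracked=tuple(ss_raw.get("tracked", SteadyStateCriteria().tracked)),
        )
        strategy = raw.get("eeo_strategy", "acceptor_routing")
        if strategy not in ("acceptor_routing", "from_acetate"):
            raise ConfigError(f"eeo_strategy: unknown strategy {strategy!r}")
        return cls(
            output_dir=Path(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            input_csv=Path(inp["timeseries_csv"]) if "timeseries_csv" in inp else None,
            preset=inp.get("preset"),
            noise_cv=float(inp.get("noise_cv", 0.0)),
            volume_l=float(reactor.get("volume_l", 1.0)),
            equilibrium=eq,
            conditions=cond,
            default_base_molarity=float(reactor.get("default_base_molarity", 2.0)),
            feed=feed,
            phases=phases,
            eeo_strategy=strategy,
            steady=steady,
            phase_average_n_last=int(raw.get("phase_average_n_last", 5)),
            aliases=dict(raw.get("aliases", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(raw)


def _load_series(cfg: PipelineConfig) -> ReactorTimeSeries:
    registry = default_registry()
    if cfg.preset is not None:
        ts, truth = build_preset(cfg.preset, seed=cfg.seed, noise_cv=cfg.noise_cv)
        cfg.output_dir.mkdir(parents=True, exist_ok=True)
        truth.to_json(cfg.output_dir / "ground_truth.json")
        return ts
    ts = read_timeseries(
        cfg.input_csv,
        registry,
        aliases=cfg.aliases,
        default_base_molarity=cfg.default_base_molarity,
    )
    if cfg.phases:
        ts = assign_phases(ts, cfg.phases)
    return ts


def render_summary_tables(
    metrics: pd.DataFrame, reactor_id: str, n_last: int = 5
) -> pd.DataFrame:
    """One row per reactor x phase: end-of-phase averaged performance.

    Mirrors the end-of-phase reporting convention: each phase is summarized
    by the mean of its last ``n_last`` interval records (selectivities,
    balances, EEO, HRT, CO2/H2 terms).  Empty input yields an empty table
    with stable headers.
    """
    base_cols = ["reactor_id", "phase", "n_records"]
    if metrics.empty:
        return pd.DataFrame(columns=base_cols)
    rows = []
    for phase in metrics["phase"].dropna().unique():
        avg = phase_average(metrics, phase, n_last)
        row = {"reactor_id": reactor_id}
        row.update(avg.to_dict())
        rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = base_cols + sorted(c for c in frame.columns if c not in base_cols)
    return frame[[c for c in ordered if c in frame.columns]]


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict[str, Path]:
    """Execute all stages and write the report bundle; returns output paths."""
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_dict(config)
    else:
        cfg = config
    registry = default_registry()
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("stage=load")
        ts = _load_series(cfg)
        log.info("loaded %d samples for %s", len(ts.samples), ts.reactor_id)

        log.info("stage=rates")
        records = compute_rates(
            ts,
            cfg.feed,
            registry,
            equilibrium=cfg.equilibrium,
            conditions=cfg.conditions,
        )
        rframe = rates_frame(records)

        log.info("stage=metrics")
        mframe = compute_metrics(
            ts, records, cfg.feed, registry, eeo_strategy=cfg.eeo_strategy
        )

        log.info("stage=steady_state")
        flags = steady_flags(ts, cfg.steady)
        # a rate interval is steady when both its endpoint samples are
        by_time = {s.time: f for s, f in zip(ts.samples, flags)}
        mframe["steady"] = [
            bool(by_time[r.t_prev] and by_time[r.t]) for r in records
        ]

        log.info("stage=summary")
        summary = render_summary_tables(
            mframe, ts.reactor_id, n_last=cfg.phase_average_n_last
        )
        sel_cols = [c for c in summary.columns if c.startswith("sel_")]
        selectivity = summary[["reactor_id", "phase"] + sel_cols] if not summary.empty else summary

        paths = {
            "rates": out / "rates.csv",
            "metrics": out / "metrics.csv",
            "phase_summary_csv": out / "phase_summary.csv",
            "phase_summary_json": out / "phase_summary.json",
            "selectivity": out / "selectivity_summary.csv",
            "config": out / "effective_config.yaml",
        }
        rframe.to_csv(paths["rates"], index=False, float_format="%.10g")
        mframe.to_csv(paths["metrics"], index=False, float_format="%.10g")
        summary.to_csv(paths["phase_summary_csv"], index=False, float_format="%.10g")
        selectivity.to_csv(paths["selectivity"], index=False, float_format="%.10g")
        with open(paths["phase_summary_json"], "w") as fh:
            json.dump(
                summary.replace({np.nan: None}).to_dict(orient="records"),
                fh,
                indent=1,
                sort_keys=True,
            )
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(_effective_config(cfg), fh, sort_keys=True)
        log.info("done; outputs in %s", out)
        return paths
    finally:
        log.removeHandler(handler)
        handler.close()


def _effective_config(cfg: PipelineConfig) -> dict:
    return {
        "output_dir": str(cfg.output_dir),
        "seed": cfg.seed,
        "input": (
            {"preset": cfg.preset, "noise_cv": cfg.noise_cv}
            if cfg.preset
            else {"timeseries_csv": str(cfg.input_csv)}
        ),
        "reactor": {
            "volume_l": cfg.volume_l,
            "kh": cfg.equilibrium.kh,
            "pka1": cfg.equilibrium.pka1,
            "speciation": cfg.equilibrium.speciation,
            "normal_temperature_K": cfg.conditions.temperature_K,
            "normal_pressure_kPa": cfg.conditions.pressure_kPa,
            "default_base_molarity": cfg.default_base_molarity,
        },
        "feed": {
            "composition": dict(cfg.feed.composition),
            "yeast_extract_g_l": cfg.feed.yeast_extract_g_l,
        },
        "phases": [
            {
                "name": p.name,
                "start_day": p.start_day,
                "end_day": p.end_day,
                "co2_load": p.co2_load,
                "n2_load": p.n2_load,
            }
            for p in cfg.phases
        ],
        "eeo_strategy": cfg.eeo_strategy,
        "steady_state": {
            "window_span": cfg.steady.window_span,
            "max_cv": cfg.steady.max_cv,
            "tracked": list(cfg.steady.tracked),
        },
        "phase_average_n_last": cfg.phase_average_n_last,
    }
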