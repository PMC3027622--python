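"""End-to-end orchestration: simulate / ingest -> estimate -> UD -> habitat.

`RunConfig` collects every knob of a run and round-trips through YAML or
JSON; `run_pipeline` executes the requested stages deterministically
(single-threaded, seeded) and writes a JSON report in which every field is
traceable to a module output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from . import trajectory as traj
from .api import BRBDensity
from .habitat import habitat_preferences
from .raster import HabitatMap
from .simulate import WalkParams, gps_subsample, simulate_walk
from .ud import export_ud

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (units: m, min, m^2/min)."""

    track: str | None = None
    columns: dict | None = None
    habitat: str | None = None
    legend: str | None = None  # CSV with columns code,name
    simulate: dict | None = None
    sigma_min: float = 100.0
    D: float | str = "estimate"
    T_max: float = 180.0
    tau: float | None = None
    L_min: float = 0.0
    immobile_active_mode: str = "drop"
    variance_mode: str = "constant_weight"
    global_mode: bool = False
    cell_size: float | None = None
    isopleth_levels: tuple = (50.0, 95.0)
    preference_level: float = 95.0
    seed: int = 0
    out_dir: str = "brbud_out"

    def __post_init__(self) -> None:
        for name in ("sigma_min", "T_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.D != "estimate" and float(self.D) < 0:
            raise ValueError("D must be >= 0 or 'estimate'")
        if self.tau is not None and not self.tau > 0:
            raise ValueError("tau must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["isopleth_levels"] = list(self.isopleth_levels)
        return d


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} does not contain a mapping")
    return RunConfig(**data)


def _read_legend(path) -> dict[int, str]:
    df = pd.read_csv(path)
    return dict(zip(df["code"].astype(int), df["name"].astype(str)))


def _simulate_stage(cfg: RunConfig, out: Path) -> pd.DataFrame:
    sim = dict(cfg.simulate)
    n_steps = int(sim.pop("n_steps", 1000))
    T_R = float(sim.pop("T_R", 30.0))
    activity = sim.pop("activity", 1.0)
    if isinstance(activity, list):
        activity = tuple(activity)
    dropout = float(sim.pop("dropout", 0.0))
    params = WalkParams(seed=cfg.seed, **sim)
    fixes = simulate_walk(params, n_steps)
    fixes = gps_subsample(fixes, T_R, activity=activity, dropout=dropout,
                          seed=cfg.seed + 1)
    traj.write_track(fixes, out / "track.csv")
    return fixes


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages and return (and write) the JSON report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_dict()}
    stage = "setup"
    try:
        if cfg.simulate:
            stage = "simulate"
            fixes = _simulate_stage(cfg, out)
        elif cfg.track:
            stage = "read_track"
            fixes = traj.read_track(cfg.track, cfg.columns)
        else:
            raise ValueError("config needs either a track path or a "
                             "simulate block")
        report["n_fixes"] = int(len(fixes))

        stage = "compute_ud"
        model = BRBDensity(
            sigma_min=cfg.sigma_min, D=cfg.D, T_max=cfg.T_max, tau=cfg.tau,
            variance_mode=cfg.variance_mode, L_min=cfg.L_min,
            immobile_active_mode=cfg.immobile_active_mode,
            global_mode=cfg.global_mode, cell_size=cfg.cell_size,
        ).fit(fixes)
        seg = model.segments_
        seg.to_csv(out / "segments.csv", index=False)
        export_ud(model.ud_, out / "ud.asc", "esri_ascii")
        excluded = seg[~seg["included"]]
        report.update({
            "n_segments": int(len(seg)),
            "n_excluded": int(len(excluded)),
            "excluded_by_reason": {
                r: int(n) for r, n in
                excluded["reason"].value_counts().items()},
            "activity_time_removed_min": float(excluded["T"].sum()),
            "D": float(model.D_),
            "beta_tmax": model.params_.beta_tmax,
            "h_min": model.params_.h_min,
            "h_max": model.params_.h_max,
            "tau": float(model.tau_),
            "n_locations": int(model.plan_.n_locations),
            "cell_size": model.grid_.cell,
            "ud_mass": model.ud_.mass,
            "ud_raw_mass": model.ud_.raw_mass,
            "lkde_degenerate": bool(model.lkde_degenerate_),
            "isopleth_area_m2": {
                str(k): v for k, v in
                model.isopleth_areas(cfg.isopleth_levels).items()},
        })
        if model.lkde_degenerate_:
            logger.warning("no segment passed the T_max filter: UD computed "
                           "as a fixed-bandwidth (h_min) location KDE")

        if cfg.habitat:
            stage = "habitat_prefs"
            legend = _read_legend(cfg.legend) if cfg.legend else None
            hab = HabitatMap.from_ascii(cfg.habitat, legend)
            step = hab.grid.cell / 2.0
            d_by_h = est.estimate_d_by_habitat(seg, hab, cfg.T_max, step)
            d_for_drift = {c: e.D_hat if e.defined else float(model.D_)
                           for c, e in d_by_h.items()}
            drift = est.estimate_drift_speeds(seg, hab, d_for_drift, step)
            table = habitat_preferences(model.ud_, hab,
                                        level=cfg.preference_level,
                                        d_estimates=d_by_h, drift=drift)
            table.to_csv(out / "habitat_preferences.csv")
            report["habitat_preferences"] = json.loads(
                table.to_json(orient="index"))
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        report["failed_stage"] = stage
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
        raise
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True))
    return report
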