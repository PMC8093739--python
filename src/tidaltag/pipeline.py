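"""End-to-end pipeline: qc -> events -> features -> fit -> interpret.

A single :class:`RunConfig` (loadable from YAML) drives the five stages;
each stage writes tidy delimited outputs into the run directory and the
whole run is summarized in a manifest (input hashes, seed, package
version) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, brt_core, brt_inference, ocean_features as of, telemetry
from ._util import child_seed

logger = logging.getLogger(__name__)

STAGES = ("qc", "events", "features", "fit", "interpret")


@dataclass
class RunConfig:
    """Validated run configuration for the full pipeline."""

    detections: str
    tags: str
    receivers: str
    pressure: str
    ctd_2m: str
    ctd_50m: str
    adcp_backscatter: str
    adcp_u: str
    adcp_v: str
    adcp_w: str
    grid_start: str = ""
    grid_end: str = ""
    focal_site: str = "Manta Alley"
    download_date: str = ""
    short_interval_min: float = 30.0
    long_interval_h: float = 12.0
    event_timeout_min: float = 60.0
    switch_count: int = 2
    fit: dict = field(default_factory=dict)
    n_top_interactions: int = 3
    seed: int = 0

    INPUT_KEYS = ("detections", "tags", "receivers", "pressure", "ctd_2m",
                  "ctd_50m", "adcp_backscatter", "adcp_u", "adcp_v", "adcp_w")

    def validate(self) -> None:
        missing = [k for k in self.INPUT_KEYS
                   if not Path(getattr(self, k)).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        if not self.grid_start or not self.grid_end:
            raise ValueError("grid_start and grid_end are required")
        if pd.Timestamp(self.grid_start) >= pd.Timestamp(self.grid_end):
            raise ValueError("grid_start must precede grid_end")
        brt_core.FitConfig(**self.fit)  # raises on bad hyperparameters

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _read_series(path) -> pd.Series:
    df = pd.read_csv(path, parse_dates=["datetime"], index_col="datetime")
    return df["value"]


def _read_profile(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["datetime"], index_col="datetime")
    if df.shape[1] != of.N_ADCP_BINS:
        raise ValueError(f"{path}: expected {of.N_ADCP_BINS} bins, "
                         f"got {df.shape[1]}")
    return df


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_features(config: RunConfig, kept: pd.DataFrame,
                   receivers: pd.DataFrame) -> pd.DataFrame:
    """Run the instrument-series stage and assemble the design matrix."""
    grid = of.make_grid(config.grid_start, config.grid_end)

    temp_2m = of.bin_mean(_read_series(config.ctd_2m), grid)
    temp_50m = of.bin_mean(_read_series(config.ctd_50m), grid)

    bs = _read_profile(config.adcp_backscatter)
    bs_clean = of.despike_running_median(bs.to_numpy())
    backscatter = of.interpolate_linear(bs.index, of.depth_mean(bs_clean), grid)

    u = _read_profile(config.adcp_u)
    v = _read_profile(config.adcp_v)
    w = _read_profile(config.adcp_w)
    picked = of.select_velocity_bins(u.to_numpy(), v.to_numpy())
    currents = {}
    for height, key in ((48.5, "48_5"), (8.5, "8_5")):
        uu, vv = picked[height]
        ls, cs = of.rotate_currents(uu, vv)
        currents[f"ls_{key}"] = of.interpolate_linear(u.index, ls, grid)
        currents[f"cs_{key}"] = of.interpolate_linear(u.index, cs, grid)
    wmean = of.interpolate_linear(w.index, of.vertical_velocity_mean(w.to_numpy()),
                                  grid)

    depth = pd.Series(of.pressure_to_depth(_read_series(config.pressure)),
                      index=_read_series(config.pressure).index)
    tide = of.extract_tide(depth)
    tth = of.time_to_high_tide(grid, tide.high_tide_times)

    focal = receivers.loc[receivers["site_name"] == config.focal_site,
                          "receiver_id"]
    if focal.empty:
        raise ValueError(f"no receiver at site {config.focal_site!r}")
    predictors = {
        "temp_2m": temp_2m, "temp_50m": temp_50m, "backscatter": backscatter,
        **currents, "vertical_velocity": wmean, "time_to_high_tide": tth,
    }
    return of.assemble_design_matrix(kept, grid, predictors,
                                     focal_receiver=str(focal.iloc[0]))


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages, writing versioned outputs plus a manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {k: _sha256(getattr(config, k)) for k in config.INPUT_KEYS},
        "stages": [],
    }

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("qc")
        dets = telemetry.read_detections(config.detections)
        kept, flagged = telemetry.filter_false_detections(
            dets,
            short=pd.Timedelta(minutes=config.short_interval_min),
            long=pd.Timedelta(hours=config.long_interval_h),
        )
        kept.to_csv(out / "detections_kept.csv", index=False)
        flagged.to_csv(out / "detections_flagged.csv", index=False)

        stage("events")
        events = telemetry.detect_resident_events(
            kept,
            timeout=pd.Timedelta(minutes=config.event_timeout_min),
            switch_count=config.switch_count,
        )
        telemetry.events_to_frame(events).to_csv(out / "resident_events.csv",
                                                 index=False)
        tags = pd.read_csv(config.tags, dtype={"tag_id": str})
        receivers = pd.read_csv(config.receivers)
        download = pd.Timestamp(config.download_date or config.grid_end)
        summary = telemetry.summarize_tracking(kept, tags, download.date())
        summary.to_csv(out / "tracking_summary.csv", index=False)

        stage("features")
        design = build_features(config, kept, receivers)
        design.rename_axis("bin_start").to_csv(out / "design_matrix.csv")
        screen = of.collinearity_screen(design.drop(columns="response"))
        provenance = {
            "n_bins_kept": len(design),
            "n_bins_dropped": design.attrs.get("n_dropped", 0),
            "prevalence": float(design["response"].mean()),
            "vif": {k: (None if v == float("inf") else v)
                    for k, v in screen["vif"].items()},
            "flagged_pairs": [(a, b, r) for a, b, r in screen["flagged_pairs"]],
        }
        (out / "features_report.json").write_text(json.dumps(provenance))

        stage("fit")
        fit_cfg = brt_core.FitConfig(**{"seed": child_seed(config.seed, 10),
                                        **config.fit})
        X = design.drop(columns="response")
        y = design["response"].to_numpy()
        model, boosters, fold = brt_core.step_cv_fit(X, y, fit_cfg)
        report = brt_core.evaluate(model, X, y, boosters, fold)
        (out / "model.json").write_text(model.to_json())
        (out / "fit_report.json").write_text(json.dumps({
            "t_auc": report.t_auc, "cv_auc": report.cv_auc,
            "delta_auc": report.delta_auc, "d2": report.d2,
            "cv_auc_band": report.auc_band(report.cv_auc),
            "n_trees": model.n_trees_selected,
        }))

        stage("interpret")
        influence = brt_inference.relative_influence(model)
        influence.rename("influence_percent").rename_axis("predictor") \
            .to_csv(out / "influence.csv")
        interactions = brt_inference.interaction_table(model, X)
        interactions.to_csv(out / "interactions.csv", index=False)
        pd_curves = {
            name: {
                "grid": curve.grid.tolist(),
                "response": curve.response.tolist(),
            }
            for name in influence.sort_values(ascending=False).index[:3]
            for curve in [brt_inference.partial_dependence(model, name, X)]
        }
        (out / "partial_dependence.json").write_text(json.dumps(pd_curves))
    except Exception as exc:
        failed = STAGES[len(manifest["stages"]) - 1] if manifest["stages"] \
            else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, default=str))
    return out
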