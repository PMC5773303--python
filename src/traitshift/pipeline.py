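"""End-to-end orchestration: simulate -> ingest -> historic models -> maps
-> change GLS, from a single config, with a manifest of every artifact.

Each stage persists its outputs under the run directory and the manifest
records per-file SHA-256 checksums, stage timings, seeds and filter counts,
so any stage can be re-run alone from persisted artifacts and identical
configs reproduce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (change_gls, climate_layers, specimen_data, spatial_lmm,
               synthetic_data, tps_change_maps)
from .synthetic_data import SynthParams


@dataclass
class PipelineConfig:
    """Single source of every analysis constant.

    Defaults are the study conditions: cutoff 1960, 1-degree latitude
    bands, 100 bootstrap replicates, 484 change points, Delta-AICc <= 2
    averaging.
    """

    out_dir: str = "traitshift_run"
    cutoff_year: int = 1960
    band_width: float = 1.0
    separation_days: float = 45.0
    B: int = 100
    n_points: int = 484
    delta_aicc_max: float = 2.0
    weight_mode: str = "variance"
    coord_mode: str = "raw"
    use_elevation: bool = True
    seed: int = 17
    records_path: str | None = None   # None -> simulate
    climate_dir: str | None = None
    synth: SynthParams = field(default_factory=SynthParams)
    responses: tuple[str, ...] = ("log_svl_female", "log_svl_male",
                                  "julian_day")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthParams(**raw.pop("synth", {}))
        cfg = cls(synth=synth, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, outputs: list[Path], t0: float,
               counts: dict | None = None) -> None:
        self.stages[stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "seconds": round(time.perf_counter() - t0, 3),
            "counts": counts or {},
        }

    def write(self, path: Path) -> None:
        payload = {"config": self.config, "stages": self.stages,
                   "warnings": self.warnings}
        path.write_text(json.dumps(payload, indent=2, default=str))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order; halts with a stage-scoped error."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    manifest_path = out / "manifest.json"

    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("ingest", _stage_ingest),
        ("climate", _stage_climate),
        ("historic_models", _stage_historic),
        ("maps", _stage_maps),
        ("change_gls", _stage_change_gls),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            outputs, counts = fn(config, out, state)
        except Exception as exc:  # halt with partial manifest
            manifest.warnings.append(f"stage {name} failed: {exc}")
            manifest.write(manifest_path)
            raise StageError(name, exc) from exc
        manifest.record(name, outputs, t0, counts)
        manifest.write(manifest_path)
    return manifest


def _stage_simulate(config: PipelineConfig, out: Path, state: dict):
    if config.records_path is not None:
        stack = climate_layers.ClimateStack.read(config.climate_dir)
        state.update(stack=stack, records_path=Path(config.records_path),
                     dem=synthetic_data.gen_dem(config.synth))
        return [], {"simulated": 0}
    params = dataclasses.replace(config.synth, seed=config.seed,
                                 cutoff_year=config.cutoff_year)
    stack = synthetic_data.gen_climate_stack(params)
    table, truth = synthetic_data.gen_specimens(params, stack)
    stack_dir = out / "climate"
    stack.write(stack_dir)
    rec_path = out / "specimens.csv"
    synthetic_data.write_specimens(table, rec_path)
    dem_path = out / "dem.asc"
    synthetic_data.write_dem(params, dem_path)
    truth_path = out / "ground_truth.json"
    truth.to_json(truth_path)
    state.update(stack=stack, records_path=rec_path, truth=truth,
                 dem=synthetic_data.gen_dem(params))
    outputs = [rec_path, dem_path, truth_path,
               *sorted(stack_dir.glob("*.asc")), stack_dir / "stack.json"]
    return outputs, {"n_records": len(table)}


def _stage_ingest(config: PipelineConfig, out: Path, state: dict):
    records, report = specimen_data.read_specimens(
        state["records_path"], cutoff_year=config.cutoff_year)
    split = specimen_data.split_breeding(
        records, band_width=config.band_width,
        separation_days=config.separation_days)
    season_path = out / "specimens_season.csv"
    split.to_table().to_csv(season_path, index=False)
    report_path = out / "season_report.json"
    split.write_report(report_path)
    state.update(records=records, split=split)
    counts = {"read": report.n_read, "kept": report.n_kept,
              "dropped": report.n_dropped,
              "breeding": len(split.breeding),
              "nonbreeding": len(split.nonbreeding)}
    return [season_path, report_path], counts


def _stage_climate(config: PipelineConfig, out: Path, state: dict):
    stack = state["stack"]
    records = climate_layers.extract_records(stack, state["records"])
    pre = records[records["period"] == "pre"]
    scaled_pre, transforms = climate_layers.scale_record_climate(pre)
    records, _ = climate_layers.scale_record_climate(records, transforms)
    state.update(records_climate=records, transforms=transforms)

    diag = climate_layers.correlation_diagnostics(records)
    vifs = climate_layers.vif(
        records[["temperature", "precipitation"]]).tolist()
    vifs_ffd = climate_layers.vif(
        records[["ffd", "precipitation"]]).tolist()
    diag_path = out / "climate_diagnostics.json"
    diag_path.write_text(json.dumps({
        "correlations": diag.to_dict(orient="records"),
        "vif_temperature_precipitation": vifs,
        "vif_ffd_precipitation": vifs_ffd,
        "chosen_thermal_variable": "ffd",
    }, indent=2))
    return [diag_path], {"n_with_climate": len(records)}


def _stage_historic(config: PipelineConfig, out: Path, state: dict):
    records = state["records_climate"]
    pre = records[records["period"] == "pre"]
    breeding_ids = set(state["split"].breeding["id"])
    outputs, counts = [], {}
    state["historic"] = {}
    for response in config.responses:
        sub = pre if response != "julian_day" else pre[
            pre["id"].isin(breeding_ids)]
        fits = spatial_lmm.fit_candidates(
            sub, response, coord_mode=config.coord_mode,
            use_elevation=config.use_elevation, seed=config.seed)
        sel = spatial_lmm.select_and_average(fits, config.delta_aicc_max)
        r2s = pd.DataFrame([{"terms": "+".join(f.terms) or "1",
                             "r2_marginal": f.r2_marginal,
                             "r2_conditional": f.r2_conditional}
                            for f in fits])
        table = sel.table.merge(r2s, on="terms")
        t_path = out / f"historic_{response}_models.csv"
        a_path = out / f"historic_{response}_averaged.csv"
        table.to_csv(t_path, index=False)
        sel.averaged.to_csv(a_path, index=False)
        outputs += [t_path, a_path]
        counts[response] = len(sub)
        state["historic"][response] = sel
    return outputs, counts


def _stage_maps(config: PipelineConfig, out: Path, state: dict):
    stack, dem = state["stack"], state["dem"]
    records = state["records_climate"]
    breeding_ids = set(state["split"].breeding["id"])
    grid_coords = tps_change_maps.grid_prediction_coords(
        stack.grid, stack.mask, dem)
    outputs, counts = [], {}
    state["change_maps"] = {}
    for response in config.responses:
        ens = {}
        for i, period in enumerate(("pre", "post")):
            sub = records[records["period"] == period]
            if response == "julian_day":
                sub = sub[sub["id"].isin(breeding_ids)]
            sub, y = spatial_lmm.response_subset(sub, response)
            coords = sub[["lat", "lon", "elev_m"]].to_numpy(dtype=float)
            ens[period] = tps_change_maps.bootstrap_maps(
                coords, y, grid_coords, B=config.B,
                seed=config.seed * 4 + i, grid=stack.grid, mask=stack.mask)
            ens[period].write(out / "maps", f"{response}_{period}")
            counts[f"{response}_{period}"] = len(sub)
        cmap = tps_change_maps.change_map(ens["pre"], ens["post"])
        cmap.write(out / "maps", f"{response}_change")
        state["change_maps"][response] = cmap
    outputs = sorted((out / "maps").glob("*"))
    return outputs, counts


def _stage_change_gls(config: PipelineConfig, out: Path, state: dict):
    stack = state["stack"]
    climate_change = climate_layers.proportional_change(
        stack, config.cutoff_year)
    climate_change.write(out / "climate_change")
    valid = climate_change.mask.copy()
    for cmap in state["change_maps"].values():
        valid &= cmap.mask if cmap.mask is not None else True
    cells = change_gls.sample_change_points(valid, n=config.n_points,
                                            seed=config.seed)
    outputs = sorted((out / "climate_change").glob("*.asc"))
    counts = {"n_points": len(cells)}
    for response, cmap in state["change_maps"].items():
        points = change_gls.build_change_points(cells, cmap, climate_change)
        sel = change_gls.enumerate_and_average(
            points, weight_mode=config.weight_mode,
            delta_max=config.delta_aicc_max)
        a_path = out / f"change_{response}_averaged.csv"
        t_path = out / f"change_{response}_models.csv"
        sel.averaged.to_csv(a_path, index=False)
        sel.table.to_csv(t_path, index=False)
        curves = change_gls.partial_effects(sel.averaged, points, var="F")
        c_path = out / f"change_{response}_partial_ffd.csv"
        curves.to_csv(c_path, index=False)
        outputs += [a_path, t_path, c_path]
    return outputs, counts
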