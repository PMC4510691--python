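"""End-to-end pipeline: simulate -> normalize -> impact -> diff -> classify -> summarize.

One :class:`RunConfig` (typically loaded from YAML) drives the whole
workflow deterministically: re-running with the same config and seed
reproduces bitwise-identical rasters and tables. Every file written is
listed in a manifest stamped with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as rio
from .change import change_map, classify, extreme_combinations
from .grid import Raster
from .impact import ContributionMap, cumulative_impact, stressor_contributions
from .layers import HabitatLayer, StressorLayer
from .normalize import normalize_stressors
from .regions import build_summary
from .synthetic import SeascapeConfig, Seascape, generate_seascape
from .vulnerability import load_weights, save_weights

__all__ = ["RunConfig", "run_pipeline", "write_seascape", "load_seascape"]

log = logging.getLogger("cumimpact")

MAX_GRID_SIDE = 2000  # in-memory, single-process contract


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either a ``synthetic`` seascape block or an ``inputs`` block of paths
    (stressor_dir, stressor_table, habitat_dir, habitat_table, weights,
    regions, region_table) must be provided.
    """

    seed: int = 0
    mode: str = "mean"
    subset: str = "comparable"  # stressor subset for the temporal comparison
    synthetic: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    thresholds: tuple[float, float, float, float] | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("mean", "sum"):
            raise ValueError(f"mode must be 'mean' or 'sum', got {self.mode!r}")
        if self.synthetic is None and self.inputs is None:
            raise ValueError("config must provide a 'synthetic' block or an 'inputs' block")
        if self.synthetic is None and self.inputs is not None and "weights" not in self.inputs:
            raise ValueError("inputs block must include a 'weights' path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def seascape_config(self) -> SeascapeConfig:
        block = dict(self.synthetic or {})
        block.setdefault("seed", self.seed)
        return SeascapeConfig(**block)

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "mode": self.mode,
            "subset": self.subset,
            "synthetic": self.synthetic,
            "inputs": self.inputs,
            "thresholds": self.thresholds,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Seascape persistence (the simulate stage's on-disk layout)
# ---------------------------------------------------------------------------


def write_seascape(seascape: Seascape, out_dir: str | Path) -> list[Path]:
    """Write all synthetic inputs to ``out_dir``; returns the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(raster: Raster, name: str) -> None:
        p = out / name
        rio.write_raster(raster, p)
        written.append(p)

    _w(seascape.bathymetry, "bathymetry.tif")
    for period, layers in seascape.stressors.items():
        for s in layers:
            _w(s.raster, f"{s.stressor_id}_{period}.tif")
    for h in seascape.habitats:
        _w(h.raster, f"{h.habitat_id}.tif")
    _w(seascape.regions, "regions.tif")

    p = out / "regions.csv"
    seascape.region_table.to_csv(p, index=False)
    written.append(p)
    p = out / "stressors.csv"
    seascape.config.stressor_table().to_csv(p, index=False)
    written.append(p)
    p = out / "habitats.csv"
    seascape.config.habitat_table().to_csv(p, index=False)
    written.append(p)
    p = out / "weights.csv"
    save_weights(seascape.weights, p)
    written.append(p)
    return written


def load_seascape(in_dir: str | Path) -> dict[str, Any]:
    """Load the files written by :func:`write_seascape` back into layer objects."""
    d = Path(in_dir)
    stressor_table = pd.read_csv(d / "stressors.csv")
    habitat_table = pd.read_csv(d / "habitats.csv")
    stressors: dict[str, list[StressorLayer]] = {"t1": [], "t2": []}
    for row in stressor_table.itertuples(index=False):
        for period in ("t1", "t2"):
            r = rio.read_raster(d / f"{row.stressor_id}_{period}.tif", "intensity")
            stressors[period].append(
                StressorLayer(row.stressor_id, period, r, bool(row.is_binary), bool(row.comparable))
            )
    habitats = [
        HabitatLayer(row.habitat_id, row.depth_class, rio.read_raster(d / f"{row.habitat_id}.tif", "presence"))
        for row in habitat_table.itertuples(index=False)
    ]
    return {
        "stressors": stressors,
        "habitats": habitats,
        "stressor_table": stressor_table,
        "habitat_table": habitat_table,
        "weights": load_weights(d / "weights.csv"),
        "regions": rio.read_raster(d / "regions.tif", "region_label"),
        "region_table": pd.read_csv(d / "regions.csv"),
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrapped

    return deco


def _subset_ids(stressor_table: pd.DataFrame, subset: str) -> list[str]:
    if subset == "all":
        return stressor_table["stressor_id"].tolist()
    if subset == "comparable":
        return stressor_table.loc[stressor_table["comparable"], "stressor_id"].tolist()
    return [s.strip() for s in subset.split(",") if s.strip()]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the manifest.

    Outputs under ``out_dir``: the simulated inputs (synthetic runs), the
    normalized stressor rasters and reference maxima, impact maps for both
    periods, per-stressor contribution maps, the change map, class and
    extreme-combination maps with their thresholds, the regional summary
    table and ``manifest.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    @_stage("simulate")
    def stage_inputs():
        if config.synthetic is not None:
            sc = config.seascape_config()
            if sc.n_rows > MAX_GRID_SIDE or sc.n_cols > MAX_GRID_SIDE:
                raise ValueError(f"grid larger than {MAX_GRID_SIDE}x{MAX_GRID_SIDE} not supported in-memory")
            seascape = generate_seascape(sc)
            sim_dir = out / "inputs"
            files.extend(write_seascape(seascape, sim_dir))
            return load_seascape(sim_dir)
        return load_seascape_paths(config.inputs)

    def load_seascape_paths(inputs):
        # explicit-path mode: one directory holding the standard layout
        return load_seascape(inputs["dir"]) if "dir" in inputs else load_seascape(Path(inputs["weights"]).parent)

    data = stage_inputs()

    @_stage("normalize")
    def stage_normalize():
        norm = normalize_stressors(data["stressors"], mode="joint")
        ref_rows = []
        for period in ("t1", "t2"):
            for layer in norm[period]:
                p = out / f"{layer.stressor_id}_{period}_norm.tif"
                rio.write_raster(layer.raster, p)
                files.append(p)
                if period == "t1":
                    ref_rows.append({"stressor_id": layer.stressor_id, "reference_max": layer.reference_max})
        p = out / "reference_max.csv"
        pd.DataFrame(ref_rows).to_csv(p, index=False)
        files.append(p)
        return norm

    norm = stage_normalize()

    @_stage("impact")
    def stage_impact():
        ids = _subset_ids(data["stressor_table"], config.subset)
        maps = {}
        for period in ("t1", "t2"):
            layers = [l for l in norm[period] if l.stressor_id in ids]
            m = cumulative_impact(layers, data["habitats"], data["weights"], mode=config.mode)
            p = out / f"impact_{period}.tif"
            rio.write_raster(m.raster, p)
            files.append(p)
            maps[period] = m
        contribs = {}
        for period in ("t1", "t2"):
            layers = [l for l in norm[period] if l.stressor_id in ids]
            contribs[period] = stressor_contributions(layers, data["habitats"], data["weights"], mode=config.mode)
        cdir = out / "contributions"
        cdir.mkdir(exist_ok=True)
        for c in contribs["t2"]:
            p = cdir / f"{c.stressor_id}_t2.tif"
            rio.write_raster(c.raster, p)
            files.append(p)
        return maps, contribs

    impact_maps, contribs = stage_impact()

    @_stage("diff")
    def stage_diff():
        ch = change_map(impact_maps["t2"], impact_maps["t1"])
        p = out / "change.tif"
        rio.write_raster(ch.raster, p)
        files.append(p)
        ch_contribs = []
        for c1, c2 in zip(contribs["t1"], contribs["t2"]):
            diff = c2.raster.values - c1.raster.values
            ch_contribs.append(
                ContributionMap(c2.stressor_id, Raster(c2.raster.grid, diff, "change"), c2.mode, "t2")
            )
        return ch, ch_contribs

    change, change_contribs = stage_diff()

    @_stage("classify")
    def stage_classify():
        cm = classify(impact_maps["t2"], change, thresholds=config.thresholds)
        for name, raster in (("class_level.tif", cm.level), ("class_trend.tif", cm.trend)):
            p = out / name
            rio.write_raster(raster, p)
            files.append(p)
        combos = extreme_combinations(cm)
        p = out / "extreme_combinations.tif"
        rio.write_raster(combos, p)
        files.append(p)
        p = out / "thresholds.csv"
        pd.DataFrame(
            [
                {"quantity": "impact_level", "low_cut": cm.level_low_cut, "high_cut": cm.level_high_cut},
                {"quantity": "change_trend", "low_cut": cm.trend_low_cut, "high_cut": cm.trend_high_cut},
            ]
        ).to_csv(p, index=False)
        files.append(p)
        return cm

    stage_classify()

    @_stage("summarize")
    def stage_summarize():
        summary = build_summary(
            impact_maps["t2"],
            change,
            contribs["t2"],
            data["regions"],
            data["region_table"],
            change_contributions=change_contribs,
        )
        p = out / "summary.csv"
        summary.to_csv(p, index=False)
        files.append(p)
        return summary

    stage_summarize()

    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "mode": config.mode,
        "subset": config.subset,
        "files": sorted(str(p.relative_to(out)) for p in files),
        "checksums": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(files)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
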