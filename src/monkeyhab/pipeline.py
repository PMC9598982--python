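"""End-to-end pipeline driver: scene -> villages -> threats -> quality -> stats.

Runs either on a simulated scene (``scene:`` block in the config) or on
user-supplied input files (``inputs:`` block). All outputs are text
formats (ASCII grids, CSV, GeoJSON, JSON) and a rerun with the same
config and seed is bit-identical: the manifest records the seed and a
content hash of the resolved parameter tables, never wall-clock times.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .params import load_params, param_hash
from .raster import Raster, read_ascii_grid, write_ascii_grid
from .synthetic_data import INDICATOR_CODES, SceneConfig, generate_scene
from .vector import read_geojson, write_geojson
from . import habitat_quality as hq
from . import spatial_stats as ss
from . import village_development as vd

__all__ = ["PipelineError", "run_pipeline", "write_scene"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _scene_config(block: dict) -> SceneConfig:
    kwargs = dict(block)
    if "grid_shape" in kwargs:
        kwargs["grid_shape"] = tuple(kwargs["grid_shape"])
    if "class_proportions" in kwargs:
        kwargs["class_proportions"] = {
            int(k): float(v) for k, v in kwargs["class_proportions"].items()
        }
    return SceneConfig(**kwargs)


def write_scene(scene, out_dir: Path) -> list[Path]:
    """Write all layers of a synthetic scene as text formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(path: Path):
        written.append(path)
        return path

    write_ascii_grid(scene.lulc, _w(out_dir / "lulc.asc"))
    scene.villages.to_csv(_w(out_dir / "villages.csv"), index=False)
    write_geojson(scene.roads, _w(out_dir / "roads.geojson"))
    scene.plots.to_csv(_w(out_dir / "plots.csv"), index=False)
    write_geojson(
        scene.groups,
        _w(out_dir / "groups.geojson"),
        properties=[{"code": c} for c in scene.group_codes],
    )
    return written


def run_pipeline(config: dict, dry_run: bool = False) -> dict:
    """Execute the full analysis; returns a result bundle dictionary.

    Stages: simulate/load -> village scoring -> threat layers ->
    degradation & quality -> grading -> spatial statistics -> reports.
    Any stage failure raises :class:`PipelineError` naming the stage and
    removes partial outputs.
    """
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "monkeyhab_out"))
    analysis = dict(config.get("analysis") or {})
    unit_size = int(analysis.get("unit_size", 5))
    permutations = int(analysis.get("permutations", 199))
    bandwidth = analysis.get("bandwidth")

    params = load_params(config.get("params_file"))
    if "scene" not in config and "inputs" not in config:
        raise PipelineError("stage 'configure' failed: need a 'scene' or 'inputs' block")
    if "scene" in config:
        _scene_config({**config["scene"], "seed": seed})  # validate eagerly
    if dry_run:
        return {"dry_run": True, "param_hash": param_hash(params), "seed": seed}

    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        bundle = _run_stages(
            config, params, seed, out_dir, unit_size, permutations, bandwidth, written
        )
    except PipelineError:
        _cleanup(written)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        _cleanup(written)
        raise PipelineError(f"pipeline failed: {exc}") from exc
    return bundle


def _cleanup(written: list[Path]) -> None:
    for path in written:
        try:
            path.unlink(missing_ok=True)
        except OSError:  # pragma: no cover
            pass


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                logger.info("stage %s: done", name)
                return out
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


@_stage("load-inputs")
def _load_inputs(config: dict, seed: int, out_dir: Path, written: list[Path]):
    if "scene" in config:
        cfg = _scene_config({**config["scene"], "seed": seed})
        scene = generate_scene(cfg)
        written.extend(write_scene(scene, out_dir / "scene"))
        groups = scene.groups
        codes = scene.group_codes
        return scene.lulc, scene.villages, scene.roads, groups, codes
    inputs = config["inputs"]
    lulc = read_ascii_grid(inputs["lulc"])
    villages = pd.read_csv(inputs["villages"])
    roads, _ = read_geojson(inputs["roads"]) if inputs.get("roads") else ([], [])
    if inputs.get("groups"):
        groups, props = read_geojson(inputs["groups"])
        codes = [p.get("code", f"C{i + 1}") for i, p in enumerate(props)]
    else:
        groups, codes = [], []
    return lulc, villages, roads, groups, codes


@_stage("village-scoring")
def _score_villages(villages: pd.DataFrame, lulc: Raster, bandwidth):
    indicators = villages[[c for c in INDICATOR_CODES if c in villages.columns]]
    std = vd.standardize_indicators(indicators)
    pca = vd.fit_pca(std, min_retain=1)
    z = vd.comprehensive_score(pca)
    grades = vd.grade_villages(z)
    xy = villages[["x", "y"]].to_numpy(dtype=float)
    density = vd.kernel_density(xy, lulc, bandwidth=bandwidth, weights=None)
    scored = villages[["x", "y"]].copy()
    scored["Z"] = z
    scored["grade"] = grades
    return scored, pca, density


@_stage("habitat-quality")
def _habitat(scored: pd.DataFrame, roads, lulc: Raster, params: dict):
    layers = hq.build_threat_layers(
        scored[["x", "y"]].to_numpy(dtype=float),
        scored["grade"].to_numpy(),
        roads,
        lulc,
        params,
    )
    d = hq.degradation(lulc, layers, params)
    q = hq.quality(d, lulc, params)
    grade_raster, area_table, mean_q = hq.grade_quality(q, params)
    return d, q, grade_raster, area_table, mean_q


@_stage("spatial-stats")
def _spatial(q: Raster, groups, codes, unit_size: int, permutations: int, seed: int):
    vals, w, block_rc = ss.aggregate_to_units(q, unit_size)
    moran = ss.morans_i(vals, ss.row_standardize(w), permutations=permutations, seed=seed)
    z = ss.gi_star(vals, ss.add_self_neighbors(w))
    labels = ss.classify_hotspots(z)
    hotspots = pd.DataFrame(
        {
            "block_row": block_rc[:, 0],
            "block_col": block_rc[:, 1],
            "mean_quality": vals,
            "gi_star_z": z,
            "hotspot": labels,
        }
    )
    if groups:
        group_table, group_summary = ss.zonal_mean(q, groups, codes)
    else:
        group_table = pd.DataFrame(columns=["code", "mean_quality", "n_pixels"])
        group_summary = ss.summarize_groups({})
    return moran, hotspots, group_table, group_summary


@_stage("reports")
def _write_reports(
    out_dir: Path, written: list[Path], density, d, q, grade_raster,
    area_table, mean_q, scored, moran, hotspots, group_table, group_summary,
    params: dict, seed: int, config: dict,
):
    def _w(path: Path):
        written.append(path)
        return path

    write_ascii_grid(density, _w(out_dir / "village_density.asc"))
    write_ascii_grid(d, _w(out_dir / "degradation.asc"))
    write_ascii_grid(q, _w(out_dir / "quality.asc"))
    write_ascii_grid(grade_raster, _w(out_dir / "quality_grades.asc"))
    area_table.to_csv(_w(out_dir / "quality_area_table.csv"), index=False)
    scored.to_csv(_w(out_dir / "village_scores.csv"), index=False)
    hotspots.to_csv(_w(out_dir / "hotspots.csv"), index=False)
    group_table.to_csv(_w(out_dir / "group_quality.csv"), index=False)
    stats = {
        "mean_quality": mean_q,
        "moran_i": moran.i,
        "moran_expected": moran.expected,
        "moran_z_norm": moran.z_norm,
        "moran_p_norm": moran.p_norm,
        "moran_p_sim": moran.p_sim,
        "group_summary": group_summary,
    }
    with open(_w(out_dir / "stats.json"), "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True, allow_nan=True)
    manifest = {
        "package": "monkeyhab",
        "version": __version__,
        "numpy": np.__version__,
        "seed": seed,
        "param_hash": param_hash(params),
        "config": {k: v for k, v in config.items() if k != "inputs"} | {
            "inputs": {k: str(v) for k, v in (config.get("inputs") or {}).items()}
        },
        "outputs": sorted(str(p.relative_to(out_dir)) for p in written),
        "coordinate_convention": "north-up grid, pixel-center registration, planar CRS",
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    written.append(out_dir / "manifest.json")
    return stats


def _run_stages(
    config, params, seed, out_dir, unit_size, permutations, bandwidth, written
):
    lulc, villages, roads, groups, codes = _load_inputs(config, seed, out_dir, written)
    scored, pca, density = _score_villages(villages, lulc, bandwidth)
    d, q, grade_raster, area_table, mean_q = _habitat(scored, roads, lulc, params)
    moran, hotspots, group_table, group_summary = _spatial(
        q, groups, codes, unit_size, permutations, seed
    )
    stats = _write_reports(
        out_dir, written, density, d, q, grade_raster, area_table, mean_q,
        scored, moran, hotspots, group_table, group_summary, params, seed, config,
    )
    return {
        "out_dir": out_dir,
        "stats": stats,
        "area_table": area_table,
        "village_scores": scored,
        "group_table": group_table,
        "pca_retained": pca.n_retained,
        "outputs": [str(p) for p in written],
    }
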