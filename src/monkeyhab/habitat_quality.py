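"""Threat-based habitat degradation and quality model.

Twelve threat factors — villages split by development grade I-VII, rural
roads, and four land-cover-derived sources (other non-forest land,
planted economic forest, cropland, artificial construction) — radiate
influence that decays with distance from the source (exponential or
linear, zero beyond each threat's maximum effective distance). Pixel
degradation ``D`` combines the per-threat influence with the land-cover
class's sensitivity, weighted by normalized threat weights:

    D(x) = sum_r (w_r / sum_w) * i_r(x) * S_{j(x),r}

with ``i_r(x)`` the decayed influence of the *nearest* source pixel of
threat ``r`` (Euclidean distance transform on pixel centers). Quality is
suitability discounted through a half-saturation response:

    Q(x) = H_j * (1 - D^z / (D^z + k^z))

so ``Q = H`` with no degradation and ``Q = H/2`` at ``D = k``.

Design notes: influence uses distance-to-nearest-source (not a sum over
all source pixels), which keeps ``D`` provably inside [0, 1] and makes
``k`` interpretable; the exponential constant is ``2.99 / d_max`` so
influence falls to ~0.05 at the maximum effective distance and is
clamped to 0 beyond it; the accessibility multiplier is fixed at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from .params import LANDCOVER_THREAT_SOURCES, THREAT_NAMES, default_params
from .raster import Raster
from .village_development import VILLAGE_GRADES

__all__ = [
    "ThreatLayer",
    "build_threat_layers",
    "rasterize_points",
    "rasterize_lines",
    "decay_influence",
    "degradation",
    "quality",
    "grade_quality",
    "QUALITY_GRADE_LABELS",
    "percent_of_grades",
    "HabitatQualityResult",
]

logger = logging.getLogger(__name__)

QUALITY_GRADE_LABELS: tuple[str, ...] = ("very poor", "poor", "medium", "good", "excellent")


@dataclass
class ThreatLayer:
    """One threat factor with its rasterized presence (0/1) layer."""

    name: str
    max_distance: float  # metres
    weight: float
    decay: str  # 'exponential' | 'linear'
    presence: np.ndarray  # bool, same grid as the LULC raster


@dataclass
class HabitatQualityResult:
    degradation: Raster
    quality: Raster
    grades: Raster  # int codes 1..5, NaN-safe via nodata
    area_table: pd.DataFrame  # grade, label, area_km2, percent
    mean_quality: float


def rasterize_points(xs, ys, grid: Raster) -> np.ndarray:
    """Mark the pixel containing each point; points off-grid are ignored."""
    out = np.zeros(grid.shape, dtype=bool)
    r, c = grid.index_of(np.asarray(xs, dtype=float), np.asarray(ys, dtype=float))
    rows, cols = grid.shape
    ok = (r >= 0) & (r < rows) & (c >= 0) & (c < cols)
    out[r[ok], c[ok]] = True
    return out


def rasterize_lines(lines, grid: Raster) -> np.ndarray:
    """Mark every pixel a polyline passes through (dense vertex sampling)."""
    out = np.zeros(grid.shape, dtype=bool)
    step = grid.pixel_size / 3.0
    for line in lines:
        if not isinstance(line, LineString) or line.length == 0:
            coords = np.asarray(getattr(line, "coords", []))
            if coords.size:
                out |= rasterize_points(coords[:, 0], coords[:, 1], grid)
            continue
        n = max(2, int(np.ceil(line.length / step)) + 1)
        ts = np.linspace(0.0, line.length, n)
        pts = np.array([line.interpolate(t).coords[0] for t in ts])
        out |= rasterize_points(pts[:, 0], pts[:, 1], grid)
    return out


def build_threat_layers(
    village_xy: np.ndarray,
    village_grades: np.ndarray,
    roads,
    lulc: Raster,
    params: dict | None = None,
) -> list[ThreatLayer]:
    """Build the 12 threat layers in canonical order.

    Villages are split by grade into seven point-presence layers (a
    grade with no villages still yields an all-zero layer), roads are
    rasterized as line presences, and four layers come straight from
    the land-cover classes that act as threats.
    """
    if params is None:
        params = default_params()
    threats = params["threats"]
    grades = np.asarray(village_grades)
    bad = set(grades) - set(VILLAGE_GRADES)
    if bad:
        raise ValueError(f"village grade(s) outside I-VII: {sorted(bad)}")
    xy = np.asarray(village_xy, dtype=float).reshape(-1, 2)
    if xy.shape[0] != grades.shape[0]:
        raise ValueError("village coordinates and grades differ in length")
    codes = lulc.data.astype(int)
    layers: list[ThreatLayer] = []
    for name in THREAT_NAMES:
        spec = threats[name]
        if name.startswith("village_") and name != "village_road":
            grade = VILLAGE_GRADES[
                ["village_i", "village_ii", "village_iii", "village_iv",
                 "village_v", "village_vi", "village_vii"].index(name)
            ]
            sel = grades == grade
            presence = rasterize_points(xy[sel, 0], xy[sel, 1], lulc)
        elif name == "village_road":
            presence = rasterize_lines(roads, lulc)
        else:
            presence = codes == LANDCOVER_THREAT_SOURCES[name]
        layers.append(
            ThreatLayer(
                name=name,
                max_distance=spec["max_distance_km"] * 1000.0,
                weight=spec["weight"],
                decay=spec["decay"],
                presence=presence,
            )
        )
    return layers


def decay_influence(d, d_max: float, decay: str):
    """Distance-decayed influence in [0, 1].

    linear: ``max(0, 1 - d/d_max)``; exponential: ``exp(-2.99*d/d_max)``
    for ``d <= d_max`` and exactly 0 beyond (hard cutoff pins d_max as a
    true maximum effective distance).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if decay == "linear":
        infl = np.maximum(0.0, 1.0 - d / d_max)
    elif decay == "exponential":
        infl = np.where(d <= d_max, np.exp(-(2.99 / d_max) * d), 0.0)
    else:
        raise ValueError(f"unknown decay type: {decay!r}")
    return float(infl) if infl.ndim == 0 else infl


def _sensitivity_lookup(params: dict) -> tuple[np.ndarray, np.ndarray]:
    """(suitability[code], sensitivity[code, threat]) lookup arrays."""
    table = params["landcover"]
    max_code = max(table)
    suit = np.full(max_code + 1, np.nan)
    sens = np.full((max_code + 1, len(THREAT_NAMES)), np.nan)
    for code, spec in table.items():
        suit[code] = spec["suitability"]
        sens[code, :] = spec["sensitivity"]
    return suit, sens


def _threat_distances(layer: ThreatLayer, pixel_size: float) -> np.ndarray:
    """Euclidean pixel-center distance to the nearest presence pixel."""
    if not layer.presence.any():
        return np.full(layer.presence.shape, np.inf)
    return ndimage.distance_transform_edt(
        ~layer.presence, sampling=(pixel_size, pixel_size)
    )


def degradation(
    lulc: Raster, layers: list[ThreatLayer], params: dict | None = None
) -> Raster:
    """Per-pixel degradation D in [0, 1]; NaN on nodata pixels.

    Threat sources on nodata pixels still radiate influence; nodata
    pixels simply receive no score themselves.
    """
    if params is None:
        params = default_params()
    codes = np.asarray(lulc.data, dtype=float)
    valid = ~np.isnan(codes) & (codes != lulc.nodata)
    icodes = np.where(valid, codes, 1).astype(int)
    suit, sens = _sensitivity_lookup(params)
    known = np.isin(icodes[valid], list(params["landcover"]))
    if not known.all():
        bad = sorted(set(np.asarray(icodes[valid])[~known].tolist()))
        raise ValueError(f"unknown land-cover code(s): {bad}")
    total_weight = sum(layer.weight for layer in layers)
    if total_weight <= 0:
        raise ValueError("threat weights must sum to a positive value")
    d = np.zeros(lulc.shape, dtype=float)
    for r, layer in enumerate(layers):
        if layer.presence.shape != lulc.shape:
            raise ValueError(f"threat layer {layer.name!r} grid mismatch")
        dist = _threat_distances(layer, lulc.pixel_size)
        infl = decay_influence(np.where(np.isinf(dist), layer.max_distance + 1, dist),
                               layer.max_distance, layer.decay)
        d += (layer.weight / total_weight) * infl * sens[icodes, r]
    d = np.where(valid, d, np.nan)
    return lulc.like(d)


def quality(
    degradation_raster: Raster,
    lulc: Raster,
    params: dict | None = None,
    k: float | None = None,
    z: float | None = None,
) -> Raster:
    """Habitat quality Q = H * (1 - D^z / (D^z + k^z)), in [0, H]."""
    if params is None:
        params = default_params()
    if k is None:
        k = params["habitat_model"]["half_saturation"]
    if z is None:
        z = params["habitat_model"]["scaling_exponent"]
    if k <= 0:
        raise ValueError("half-saturation constant k must be positive")
    if not degradation_raster.same_grid(lulc):
        raise ValueError("degradation and LULC rasters are on different grids")
    suit, _ = _sensitivity_lookup(params)
    codes = np.asarray(lulc.data, dtype=float)
    valid = ~np.isnan(codes) & (codes != lulc.nodata)
    h = np.where(valid, suit[np.where(valid, codes, 1).astype(int)], np.nan)
    d = np.asarray(degradation_raster.data, dtype=float)
    dz = np.power(d, z, where=~np.isnan(d), out=np.full_like(d, np.nan))
    q = h * (1.0 - dz / (dz + k**z))
    return lulc.like(q)


def grade_quality(
    quality_raster: Raster, params: dict | None = None
) -> tuple[Raster, pd.DataFrame, float]:
    """Grade Q into five classes and tabulate areas.

    Intervals: very poor [0, 0.2), poor [0.2, 0.4), medium [0.4, 0.6),
    good [0.6, 0.8), excellent [0.8, 1] (upper bound closed). Returns
    the grade raster (codes 1..5, 0 on nodata), the per-grade area table
    (km^2 and percent of the non-nodata area) and the mean quality over
    non-nodata pixels.
    """
    if params is None:
        params = default_params()
    bounds = list(params["quality_grade_bounds"])  # lower bounds of the 5 grades
    q = np.asarray(quality_raster.data, dtype=float)
    valid = ~np.isnan(q)
    if valid.any() and (np.nanmin(q) < 0 or np.nanmax(q) > 1):
        raise ValueError("quality values must lie in [0, 1]")
    grade = np.zeros(q.shape, dtype=int)
    grade[valid] = np.digitize(q[valid], bounds[1:], right=False) + 1
    pixel_area_km2 = (quality_raster.pixel_size / 1000.0) ** 2
    n_valid = int(valid.sum())
    rows = []
    for code, label in enumerate(QUALITY_GRADE_LABELS, start=1):
        count = int((grade[valid] == code).sum())
        rows.append(
            {
                "grade": code,
                "label": label,
                "area_km2": count * pixel_area_km2,
                "percent": 100.0 * count / n_valid if n_valid else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    mean_q = float(np.nanmean(q)) if n_valid else np.nan
    grade_raster = Raster(
        data=np.where(valid, grade.astype(float), np.nan),
        x_origin=quality_raster.x_origin,
        y_origin=quality_raster.y_origin,
        pixel_size=quality_raster.pixel_size,
        nodata=quality_raster.nodata,
    )
    return grade_raster, table, mean_q


def percent_of_grades(area_table: pd.DataFrame, labels) -> float:
    """Sum the area-percent column over the named quality grades."""
    labels = set(labels)
    unknown = labels - set(area_table["label"])
    if unknown:
        raise KeyError(f"unknown grade label(s): {sorted(unknown)}")
    sel = area_table["label"].isin(labels)
    return float(area_table.loc[sel, "percent"].sum())
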