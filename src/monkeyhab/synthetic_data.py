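"""Synthetic landscape generator.

Builds the full set of inputs the analysis pipeline consumes — a patchy
multi-class land-cover raster, villages whose 30 socio-economic
indicators are driven by a single latent development factor, a road
network, a regular grid of square survey plots, and monkey-group range
polygons seeded in high-suitability forest — so that every downstream
stage can be exercised and validated without any external data.

Everything is deterministic for a fixed :class:`SceneConfig` seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Polygon, box
from shapely.ops import unary_union

from .params import default_params
from .raster import Raster

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "INDICATOR_CODES",
    "INVERSE_INDICATORS",
    "generate_lulc",
    "generate_villages",
    "generate_scene",
]


# ---------------------------------------------------------------------------
# Indicator schema: 30 socio-economic indicators in six categories.
# ---------------------------------------------------------------------------

#: Column codes in canonical order (natural resources, population,
#: economy, infrastructure, energy, education).
INDICATOR_CODES: tuple[str, ...] = (
    "X11", "X12", "X13", "X14", "X15", "X16",          # areas (km^2)
    "X21", "X22", "X23", "X24", "X25", "X26", "X27", "X28",  # people counts
    "X31", "X32", "X33", "X34", "X35", "X36",          # income (yuan)
    "X41", "X42",                                      # distances (km)
    "X43", "X44", "X45", "X46",                        # vehicle counts
    "X51", "X52",                                      # households
    "X61", "X62",                                      # enrollment rates (%)
)

#: Indicators that *decrease* with development: distance to the nearest
#: station/market and the out-of-school head count.
INVERSE_INDICATORS: frozenset[str] = frozenset({"X41", "X42", "X28"})

_COUNT_INDICATORS = frozenset(
    {"X21", "X22", "X23", "X24", "X25", "X26", "X27", "X28",
     "X43", "X44", "X45", "X46", "X51", "X52"}
)
_PERCENT_INDICATORS = frozenset({"X61", "X62"})

# Per-indicator (offset, scale) putting values on plausible ranges. Large
# scales keep integer rounding of counts a negligible perturbation.
_INDICATOR_BASE: dict[str, tuple[float, float]] = {}
for _code in INDICATOR_CODES:
    if _code in _PERCENT_INDICATORS:
        _INDICATOR_BASE[_code] = (80.0, 5.0)
    elif _code in _COUNT_INDICATORS:
        _INDICATOR_BASE[_code] = (400.0, 90.0)
    elif _code in ("X41", "X42"):
        _INDICATOR_BASE[_code] = (25.0, 6.0)
    elif _code.startswith("X3"):
        _INDICATOR_BASE[_code] = (10.0, 3.0)
    else:  # areas
        _INDICATOR_BASE[_code] = (4.0, 1.2)


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one synthetic landscape."""

    grid_shape: tuple[int, int] = (200, 200)
    pixel_size: float = 100.0
    class_proportions: dict[int, float] = field(
        default_factory=lambda: {
            1: 0.05, 2: 0.10, 3: 0.10, 4: 0.15, 5: 0.05, 6: 0.10, 7: 0.10,
            8: 0.05, 9: 0.02, 10: 0.08, 11: 0.12, 12: 0.05, 13: 0.02, 14: 0.01,
        }
    )
    n_villages: int = 200
    latent_sd: float = 1.0
    noise_sd: float = 0.3
    n_groups: int = 3
    plot_size: float = 2000.0  # square plots, 4 km^2
    smooth_sigma: float = 3.0  # pixels; patchiness of the land-cover field
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape entries must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_villages <= 0:
            raise ValueError("n_villages must be positive")
        if self.n_groups < 0:
            raise ValueError("n_groups must be non-negative")
        if self.plot_size <= 0:
            raise ValueError("plot_size must be positive")
        if self.latent_sd <= 0 or self.noise_sd < 0:
            raise ValueError("latent_sd must be positive and noise_sd non-negative")
        unknown = set(self.class_proportions) - set(range(1, 15))
        if unknown:
            raise ValueError(f"unknown land-cover code(s) in proportions: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")


@dataclass
class SyntheticScene:
    """All layers of one generated landscape."""

    config: SceneConfig
    lulc: Raster
    villages: pd.DataFrame       # INDICATOR_CODES columns + x, y, latent
    roads: list[LineString]
    plots: pd.DataFrame          # plot_id, x, y + 7 raw ecological indices
    groups: list[Polygon]
    group_codes: list[str]


def _suitability_lookup() -> np.ndarray:
    table = default_params()["landcover"]
    lut = np.zeros(15)
    for code, spec in table.items():
        lut[code] = spec["suitability"]
    return lut


def generate_lulc(config: SceneConfig) -> Raster:
    """Generate a patchy integer-coded land-cover raster.

    A Gaussian-smoothed white-noise field is rank-thresholded at the
    cumulative class proportions, which yields contiguous patches whose
    realized fractions track the requested ones to within ties.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    fld = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), config.smooth_sigma)
    order = np.argsort(fld, axis=None, kind="stable")
    codes = sorted(config.class_proportions)
    out = np.empty(rows * cols, dtype=np.int16)
    start = 0
    n = rows * cols
    cum = 0.0
    for i, code in enumerate(codes):
        cum += config.class_proportions[code]
        stop = n if i == len(codes) - 1 else int(round(cum * n))
        out[order[start:stop]] = code
        start = stop
    return Raster(
        data=out.reshape(rows, cols),
        x_origin=0.0,
        y_origin=rows * config.pixel_size,
        pixel_size=config.pixel_size,
        nodata=-9999,
    )


def generate_villages(config: SceneConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the 30-indicator village table from a latent factor.

    Each village draws a latent development factor ``f ~ N(0, latent_sd)``
    and each indicator is ``offset + scale * (a*f + eps)`` with loading
    ``a = +1`` (``-1`` for the inverse indicators) and
    ``eps ~ N(0, noise_sd)``. Count indicators are rounded to
    non-negative integers and percentage indicators clipped to [0, 100].
    The latent factor is kept in column ``latent`` as ground truth for
    recovery tests; it is not an indicator.
    """
    if config.n_villages < 2:
        raise ValueError("need at least 2 villages (PCA is undefined otherwise)")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = config.n_villages
    latent = rng.normal(0.0, config.latent_sd, size=n)
    data: dict[str, np.ndarray] = {}
    for code in INDICATOR_CODES:
        sign = -1.0 if code in INVERSE_INDICATORS else 1.0
        eps = rng.normal(0.0, config.noise_sd, size=n)
        offset, scale = _INDICATOR_BASE[code]
        raw = offset + scale * (sign * latent + eps)
        if code in _PERCENT_INDICATORS:
            raw = np.clip(raw, 0.0, 100.0)
        elif code in _COUNT_INDICATORS:
            raw = np.maximum(np.rint(raw), 0.0)
        else:
            raw = np.maximum(raw, 0.0)
        data[code] = raw
    frame = pd.DataFrame(data, columns=list(INDICATOR_CODES))
    frame["latent"] = latent
    return frame


def _place_villages(
    lulc: Raster, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample village locations preferring low-suitability pixels."""
    rows, cols = lulc.shape
    n_pix = rows * cols
    if n > n_pix:
        raise ValueError(f"grid of {n_pix} pixels cannot host {n} villages")
    suit = _suitability_lookup()[lulc.data.astype(int)]
    weight = (1.0 - suit).ravel() + 0.05  # floor keeps all-forest maps usable
    prob = weight / weight.sum()
    idx = rng.choice(n_pix, size=n, replace=False, p=prob)
    r, c = np.unravel_index(idx, (rows, cols))
    jitter_x = rng.uniform(-0.4, 0.4, size=n)
    jitter_y = rng.uniform(-0.4, 0.4, size=n)
    xs = lulc.x_origin + (c + 0.5 + jitter_x) * lulc.pixel_size
    ys = lulc.y_origin - (r + 0.5 + jitter_y) * lulc.pixel_size
    return xs, ys


def _build_roads(xs: np.ndarray, ys: np.ndarray) -> list[LineString]:
    """Connect each village to its nearest neighbour (deduplicated)."""
    from scipy.spatial import cKDTree

    pts = np.column_stack([xs, ys])
    tree = cKDTree(pts)
    _, nn = tree.query(pts, k=2)
    seen: set[tuple[int, int]] = set()
    roads = []
    for i, j in enumerate(nn[:, 1]):
        pair = (min(i, int(j)), max(i, int(j)))
        if pair in seen:
            continue
        seen.add(pair)
        roads.append(LineString([pts[pair[0]], pts[pair[1]]]))
    return roads


def _build_plot_grid(config: SceneConfig, lulc: Raster, rng: np.random.Generator) -> pd.DataFrame:
    rows, cols = lulc.shape
    extent_x = cols * lulc.pixel_size
    extent_y = rows * lulc.pixel_size
    nx = int(extent_x // config.plot_size)
    ny = int(extent_y // config.plot_size)
    records = []
    pid = 0
    for iy in range(ny):
        for ix in range(nx):
            cx = lulc.x_origin + (ix + 0.5) * config.plot_size
            cy = lulc.y_origin - (iy + 0.5) * config.plot_size
            records.append(
                {
                    "plot_id": pid,
                    "x": cx,
                    "y": cy,
                    "forest_naturalness": int(rng.integers(1, 6)),
                    "community_structure": int(rng.integers(1, 4)),
                    "tree_species_structure": int(rng.integers(1, 8)),
                    "vegetation_coverage": float(rng.uniform(0.0, 100.0)),
                    "crown_density": float(rng.uniform(0.2, 1.0)),
                    "tree_height": float(rng.uniform(0.9, 30.0)),
                    "litter_depth": int(rng.integers(1, 4)),
                }
            )
            pid += 1
    return pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["plot_id", "x", "y", "forest_naturalness", "community_structure",
                 "tree_species_structure", "vegetation_coverage", "crown_density",
                 "tree_height", "litter_depth"]
    )


def _grow_group(
    lulc: Raster, suit: np.ndarray, seed_rc: tuple[int, int], target: int,
) -> Polygon:
    """Region-grow a connected blob over suitable (H > 0) pixels."""
    rows, cols = lulc.shape
    visited = {seed_rc}
    frontier = [seed_rc]
    while frontier and len(visited) < target:
        nxt = []
        for r, c in frontier:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and (rr, cc) not in visited:
                    if suit[rr, cc] > 0:
                        visited.add((rr, cc))
                        nxt.append((rr, cc))
                        if len(visited) >= target:
                            break
            if len(visited) >= target:
                break
        frontier = nxt
    px = lulc.pixel_size
    boxes = [
        box(
            lulc.x_origin + c * px,
            lulc.y_origin - (r + 1) * px,
            lulc.x_origin + (c + 1) * px,
            lulc.y_origin - r * px,
        )
        for r, c in visited
    ]
    geom = unary_union(boxes)
    if geom.geom_type == "MultiPolygon":  # union of boxes of a connected set is one part
        geom = max(geom.geoms, key=lambda g: g.area)
    return geom


def _build_groups(
    config: SceneConfig, lulc: Raster, rng: np.random.Generator
) -> tuple[list[Polygon], list[str]]:
    if config.n_groups == 0:
        return [], []
    suit = _suitability_lookup()[lulc.data.astype(int)]
    high = np.argwhere(suit >= 0.8)
    if high.size == 0:
        high = np.argwhere(suit > 0)
    if high.size == 0:
        raise ValueError("no suitable habitat pixels to seed monkey groups")
    rows, cols = lulc.shape
    target = max(9, (rows * cols) // 400)
    order = rng.permutation(len(high))
    polys, codes = [], []
    for k in range(config.n_groups):
        seed_rc = tuple(high[order[k % len(high)]])
        polys.append(_grow_group(lulc, suit, seed_rc, target))
        codes.append(f"C{k + 1}")
    return polys, codes


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Assemble a full synthetic landscape from one configuration."""
    lulc = generate_lulc(config)
    rng = np.random.default_rng(config.seed + 1)
    villages = generate_villages(config, rng=rng)
    xs, ys = _place_villages(lulc, config.n_villages, rng)
    villages = villages.copy()
    villages["x"] = xs
    villages["y"] = ys
    roads = _build_roads(xs, ys)
    plots = _build_plot_grid(config, lulc, rng)
    groups, group_codes = _build_groups(config, lulc, rng)
    return SyntheticScene(
        config=config,
        lulc=lulc,
        villages=villages,
        roads=roads,
        plots=plots,
        groups=groups,
        group_codes=group_codes,
    )
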