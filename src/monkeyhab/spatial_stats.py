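"""Spatial statistics on the habitat-quality surface.

Global Moran's I (permutation + analytic inference), Getis-Ord Gi*
hot-spot z-scores with a five-class labelling, block aggregation of the
quality raster into analysis units with queen contiguity, and zonal mean
quality over monkey-group range polygons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import sparse, stats

from .raster import Raster

__all__ = [
    "aggregate_to_units",
    "queen_adjacency",
    "row_standardize",
    "add_self_neighbors",
    "MoranResult",
    "morans_i",
    "gi_star",
    "classify_hotspots",
    "HOTSPOT_LABELS",
    "zonal_mean",
    "summarize_groups",
]

logger = logging.getLogger(__name__)

HOTSPOT_LABELS: tuple[str, ...] = ("cold", "sub-cold", "not significant", "sub-hot", "hot")


def aggregate_to_units(
    q: Raster, unit_size: int
) -> tuple[np.ndarray, sparse.csr_matrix, np.ndarray]:
    """Mean Q per square block of pixels, with queen adjacency.

    Returns ``(values, weights, block_rc)`` where ``values[i]`` is the
    NaN-ignoring mean of block ``i``, ``weights`` is the binary queen
    contiguity matrix among retained blocks, and ``block_rc`` holds each
    block's (row, col) position in the block grid. Blocks that are
    entirely nodata are dropped.
    """
    if unit_size < 1:
        raise ValueError("unit_size must be >= 1")
    data = np.asarray(q.data, dtype=float)
    rows, cols = data.shape
    brows = int(np.ceil(rows / unit_size))
    bcols = int(np.ceil(cols / unit_size))
    values = np.full((brows, bcols), np.nan)
    for br in range(brows):
        for bc in range(bcols):
            block = data[
                br * unit_size : (br + 1) * unit_size,
                bc * unit_size : (bc + 1) * unit_size,
            ]
            if np.isnan(block).all():
                continue
            values[br, bc] = np.nanmean(block)
    keep = ~np.isnan(values)
    block_rc = np.argwhere(keep)
    vals = values[keep]
    w = queen_adjacency(block_rc)
    return vals, w, block_rc


def queen_adjacency(block_rc: np.ndarray) -> sparse.csr_matrix:
    """Binary queen (8-neighbour) contiguity for a set of grid cells."""
    index = {tuple(rc): i for i, rc in enumerate(map(tuple, block_rc))}
    rows_idx, cols_idx = [], []
    for (r, c), i in index.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    rows_idx.append(i)
                    cols_idx.append(j)
    n = len(index)
    return sparse.csr_matrix(
        (np.ones(len(rows_idx)), (rows_idx, cols_idx)), shape=(n, n)
    )


def row_standardize(w: sparse.spmatrix) -> sparse.csr_matrix:
    w = sparse.csr_matrix(w, dtype=float)
    rs = np.asarray(w.sum(axis=1)).ravel()
    rs[rs == 0] = 1.0
    return sparse.diags(1.0 / rs) @ w


def add_self_neighbors(w: sparse.spmatrix) -> sparse.csr_matrix:
    """Gi* variant: each unit is its own neighbour."""
    w = sparse.csr_matrix(w, dtype=float)
    return (w + sparse.identity(w.shape[0], format="csr")).tocsr()


@dataclass
class MoranResult:
    i: float
    expected: float
    z_norm: float
    p_norm: float
    p_sim: float | None
    permutations: int


def _moran_stat(z: np.ndarray, w: sparse.csr_matrix, s0: float) -> float:
    return float(len(z) / s0 * (z @ (w @ z)) / (z @ z))


def morans_i(
    values: np.ndarray,
    w: sparse.spmatrix,
    permutations: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with permutation and normal-approximation inference.

    ``I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with deviations
    ``z`` from the mean; ``E[I] = -1/(n-1)``. The permutation p-value is
    two-sided around E[I]; the analytic z/p use the normality variance.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Moran's I needs at least 4 units")
    if np.std(x) == 0:
        raise ValueError("values have zero variance")
    w = sparse.csr_matrix(w, dtype=float)
    if w.diagonal().any():
        raise ValueError("Moran's I weights must have a zero diagonal")
    s0 = float(w.sum())
    z = x - x.mean()
    i_obs = _moran_stat(z, w, s0)
    e_i = -1.0 / (n - 1)
    # normality-assumption variance
    wt = w.T.tocsr()
    s1 = 0.5 * float(((w + wt).power(2)).sum())
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(((row + col) ** 2).sum())
    var_norm = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - e_i**2
    z_norm = (i_obs - e_i) / np.sqrt(var_norm)
    p_norm = 2.0 * stats.norm.sf(abs(z_norm))
    p_sim = None
    if permutations and permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            zp = rng.permutation(z)
            if abs(_moran_stat(zp, w, s0) - e_i) >= abs(i_obs - e_i):
                count += 1
        p_sim = (count + 1) / (permutations + 1)
    return MoranResult(
        i=i_obs, expected=e_i, z_norm=float(z_norm), p_norm=float(p_norm),
        p_sim=p_sim, permutations=int(permutations or 0),
    )


def gi_star(values: np.ndarray, w: sparse.spmatrix) -> np.ndarray:
    """Getis-Ord Gi* z-scores; ``w`` must include self-neighbours.

    ``Gi* = [sum_j w_ij x_j - xbar sum_j w_ij] /
    (S * sqrt((n sum_j w_ij^2 - (sum_j w_ij)^2) / (n - 1)))`` with the
    global mean and (population) standard deviation.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Gi* needs at least 4 units")
    s = np.sqrt((x**2).mean() - x.mean() ** 2)
    if s == 0:
        raise ValueError("values have zero variance")
    w = sparse.csr_matrix(w, dtype=float)
    wx = w @ x
    sw = np.asarray(w.sum(axis=1)).ravel()
    sw2 = np.asarray(w.power(2).sum(axis=1)).ravel()
    num = wx - x.mean() * sw
    inner = (n * sw2 - sw**2) / (n - 1)
    den = s * np.sqrt(np.maximum(inner, 0.0))
    out = np.zeros(n)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def classify_hotspots(z: np.ndarray) -> np.ndarray:
    """Label Gi* z-scores: hot >= 2.58, sub-hot >= 1.96, cold <= -2.58,
    sub-cold <= -1.96, otherwise not significant."""
    z = np.asarray(z, dtype=float)
    if np.isnan(z).any():
        raise ValueError("Gi* z-scores contain NaN")
    labels = np.full(z.shape, "not significant", dtype=object)
    labels[z >= 1.96] = "sub-hot"
    labels[z >= 2.58] = "hot"
    labels[z <= -1.96] = "sub-cold"
    labels[z <= -2.58] = "cold"
    return labels


def zonal_mean(q: Raster, polygons, codes=None) -> tuple[pd.DataFrame, dict]:
    """Mean quality over pixels whose centers fall inside each polygon.

    Returns the per-group table (code, mean, pixel count) and the
    cross-group summary from :func:`summarize_groups`. A polygon
    covering no valid pixel is reported with a NaN mean and a warning.
    """
    polygons = list(polygons)
    if codes is None:
        codes = [f"C{i + 1}" for i in range(len(polygons))]
    xs, ys = q.cell_centers()
    data = np.asarray(q.data, dtype=float)
    valid = ~np.isnan(data)
    records = []
    for code, poly in zip(codes, polygons):
        inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(q.shape)
        sel = inside & valid
        n_pix = int(sel.sum())
        if n_pix == 0:
            logger.warning("group %s covers no valid pixels; reported as missing", code)
            records.append({"code": code, "mean_quality": np.nan, "n_pixels": 0})
        else:
            records.append(
                {"code": code, "mean_quality": float(data[sel].mean()), "n_pixels": n_pix}
            )
    table = pd.DataFrame.from_records(records, columns=["code", "mean_quality", "n_pixels"])
    present = table.dropna(subset=["mean_quality"])
    summary = summarize_groups(dict(zip(present["code"], present["mean_quality"])))
    return table, summary


def summarize_groups(group_values: dict[str, float]) -> dict:
    """Cross-group summary of per-group habitat-quality values.

    Returns the arithmetic mean over groups, the maximum and minimum
    with their group codes, and the group count.
    """
    if not group_values:
        return {"n_groups": 0, "mean": np.nan, "max": np.nan, "max_code": None,
                "min": np.nan, "min_code": None}
    codes = list(group_values)
    vals = np.array([group_values[c] for c in codes], dtype=float)
    i_max = int(np.argmax(vals))
    i_min = int(np.argmin(vals))
    return {
        "n_groups": len(codes),
        "mean": float(vals.mean()),
        "max": float(vals[i_max]),
        "max_code": codes[i_max],
        "min": float(vals[i_min]),
        "min_code": codes[i_min],
    }
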