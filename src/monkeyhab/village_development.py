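"""Village development scoring and mapping.

Pipeline: standardize the 30 socio-economic indicators, run a
correlation-matrix PCA retaining components with eigenvalue > 1
(Kaiser), combine the retained component scores into a composite
development score ``Z`` with variance-explained weights, bin ``Z`` into
grades I-VII, and render the village agglomeration pattern as a quartic
kernel-density surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster

__all__ = [
    "PCAResult",
    "standardize_indicators",
    "fit_pca",
    "comprehensive_score",
    "grade_villages",
    "VILLAGE_GRADES",
    "kernel_density",
]

logger = logging.getLogger(__name__)

#: Development grades from least (I) to most (VII) developed.
VILLAGE_GRADES: tuple[str, ...] = ("I", "II", "III", "IV", "V", "VI", "VII")

#: Lower bounds of grades II..VII; scores below the first bound are grade I.
DEFAULT_GRADE_BOUNDS: tuple[float, ...] = (-0.5, 0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass
class PCAResult:
    """Correlation-matrix PCA with Kaiser retention.

    ``eigenvalues`` holds the full spectrum (descending); ``loadings``
    (p x k) and ``scores`` (n x k) cover only the ``n_retained``
    components with eigenvalue > 1. ``weights`` are the retained
    eigenvalues normalized to sum to 1.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    n_retained: int
    weights: np.ndarray
    columns: list[str]


def standardize_indicators(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median-impute, drop constant columns, and z-score each column.

    Uses the sample standard deviation (n-1 denominator). Constant
    columns carry no correlation information and are dropped with a
    logged warning; if every column is constant this raises.
    """
    m = matrix.apply(pd.to_numeric).astype(float)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    if m.isna().any().any():
        m = m.fillna(m.median())
    std = m.std(ddof=1)
    constant = std[(std == 0) | std.isna()].index.tolist()
    if constant:
        if len(constant) == m.shape[1]:
            raise ValueError("all indicator columns are constant")
        logger.warning("dropping constant indicator column(s): %s", constant)
        m = m.drop(columns=constant)
        std = std.drop(constant)
    return (m - m.mean()) / std


def fit_pca(standardized: pd.DataFrame, min_retain: int | None = None) -> PCAResult:
    """Eigen-decompose the correlation matrix and retain by Kaiser rule.

    Parameters
    ----------
    standardized : DataFrame
        Output of :func:`standardize_indicators`.
    min_retain : int, optional
        Floor on the retained component count, for degenerate inputs
        where no eigenvalue exceeds 1.

    Notes
    -----
    Loading columns are unit-norm eigenvectors, sign-oriented so that
    each column's largest-magnitude entry is positive (PCA signs are
    otherwise arbitrary and would break run-to-run determinism).
    """
    x = standardized.to_numpy(dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    corr = (x.T @ x) / (n - 1)  # correlation matrix: columns are z-scored
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # tolerance absorbs float noise: exactly-uncorrelated columns give
    # eigenvalues of 1 +- a few ulp, which Kaiser must not retain
    k = int(np.sum(eigvals > 1.0 + 1e-9))
    if k < 1:
        if min_retain is None:
            raise ValueError(
                "no eigenvalue exceeds 1 (Kaiser retains nothing); "
                "pass min_retain=1 to fall back to the first component"
            )
        k = max(1, min_retain)
    elif min_retain is not None:
        k = max(k, min_retain)
    load = eigvecs[:, :k].copy()
    flip = load[np.argmax(np.abs(load), axis=0), np.arange(k)] < 0
    load[:, flip] *= -1.0
    scores = x @ load
    weights = eigvals[:k] / eigvals[:k].sum()
    return PCAResult(
        eigenvalues=eigvals,
        loadings=load,
        scores=scores,
        n_retained=k,
        weights=weights,
        columns=list(standardized.columns),
    )


def comprehensive_score(pca: PCAResult) -> np.ndarray:
    """Composite development score Z: variance-weighted sum of scores.

    ``Z_i = sum_c weight_c * score_ic``; has mean 0 across villages
    because each component score is centred.
    """
    if pca.n_retained < 1:
        raise ValueError("no retained components")
    return pca.scores @ pca.weights


def grade_villages(
    z: np.ndarray, bounds: tuple[float, ...] = DEFAULT_GRADE_BOUNDS
) -> np.ndarray:
    """Assign development grades I-VII from composite scores.

    Bins are half-open upward: grade I is (-inf, b0), grade II is
    [b0, b1), ..., grade VII is [b5, +inf), so every finite score maps
    to exactly one grade and boundary scores go to the higher grade.
    """
    z = np.asarray(z, dtype=float)
    if np.isnan(z).any():
        raise ValueError("composite scores contain NaN")
    idx = np.digitize(z, bounds, right=False)
    return np.array(VILLAGE_GRADES)[idx]


def kernel_density(
    points: np.ndarray,
    grid: Raster,
    bandwidth: float | None = None,
    weights: np.ndarray | None = None,
) -> Raster:
    """Quartic (biweight) kernel density surface on a raster grid.

    Each point contributes ``w * 3/(pi*h^2) * (1 - (d/h)^2)^2`` within
    radius ``h`` of its location, so the surface integrates to the total
    weight (up to grid discretisation and edge clipping).

    Parameters
    ----------
    points : (n, 2) array of x, y coordinates.
    grid : Raster whose geometry defines the output surface.
    bandwidth : kernel radius in map units; default is 1/30 of the
        larger grid extent.
    weights : optional per-point weights (default 1).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    out = np.zeros(grid.shape, dtype=float)
    if pts.shape[0] == 0:
        logger.warning("kernel_density called with no points; returning zero surface")
        return grid.like(out)
    if bandwidth is None:
        rows, cols = grid.shape
        bandwidth = max(rows, cols) * grid.pixel_size / 30.0
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    w = np.ones(pts.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    if w.shape[0] != pts.shape[0]:
        raise ValueError("weights length does not match points")
    rows, cols = grid.shape
    px = grid.pixel_size
    norm = 3.0 / (np.pi * bandwidth**2)
    reach = int(np.ceil(bandwidth / px)) + 1
    for (x, y), wi in zip(pts, w):
        r0, c0 = grid.index_of(x, y)
        rlo, rhi = max(0, r0 - reach), min(rows, r0 + reach + 1)
        clo, chi = max(0, c0 - reach), min(cols, c0 + reach + 1)
        if rlo >= rhi or clo >= chi:
            continue
        cx = grid.x_origin + (np.arange(clo, chi) + 0.5) * px
        cy = grid.y_origin - (np.arange(rlo, rhi) + 0.5) * px
        d2 = (cx[None, :] - x) ** 2 + (cy[:, None] - y) ** 2
        u2 = d2 / bandwidth**2
        mask = u2 < 1.0
        out[rlo:rhi, clo:chi] += np.where(mask, wi * norm * (1.0 - u2) ** 2, 0.0)
    return grid.like(out)
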