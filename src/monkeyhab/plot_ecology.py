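"""Survey-plot ecological quality scoring.

Each square plot carries seven forest-condition indices. Every index is
classified into type I/II/III (scored 1/2/3; lower is better) against
the shipped classification criteria, and the composite ecological score
is the weighted sum ``Y = sum_i W_i * X_i`` with the shipped expert
weights. ``Y`` in [1, 3] is then binned into four ecological grades.

Also provides the distance-threshold estimator used to set threat reach:
the distance beyond which plot quality no longer correlates with
distance to a disturbance feature.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from shapely.geometry import Point
from shapely.strtree import STRtree

from .params import default_params

__all__ = [
    "PLOT_INDEX_ORDER",
    "classify_index",
    "classify_plot",
    "plot_quality",
    "grade_plot",
    "PLOT_GRADE_LABELS",
    "threat_distance_threshold",
]

logger = logging.getLogger(__name__)

#: Canonical index order (matches the shipped weight table).
PLOT_INDEX_ORDER: tuple[str, ...] = (
    "forest_naturalness",
    "community_structure",
    "tree_species_structure",
    "vegetation_coverage",
    "crown_density",
    "tree_height",
    "litter_depth",
)

PLOT_GRADE_LABELS: dict[int, str] = {1: "excellent", 2: "good", 3: "medium", 4: "poor"}


def _default_criteria() -> dict:
    return default_params()["plot_criteria"]


def classify_index(index_name: str, raw_value, criteria: Mapping | None = None) -> int:
    """Type-score one evaluation index: 1, 2 or 3 (I/II/III).

    Categorical indices match code sets; numeric indices match the
    left-closed intervals of the criteria table. A numeric value falling
    outside every listed interval (e.g. crown density below 0.2) is
    scored type III with a warning.
    """
    crit = (criteria or _default_criteria()).get(index_name)
    if crit is None:
        raise KeyError(f"unknown evaluation index: {index_name!r}")
    if crit["kind"] == "categorical":
        code = int(raw_value)
        for score, codes in crit["classes"].items():
            if code in codes:
                return int(score)
        logger.warning(
            "%s=%r matches no class; scored type III", index_name, raw_value
        )
        return 3
    value = float(raw_value)
    for iv in crit["intervals"]:
        lo, hi = iv["lo"], iv["hi"]
        if value < lo:
            continue
        if hi is None or value < hi or (iv.get("hi_closed") and value == hi):
            return int(iv["score"])
    logger.warning(
        "%s=%r outside all intervals; scored type III", index_name, raw_value
    )
    return 3


def classify_plot(raw: Mapping[str, object], criteria: Mapping | None = None) -> dict[str, int]:
    """Type-score all seven indices of one plot record."""
    crit = criteria or _default_criteria()
    return {name: classify_index(name, raw[name], crit) for name in PLOT_INDEX_ORDER}


def plot_quality(
    type_scores: Sequence[int] | Mapping[str, int],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Composite ecological score Y = sum_i W_i * X_i (lower is better)."""
    if weights is None:
        weights = default_params()["plot_weights"]
    if isinstance(type_scores, Mapping):
        scores = [type_scores[name] for name in PLOT_INDEX_ORDER]
    else:
        scores = list(type_scores)
    if len(scores) != len(PLOT_INDEX_ORDER):
        raise ValueError(f"expected {len(PLOT_INDEX_ORDER)} type scores, got {len(scores)}")
    for s in scores:
        if s not in (1, 2, 3):
            raise ValueError(f"type scores must be 1, 2 or 3; got {s!r}")
    return float(
        sum(weights[name] * s for name, s in zip(PLOT_INDEX_ORDER, scores))
    )


def grade_plot(y: float, bounds: Sequence[float] | None = None) -> int:
    """Ecological grade code from Y: 1 excellent .. 4 poor.

    Boundaries: excellent Y < 1.4; good [1.4, 1.8); medium [1.8, 2.2];
    poor Y > 2.2. The 2.2 boundary closes the medium grade because the
    poor grade is defined strictly above it.
    """
    if bounds is None:
        bounds = default_params()["plot_grade_bounds"]
    b_good, b_medium, b_poor = bounds
    y = float(y)
    if np.isnan(y):
        raise ValueError("plot score is NaN")
    if y < b_good:
        return 1
    if y < b_medium:
        return 2
    if y <= b_poor:
        return 3
    return 4


def threat_distance_threshold(
    plot_xy: np.ndarray,
    plot_scores: np.ndarray,
    features: Sequence,
    max_search: float = 10_000.0,
    bin_width: float = 500.0,
    alpha: float = 0.05,
) -> float:
    """Estimate a threat's maximum effective distance from plot scores.

    For each plot, the distance to the nearest disturbance feature is
    computed; the distance axis is then swept in ``bin_width`` steps and
    the Pearson correlation between plot score Y and distance is tested
    within each successive distance band. The returned threshold is the
    near edge-distance at which the correlation first stops being
    significant at ``alpha`` — i.e. the reach beyond which the feature no
    longer measurably degrades plots. If the correlation stays
    significant throughout, ``max_search`` is returned with a warning.

    Bands with fewer than 3 plots cannot support a correlation test and
    are treated as non-significant.
    """
    xy = np.asarray(plot_xy, dtype=float).reshape(-1, 2)
    y = np.asarray(plot_scores, dtype=float)
    if xy.shape[0] < 10:
        raise ValueError("need at least 10 plots to estimate a distance threshold")
    if bin_width <= 0 or max_search <= 0:
        raise ValueError("bin_width and max_search must be positive")
    feats = list(features)
    if not feats:
        logger.warning("no features supplied; returning max_search")
        return float(max_search)
    tree = STRtree(feats)
    pts = [Point(p) for p in xy]
    nearest = tree.nearest(pts)
    dist = np.array([pts[i].distance(feats[j]) for i, j in enumerate(np.atleast_1d(nearest))])
    edges = np.arange(bin_width, max_search + bin_width / 2, bin_width)
    for i, edge in enumerate(edges):
        lo = edges[i - 1] if i else 0.0
        sel = (dist > lo) & (dist <= edge) if i else (dist <= edge)
        if sel.sum() < 3 or np.std(y[sel]) == 0 or np.std(dist[sel]) == 0:
            return float(edge)
        _, p = stats.pearsonr(y[sel], dist[sel])
        if p >= alpha:
            return float(edge)
    logger.warning(
        "correlation remained significant out to max_search=%g; returning it", max_search
    )
    return float(max_search)
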