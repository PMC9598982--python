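"""Default parameter tables and YAML override loading.

The shipped defaults are the published coefficient tables of the study:
threat factor attributes (12 threats), land-cover suitability/sensitivity
(14 classes), plot evaluation weights and classification criteria, and
the grade intervals for villages, plots and habitat quality. Every table
can be overridden from a YAML file; overrides are schema-validated.
"""

from __future__ import annotations

import copy
import hashlib
import json
from typing import Any, Mapping

import yaml

__all__ = [
    "THREAT_NAMES",
    "default_params",
    "load_params",
    "param_hash",
    "ParameterError",
]


class ParameterError(ValueError):
    """A parameter override failed validation; the message names the field."""


#: Canonical threat ordering (village grades I-VII, road, then land-derived).
THREAT_NAMES: tuple[str, ...] = (
    "village_i",
    "village_ii",
    "village_iii",
    "village_iv",
    "village_v",
    "village_vi",
    "village_vii",
    "village_road",
    "other_nonforest",
    "economic_forest",
    "cropland",
    "artificial_construction",
)

# Threat attributes: maximum effective distance (km), weight, decay type.
_THREATS = {
    "village_i": {"max_distance_km": 2.0, "weight": 0.4, "decay": "exponential"},
    "village_ii": {"max_distance_km": 2.0, "weight": 0.5, "decay": "exponential"},
    "village_iii": {"max_distance_km": 2.0, "weight": 0.6, "decay": "exponential"},
    "village_iv": {"max_distance_km": 2.0, "weight": 0.7, "decay": "exponential"},
    "village_v": {"max_distance_km": 2.0, "weight": 0.8, "decay": "exponential"},
    "village_vi": {"max_distance_km": 2.0, "weight": 0.9, "decay": "exponential"},
    "village_vii": {"max_distance_km": 2.0, "weight": 0.95, "decay": "exponential"},
    "village_road": {"max_distance_km": 4.0, "weight": 0.7, "decay": "linear"},
    "other_nonforest": {"max_distance_km": 1.0, "weight": 0.6, "decay": "exponential"},
    "economic_forest": {"max_distance_km": 1.0, "weight": 0.7, "decay": "exponential"},
    "cropland": {"max_distance_km": 1.0, "weight": 0.5, "decay": "exponential"},
    "artificial_construction": {"max_distance_km": 3.0, "weight": 0.8, "decay": "exponential"},
}

# Land-cover classes: name, habitat suitability, sensitivity to each threat
# (sensitivities listed in THREAT_NAMES order).
_LANDCOVER = {
    1: {"name": "other non-forest land", "suitability": 0.0,
        "sensitivity": [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]},
    2: {"name": "cold coniferous forest", "suitability": 0.6,
        "sensitivity": [0.7, 0.75, 0.8, 0.9, 0.9, 0.9, 0.9, 0.95, 0.4, 0.3, 0.4, 0.8]},
    3: {"name": "shrublands", "suitability": 0.8,
        "sensitivity": [0.3, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3, 0.5, 0.3, 0.4, 0.8]},
    4: {"name": "Armand pine and hemlock", "suitability": 1.0,
        "sensitivity": [0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.5, 0.4, 0.5, 0.9]},
    5: {"name": "barren land", "suitability": 0.2,
        "sensitivity": [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.2, 0.1, 0.1, 0.2]},
    6: {"name": "broad-leaved forests", "suitability": 0.6,
        "sensitivity": [0.6, 0.6, 0.6, 0.6, 0.7, 0.7, 0.8, 0.9, 0.4, 0.3, 0.4, 0.8]},
    7: {"name": "cropland", "suitability": 0.0,
        "sensitivity": [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]},
    8: {"name": "planted economic forests", "suitability": 0.0,
        "sensitivity": [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]},
    9: {"name": "water body", "suitability": 0.2,
        "sensitivity": [0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 0.3, 0.4, 0.2, 0.1, 0.1, 0.2]},
    10: {"name": "sclerophyllous evergreen broad-leaved forest", "suitability": 0.8,
         "sensitivity": [0.7, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.5, 0.3, 0.4, 0.8]},
    11: {"name": "fir-spruce forest", "suitability": 1.0,
         "sensitivity": [0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.5, 0.4, 0.5, 0.9]},
    12: {"name": "warm coniferous forest", "suitability": 0.2,
         "sensitivity": [0.3, 0.3, 0.3, 0.3, 0.4, 0.4, 0.4, 0.4, 0.2, 0.3, 0.1, 0.2]},
    13: {"name": "coniferous broad-leaved mixed forest", "suitability": 1.0,
         "sensitivity": [0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.85, 0.85, 0.5, 0.4, 0.5, 0.9]},
    14: {"name": "artificial construction", "suitability": 0.0,
         "sensitivity": [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]},
}

#: LULC code feeding each land-derived threat's presence layer.
LANDCOVER_THREAT_SOURCES = {
    "other_nonforest": 1,
    "economic_forest": 8,
    "cropland": 7,
    "artificial_construction": 14,
}

# Plot evaluation: index weights and I/II/III classification criteria.
_PLOT_WEIGHTS = {
    "forest_naturalness": 0.19,
    "community_structure": 0.18,
    "tree_species_structure": 0.17,
    "vegetation_coverage": 0.14,
    "crown_density": 0.13,
    "tree_height": 0.13,
    "litter_depth": 0.06,
}

_PLOT_CRITERIA = {
    "forest_naturalness": {"kind": "categorical", "classes": {1: [1, 2], 2: [3, 4], 3: [5]}},
    "community_structure": {"kind": "categorical", "classes": {1: [1], 2: [2], 3: [3]}},
    "tree_species_structure": {"kind": "categorical", "classes": {1: [6, 7], 2: [3, 4, 5], 3: [1, 2]}},
    # numeric intervals [lo, hi); hi_closed marks a closed upper bound
    "vegetation_coverage": {"kind": "interval", "intervals": [
        {"score": 1, "lo": 70.0, "hi": 100.0, "hi_closed": True},
        {"score": 2, "lo": 50.0, "hi": 70.0},
        {"score": 3, "lo": 0.0, "hi": 50.0},
    ]},
    "crown_density": {"kind": "interval", "intervals": [
        {"score": 1, "lo": 0.7, "hi": 1.0, "hi_closed": True},
        {"score": 2, "lo": 0.4, "hi": 0.7},
        {"score": 3, "lo": 0.2, "hi": 0.4},
    ]},
    "tree_height": {"kind": "interval", "intervals": [
        {"score": 1, "lo": 15.0, "hi": None},
        {"score": 2, "lo": 5.0, "hi": 15.0},
        {"score": 3, "lo": 0.9, "hi": 5.0},
    ]},
    "litter_depth": {"kind": "categorical", "classes": {1: [1], 2: [2], 3: [3]}},
}

# Grade intervals. Lower bounds of half-open [lo, next_lo) bins except as
# noted in the grading functions.
_VILLAGE_GRADE_BOUNDS = [-0.5, 0.0, 0.5, 1.0, 1.5, 2.0]  # I..VII
_PLOT_GRADE_BOUNDS = [1.4, 1.8, 2.2]  # excellent < 1.4 ... poor > 2.2
_QUALITY_GRADE_BOUNDS = [0.0, 0.2, 0.4, 0.6, 0.8]  # very poor .. excellent

_HABITAT_MODEL = {
    "half_saturation": 0.5,   # k
    "scaling_exponent": 2.5,  # z
}


def default_params() -> dict[str, Any]:
    """A deep copy of the full shipped parameter set."""
    return copy.deepcopy(
        {
            "threats": _THREATS,
            "landcover": _LANDCOVER,
            "plot_weights": _PLOT_WEIGHTS,
            "plot_criteria": _PLOT_CRITERIA,
            "village_grade_bounds": _VILLAGE_GRADE_BOUNDS,
            "plot_grade_bounds": _PLOT_GRADE_BOUNDS,
            "quality_grade_bounds": _QUALITY_GRADE_BOUNDS,
            "habitat_model": _HABITAT_MODEL,
        }
    )


def _merge(base: dict, override: Mapping) -> dict:
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _merge(base[key], value)
        else:
            base[key] = copy.deepcopy(value)
    return base


def _check(cond: bool, field: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{field}: {msg}")


def validate_params(params: Mapping[str, Any]) -> None:
    n_threats = len(params["threats"])
    for name, spec in params["threats"].items():
        _check(0 < spec["weight"] <= 1, f"threats.{name}.weight", "must be in (0, 1]")
        _check(spec["max_distance_km"] > 0, f"threats.{name}.max_distance_km", "must be positive")
        _check(
            spec["decay"] in {"exponential", "linear"},
            f"threats.{name}.decay",
            "must be 'exponential' or 'linear'",
        )
    for code, spec in params["landcover"].items():
        _check(
            0 <= spec["suitability"] <= 1,
            f"landcover.{code}.suitability",
            "must be in [0, 1]",
        )
        _check(
            len(spec["sensitivity"]) == n_threats,
            f"landcover.{code}.sensitivity",
            f"needs {n_threats} entries (one per threat)",
        )
        for i, s in enumerate(spec["sensitivity"]):
            _check(0 <= s <= 1, f"landcover.{code}.sensitivity[{i}]", "must be in [0, 1]")
    wsum = sum(params["plot_weights"].values())
    _check(abs(wsum - 1.0) <= 1e-9, "plot_weights", f"must sum to 1, got {wsum}")
    for name, w in params["plot_weights"].items():
        _check(0 < w <= 1, f"plot_weights.{name}", "must be in (0, 1]")
    hm = params["habitat_model"]
    _check(hm["half_saturation"] > 0, "habitat_model.half_saturation", "must be positive")
    _check(hm["scaling_exponent"] > 0, "habitat_model.scaling_exponent", "must be positive")
    for key in ("village_grade_bounds", "plot_grade_bounds", "quality_grade_bounds"):
        bounds = list(params[key])
        _check(bounds == sorted(bounds), key, "must be non-decreasing")


def load_params(path=None) -> dict[str, Any]:
    """Load the parameter set, merging YAML overrides onto the defaults.

    An absent or empty file yields the full defaults. Any overridden
    value is validated; a violation raises :class:`ParameterError`
    naming the offending field.
    """
    params = default_params()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh)
        if override is not None:
            if not isinstance(override, Mapping):
                raise ParameterError("top level: expected a mapping of parameter tables")
            unknown = set(override) - set(params)
            if unknown:
                raise ParameterError(f"unknown parameter table(s): {sorted(unknown)}")
            # YAML integer keys for landcover codes may arrive as strings
            if "landcover" in override and isinstance(override["landcover"], Mapping):
                override = dict(override)
                override["landcover"] = {int(k): v for k, v in override["landcover"].items()}
            _merge(params, override)
    validate_params(params)
    return params


def param_hash(params: Mapping[str, Any]) -> str:
    """Stable content hash of a parameter set (canonical JSON, sha256)."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
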