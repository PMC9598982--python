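"""GeoJSON read/write for point, line and polygon layers (shapely-backed)."""

from __future__ import annotations

import json
from typing import Iterable, Mapping

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = ["write_geojson", "read_geojson"]


def write_geojson(
    geometries: Iterable[BaseGeometry],
    path,
    properties: Iterable[Mapping] | None = None,
) -> None:
    geoms = list(geometries)
    props = list(properties) if properties is not None else [{} for _ in geoms]
    if len(props) != len(geoms):
        raise ValueError("properties length does not match geometries")
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": dict(p)}
        for g, p in zip(geoms, props)
    ]
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_geojson(path) -> tuple[list[BaseGeometry], list[dict]]:
    """Return (geometries, properties) from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    geoms, props = [], []
    for feat in doc.get("features", []):
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties") or {})
    return geoms, props
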