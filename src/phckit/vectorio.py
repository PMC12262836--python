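"""GeoJSON read/write for the pipeline's vector features (shapely-backed)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = ["write_geojson", "read_geojson"]


def write_geojson(
    geometries: Iterable[BaseGeometry],
    path: str | Path,
    properties: Iterable[dict] | None = None,
) -> None:
    geometries = list(geometries)
    props = list(properties) if properties is not None else [{} for _ in geometries]
    if len(props) != len(geometries):
        raise ValueError("properties length must match geometries length")
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, props)
    ]
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> tuple[list[BaseGeometry], list[dict]]:
    fc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in fc["features"]]
    props = [f.get("properties", {}) for f in fc["features"]]
    return geoms, props
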