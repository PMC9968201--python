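"""Minimal GeoJSON writing for shapely geometries (planar km coordinates)."""

from __future__ import annotations

import json
import pathlib

from shapely.geometry import mapping


def feature(geom, properties: dict | None = None) -> dict:
    return {"type": "Feature", "geometry": mapping(geom) if geom is not None else None,
            "properties": properties or {}}


def write_geojson(features: list[dict], path) -> None:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
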