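"""Vector I/O: GeoJSON fire perimeters and region polygons.

Fire perimeters are GeoJSON FeatureCollections whose features carry a
``year`` property; regions carry a ``name`` property.  Geometries are in
the run's planar grid coordinates.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .synthetic import FireEvent

log = logging.getLogger(__name__)


def read_vectors(path) -> list[FireEvent]:
    """Read dated fire perimeters from GeoJSON; years coerced to int."""
    with open(path) as fh:
        gj = json.load(fh)
    features = gj.get("features", [])
    if not features:
        log.warning("%s: empty fire collection", path)
    fires: list[FireEvent] = []
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        if "year" not in props or props["year"] is None:
            raise ValueError(f"fire feature {i} is missing the 'year' property")
        geom = shape(feat["geometry"])
        if geom.is_empty or not geom.is_valid:
            raise ValueError(f"fire feature {i} has invalid geometry")
        fires.append(FireEvent(polygon=geom, year=int(props["year"])))
    return fires


def write_fires(path, fires: list[FireEvent]) -> None:
    """Write fire perimeters as a GeoJSON FeatureCollection."""
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"year": int(f.year)},
                "geometry": mapping(f.polygon),
            }
            for f in fires
        ],
    }
    Path(path).write_text(json.dumps(gj))


def read_regions(path) -> list[tuple[str, BaseGeometry]]:
    """Read named region polygons from GeoJSON."""
    with open(path) as fh:
        gj = json.load(fh)
    regions = []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        name = str(props.get("name", f"region_{i}"))
        geom = shape(feat["geometry"])
        if geom.is_empty or not geom.is_valid:
            raise ValueError(f"region feature {i} ({name}) has invalid geometry")
        regions.append((name, geom))
    return regions


def write_regions(path, regions: list[tuple[str, BaseGeometry]]) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": mapping(geom),
            }
            for name, geom in regions
        ],
    }
    Path(path).write_text(json.dumps(gj))
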