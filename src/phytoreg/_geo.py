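"""Small geometry helpers shared across modules: cell polygons, GeoJSON IO,
and great-circle distances."""

from __future__ import annotations

import json
import math
from typing import Iterable, Sequence

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0


def cell_polygon_coords(
    ix: int, iy: int, origin: tuple[float, float], cell_size: float, precision: int = 6
) -> list[list[float]]:
    """Closed exterior ring of the grid cell at integer index ``(ix, iy)``."""
    x0 = origin[0] + ix * cell_size
    y0 = origin[1] + iy * cell_size
    x1, y1 = x0 + cell_size, y0 + cell_size
    ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
    return [[round(x, precision), round(y, precision)] for x, y in ring]


def _round_coords(obj, precision: int):
    if isinstance(obj, (list, tuple)):
        return [_round_coords(o, precision) for o in obj]
    return round(float(obj), precision)


def write_feature_collection(
    path,
    geometries: Iterable[dict | BaseGeometry],
    properties: Sequence[dict],
    precision: int = 6,
) -> None:
    """Write a GeoJSON FeatureCollection with fixed coordinate precision.

    Fixed precision keeps reruns byte-identical across platforms.
    """
    features = []
    for geom, props in zip(geometries, properties):
        gj = mapping(geom) if isinstance(geom, BaseGeometry) else dict(geom)
        gj = dict(gj)
        gj["coordinates"] = _round_coords(gj["coordinates"], precision)
        features.append({"type": "Feature", "geometry": gj, "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
        fh.write("\n")


def read_feature_collection(path) -> list[tuple[BaseGeometry, dict]]:
    with open(path) as fh:
        fc = json.load(fh)
    return [(shape(f["geometry"]), f.get("properties", {})) for f in fc["features"]]


def haversine_km(
    lon1: float, lat1: float, lon2: float, lat2: float, radius: float = EARTH_RADIUS_KM
) -> float:
    """Great-circle distance in km on a spherical Earth (R = 6371 km)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * radius * math.asin(min(1.0, math.sqrt(h)))
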