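"""Planar <-> WGS84 coordinate handling and GeoJSON helpers.

Synthetic cities live in a local planar frame with metre units. GPS output is
expressed in WGS84 degrees through a fixed affine mapping anchored at a
reference coordinate; the mapping is exactly invertible, so point-in-polygon
relations are identical in either frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from shapely.geometry import Polygon, shape


#: metres per degree of latitude (spherical approximation, fixed by convention)
M_PER_DEG_LAT = 111_320.0


@dataclass(frozen=True)
class PlanarCRS:
    """Fixed affine mapping between a local metre frame and WGS84 degrees.

    ``lon = lon0 + x / (M_PER_DEG_LAT * cos(lat0))`` and
    ``lat = lat0 + y / M_PER_DEG_LAT``.  The anchor ``(lon0, lat0)`` maps to
    the planar origin.
    """

    lon0: float = -73.6
    lat0: float = 45.5

    @property
    def m_per_deg_lon(self) -> float:
        return M_PER_DEG_LAT * float(np.cos(np.radians(self.lat0)))

    def to_wgs84(self, x, y):
        """Planar metres -> (lon, lat) degrees; accepts scalars or arrays."""
        lon = self.lon0 + np.asarray(x, dtype=float) / self.m_per_deg_lon
        lat = self.lat0 + np.asarray(y, dtype=float) / M_PER_DEG_LAT
        return lon, lat

    def to_planar(self, lon, lat):
        """(lon, lat) degrees -> planar metres."""
        x = (np.asarray(lon, dtype=float) - self.lon0) * self.m_per_deg_lon
        y = (np.asarray(lat, dtype=float) - self.lat0) * M_PER_DEG_LAT
        return x, y

    def polygon_to_wgs84(self, poly: Polygon) -> Polygon:
        xs, ys = np.asarray(poly.exterior.coords).T
        lon, lat = self.to_wgs84(xs, ys)
        return Polygon(np.column_stack([lon, lat]))


def rect_polygon(x0: float, y0: float, x1: float, y1: float) -> Polygon:
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def feature_collection(features: Iterable[dict], metadata: dict | None = None) -> dict:
    fc: dict = {"type": "FeatureCollection", "features": list(features)}
    if metadata:
        fc["metadata"] = metadata
    return fc


def write_geojson(path, fc: dict) -> None:
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_geojson_polygons(path) -> dict[str, Polygon]:
    """Read a FeatureCollection of polygons keyed by the ``da_id`` property."""
    with open(path) as fh:
        fc = json.load(fh)
    out: dict[str, Polygon] = {}
    for feat in fc["features"]:
        out[feat["properties"]["da_id"]] = shape(feat["geometry"])
    return out
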