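"""Route-retention filters based on land cover and study-area containment.

A survey route is kept only if (a) less than half of the landscape within a
39.4-km radius of its start point is covered by human-dominated land-cover
classes (croplands, urban/built-up, cropland mosaics) and (b) the whole
buffer disk lies inside the study-area boundary, so every covariate buffer
is fully backed by data.  Dropped routes carry a ``drop_reason`` code so the
filtering is auditable; filters commute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon
from shapely import wkt as _wkt

from .grids import RasterGrid

__all__ = [
    "human_cover_filter",
    "containment_filter",
    "human_cover_fraction",
    "read_boundary",
]

DEFAULT_RADIUS_KM = 39.4
DEFAULT_THRESHOLD = 0.5


def _ensure_flags(routes: pd.DataFrame) -> pd.DataFrame:
    out = routes.copy()
    if "retained" not in out:
        out["retained"] = True
    if "drop_reason" not in out:
        out["drop_reason"] = ""
    return out


def human_cover_fraction(
    landcover: RasterGrid,
    point: tuple[float, float],
    human_classes: set[int],
    radius_km: float,
) -> float:
    """Fraction of valid buffer pixels in human-dominated classes.

    Returns NaN when the buffer contains no valid pixel center.
    """
    xs, ys = landcover.pixel_centers()
    px, py = point
    mask = (ys[:, None] - py) ** 2 + (xs[None, :] - px) ** 2 <= radius_km**2
    vals = landcover.values[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(np.isin(vals.astype(int), list(human_classes)).mean())


def human_cover_filter(
    routes: pd.DataFrame,
    landcover: RasterGrid,
    human_classes: set[int],
    radius_km: float = DEFAULT_RADIUS_KM,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Retain routes with human-class cover strictly below ``threshold``.

    The boundary is exclusive: a landscape at exactly the threshold is
    dropped.  Buffers with no valid land-cover pixel get their own reason
    code (``empty_buffer``).
    """
    out = _ensure_flags(routes)
    for idx, row in out.iterrows():
        if not out.at[idx, "retained"]:
            continue
        frac = human_cover_fraction(
            landcover, (row["x_km"], row["y_km"]), human_classes, radius_km
        )
        if np.isnan(frac):
            out.at[idx, "retained"] = False
            out.at[idx, "drop_reason"] = "empty_buffer"
        elif frac >= threshold:
            out.at[idx, "retained"] = False
            out.at[idx, "drop_reason"] = "human_cover"
    return out


def containment_filter(
    routes: pd.DataFrame,
    boundary: Polygon,
    radius_km: float = DEFAULT_RADIUS_KM,
) -> pd.DataFrame:
    """Retain routes whose full buffer disk lies inside the boundary.

    Implemented as ``distance(point, boundary edge) >= radius`` for points
    inside the polygon; an exact tie is retained.
    """
    if not boundary.is_valid:
        raise ValueError("invalid boundary geometry")
    out = _ensure_flags(routes)
    edge = boundary.boundary
    for idx, row in out.iterrows():
        if not out.at[idx, "retained"]:
            continue
        p = Point(row["x_km"], row["y_km"])
        if not (boundary.covers(p) and p.distance(edge) >= radius_km):
            out.at[idx, "retained"] = False
            out.at[idx, "drop_reason"] = "outside_boundary"
    return out


def read_boundary(path) -> Polygon:
    """Read a boundary polygon from a GeoJSON or WKT file."""
    text = open(path).read().strip()
    if text.startswith("{"):
        import json

        geo = json.loads(text)
        if geo.get("type") == "FeatureCollection":
            geo = geo["features"][0]["geometry"]
        elif geo.get("type") == "Feature":
            geo = geo["geometry"]
        geom = shapely.geometry.shape(geo)
    else:
        geom = _wkt.loads(text)
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise ValueError(f"boundary must be polygonal, got {geom.geom_type}")
    return geom
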