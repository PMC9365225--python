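"""Convex-hull service-area analysis per helicopter base.

Each base's empirical service area is the convex hull of its mission
coordinates after discarding the 5% of missions farthest (by WGS84 geodesic
distance) from the base. Hulls are built in an azimuthal equidistant plane
centred on the base — which preserves exactly the distance ordering the
filter uses — and their areas are measured in an equal-area projection
centred on the hull centroid, so the km^2 figures do not depend on latitude.
Median and IQR mission distances are computed on *all* map-eligible
missions; only the hull uses the filtered subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon

from .config import BaseDefinition
from .cohort import hodges_lehmann_ci, mann_whitney
from .geodesy import (azimuthal_equidistant_xy, geodesic_distance_km,
                      lambert_equal_area_xy, shoelace_area)

__all__ = [
    "HullResult", "base_distances_km", "filter_distance_outliers",
    "convex_hull_ring", "hull_area_km2", "analyze_base", "compare_periods",
    "hulls_to_geojson",
]


@dataclass(frozen=True)
class HullResult:
    """Service-area summary for one base in one period."""

    base_id: str
    period: str
    n_input: int
    n_retained: int
    hull_vertices: tuple[tuple[float, float], ...]  # (lat, lon) ring, open
    area_km2: float
    median_distance_km: float
    iqr_distance_km: float
    degenerate: bool = False


def base_distances_km(lats, lons, base: BaseDefinition) -> np.ndarray:
    """Geodesic distance from every point to the base, km."""
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    return np.array([geodesic_distance_km(base.latitude, base.longitude, la, lo)
                     for la, lo in zip(lats, lons)])


def filter_distance_outliers(lats, lons, base: BaseDefinition,
                             quantile: float = 0.95) -> np.ndarray:
    """Boolean mask retaining points at or below the per-base distance
    quantile (linear-interpolation percentile; ties at the cutoff kept)."""
    lats = np.asarray(lats, float)
    if lats.size == 0:
        raise ValueError("cannot filter an empty point list")
    d = base_distances_km(lats, lons, base)
    cutoff = np.quantile(d, quantile, method="linear")
    return d <= cutoff


def convex_hull_ring(lats, lons, base: BaseDefinition
                     ) -> tuple[tuple[tuple[float, float], ...], bool]:
    """Convex hull of points, computed in the base-centred azimuthal
    equidistant plane. Returns ``(ring, degenerate)`` where ring is an
    ordered (lat, lon) vertex tuple (counter-clockwise, not closed); fewer
    than 3 non-collinear points give a degenerate result."""
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    if lats.size < 3:
        return tuple(zip(lats, lons)), True
    xy = azimuthal_equidistant_xy(lats, lons, base.latitude, base.longitude)
    try:
        hull = ConvexHull(xy)
    except QhullError:
        return tuple(zip(lats, lons)), True  # collinear or duplicate points
    verts = hull.vertices  # counter-clockwise indices into the inputs
    if shoelace_area(xy[verts]) < 1e-6:  # km^2: numerically collinear sliver
        return tuple(zip(lats, lons)), True
    return tuple((float(lats[i]), float(lons[i])) for i in verts), False


def hull_area_km2(ring: tuple[tuple[float, float], ...]) -> float:
    """Area of a (lat, lon) ring in km^2, via an equal-area projection
    centred on the ring's vertex centroid."""
    if len(ring) < 3:
        return 0.0
    lats = np.array([p[0] for p in ring])
    lons = np.array([p[1] for p in ring])
    xy = lambert_equal_area_xy(lats, lons, float(lats.mean()), float(lons.mean()))
    poly = Polygon(xy)
    if not poly.is_valid:
        raise ValueError("hull ring is self-intersecting")
    area = shoelace_area(xy)
    return 0.0 if area < 1e-3 else area  # sub-milli-km^2 is projection noise


def analyze_base(lats, lons, base: BaseDefinition, period: str,
                 quantile: float = 0.95) -> HullResult:
    """Full per-base, per-period service-area summary."""
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    if lats.size == 0:
        raise ValueError(f"no map-eligible missions for base {base.base_id}")
    d = base_distances_km(lats, lons, base)
    keep = d <= np.quantile(d, quantile, method="linear")
    ring, degenerate = convex_hull_ring(lats[keep], lons[keep], base)
    area = 0.0 if degenerate else hull_area_km2(ring)
    q25, q50, q75 = np.percentile(d, [25, 50, 75])
    return HullResult(
        base_id=base.base_id, period=period,
        n_input=int(lats.size), n_retained=int(keep.sum()),
        hull_vertices=ring, area_km2=float(area),
        median_distance_km=float(q50), iqr_distance_km=float(q75 - q25),
        degenerate=degenerate)


def contains_point(ring: tuple[tuple[float, float], ...],
                   lat: float, lon: float, tol: float = 1e-6) -> bool:
    """Whether a point lies inside or on the hull (degree-space test with a
    small tolerance; adequate because the ring is convex and regional)."""
    poly = Polygon([(lo, la) for la, lo in ring])
    return poly.buffer(tol).contains(Point(lon, lat))


def compare_periods(pre: HullResult, post: HullResult,
                    pre_distances, post_distances) -> dict:
    """Pre/post comparison for one base: area change (absolute and percent,
    computed from unrounded areas), and the median-distance shift with a
    Mann-Whitney p-value and Hodges-Lehmann 95% CI."""
    if pre.base_id != post.base_id:
        raise ValueError(f"base mismatch: {pre.base_id!r} vs {post.base_id!r}")
    pre_d = np.asarray(pre_distances, float)
    post_d = np.asarray(post_distances, float)
    area_change = post.area_km2 - pre.area_km2
    pct = 100.0 * area_change / pre.area_km2 if pre.area_km2 > 0 else np.nan
    _, p = mann_whitney(pre_d, post_d)
    hl = hodges_lehmann_ci(post_d, pre_d)
    return {
        "base_id": pre.base_id,
        "area_pre_km2": pre.area_km2,
        "area_post_km2": post.area_km2,
        "area_change_km2": area_change,
        "area_change_pct": pct,
        "median_pre_km": pre.median_distance_km,
        "median_post_km": post.median_distance_km,
        "median_diff_km": post.median_distance_km - pre.median_distance_km,
        "hl_estimate_km": hl.estimate,
        "hl_ci_low_km": hl.ci_low,
        "hl_ci_high_km": hl.ci_high,
        "mw_p": p,
    }


def hulls_to_geojson(results: list[HullResult], path: str | Path) -> None:
    """Write hull polygons as a GeoJSON FeatureCollection (lon/lat order)."""
    features = []
    for r in results:
        ring = [[lon, lat] for lat, lon in r.hull_vertices]
        if ring:
            ring.append(ring[0])
        features.append({
            "type": "Feature",
            "properties": {
                "base_id": r.base_id, "period": r.period,
                "area_km2": round(r.area_km2, 3),
                "n_retained": r.n_retained,
                "median_distance_km": round(r.median_distance_km, 3),
            },
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))
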