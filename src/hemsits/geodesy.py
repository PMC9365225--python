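"""WGS84 geodesic computations and local map projections.

Distances between mission coordinates and helicopter bases are geodesics on
the WGS84 ellipsoid, computed with Vincenty's inverse/direct formulae
(sub-millimetre accuracy at the few-hundred-kilometre scale relevant here;
the near-antipodal non-convergence regime is unreachable for regional data
and raises an explicit error).

Two local projections support the service-area analysis:

* azimuthal equidistant, centred on a base — distances and bearings from the
  centre are preserved, so convex hulls built in this plane are faithful to
  geodesic distance ordering around the base;
* Lambert azimuthal equal-area on the authalic sphere, centred on a polygon
  centroid — areas are preserved, so planar shoelace areas are km^2 on the
  ellipsoid to well within the precision the analysis needs.
"""

from __future__ import annotations

import math

import numpy as np

# WGS84 ellipsoid
WGS84_A = 6378137.0            # semi-major axis, m
WGS84_F = 1.0 / 298.257223563  # flattening
WGS84_B = WGS84_A * (1.0 - WGS84_F)

#: Authalic (equal-area) sphere radius for WGS84, km.
AUTHALIC_RADIUS_KM = 6371.0072


def _validate_latlon(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude {lat!r} outside [-90, 90]")
    if not (-180.0 <= lon <= 180.0):
        raise ValueError(f"longitude {lon!r} outside [-180, 180]")
    if not (math.isfinite(lat) and math.isfinite(lon)):
        raise ValueError("coordinates must be finite")


def geodesic_inverse(lat1: float, lon1: float, lat2: float, lon2: float,
                     *, max_iter: int = 200, tol: float = 1e-12) -> tuple[float, float]:
    """Solve the geodesic inverse problem on WGS84.

    Returns ``(distance_km, forward_azimuth_deg)`` from point 1 to point 2.
    Azimuth is measured clockwise from north in degrees.
    """
    _validate_latlon(lat1, lon1)
    _validate_latlon(lat2, lon2)
    if lat1 == lat2 and lon1 == lon2:
        return 0.0, 0.0

    a, b, f = WGS84_A, WGS84_B, WGS84_F
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - f) * math.tan(math.radians(lat1)))
    U2 = math.atan((1 - f) * math.tan(math.radians(lat2)))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sin_lam,
                               cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:  # coincident points
            return 0.0, 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:  # equatorial geodesic
            cos_2sigma_m = 0.0
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * f * sin_alpha * (
            sigma + C * sin_sigma * (
                cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)))
        if abs(lam - lam_prev) < tol:
            break
    else:
        raise ValueError(
            "geodesic inverse failed to converge (near-antipodal points)")

    u2 = cos2_alpha * (a * a - b * b) / (b * b)
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
            - B / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma ** 2)
            * (-3.0 + 4.0 * cos_2sigma_m ** 2)))
    s = b * A * (sigma - delta_sigma)
    alpha1 = math.atan2(cosU2 * math.sin(lam),
                        cosU1 * sinU2 - sinU1 * cosU2 * math.cos(lam))
    return s / 1000.0, math.degrees(alpha1) % 360.0


def geodesic_distance_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Geodesic (shortest-path) distance between two WGS84 points, in km."""
    return geodesic_inverse(lat1, lon1, lat2, lon2)[0]


def geodesic_direct(lat1: float, lon1: float, azimuth_deg: float,
                    distance_km: float) -> tuple[float, float]:
    """Solve the geodesic direct problem: destination of a geodesic of given
    length and initial azimuth. Returns ``(lat, lon)`` in degrees."""
    _validate_latlon(lat1, lon1)
    if distance_km < 0:
        raise ValueError("distance must be non-negative")
    a, b, f = WGS84_A, WGS84_B, WGS84_F
    s = distance_km * 1000.0
    alpha1 = math.radians(azimuth_deg)
    U1 = math.atan((1 - f) * math.tan(math.radians(lat1)))
    sigma1 = math.atan2(math.tan(U1), math.cos(alpha1))
    sin_alpha = math.cos(U1) * math.sin(alpha1)
    cos2_alpha = 1.0 - sin_alpha ** 2
    u2 = cos2_alpha * (a * a - b * b) / (b * b)
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))

    sigma = s / (b * A)
    for _ in range(200):
        cos_2sigma_m = math.cos(2.0 * sigma1 + sigma)
        sin_sigma, cos_sigma = math.sin(sigma), math.cos(sigma)
        delta_sigma = B * sin_sigma * (
            cos_2sigma_m + B / 4.0 * (
                cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
                - B / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma ** 2)
                * (-3.0 + 4.0 * cos_2sigma_m ** 2)))
        sigma_prev = sigma
        sigma = s / (b * A) + delta_sigma
        if abs(sigma - sigma_prev) < 1e-13:
            break
    sin_sigma, cos_sigma = math.sin(sigma), math.cos(sigma)
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    cos_alpha1 = math.cos(alpha1)
    lat2 = math.atan2(
        sinU1 * cos_sigma + cosU1 * sin_sigma * cos_alpha1,
        (1 - f) * math.hypot(sin_alpha,
                             sinU1 * sin_sigma - cosU1 * cos_sigma * cos_alpha1))
    lam = math.atan2(sin_sigma * math.sin(alpha1),
                     cosU1 * cos_sigma - sinU1 * sin_sigma * cos_alpha1)
    C = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
    cos_2sigma_m = math.cos(2.0 * sigma1 + sigma)
    L = lam - (1.0 - C) * f * sin_alpha * (
        sigma + C * sin_sigma * (
            cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)))
    lon2 = (math.degrees(L) + lon1 + 540.0) % 360.0 - 180.0
    return math.degrees(lat2), lon2


def azimuthal_equidistant_xy(lats: np.ndarray, lons: np.ndarray,
                             lat0: float, lon0: float) -> np.ndarray:
    """Project points to a plane centred on (lat0, lon0) preserving geodesic
    distance and azimuth from the centre. Returns an (n, 2) array in km."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    out = np.empty((lats.size, 2))
    for i, (la, lo) in enumerate(zip(lats.ravel(), lons.ravel())):
        d, az = geodesic_inverse(lat0, lon0, la, lo)
        az_r = math.radians(az)
        out[i, 0] = d * math.sin(az_r)
        out[i, 1] = d * math.cos(az_r)
    return out


_E2 = WGS84_F * (2.0 - WGS84_F)  # first eccentricity squared
_E = math.sqrt(_E2)


def _authalic_latitude(phi: np.ndarray) -> np.ndarray:
    """Geodetic -> authalic latitude (radians): the sphere latitude that
    makes the ellipsoid-to-sphere mapping exactly area-preserving."""
    s = np.sin(phi)

    def q(sin_phi):
        return (1.0 - _E2) * (sin_phi / (1.0 - _E2 * sin_phi ** 2)
                              - np.log((1.0 - _E * sin_phi)
                                       / (1.0 + _E * sin_phi)) / (2.0 * _E))

    return np.arcsin(np.clip(q(s) / q(1.0), -1.0, 1.0))


def lambert_equal_area_xy(lats: np.ndarray, lons: np.ndarray,
                          lat0: float, lon0: float) -> np.ndarray:
    """Lambert azimuthal equal-area projection on the authalic sphere,
    centred on (lat0, lon0). Latitudes are converted to authalic latitude
    first, so planar polygon areas equal ellipsoidal areas in km^2.
    Returns an (n, 2) array in km."""
    R = AUTHALIC_RADIUS_KM
    phi = _authalic_latitude(np.radians(np.asarray(lats, dtype=float)))
    lam = np.radians(np.asarray(lons, dtype=float))
    phi0 = float(_authalic_latitude(np.array(math.radians(lat0))))
    lam0 = math.radians(lon0)
    dlam = lam - lam0
    denom = 1.0 + math.sin(phi0) * np.sin(phi) + math.cos(phi0) * np.cos(phi) * np.cos(dlam)
    if np.any(denom <= 1e-12):
        raise ValueError("point antipodal to projection centre")
    k = np.sqrt(2.0 / denom)
    x = R * k * np.cos(phi) * np.sin(dlam)
    y = R * k * (math.cos(phi0) * np.sin(phi)
                 - math.sin(phi0) * np.cos(phi) * np.cos(dlam))
    return np.column_stack([x, y])


def shoelace_area(xy: np.ndarray) -> float:
    """Unsigned polygon area of a planar ring given as an (n, 2) array."""
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
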