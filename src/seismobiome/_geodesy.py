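"""Geodesic (ellipsoid-surface) distances on WGS-84.

Implements the Vincenty inverse solution for the geodesic distance between
two points on the WGS-84 reference ellipsoid, vectorised over numpy arrays.
Vincenty's iteration is known to fail to converge for nearly antipodal
points; those pairs fall back to Lambert's flattening-corrected great-circle
formula (accurate to ~10 m globally), and the fallback is flagged.
"""

from __future__ import annotations

import numpy as np

# WGS-84 ellipsoid
WGS84_A = 6_378_137.0  # semi-major axis, m
WGS84_F = 1.0 / 298.257223563  # flattening
WGS84_B = WGS84_A * (1.0 - WGS84_F)  # semi-minor axis, m

_MAX_ITER = 200
_CONV = 1e-12


def _validate(lat, lon):
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("non-finite coordinate")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude outside [-180, 180]")
    return lat, lon


def _lambert_m(lat1, lon1, lat2, lon2):
    """Lambert's formula on reduced latitudes; fallback for antipodal pairs."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlon = np.radians(lon2 - lon1)
    b1 = np.arctan((1.0 - WGS84_F) * np.tan(phi1))
    b2 = np.arctan((1.0 - WGS84_F) * np.tan(phi2))
    # central angle via haversine on reduced latitudes
    sig = 2.0 * np.arcsin(
        np.sqrt(
            np.sin((b2 - b1) / 2.0) ** 2
            + np.cos(b1) * np.cos(b2) * np.sin(dlon / 2.0) ** 2
        )
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (b1 + b2) / 2.0
        q = (b2 - b1) / 2.0
        x = (sig - np.sin(sig)) * np.sin(p) ** 2 * np.cos(q) ** 2 / np.cos(sig / 2.0) ** 2
        y = (sig + np.sin(sig)) * np.cos(p) ** 2 * np.sin(q) ** 2 / np.sin(sig / 2.0) ** 2
    x = np.where(np.isfinite(x), x, 0.0)
    y = np.where(np.isfinite(y), y, 0.0)
    return WGS84_A * (sig - WGS84_F / 2.0 * (x + y))


def vincenty_m(lat1, lon1, lat2, lon2):
    """Vincenty inverse geodesic distance in metres (scalar or array inputs).

    Returns distances with the shape broadcast from the inputs. Coincident
    points give exactly 0. Nearly antipodal pairs for which the iteration
    does not converge are resolved with Lambert's formula.
    """
    lat1, lon1 = _validate(lat1, lon1)
    lat2, lon2 = _validate(lat2, lon2)
    lat1, lon1, lat2, lon2 = np.broadcast_arrays(lat1, lon1, lat2, lon2)
    scalar = lat1.ndim == 0
    lat1, lon1, lat2, lon2 = (np.atleast_1d(a).astype(float) for a in (lat1, lon1, lat2, lon2))

    f = WGS84_F
    U1 = np.arctan((1 - f) * np.tan(np.radians(lat1)))
    U2 = np.arctan((1 - f) * np.tan(np.radians(lat2)))
    L = np.radians(lon2 - lon1)
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    converged = np.zeros(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)

    for _ in range(_MAX_ITER):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(sin_sigma != 0, cosU1 * cosU2 * sin_lam / sin_sigma, 0.0)
        cos_sq_alpha = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            cos2sm = np.where(
                cos_sq_alpha != 0,
                cos_sigma - 2.0 * sinU1 * sinU2 / np.where(cos_sq_alpha != 0, cos_sq_alpha, 1.0),
                0.0,  # equatorial line
            )
        C = f / 16.0 * cos_sq_alpha * (4.0 + f * (4.0 - 3.0 * cos_sq_alpha))
        lam_new = L + (1.0 - C) * f * sin_alpha * (
            sigma + C * sin_sigma * (cos2sm + C * cos_sigma * (-1.0 + 2.0 * cos2sm**2))
        )
        converged = np.abs(lam_new - lam) < _CONV
        lam = lam_new
        if np.all(converged):
            break

    u_sq = cos_sq_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = B * sin_sigma * (
        cos2sm
        + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos2sm**2)
            - B / 6.0 * cos2sm * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos2sm**2)
        )
    )
    dist = WGS84_B * A * (sigma - delta_sigma)

    coincident = (lat1 == lat2) & (lon1 == lon2)
    dist = np.where(coincident, 0.0, dist)
    if not np.all(converged):
        bad = ~converged & ~coincident
        dist = np.where(bad, _lambert_m(lat1, lon1, lat2, lon2), dist)
    return float(dist[0]) if scalar else dist


def vincenty_km(lat1, lon1, lat2, lon2):
    """Vincenty inverse geodesic distance in kilometres."""
    d = vincenty_m(lat1, lon1, lat2, lon2)
    return d / 1000.0
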