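"""Great-circle geometry helpers (haversine distances, spherical centroids)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two points in km (haversine form)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise haversine distances (km) for an array of (lat, lon) rows."""
    coords = np.asarray(coords, float)
    k = len(coords)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = haversine_km(*coords[i], *coords[j])
    return out


def _unit_vectors(coords: np.ndarray) -> np.ndarray:
    lat = np.radians(coords[:, 0])
    lon = np.radians(coords[:, 1])
    return np.column_stack([np.cos(lat) * np.cos(lon),
                            np.cos(lat) * np.sin(lon),
                            np.sin(lat)])


def weighted_centroid(coords: np.ndarray, weights: np.ndarray):
    """Frequency-weighted centroid on the sphere.

    The weighted mean of the 3-D unit vectors is projected back to the
    surface; appropriate when samples span several degrees, where a planar
    mean would distort longitudes.
    """
    v = (np.asarray(weights, float)[:, None] * _unit_vectors(np.asarray(coords, float))).sum(axis=0)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("degenerate centroid (weights sum to zero or antipodal)")
    v = v / norm
    lat = np.degrees(np.arcsin(np.clip(v[2], -1, 1)))
    lon = np.degrees(np.arctan2(v[1], v[0]))
    return float(lat), float(lon)


def mean_distance_to(coords: np.ndarray, weights: np.ndarray, point) -> float:
    """Weighted mean great-circle distance (km) from rows of coords to point."""
    w = np.asarray(weights, float)
    d = np.array([haversine_km(la, lo, point[0], point[1])
                  for la, lo in np.asarray(coords, float)])
    return float((w * d).sum() / w.sum())
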