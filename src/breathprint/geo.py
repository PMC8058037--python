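"""Great-circle distances and habitual-location clustering."""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

EARTH_RADIUS_KM = 6371.0

__all__ = ["haversine_km", "assign_geo_clusters", "EARTH_RADIUS_KM"]


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km.

    Vectorized; inputs in decimal degrees.  Invalid coordinates
    (|lat| > 90 or |lon| > 180) yield NaN with a warning.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(a, float) for a in (lat1, lon1, lat2, lon2))
    bad = ((np.abs(lat1) > 90) | (np.abs(lat2) > 90)
           | (np.abs(lon1) > 180) | (np.abs(lon2) > 180))
    if np.any(bad):
        warnings.warn("invalid coordinates encountered; distances set to NaN")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return np.where(bad, np.nan, d)


def assign_geo_clusters(table: pd.DataFrame, k: int = 120, seed: int = 0
                        ) -> tuple[pd.Series, np.ndarray]:
    """K-means on (lat, lon) of all geolocated rows.

    Returns per-row cluster labels (NaN where geolocation is missing) and
    the (k, 2) centroid array.  Used for density mapping/visualization;
    cluster ids are not default model features.  If fewer geolocated points
    than k exist, k is reduced with a warning.
    """
    geo = table[["lat", "lon"]].apply(pd.to_numeric, errors="coerce")
    mask = geo["lat"].notna() & geo["lon"].notna()
    pts = geo[mask].to_numpy(float)
    if len(pts) == 0:
        raise ValueError("no geolocated rows to cluster")
    if len(pts) < k:
        warnings.warn(f"only {len(pts)} geolocated rows; reducing k from {k}")
        k = len(pts)
    km = KMeans(n_clusters=k, n_init=4, random_state=seed)
    labels = km.fit_predict(pts)
    out = pd.Series(np.nan, index=table.index, name="geo_cluster")
    out[mask] = labels
    return out, km.cluster_centers_
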