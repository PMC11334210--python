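"""Geographic range size from occurrence coordinates.

Range size is the area of the convex hull of a species' occurrence points
(decimal lon/lat), evaluated on a sphere of authalic Earth radius
6371.0088 km.  The hull is taken in lon/lat after unwrapping longitudes for
point sets spanning the antimeridian; the polygon's spherical area comes from
Girard's theorem (sum of interior angles minus (n-2)π, times R²).  Species
are then split into 'small' and 'large' range classes at the dataset median,
with areas >= the median classed as large.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

logger = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_KM",
    "read_occurrences",
    "estimate_range",
    "estimate_ranges",
    "discretize_by_median",
]

EARTH_RADIUS_KM = 6371.0088


def read_occurrences(path: str) -> pd.DataFrame:
    """Load a GBIF-style delimited file of species occurrence coordinates.

    Requires columns ``species``, ``decimalLongitude``, ``decimalLatitude``
    (or ``longitude`` / ``latitude``); extra columns are ignored.  Rows with
    missing or out-of-bounds coordinates are dropped with a logged count.
    """
    sep = "\t" if open(path).readline().count("\t") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    lon = cols.get("decimallongitude", cols.get("longitude"))
    lat = cols.get("decimallatitude", cols.get("latitude"))
    if "species" not in df.columns or lon is None or lat is None:
        raise ValueError("need species, decimalLongitude, decimalLatitude columns")
    out = df[["species", lon, lat]].rename(columns={lon: "longitude", lat: "latitude"})
    out["longitude"] = pd.to_numeric(out["longitude"], errors="coerce")
    out["latitude"] = pd.to_numeric(out["latitude"], errors="coerce")
    n0 = len(out)
    out = out.dropna()
    out = out[(out["longitude"].between(-180, 180)) & (out["latitude"].between(-90, 90))]
    if len(out) < n0:
        logger.info("dropped %d occurrence rows with bad coordinates", n0 - len(out))
    return out.reset_index(drop=True)


def _unwrap_lons(lons: np.ndarray) -> np.ndarray:
    """Shift longitudes so antimeridian-spanning sets become contiguous."""
    if lons.max() - lons.min() > 180:
        lons = np.where(lons < 0, lons + 360, lons)
    return lons


def _to_unit_xyz(lon_deg: np.ndarray, lat_deg: np.ndarray) -> np.ndarray:
    lon = np.radians(lon_deg)
    lat = np.radians(lat_deg)
    return np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def spherical_polygon_area(lon_deg: np.ndarray, lat_deg: np.ndarray,
                           radius: float = EARTH_RADIUS_KM) -> float:
    """Area of a simple spherical polygon via Girard's theorem.

    Vertices must be ordered along the boundary.  The excess is the sum of
    interior angles minus (n-2)π; interior angles are measured between the
    great-circle tangents at each vertex.
    """
    xyz = _to_unit_xyz(np.asarray(lon_deg, float), np.asarray(lat_deg, float))
    n = xyz.shape[0]
    if n < 3:
        return 0.0
    total = 0.0
    for i in range(n):
        a, b, c = xyz[i - 1], xyz[i], xyz[(i + 1) % n]
        t1 = a - np.dot(a, b) * b
        t2 = c - np.dot(c, b) * b
        n1, n2 = np.linalg.norm(t1), np.linalg.norm(t2)
        if n1 == 0 or n2 == 0:  # coincident vertices
            return 0.0
        cosang = np.clip(np.dot(t1, t2) / (n1 * n2), -1.0, 1.0)
        total += np.arccos(cosang)
    excess = total - (n - 2) * np.pi
    return float(max(excess, 0.0) * radius**2)


def estimate_range(points: pd.DataFrame) -> dict:
    """Convex-hull spherical area (km²) for one species' occurrences.

    Returns ``{'area_km2': float, 'n_points': int}``.  Fewer than three
    distinct non-collinear points give area 0.
    """
    if len(points) == 0:
        raise ValueError("no valid occurrence points")
    pts = points[["longitude", "latitude"]].drop_duplicates().to_numpy(float)
    n_used = len(pts)
    if n_used < 3:
        return dict(area_km2=0.0, n_points=n_used)
    lons = _unwrap_lons(pts[:, 0])
    lats = pts[:, 1]
    try:
        hull = ConvexHull(np.column_stack([lons, lats]))
    except QhullError:  # collinear points
        return dict(area_km2=0.0, n_points=n_used)
    v = hull.vertices  # counter-clockwise boundary order
    area = spherical_polygon_area(lons[v], lats[v])
    return dict(area_km2=area, n_points=n_used)


def estimate_ranges(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Per-species range estimates from a pooled occurrence table."""
    rows = []
    for sp, grp in occurrences.groupby("species", sort=True):
        est = estimate_range(grp)
        rows.append(dict(species=sp, **est))
    return pd.DataFrame(rows)


def discretize_by_median(estimates: pd.DataFrame) -> pd.DataFrame:
    """Binary range-size classes at the dataset median (>= median -> large)."""
    if len(estimates) < 2:
        raise ValueError("need at least 2 species to discretize")
    med = float(estimates["area_km2"].median())
    if estimates["area_km2"].nunique() == 1:
        logger.warning("all range areas identical; every species classed 'large'")
    out = estimates.copy()
    out["state"] = np.where(out["area_km2"] >= med, "large", "small")
    out["median_km2"] = med
    return out
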