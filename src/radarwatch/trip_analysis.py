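"""Foraging-trip segmentation, trip metrics, and kernel home ranges.

A foraging trip is a maximal excursion outside the colony buffer by a
central-place forager. Space use is summarised as a kernel utilization
distribution (UD) on a local planar grid; the "90% contour" is the smallest
set of highest-density cells holding 90% of the probability mass (a volume
contour, not an isopleth of raw density height).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
from shapely.ops import unary_union

from ._project import aeqd_forward, aeqd_inverse
from .errors import InsufficientDataError
from .geotrack import Colony, Track, haversine_km, path_length_km


@dataclass
class Trip:
    """One colony-to-colony excursion with its metric summary.

    ``complete`` is False when the record ended (battery failure, recovery)
    before the bird returned to the colony.
    """

    bird_id: str
    device: str
    fixes: pd.DataFrame
    complete: bool = True
    duration_h: float | None = None
    path_length_km: float | None = None
    max_range_km: float | None = None
    mean_speed_kmh: float | None = None

    @property
    def start(self) -> pd.Timestamp:
        return self.fixes["time"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.fixes["time"].iloc[-1]


def segment_trips(
    t: Track,
    colony: Colony,
    min_duration_h: float = 0.5,
    min_range_km: float = 2.0,
) -> list[Trip]:
    """Cut a resampled track into foraging trips.

    A trip is a maximal run of fixes outside the colony buffer, extended by
    one boundary fix at each end (the last fix at the colony before
    departure and the first after return). Runs shorter than
    ``min_duration_h`` or never exceeding ``min_range_km`` from the colony
    are discarded as loafing. A run truncated by the end of the record is
    kept but flagged incomplete.
    """
    df = t.fixes
    if len(df) == 0:
        return []
    dist = haversine_km(df["lat"].to_numpy(), df["lon"].to_numpy(), colony.lat, colony.lon)
    outside = dist > colony.radius_km
    trips: list[Trip] = []
    n = len(df)
    i = 0
    while i < n:
        if not outside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and outside[j + 1]:
            j += 1
        lo = max(i - 1, 0)  # boundary fix before departure
        hi = min(j + 1, n - 1)  # boundary fix after return
        truncated = j == n - 1  # record ended before the bird returned
        seg = df.iloc[lo : hi + 1].reset_index(drop=True)
        dur_h = (seg["time"].iloc[-1] - seg["time"].iloc[0]).total_seconds() / 3600.0
        rng = float(dist[i : j + 1].max())
        if dur_h >= min_duration_h and rng > min_range_km:
            trips.append(Trip(t.bird_id, t.device, seg, complete=not truncated))
        i = j + 1
    return trips


def trip_metrics(tr: Trip, colony: Colony) -> Trip:
    """Fill duration, path length, maximum range and mean speed in place."""
    df = tr.fixes
    if len(df) < 2:
        raise InsufficientDataError("trip metrics need >=2 fixes")
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    tr.duration_h = (df["time"].iloc[-1] - df["time"].iloc[0]).total_seconds() / 3600.0
    tr.path_length_km = path_length_km(lat, lon)
    tr.max_range_km = float(np.max(haversine_km(lat, lon, colony.lat, colony.lon)))
    tr.mean_speed_kmh = tr.path_length_km / tr.duration_h
    return tr


def trips_table(trips: list[Trip]) -> pd.DataFrame:
    """One row per trip with its metrics."""
    return pd.DataFrame(
        {
            "bird_id": [tr.bird_id for tr in trips],
            "device": [tr.device for tr in trips],
            "start": [tr.start for tr in trips],
            "end": [tr.end for tr in trips],
            "complete": [tr.complete for tr in trips],
            "duration_h": [tr.duration_h for tr in trips],
            "path_length_km": [tr.path_length_km for tr in trips],
            "max_range_km": [tr.max_range_km for tr in trips],
            "mean_speed_kmh": [tr.mean_speed_kmh for tr in trips],
        }
    )


# ---------------------------------------------------------------------------
# kernel utilization distribution

@dataclass
class UDGrid:
    """Gridded kernel utilization distribution in a local planar frame.

    ``mass[iy, ix]`` is probability mass per cell (sums to 1); the frame is
    azimuthal-equidistant centred on (``center_lat``, ``center_lon``); the
    origin (``x0``, ``y0``) is the lower-left cell *centre* in km.
    """

    x0: float
    y0: float
    cell_km: float
    mass: np.ndarray
    bandwidth_km: float
    center_lat: float
    center_lon: float

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + self.cell_km * np.arange(self.mass.shape[1])

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + self.cell_km * np.arange(self.mass.shape[0])

    def to_frame(self) -> pd.DataFrame:
        iy, ix = np.nonzero(self.mass > 0)
        return pd.DataFrame(
            {
                "x_km": self.x_centers[ix],
                "y_km": self.y_centers[iy],
                "mass": self.mass[iy, ix],
            }
        )


def href_bandwidth_km(x: np.ndarray, y: np.ndarray) -> float:
    """Reference bandwidth sigma * n**(-1/6), sigma the mean marginal SD."""
    sigma = 0.5 * (np.std(x, ddof=1) + np.std(y, ddof=1))
    return float(sigma * len(x) ** (-1.0 / 6.0))


def kernel_ud(
    lat,
    lon,
    bandwidth_km: float | str = "href",
    cell_km: float = 2.0,
) -> UDGrid:
    """Bivariate Gaussian kernel UD of a point cloud.

    Points are projected to an azimuthal-equidistant frame centred on their
    centroid; the density is evaluated exactly (sum of Gaussians) at cell
    centres on a grid padded by three bandwidths, then normalised so cell
    masses sum to 1.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size < 10:
        raise InsufficientDataError(f"kernel UD needs >=10 points, got {lat.size}")
    c_lat, c_lon = float(np.mean(lat)), float(np.mean(lon))
    x, y = aeqd_forward(lat, lon, c_lat, c_lon)
    h = href_bandwidth_km(x, y) if bandwidth_km == "href" else float(bandwidth_km)
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    pad = 3.0 * h
    xc = np.arange(x.min() - pad, x.max() + pad + cell_km, cell_km)
    yc = np.arange(y.min() - pad, y.max() + pad + cell_km, cell_km)
    # separable exact evaluation: density = Gx @ Gy.T summed over points
    gx = np.exp(-((xc[:, None] - x[None, :]) ** 2) / (2.0 * h * h))
    gy = np.exp(-((yc[:, None] - y[None, :]) ** 2) / (2.0 * h * h))
    dens = gy @ gx.T  # (ny, nx)
    mass = dens / dens.sum()
    return UDGrid(
        x0=float(xc[0]), y0=float(yc[0]), cell_km=cell_km, mass=mass,
        bandwidth_km=h, center_lat=c_lat, center_lon=c_lon,
    )


def ud_contour(ud: UDGrid, level: float = 0.90):
    """Volume contour: smallest set of highest-density cells with mass >= level.

    Cells enter in decreasing density; equal densities at the cutoff are
    resolved in stable grid order so the set stays minimal (a uniform density
    on 100 cells at level 0.9 yields exactly 90 cells). Returns
    ``(mask, polygons)`` where ``mask`` is a boolean cell array and
    ``polygons`` a list of shapely Polygons (planar km) tracing the boundary.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    flat = ud.mass.ravel()
    order = np.argsort(flat, kind="stable")[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level) + 1)
    k = min(k, len(flat))
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    mask &= flat > 0
    mask = mask.reshape(ud.mass.shape)

    half = ud.cell_km / 2.0
    boxes = [
        sgeom.box(
            ud.x0 + ix * ud.cell_km - half,
            ud.y0 + iy * ud.cell_km - half,
            ud.x0 + ix * ud.cell_km + half,
            ud.y0 + iy * ud.cell_km + half,
        )
        for iy, ix in zip(*np.nonzero(mask))
    ]
    merged = unary_union(boxes) if boxes else sgeom.Polygon()
    if merged.is_empty:
        polys = []
    elif merged.geom_type == "Polygon":
        polys = [merged]
    else:
        polys = list(merged.geoms)
    return mask, polys


def contour_area_km2(mask: np.ndarray, cell_km: float) -> float:
    return float(mask.sum()) * cell_km * cell_km


def contour_mass(ud: UDGrid, mask: np.ndarray) -> float:
    return float(ud.mass[mask].sum())


def points_inside_fraction(ud: UDGrid, mask: np.ndarray, lat, lon) -> float:
    """Fraction of points falling in cells included in the contour mask."""
    x, y = aeqd_forward(np.asarray(lat, float), np.asarray(lon, float), ud.center_lat, ud.center_lon)
    ix = np.round((x - ud.x0) / ud.cell_km).astype(int)
    iy = np.round((y - ud.y0) / ud.cell_km).astype(int)
    ny, nx = ud.mass.shape
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    inside = np.zeros(len(x), dtype=bool)
    inside[ok] = mask[iy[ok], ix[ok]]
    return float(inside.mean())


def contour_geojson(ud: UDGrid, polys, level: float) -> dict:
    """Contour polygons as a GeoJSON FeatureCollection in WGS84."""
    feats = []
    for p in polys:
        rings = [np.asarray(p.exterior.coords)] + [np.asarray(r.coords) for r in p.interiors]
        ll_rings = []
        for ring in rings:
            la, lo = aeqd_inverse(ring[:, 0], ring[:, 1], ud.center_lat, ud.center_lon)
            ll_rings.append([[float(a), float(b)] for a, b in zip(lo, la)])
        feats.append(
            {
                "type": "Feature",
                "properties": {"level": level, "bandwidth_km": ud.bandwidth_km},
                "geometry": {"type": "Polygon", "coordinates": ll_rings},
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def write_contour_geojson(ud: UDGrid, polys, level: float, path) -> None:
    with open(path, "w") as fh:
        json.dump(contour_geojson(ud, polys, level), fh)
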