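"""Core trajectory data model for bird-borne GPS / radar-detector loggers.

A :class:`Track` holds one bird's time-ordered fixes in a pandas DataFrame
with a small fixed schema. Two device classes are distinguished:

* ``GPS30s`` — plain GPS logger sampling every 30 s, no radar detector;
* ``XGPS1min`` — combined GPS + X-band radar detector: a fix every minute
  and a radar scan (30-s signal integration) every minute.

The radar scan result is ternary (``positive`` / ``negative`` / ``no-scan``):
a device that never scanned is not evidence of vessel absence, so "no scan"
must never be conflated with "no detection".

All timestamps are UTC. Geometry is spherical (radius 6371.0088 km); at the
<=200 km ranges of a chick-provisioning gannet the ellipsoidal correction is
far below GPS noise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

from .errors import DegenerateTrackError, SchemaError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

RADAR_POSITIVE = "positive"
RADAR_NEGATIVE = "negative"
RADAR_NOSCAN = "no-scan"
RADAR_VALUES = (RADAR_POSITIVE, RADAR_NEGATIVE, RADAR_NOSCAN)

DEVICE_GPS30S = "GPS30s"
DEVICE_XGPS = "XGPS1min"

#: canonical fix-table columns; device_speed_kmh / speed_kmh / is_night optional
FIX_COLUMNS = ("time", "lat", "lon")


class GeoFix(NamedTuple):
    """One timestamped position with derived annotations."""

    time: pd.Timestamp
    lat: float
    lon: float
    speed: float | None  # km/h, position-derived; None until derive_speeds
    radar: str  # RADAR_POSITIVE / RADAR_NEGATIVE / RADAR_NOSCAN
    is_night: bool | None


@dataclass
class Colony:
    """Breeding colony location with the buffer radius defining "at colony"."""

    lat: float
    lon: float
    radius_km: float = 2.0

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("colony radius_km must be > 0")
        if not (-90 <= self.lat <= 90) or not (-180 < self.lon <= 180):
            raise ValueError("colony coordinates out of range")


@dataclass
class Track:
    """Time-ordered fixes for one bird.

    ``fixes`` columns: time (UTC datetime64), lat, lon, radar (str); plus
    device_speed_kmh (device-reported, optional), speed_kmh (derived),
    is_night after annotation.
    """

    bird_id: str
    device: str
    fixes: pd.DataFrame
    complete: bool = True

    def __post_init__(self) -> None:
        if self.device not in (DEVICE_GPS30S, DEVICE_XGPS):
            raise ValueError(f"unknown device {self.device!r}")
        df = self.fixes
        if "radar" not in df.columns:
            df = df.copy()
            df["radar"] = RADAR_NOSCAN
            self.fixes = df
        tcol = df["time"]
        if len(tcol) > 1 and (
            not tcol.is_monotonic_increasing or tcol.duplicated().any()
        ):
            raise ValueError(f"track {self.bird_id}: fix times not strictly increasing")
        if self.device == DEVICE_GPS30S and (df["radar"] != RADAR_NOSCAN).any():
            raise ValueError(f"track {self.bird_id}: GPS30s device cannot carry radar scans")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def has_scans(self) -> bool:
        return bool((self.fixes["radar"] != RADAR_NOSCAN).any())

    def iter_fixes(self) -> Iterator[GeoFix]:
        sp = self.fixes["speed_kmh"] if "speed_kmh" in self.fixes else None
        nt = self.fixes["is_night"] if "is_night" in self.fixes else None
        for i, row in enumerate(self.fixes.itertuples(index=False)):
            yield GeoFix(
                time=row.time,
                lat=row.lat,
                lon=row.lon,
                speed=None if sp is None else float(sp.iloc[i]),
                radar=row.radar,
                is_night=None if nt is None else bool(nt.iloc[i]),
            )


# ---------------------------------------------------------------------------
# geometry

def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in WGS84 degrees.

    Vectorised; symmetric, non-negative, satisfies the triangle inequality.
    """
    la1, lo1, la2, lo2 = (np.deg2rad(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def path_length_km(lat, lon) -> float:
    """Summed consecutive great-circle distances along a position sequence."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size < 2:
        return 0.0
    return float(np.sum(haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])))


# ---------------------------------------------------------------------------
# ingestion

DEFAULT_SCHEMA = {
    "id": "bird_id",
    "time": "time",
    "lat": "lat",
    "lon": "lon",
    "speed": "speed_kmh",
    "radar": "radar",
    "device": "device",
}


def read_tracks(
    path,
    schema: dict | None = None,
    default_device: str = DEVICE_XGPS,
    stats: dict | None = None,
) -> list[Track]:
    """Read delimited-text fixes (comma or tab autodetected) into Tracks.

    ``schema`` maps the logical fields id/time/lat/lon (required) and
    speed/radar/device (optional) to the file's column names. Rows with an
    unparseable timestamp or out-of-range coordinates are dropped and counted;
    duplicate timestamps within a bird keep the first row. ``stats``, if
    given, is filled with drop counts.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    raw = pd.read_csv(path, sep=None, engine="python")
    for key in ("id", "time", "lat", "lon"):
        if sch[key] not in raw.columns:
            raise SchemaError(f"required column {sch[key]!r} (field {key!r}) not found in {path}")

    n0 = len(raw)
    df = pd.DataFrame(
        {
            "bird_id": raw[sch["id"]].astype(str),
            "time": pd.to_datetime(raw[sch["time"]], errors="coerce", utc=True, format="ISO8601"),
            "lat": pd.to_numeric(raw[sch["lat"]], errors="coerce"),
            "lon": pd.to_numeric(raw[sch["lon"]], errors="coerce"),
        }
    )
    if sch["speed"] in raw.columns:
        df["device_speed_kmh"] = pd.to_numeric(raw[sch["speed"]], errors="coerce")
    if sch["radar"] in raw.columns:
        df["radar"] = raw[sch["radar"]].fillna(RADAR_NOSCAN).astype(str)
    else:
        df["radar"] = RADAR_NOSCAN
    if sch["device"] in raw.columns:
        df["device"] = raw[sch["device"]].astype(str)
    else:
        df["device"] = default_device

    bad_time = df["time"].isna()
    bad_coord = ~(
        df["lat"].between(-90, 90) & (df["lon"] > -180) & (df["lon"] <= 180)
    ) | df["lat"].isna() | df["lon"].isna()
    keep = ~(bad_time | bad_coord)
    n_bad_time = int(bad_time.sum())
    n_bad_coord = int((bad_coord & ~bad_time).sum())
    df = df[keep]

    df = df.sort_values(["bird_id", "time"], kind="mergesort")
    dup = df.duplicated(subset=["bird_id", "time"], keep="first")
    n_dup = int(dup.sum())
    df = df[~dup]

    if stats is not None:
        stats.update(
            n_rows=n0, n_dropped_time=n_bad_time, n_dropped_coord=n_bad_coord,
            n_dropped_duplicate=n_dup, n_kept=len(df),
        )
    if n_bad_time or n_bad_coord or n_dup:
        logger.info(
            "read_tracks(%s): dropped %d unparseable-time, %d out-of-range, "
            "%d duplicate-time rows of %d",
            path, n_bad_time, n_bad_coord, n_dup, n0,
        )

    tracks = []
    for bird_id, g in df.groupby("bird_id", sort=True):
        device = g["device"].iloc[0]
        cols = ["time", "lat", "lon", "radar"] + (
            ["device_speed_kmh"] if "device_speed_kmh" in g.columns else []
        )
        tracks.append(Track(str(bird_id), device, g[cols].reset_index(drop=True)))
    return tracks


def write_tracks(tracks: Iterable[Track], path) -> None:
    """Write normalized tracks (with any derived columns) to one CSV."""
    frames = []
    for t in tracks:
        g = t.fixes.copy()
        g.insert(0, "bird_id", t.bird_id)
        g.insert(1, "device", t.device)
        frames.append(g)
    out = pd.concat(frames, ignore_index=True)
    out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# resampling

def resample_track(t: Track, interval_s: int = 60, max_gap_s: int = 600) -> Track:
    """Resample to a regular time grid anchored at the first fix.

    Positions are linearly interpolated in lat/lon between bracketing raw
    fixes. No fix is synthesized across a raw gap longer than ``max_gap_s``:
    the grid simply has no fix there (a grid instant exactly coinciding with
    a raw fix is always kept). Radar scan results are reassigned to the
    nearest grid instant within ``interval_s / 2`` without duplication.
    """
    if len(t) < 2:
        raise DegenerateTrackError(f"track {t.bird_id}: need >=2 fixes to resample")
    df = t.fixes
    tt = df["time"].astype("int64").to_numpy() / 1e9  # epoch seconds
    rel = tt - tt[0]
    n_grid = int(np.floor(rel[-1] / interval_s)) + 1
    grid = np.arange(n_grid, dtype=float) * interval_s

    # bracketing raw interval for each grid instant
    j = np.searchsorted(rel, grid, side="right")  # first raw strictly after g
    i = np.clip(j - 1, 0, len(rel) - 1)
    j = np.clip(j, 0, len(rel) - 1)
    on_fix = np.isclose(grid, rel[i], atol=1e-9)
    gap_ok = (rel[j] - rel[i]) <= max_gap_s
    keep = on_fix | (gap_ok & (j > i))

    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(j > i, (grid - rel[i]) / np.where(j > i, rel[j] - rel[i], 1.0), 0.0)
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    glat = lat[i] * (1 - w) + lat[j] * w
    glon = lon[i] * (1 - w) + lon[j] * w

    out = pd.DataFrame(
        {
            "time": pd.to_datetime((tt[0] + grid) * 1e9, utc=True),
            "lat": glat,
            "lon": glon,
            "radar": RADAR_NOSCAN,
        }
    )
    if "device_speed_kmh" in df.columns:
        dsp = df["device_speed_kmh"].to_numpy(dtype=float)
        out["device_speed_kmh"] = dsp[i] * (1 - w) + dsp[j] * w
    out = out[keep].reset_index(drop=True)
    kept_grid = grid[keep]

    # reassign scans: nearest kept grid instant within interval_s/2, no duplication
    scan_rows = np.flatnonzero((df["radar"] != RADAR_NOSCAN).to_numpy())
    occupied: dict[int, str] = {}
    n_lost = 0
    for r in scan_rows:
        ts = rel[r]
        k = int(np.searchsorted(kept_grid, ts))
        cands = sorted(
            (c for c in (k - 1, k, k + 1) if 0 <= c < len(kept_grid)),
            key=lambda c: abs(kept_grid[c] - ts),
        )
        placed = False
        for c in cands:
            if abs(kept_grid[c] - ts) <= interval_s / 2 and c not in occupied:
                occupied[c] = df["radar"].iat[r]
                placed = True
                break
        if not placed:
            n_lost += 1
            if df["radar"].iat[r] == RADAR_POSITIVE:
                logger.warning(
                    "track %s: positive radar scan at +%gs could not be mapped onto "
                    "the resampled grid (data gap); scan dropped", t.bird_id, ts,
                )
    if occupied:
        idx = np.fromiter(occupied.keys(), dtype=int)
        out.loc[idx, "radar"] = [occupied[k] for k in idx]

    return replace(t, fixes=out)


def derive_speeds(t: Track) -> Track:
    """Add position-derived speeds (km/h) as column ``speed_kmh``.

    Speed at fix i is the great-circle distance from fix i-1 divided by the
    elapsed time; the first fix inherits the second's speed. Device-reported
    speed, when present, is kept separately in ``device_speed_kmh``.
    """
    df = t.fixes.copy()
    if len(df) < 2:
        df["speed_kmh"] = 0.0
        return replace(t, fixes=df)
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    tt = df["time"].astype("int64").to_numpy() / 1e9
    d = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dt_h = np.diff(tt) / 3600.0
    sp = np.empty(len(df))
    sp[1:] = d / dt_h
    sp[0] = sp[1]
    df["speed_kmh"] = sp
    return replace(t, fixes=df)


# ---------------------------------------------------------------------------
# solar position / day-night annotation

def solar_elevation_deg(lat, lon, times) -> np.ndarray:
    """Solar elevation angle (degrees) from the low-precision NOAA formulas.

    Declination and the equation of time from the Spencer Fourier fits;
    accurate to well under 0.5 degrees, ample for a day/night flag.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    times = pd.DatetimeIndex(times)
    doy = times.dayofyear.to_numpy().astype(float)
    frac_h = (
        times.hour.to_numpy() + times.minute.to_numpy() / 60.0 + times.second.to_numpy() / 3600.0
    )
    g = 2.0 * np.pi / 365.0 * (doy - 1.0 + (frac_h - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    tst = frac_h * 60.0 + eqtime + 4.0 * lon  # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle
    la = np.deg2rad(lat)
    cos_zen = np.sin(la) * np.sin(decl) + np.cos(la) * np.cos(decl) * np.cos(ha)
    return 90.0 - np.rad2deg(np.arccos(np.clip(cos_zen, -1.0, 1.0)))


def annotate_night(t: Track) -> Track:
    """Add boolean ``is_night``: true iff solar elevation < 0 at the fix."""
    df = t.fixes.copy()
    elev = solar_elevation_deg(df["lat"].to_numpy(), df["lon"].to_numpy(), df["time"])
    df["is_night"] = elev < 0.0
    return replace(t, fixes=df)
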