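"""Ground-truthed biologger simulator: bird trips, a fishing fleet, radar scans.

The simulator is a test harness for the downstream pipeline, not an
inference target. It emulates the study conditions of a radar-detector
tracking campaign on a gannet colony: fixes every 30 s or 60 s, a radar scan
every minute with a hard 5 km detection footprint, commuting flight at
47 +/- 11 km/h, vessels steaming at 13 km/h, trips of hours to days from a
fixed colony.

A bird's trip is a behavioural state machine on a planar
azimuthal-equidistant frame centred on the colony:

    colony -> commute(out) -> {search | rest | attend}* -> commute(in) -> colony

Per-state speeds are truncated normals; headings are persistent while
commuting and tortuous while searching; at night the bird rests, drifting
slowly on the water. On entering the detection footprint of a vessel the
bird either begins attending (probability ``p_attend_given_proximity``),
tracking the vessel closely at the vessel's working speed, or it avoids the
vessel — flying directly away at commuting speed, the documented response of
non-scavenging birds (including flushing off the water when resting).
Avoidance is what keeps chance footprint crossings fast and brief.

Everything emitted is reproducible from the seed, and every scan carries
ground truth (behavioural state, nearest-vessel distance, attendance bouts).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom
import yaml

from ._project import aeqd_forward, aeqd_inverse
from .geotrack import (
    DEVICE_GPS30S,
    DEVICE_XGPS,
    RADAR_NEGATIVE,
    RADAR_NOSCAN,
    RADAR_POSITIVE,
    Colony,
    Track,
    solar_elevation_deg,
)

STUDY_START = pd.Timestamp("2017-10-24T00:00:00Z")

#: default shelf polygon vertices, km in the colony-centred frame
#: (ocean west and south-southeast of the colony)
DEFAULT_SHELF = [(-160.0, -230.0), (150.0, -230.0), (150.0, 40.0), (-160.0, 40.0)]


@dataclass
class SimConfig:
    """All knobs of the simulator, with the campaign's conditions as defaults."""

    seed: int = 0
    n_birds: int = 50
    xgps_fraction: float = 0.4  # 20 of 50 birds carry the radar detector
    n_trips_per_bird: int = 1
    colony: Colony = field(default_factory=lambda: Colony(-33.05, 17.93, 2.0))
    # speeds, km/h
    commute_speed_mean: float = 47.0
    commute_speed_sd: float = 11.0
    attend_speed_mean: float = 13.0
    attend_speed_sd: float = 4.3
    rest_speed_max: float = 5.0
    search_speed_mean: float = 20.0
    search_speed_sd: float = 6.0
    vessel_speed: float = 13.0
    # fleet / detector: density chosen to put a foraging bird within radar
    # range of a vessel roughly once per trip, the regime of a shelf worked
    # daily by a demersal trawl fleet
    n_vessels: int = 35
    detection_radius_km: float = 5.0
    vessel_turn_sd_deg: float = 12.0
    scan_interval_s: int = 60
    fix_interval_s: int = 60
    p_attend_given_proximity: float = 0.5
    # a disturbed bird relocates: it keeps flying until this many detection
    # radii from the vessel before resuming its previous behaviour
    avoid_exit_radius_factor: float = 2.5
    # state-duration / trip-envelope means
    attend_duration_mean_h: float = 1.7
    forage_budget_mean_h: float = 12.0
    trip_range_mean_km: float = 93.0
    trip_range_sd_km: float = 59.0
    max_trip_h: float = 168.0  # 7 days, the longest recorded deployment
    search_turn_sd_deg: float = 60.0
    shelf: list = field(default_factory=lambda: [list(v) for v in DEFAULT_SHELF])
    # morphometrics / diet generation
    n_chicks: int = 30
    n_diet_samples: int = 14
    adult_mass_mean_g: float = 2600.0
    adult_mass_sd_g: float = 170.0
    adult_wing_mean_mm: float = 480.0
    adult_wing_sd_mm: float = 12.0
    chick_growth_mean_g_day: float = 60.0
    chick_growth_sd_g_day: float = 20.0
    diet_species_probs: dict = field(default_factory=lambda: {"saury": 1.0})

    def __post_init__(self) -> None:
        for name in (
            "commute_speed_mean", "commute_speed_sd", "attend_speed_mean",
            "attend_speed_sd", "rest_speed_max", "search_speed_mean",
            "vessel_speed", "detection_radius_km", "scan_interval_s",
            "fix_interval_s", "attend_duration_mean_h", "forage_budget_mean_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.p_attend_given_proximity <= 1.0:
            raise ValueError("p_attend_given_proximity must be in [0, 1]")
        if not 0.0 <= self.xgps_fraction <= 1.0:
            raise ValueError("xgps_fraction must be in [0, 1]")

    @property
    def shelf_polygon(self) -> sgeom.Polygon:
        return sgeom.Polygon(self.shelf)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "colony" in raw and isinstance(raw["colony"], dict):
            raw["colony"] = Colony(**raw["colony"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = {**self.__dict__}
        d["colony"] = {"lat": self.colony.lat, "lon": self.colony.lon,
                       "radius_km": self.colony.radius_km}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class Fleet:
    """Vessel trajectories on the colony-centred planar frame."""

    t0: pd.Timestamp
    dt_s: int
    xy: np.ndarray  # (n_vessels, n_steps, 2) km

    @property
    def n_vessels(self) -> int:
        return self.xy.shape[0]

    @property
    def n_steps(self) -> int:
        return self.xy.shape[1]

    def positions_at(self, t: pd.Timestamp) -> np.ndarray:
        """Vessel positions (n_vessels, 2) linearly interpolated in time."""
        s = (t - self.t0).total_seconds() / self.dt_s
        i = int(np.floor(s))
        if i < 0 or i >= self.n_steps:
            raise ValueError("time outside fleet simulation window")
        if i == self.n_steps - 1:
            return self.xy[:, i]
        w = s - i
        return self.xy[:, i] * (1 - w) + self.xy[:, i + 1] * w


@dataclass
class SimTruth:
    """Per-fix ground truth of one simulated trip."""

    bird_id: str
    frame: pd.DataFrame  # time, state, nearest_vessel_km, scanned, bout_id
    bouts: pd.DataFrame  # bout_id, start, end


def truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                     size=None, low: float = 0.0) -> np.ndarray | float:
    """Normal(mean, sd) truncated below at ``low``, sampled by rejection."""
    n = 1 if size is None else int(np.prod(size))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        ok = draw > low
        k = int(ok.sum())
        out[filled:filled + k] = draw[ok]
        filled += k
    if size is None:
        return float(out[0])
    return out.reshape(size)


def _unit(az_rad: float) -> np.ndarray:
    return np.array([np.sin(az_rad), np.cos(az_rad)])


def simulate_fleet(cfg: SimConfig, n_steps: int, rng: np.random.Generator,
                   t0: pd.Timestamp = STUDY_START) -> Fleet:
    """Correlated random walk of ``n_vessels`` at constant ``vessel_speed``.

    Headings persist with Gaussian turning noise; a step that would leave
    the shelf polygon is re-aimed toward the polygon centroid (step length,
    hence cumulative path length, is exactly ``vessel_speed * elapsed``).
    """
    nv = cfg.n_vessels
    poly = cfg.shelf_polygon
    xy = np.empty((nv, n_steps, 2))
    if nv == 0:
        return Fleet(t0=t0, dt_s=cfg.scan_interval_s, xy=xy)
    minx, miny, maxx, maxy = poly.bounds
    pos = np.empty((nv, 2))
    placed = 0
    while placed < nv:  # rejection-sample initial positions inside the shelf
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(nv - placed, 2))
        ok = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        k = int(ok.sum())
        pos[placed:placed + k] = cand[ok]
        placed += k
    heading = rng.uniform(0.0, 2 * np.pi, size=nv)
    step_km = cfg.vessel_speed * cfg.scan_interval_s / 3600.0
    turn_sd = np.deg2rad(cfg.vessel_turn_sd_deg)
    cx, cy = poly.centroid.x, poly.centroid.y
    xy[:, 0] = pos
    for s in range(1, n_steps):
        heading = heading + rng.normal(0.0, turn_sd, size=nv)
        prop = pos + step_km * np.column_stack([np.sin(heading), np.cos(heading)])
        outside = ~shapely.contains_xy(poly, prop[:, 0], prop[:, 1])
        if outside.any():
            back = np.arctan2(cx - pos[outside, 0], cy - pos[outside, 1])
            heading[outside] = back + rng.normal(0.0, 0.3, size=int(outside.sum()))
            prop[outside] = pos[outside] + step_km * np.column_stack(
                [np.sin(heading[outside]), np.cos(heading[outside])]
            )
        pos = prop
        xy[:, s] = pos
    return Fleet(t0=t0, dt_s=cfg.scan_interval_s, xy=xy)


def _is_night(cfg: SimConfig, x: float, y: float, t: pd.Timestamp) -> bool:
    lat, lon = aeqd_inverse(x, y, cfg.colony.lat, cfg.colony.lon)
    return bool(solar_elevation_deg(float(lat), float(lon), [t])[0] < 0.0)


def simulate_trip(
    cfg: SimConfig,
    bird_seed: int,
    fleet: Fleet | None = None,
    depart_time: pd.Timestamp | None = None,
    device: str = DEVICE_XGPS,
    bird_id: str | None = None,
) -> tuple[Track, SimTruth]:
    """Simulate one foraging trip; returns the logger Track and its truth.

    The Track mimics what the device records (fixes, radar scan results, a
    noisy device speed for the plain GPS logger); the SimTruth carries the
    per-fix behavioural state, nearest-vessel distance and attendance bouts.
    """
    rng = np.random.default_rng([cfg.seed, int(bird_seed)])
    bird_id = bird_id or f"bird_{bird_seed:03d}"
    dt = cfg.fix_interval_s
    dt_h = dt / 3600.0
    R = cfg.detection_radius_km
    poly = cfg.shelf_polygon
    if depart_time is None:
        depart_time = STUDY_START + pd.Timedelta(hours=float(rng.uniform(6.0, 14.0)))
    if fleet is None:
        n_steps = int(cfg.max_trip_h * 3600 / cfg.scan_interval_s) + 2880
        fleet = simulate_fleet(cfg, n_steps, np.random.default_rng([cfg.seed, 7]),
                               t0=depart_time - pd.Timedelta(days=1))

    # outbound target: a point at trip-range distance inside the shelf
    for _ in range(200):
        az = np.deg2rad(rng.uniform(135.0, 290.0))
        dist = truncated_normal(rng, cfg.trip_range_mean_km, cfg.trip_range_sd_km, low=15.0)
        if poly.contains(sgeom.Point(dist * np.sin(az), dist * np.cos(az))):
            break
    target_az, target_dist = float(az), float(dist)

    scan_every = max(1, round(cfg.scan_interval_s / dt))
    max_steps = int(cfg.max_trip_h * 3600 / dt)

    rows = []  # time, x, y, state, nearest_km, scanned, bout_id
    bouts: list[dict] = []

    def nearest_km(t, p):
        if fleet.n_vessels == 0:
            return np.inf, -1
        v = fleet.positions_at(t)
        d = np.hypot(v[:, 0] - p[0], v[:, 1] - p[1])
        j = int(np.argmin(d))
        return float(d[j]), j

    def record(step, t, p, state, scanned):
        nk, _ = nearest_km(t, p)
        rows.append((t, p[0], p[1], state, nk, scanned,
                     bouts[-1]["bout_id"] if state == "attend" else -1))
        return nk

    # ------- at-colony dwell before departure (5 fixes)
    t = depart_time - pd.Timedelta(seconds=5 * dt)
    pos = np.zeros(2)
    for s in range(5):
        jitter = rng.normal(0.0, 0.05, 2)
        record(s, t, jitter, "rest", (s % scan_every == 0) and device == DEVICE_XGPS)
        t += pd.Timedelta(seconds=dt)

    state = "commute_out"
    base_state = "search"
    heading = target_az
    forage_end: pd.Timestamp | None = None
    bout_end: pd.Timestamp | None = None
    attend_vessel = -1
    attend_mode = "chase"
    was_in_footprint = False
    bout_counter = -1

    for step in range(max_steps):
        scanned = (step % scan_every == 0) and device == DEVICE_XGPS
        night = _is_night(cfg, pos[0], pos[1], t)
        nk, nv_idx = nearest_km(t, pos)

        # state transitions driven by vessel proximity
        in_footprint = nk <= R
        if state in ("search", "rest") and in_footprint and not was_in_footprint:
            if rng.random() < cfg.p_attend_given_proximity:
                state = "attend"
                attend_vessel = nv_idx
                bout_counter += 1
                dur_h = min(max(rng.exponential(cfg.attend_duration_mean_h), 4 / 60), 6.0)
                bout_end = t + pd.Timedelta(hours=dur_h)
                attend_mode = "chase"
                bouts.append({"bout_id": bout_counter, "start": t, "end": bout_end})
            else:
                state = "avoid"
        was_in_footprint = in_footprint

        # behaviour of the current state
        if state == "attend":
            # sit-and-chase attendance: drift on the water until the vessel
            # opens a gap, then a flight burst to catch up. Time-averaged
            # ground speed equals the vessel's, i.e. attend_speed_mean at the
            # defaults, with about half the fixes at sitting speeds.
            v = fleet.positions_at(t)[attend_vessel]
            gap = pos - v
            d = float(np.hypot(*gap))
            if attend_mode == "sit" and d > 0.5 * R:
                attend_mode = "chase"
            elif attend_mode == "chase" and d < 0.15 * R:
                attend_mode = "sit"
            if attend_mode == "sit":
                drift = float(rng.uniform(0.2, 1.5)) * dt_h
                new_pos = pos + drift * _unit(rng.uniform(0.0, 2 * np.pi))
            else:
                sp = truncated_normal(
                    rng, cfg.vessel_speed + cfg.attend_speed_mean,
                    2.0 * cfg.attend_speed_sd, low=cfg.vessel_speed + 2.0,
                )
                toward = np.arctan2(v[0] - pos[0], v[1] - pos[1])
                step = min(sp * dt_h, max(d - 0.1 * R, 0.0))
                new_pos = pos + step * _unit(toward)
            if t >= bout_end:
                bouts[-1]["end"] = t
                state = "avoid"
                was_in_footprint = True
        elif state == "avoid":
            v = fleet.positions_at(t)[nv_idx] if nv_idx >= 0 else np.zeros(2)
            away = np.arctan2(pos[0] - v[0], pos[1] - v[1])
            sp = truncated_normal(rng, cfg.commute_speed_mean, cfg.commute_speed_sd, low=5.0)
            new_pos = pos + sp * dt_h * _unit(away + rng.normal(0.0, 0.1))
            if nk > cfg.avoid_exit_radius_factor * R:
                state = base_state if forage_end is not None else "commute_out"
        elif state == "commute_out":
            sp = truncated_normal(rng, cfg.commute_speed_mean, cfg.commute_speed_sd, low=5.0)
            new_pos = pos + sp * dt_h * _unit(heading + rng.normal(0.0, np.deg2rad(5.0)))
            if np.hypot(*new_pos) >= target_dist:
                state = "search"
                forage_end = t + pd.Timedelta(
                    hours=float(np.clip(rng.exponential(cfg.forage_budget_mean_h), 2.0, 72.0))
                )
        elif state == "commute_in":
            back = np.arctan2(-pos[0], -pos[1])
            sp = truncated_normal(rng, cfg.commute_speed_mean, cfg.commute_speed_sd, low=5.0)
            new_pos = pos + sp * dt_h * _unit(back + rng.normal(0.0, np.deg2rad(4.0)))
            if np.hypot(*new_pos) <= cfg.colony.radius_km * 0.5:
                record(step, t, new_pos, "commute", scanned)
                t += pd.Timedelta(seconds=dt)
                break
        else:  # search / rest, by daylight
            if night:
                state = "rest"
                sp = float(rng.uniform(0.3, min(2.0, cfg.rest_speed_max)))
                heading = heading + rng.normal(0.0, np.deg2rad(20.0))
            else:
                state = "search"
                sp = truncated_normal(rng, cfg.search_speed_mean, cfg.search_speed_sd, low=2.0)
                heading = heading + rng.normal(0.0, np.deg2rad(cfg.search_turn_sd_deg))
            base_state = state
            new_pos = pos + sp * dt_h * _unit(heading)
            if forage_end is not None and t >= forage_end:
                state = "commute_in"

        # keep the bird over the shelf (except on the final approach home)
        if state not in ("commute_in", "attend") and not poly.contains(
            sgeom.Point(new_pos[0], new_pos[1])
        ):
            back = np.arctan2(-pos[0], -pos[1])
            new_pos = pos + 20.0 * dt_h * _unit(back)
            heading = back

        truth_state = {
            "commute_out": "commute", "commute_in": "commute", "avoid": "commute",
            "search": "search", "rest": "rest", "attend": "attend",
        }[state]
        record(step, t, new_pos, truth_state, scanned)
        pos = new_pos
        t += pd.Timedelta(seconds=dt)
        if state != "commute_in" and forage_end is not None and step == max_steps - 1:
            break
        if forage_end is None and step * dt_h > cfg.max_trip_h / 2:
            forage_end = t  # never reached the target; turn around
            state = "commute_in"

    # ------- at-colony dwell after return
    for s in range(5):
        jitter = rng.normal(0.0, 0.05, 2)
        record(0, t, jitter, "rest", False)
        t += pd.Timedelta(seconds=dt)

    times = pd.DatetimeIndex([r[0] for r in rows])
    x = np.array([r[1] for r in rows])
    y = np.array([r[2] for r in rows])
    lat, lon = aeqd_inverse(x, y, cfg.colony.lat, cfg.colony.lon)
    nearest = np.array([r[4] for r in rows])
    scanned = np.array([r[5] for r in rows], dtype=bool)
    radar = np.where(
        scanned, np.where(nearest <= R, RADAR_POSITIVE, RADAR_NEGATIVE), RADAR_NOSCAN
    )
    fixes = pd.DataFrame({"time": times, "lat": lat, "lon": lon, "radar": radar})
    if device == DEVICE_GPS30S:
        step_km = np.hypot(np.diff(x, prepend=x[0]), np.diff(y, prepend=y[0]))
        dev_speed = step_km / dt_h + rng.normal(0.0, 0.5, len(x))
        fixes["device_speed_kmh"] = np.clip(dev_speed, 0.0, None)
        fixes["radar"] = RADAR_NOSCAN
    track = Track(bird_id, device, fixes)

    truth_frame = pd.DataFrame(
        {
            "time": times,
            "state": [r[3] for r in rows],
            "nearest_vessel_km": nearest,
            "scanned": scanned if device == DEVICE_XGPS else False,
            "bout_id": [r[6] for r in rows],
        }
    )
    bouts_df = pd.DataFrame(bouts, columns=["bout_id", "start", "end"])
    return track, SimTruth(bird_id=bird_id, frame=truth_frame, bouts=bouts_df)


def attendance_bouts(truth_frame: pd.DataFrame) -> pd.DataFrame:
    """Recover attendance intervals from a per-fix truth table."""
    rows = []
    att = truth_frame[truth_frame["bout_id"] >= 0]
    for (bid, g) in att.groupby("bout_id"):
        rows.append({"bout_id": int(bid), "start": g["time"].iloc[0], "end": g["time"].iloc[-1]})
    return pd.DataFrame(rows, columns=["bout_id", "start", "end"])


def generate_dataset(cfg: SimConfig, out_dir) -> dict[str, Path]:
    """Write a full synthetic campaign: tracks, truth, morphometrics, diet.

    ``n_birds`` tracks (the first ``round(n_birds * xgps_fraction)`` carry
    the radar detector, the rest are plain 30-s GPS loggers with a
    device-reported speed column), a per-fix truth table with attendance
    bouts, adult morphometrics, chick mass series and diet samples. Byte
    identical given the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 2])
    n_xgps = int(round(cfg.n_birds * cfg.xgps_fraction))

    birds_per_day = 6
    n_days = cfg.n_birds // birds_per_day + 1 + int(np.ceil(cfg.max_trip_h / 24)) + 2
    fleet = simulate_fleet(
        cfg, int(n_days * 86400 / cfg.scan_interval_s),
        np.random.default_rng([cfg.seed, 3]),
    )

    track_frames, truth_frames, bout_frames = [], [], []
    for i in range(cfg.n_birds):
        device = DEVICE_XGPS if i < n_xgps else DEVICE_GPS30S
        bird_id = f"{'X' if device == DEVICE_XGPS else 'G'}{i + 1:03d}"
        brng = np.random.default_rng([cfg.seed, 1000 + i])
        depart = STUDY_START + pd.Timedelta(
            days=i // birds_per_day, hours=float(brng.uniform(5.0, 15.0))
        )
        for k in range(cfg.n_trips_per_bird):
            dcfg = dataclass_replace_interval(cfg, device)
            track, truth = simulate_trip(
                dcfg, bird_seed=1000 + i * 10 + k, fleet=fleet,
                depart_time=depart, device=device, bird_id=bird_id,
            )
            g = track.fixes.copy()
            # raw logger files report speed as plain "speed_kmh"
            g = g.rename(columns={"device_speed_kmh": "speed_kmh"})
            g.insert(0, "bird_id", bird_id)
            g.insert(1, "device", device)
            track_frames.append(g)
            tf = truth.frame.copy()
            tf.insert(0, "bird_id", bird_id)
            truth_frames.append(tf)
            bf = truth.bouts.copy()
            bf.insert(0, "bird_id", bird_id)
            bout_frames.append(bf)
            depart = track.fixes["time"].iloc[-1] + pd.Timedelta(hours=float(brng.uniform(8, 20)))

    tracks_df = pd.concat(track_frames, ignore_index=True)
    tracks_df["time"] = tracks_df["time"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    paths = {"tracks": out / "tracks.csv", "truth": out / "truth.csv",
             "bouts": out / "bouts.csv", "adults": out / "morpho_adults.csv",
             "chicks": out / "morpho_chicks.csv", "diet": out / "diet.csv",
             "config": out / "config_resolved.yaml"}
    tracks_df.to_csv(paths["tracks"], index=False)
    truth_df = pd.concat(truth_frames, ignore_index=True)
    truth_df["time"] = truth_df["time"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    truth_df.to_csv(paths["truth"], index=False)
    bout_frames = [b for b in bout_frames if len(b)]
    bouts_df = pd.concat(bout_frames, ignore_index=True) if bout_frames else pd.DataFrame(
        columns=["bird_id", "bout_id", "start", "end"])
    for c in ("start", "end"):
        if len(bouts_df):
            bouts_df[c] = pd.to_datetime(bouts_df[c]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    bouts_df.to_csv(paths["bouts"], index=False)

    # morphometrics: adults, chick mass series, diet occurrences
    adults = pd.DataFrame(
        {
            "bird_id": [f"A{i + 1:03d}" for i in range(cfg.n_birds)],
            "mass_g": np.round(truncated_normal(
                rng, cfg.adult_mass_mean_g, cfg.adult_mass_sd_g, cfg.n_birds, low=1500.0
            ) / 10) * 10,
            "wing_mm": np.round(truncated_normal(
                rng, cfg.adult_wing_mean_mm, cfg.adult_wing_sd_mm, cfg.n_birds, low=400.0
            )),
        }
    )
    adults.to_csv(paths["adults"], index=False)

    chick_rows = []
    for c in range(cfg.n_chicks):
        mass = float(truncated_normal(rng, 800.0, 200.0, low=150.0))
        date = STUDY_START + pd.Timedelta(days=int(rng.integers(0, 3)))
        rate = float(rng.normal(cfg.chick_growth_mean_g_day, cfg.chick_growth_sd_g_day))
        for m in range(int(rng.integers(2, 5))):
            chick_rows.append(
                {"chick_id": f"C{c + 1:03d}", "date": date.strftime("%Y-%m-%d"),
                 "mass_g": round(mass)}
            )
            gap = int(rng.integers(2, 5))
            date += pd.Timedelta(days=gap)
            mass += rate * gap + float(rng.normal(0.0, 15.0))
    pd.DataFrame(chick_rows).to_csv(paths["chicks"], index=False)

    species = list(cfg.diet_species_probs)
    probs = np.array([cfg.diet_species_probs[s] for s in species], dtype=float)
    probs = probs / probs.sum()
    diet_rows = []
    for s in range(cfg.n_diet_samples):
        sp = species[int(rng.choice(len(species), p=probs))]
        diet_rows.append(
            {"sample_id": f"D{s + 1:03d}",
             "date": (STUDY_START + pd.Timedelta(days=int(rng.integers(0, 13)))).strftime("%Y-%m-%d"),
             "species": sp}
        )
    pd.DataFrame(diet_rows).to_csv(paths["diet"], index=False)
    cfg.to_yaml(paths["config"])
    return paths


def dataclass_replace_interval(cfg: SimConfig, device: str) -> SimConfig:
    """Per-device fix cadence: 30 s for the plain GPS logger, 60 s for XGPS."""
    if device == DEVICE_XGPS or cfg.fix_interval_s != 60:
        return cfg
    from dataclasses import replace

    return replace(cfg, fix_interval_s=30)
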