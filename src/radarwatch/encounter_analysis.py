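"""Vessel-encounter detection and attendance classification.

The radar detector on an XGPS tag scans once a minute; a positive scan means
a marine X-band radar (in practice a vessel) is within detection range
(~5 km, validated at sea). Successive positive scans separated by less than
one hour are grouped into one "encounter" with a single vessel. Each
encounter is characterised by its duration, the bird's average travel speed
between first and last detection, and the proportion of fixes in that window
carrying a detection, and then classified:

* ``transit`` — the bird crossed detection range at commuting flight speed;
* ``short_attendance`` — the bird slowed near a vessel but only briefly;
* ``true_attendance`` — prolonged, slow association, i.e. feeding at the
  vessel.

The classification replaces a by-eye categorisation of the speed/duration
scatter with explicit, configurable thresholds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NotApplicableError, UndefinedProportionError
from .geotrack import RADAR_NOSCAN, RADAR_POSITIVE, Track
from .trip_analysis import Trip

CATEGORY_TRANSIT = "transit"
CATEGORY_SHORT = "short_attendance"
CATEGORY_TRUE = "true_attendance"


@dataclass
class ClassifierRule:
    """Thresholds separating the three encounter categories.

    ``attend_max_speed_kmh`` splits attendance from transit: it sits midway
    between observed attendance speeds (6-13 km/h, vessel working speed) and
    commuting flight (47 +/- 11 km/h). ``short_max_duration_min`` is the
    short/true attendance boundary. ``slow_speed_kmh`` is the "sitting on
    water" speed used for the slow-fix proportion diagnostic.
    """

    short_max_duration_min: float = 10.0
    attend_max_speed_kmh: float = 25.0
    slow_speed_kmh: float = 10.0

    def __post_init__(self) -> None:
        if min(self.short_max_duration_min, self.attend_max_speed_kmh, self.slow_speed_kmh) <= 0:
            raise ValueError("classifier thresholds must be > 0")


@dataclass
class Encounter:
    """A maximal run of positive radar scans separated by less than the gap."""

    bird_id: str
    trip_ref: int | None  # index into the trip list; None = detection at colony
    first_detection_time: pd.Timestamp
    last_detection_time: pd.Timestamp
    n_positive_scans: int
    duration_min: float | None = None
    mean_speed_kmh: float | None = None
    detection_proportion: float | None = None
    category: str | None = None


def group_encounters(
    t: Track,
    gap_s: int = 3600,
    trips: list[Trip] | None = None,
    merge_exact_gap: bool = False,
) -> list[Encounter]:
    """Group positive radar scans into encounters.

    Consecutive positives separated by less than ``gap_s`` (or exactly
    ``gap_s`` when ``merge_exact_gap``) belong to the same encounter; a
    single isolated positive forms a zero-duration encounter. When ``trips``
    is given, encounters never span two trips, and detections falling outside
    every trip (i.e. at the colony — a coastal vessel) are grouped separately
    with ``trip_ref=None``.

    Raises :class:`NotApplicableError` for a track that never scanned at all
    (plain GPS device): "no scans" is not "zero encounters".
    """
    df = t.fixes
    if not (df["radar"] != RADAR_NOSCAN).any():
        raise NotApplicableError(f"track {t.bird_id}: device carried no radar detector scans")
    pos_times = df.loc[df["radar"] == RADAR_POSITIVE, "time"]

    # partition positives by trip membership
    segments: list[tuple[int | None, pd.Series]] = []
    if trips is None:
        segments.append((None, pos_times))
    else:
        assigned = pd.Series(-1, index=pos_times.index, dtype=int)
        for k, tr in enumerate(trips):
            in_trip = (pos_times >= tr.start) & (pos_times <= tr.end)
            assigned[in_trip] = k
        for k, tr in enumerate(trips):
            segments.append((k, pos_times[assigned == k]))
        leftover = pos_times[assigned == -1]
        if len(leftover):
            segments.append((None, leftover))

    encounters: list[Encounter] = []
    for trip_ref, times in segments:
        if len(times) == 0:
            continue
        ts = times.sort_values().reset_index(drop=True)
        dt = ts.diff().dt.total_seconds().to_numpy()
        if merge_exact_gap:
            new_run = dt > gap_s
        else:
            new_run = dt >= gap_s
        run_id = np.concatenate([[0], np.cumsum(new_run[1:])]).astype(int)
        for rid in np.unique(run_id):
            sel = ts[run_id == rid]
            encounters.append(
                Encounter(
                    bird_id=t.bird_id,
                    trip_ref=trip_ref,
                    first_detection_time=sel.iloc[0],
                    last_detection_time=sel.iloc[-1],
                    n_positive_scans=int(len(sel)),
                )
            )
    encounters.sort(key=lambda e: e.first_detection_time)
    return encounters


def characterize(e: Encounter, t: Track) -> Encounter:
    """Fill duration, mean bird speed and detection proportion.

    All three are computed over the fixes between the first and last
    detection of the encounter, inclusive. A single-scan encounter has
    duration 0 and detection proportion 1.
    """
    df = t.fixes
    win = df[(df["time"] >= e.first_detection_time) & (df["time"] <= e.last_detection_time)]
    if len(win) == 0:  # detections must come from the track
        raise ValueError("encounter window contains no fixes of the given track")
    e.duration_min = (
        e.last_detection_time - e.first_detection_time
    ).total_seconds() / 60.0
    if "speed_kmh" not in win.columns:
        raise ValueError("track must be speed-annotated before characterize()")
    e.mean_speed_kmh = float(win["speed_kmh"].mean())
    n_pos = int((win["radar"] == RADAR_POSITIVE).sum())
    e.detection_proportion = n_pos / len(win)
    return e


def classify(e: Encounter, rule: ClassifierRule | None = None) -> Encounter:
    """Assign the encounter category from mean speed, then duration."""
    rule = rule or ClassifierRule()
    if e.mean_speed_kmh is None or e.duration_min is None:
        raise ValueError("encounter must be characterized before classify()")
    if e.mean_speed_kmh > rule.attend_max_speed_kmh:
        e.category = CATEGORY_TRANSIT
    elif e.duration_min < rule.short_max_duration_min:
        e.category = CATEGORY_SHORT
    else:
        e.category = CATEGORY_TRUE
    return e


def trip_exposure(tr: Trip, scan_interval_s: int = 60) -> float:
    """Percent of trip duration spent within radar-detection range.

    ``n_positive_scans * scan_interval / trip_duration``, in percent. Only
    meaningful for radar-equipped trips; a trip that never scanned raises
    :class:`NotApplicableError`.
    """
    df = tr.fixes
    if not (df["radar"] != RADAR_NOSCAN).any():
        raise NotApplicableError("trip has no radar scans; exposure undefined")
    n_pos = int((df["radar"] == RADAR_POSITIVE).sum())
    dur_s = (df["time"].iloc[-1] - df["time"].iloc[0]).total_seconds()
    return 100.0 * n_pos * scan_interval_s / dur_s


def slow_speed_proportion(
    fixes: pd.DataFrame, threshold_kmh: float = 10.0, daytime_only: bool = False
) -> float:
    """Fraction of fixes with apparent speed below threshold (sitting on water)."""
    sel = fixes
    if daytime_only:
        if "is_night" not in sel.columns:
            raise ValueError("fixes must be night-annotated for daytime_only")
        sel = sel[~sel["is_night"]]
    if len(sel) == 0:
        raise UndefinedProportionError("no fixes in selection")
    return float((sel["speed_kmh"] < threshold_kmh).mean())


def encounters_table(encounters: list[Encounter]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bird_id": [e.bird_id for e in encounters],
            "trip_ref": [e.trip_ref for e in encounters],
            "first_detection": [e.first_detection_time for e in encounters],
            "last_detection": [e.last_detection_time for e in encounters],
            "n_positive_scans": [e.n_positive_scans for e in encounters],
            "duration_min": [e.duration_min for e in encounters],
            "mean_speed_kmh": [e.mean_speed_kmh for e in encounters],
            "detection_proportion": [e.detection_proportion for e in encounters],
            "category": [e.category for e in encounters],
        }
    )
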