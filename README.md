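# radarwatch

Analysis of combined GPS + ship-radar-detector ("XGPS") biologging data
from colonial seabirds — built around the question of how often a
central-place forager such as a gannet actually meets and attends fishing
vessels at sea.

An XGPS tag records a GPS fix every minute and scans for X-band (9.41 GHz)
marine-radar emissions once a minute; a positive scan means a vessel is
within the ~5 km validated detection footprint. From raw logger files the
package produces:

* **Trips** — colony-to-colony excursions with duration, path length,
  maximum range and mean speed;
* **Home ranges** — kernel utilization distributions (UD) with volume
  contours: the 90% contour is the smallest set of highest-density cells
  holding 90% of the probability mass, with reference bandwidth
  `h = σ·n^(−1/6)`;
* **Encounters** — maximal runs of positive scans separated by <1 h,
  characterised by duration *T*, mean bird speed *v̄* and detection
  proportion, and classified as `transit` (*v̄* > 25 km/h),
  `short_attendance` (*T* < 10 min) or `true_attendance` (slow and
  prolonged — feeding at the vessel);
* **Exposure** — percent of trip duration within radar detection range;
* **Colony metrics** — adult body condition (mass/wing, g·mm⁻¹), chick
  growth (mean of per-interval Δmass/Δdays), diet percent frequency of
  occurrence;
* **Statistics** — Welch's t (computable from (n, mean, sd) summaries;
  df by Welch–Satterthwaite) and the Wilcoxon rank-sum / Mann–Whitney U
  test with an exact enumerated null for small samples.

A ground-truthed simulator (`radarwatch.synthetic_data`) generates the
whole study design — multi-state bird trips (commute / search / rest /
attend at 47, 20, <5 and 13 km/h respectively), a correlated-random-walk
fishing fleet at 13 km/h, per-minute scans against the 5 km footprint —
so every downstream stage is testable without field data.

## Worked example

```bash
radarwatch simulate --seed 5 --n-birds 6 --out-dir demo
radarwatch report demo/tracks.csv --out-dir demo_report
```

`trips.csv` (rounded):

```
bird_id   device    duration_h  path_length_km  max_range_km  mean_speed_kmh
   G003   GPS30s          12.8           316.3          84.7            24.7
   G004   GPS30s          18.5           341.4         117.3            18.4
   G005   GPS30s          25.5           507.2         200.3            19.9
   G006   GPS30s          18.8           340.4         104.4            18.1
   X001   XGPS1min         6.2           226.7          74.2            36.6
   X002   XGPS1min        28.9           559.3         175.2            19.3
```

Six trips in the hours-to-days range with maximum ranges of 74–200 km —
the envelope of a chick-provisioning gannet. `encounters.csv` for the one
bird that met vessels:

```
bird_id  n_positive_scans  duration_min  mean_speed_kmh  detection_prop  category
   X001                44          43.0           29.07            1.00  transit
   X001                42          44.0           19.75            0.93  true_attendance
   X001                 2           1.0           55.20            1.00  transit
```

The second row is a recovered attendance bout (the simulator's truth file
records a 34-min bout inside that window): slow mean speed, near-total
detection proportion. The two `transit` rows are fast flight through
detection range. `exposure.csv` shows X001 spent 23.7% of that trip within
radar range and X002 0% — across a full 30-bird campaign the median trip
exposure lands near 1.5–2.3%, i.e. radar contact is rare even with an
active fleet on the shelf.

Library use mirrors the CLI:

```python
from radarwatch import (Colony, read_tracks, resample_track, derive_speeds,
                        segment_trips, group_encounters, characterize, classify)

colony = Colony(lat=-33.05, lon=17.93, radius_km=2.0)
track = derive_speeds(resample_track(read_tracks("demo/tracks.csv")[4]))
trips = segment_trips(track, colony)
for enc in group_encounters(track, gap_s=3600, trips=trips):
    print(classify(characterize(enc, track)).category)
```

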