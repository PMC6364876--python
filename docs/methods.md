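# Methods

`radarwatch` analyses combined GPS + ship-radar-detector ("XGPS") biologging
data from colonial seabirds, and validates the whole chain against a
simulator with known ground truth. This note records the models, the
defaults and the design decisions, in the package's own words.

## Trajectory model

A track is a time-ordered sequence of fixes (UTC time, WGS84 lat/lon) from
one of two device classes: a plain GPS logger sampling every 30 s, or an
XGPS tag fixing every minute and scanning for X-band (9.41 GHz) marine-radar
emissions once a minute with 30-s signal integration. The scan result is
kept ternary — positive, negative, no-scan — because a device that never
scanned carries no information about vessel presence; collapsing "no scan"
onto "no detection" would bias encounter rates for the GPS-only birds.

Geometry is spherical with radius 6371.0088 km. At working ranges under
~200 km the ellipsoidal correction (<0.5%) is far below GPS noise.
Tracks are resampled onto a regular grid (default 60 s) anchored at the
first fix, interpolating lat/lon linearly in time. Linear (chord)
interpolation rather than great-circle interpolation is a documented
limitation; for fixes ≤60 s apart the chord error is sub-metre. No fix is
synthesised across a raw gap longer than `max_gap_s` (default 600 s):
interpolating across longer outages would fabricate behaviour, so the grid
simply has holes. Scan results are reassigned to the nearest kept grid
instant within half an interval, never duplicated; a positive scan that
cannot be placed (it fell inside an unbridgeable gap) is dropped with a
warning rather than silently moved.

Speeds are re-derived from positions (distance from the previous fix over
elapsed time; the first fix inherits the second's value). Device-reported
speed, when present, is preserved in a separate column — the two are never
merged, since the reconciliation rule used in the field is unknown.

Day/night is flagged by the sign of solar elevation from the low-precision
NOAA formulas (Spencer's Fourier fits for declination and the equation of
time), accurate to well under 0.5°, ample for a binary flag.

## Trips and home ranges

A foraging trip is a maximal run of fixes outside the colony buffer
(default 2 km — wider than GPS scatter at the nest, narrower than nearshore
foraging), extended by one boundary fix at each end. Runs shorter than
0.5 h or never exceeding 2 km range are discarded as loafing; a run cut off
by the end of the record is kept and flagged incomplete. Trip metrics are
duration, summed great-circle path length, maximum distance to the colony,
and mean speed (path/duration).

The utilization distribution is a bivariate Gaussian kernel density on a
planar azimuthal-equidistant grid (default cell 2 km) centred on the point
cloud's centroid, evaluated exactly (sum of Gaussians, separable in x and
y) and normalised to unit mass. The reference bandwidth is
`h = sigma * n^(-1/6)` with sigma the mean of the two marginal standard
deviations — the movement-ecology convention. Fixes from all trips are
pooled across birds for the population UD; per-bird UDs are available by
calling `kernel_ud` per bird.

The "90% contour" is a volume contour: the smallest set of highest-density
cells whose summed mass reaches the level. Cells enter in decreasing
density; equal densities at the cutoff are resolved in stable grid order so
that the set stays minimal (a uniform density over 100 cells at level 0.9
yields exactly 90 cells, and removing any included cell drops the mass
below the level). Kernel smoothing inflates the contour of an isotropic
Gaussian sample by roughly `(1 + h^2/sigma^2)`; at n = 1000, sigma = 10 km
that is ~10%, which is why the closed-form check carries a 15% band.

## Encounters and attendance

Positive radar scans separated by less than one hour are grouped into one
vessel encounter; a gap of exactly one hour splits (a merge flag exists
because the verbal rule is ambiguous at the boundary). A single isolated
positive forms a zero-duration encounter. Encounters never span two trips,
and detections while at the colony (a coastal vessel) are reported with a
null trip reference rather than as foraging encounters.

Each encounter window — first to last detection, inclusive — yields its
duration, the mean position-derived bird speed, and the detection
proportion (positive scans over fixes in the window). Classification
replaces the original by-eye reading of the speed/duration scatter with
explicit thresholds:

* mean speed > 25 km/h → **transit** (commuting flight through the
  footprint; 25 km/h sits midway between attendance speeds of 6–13 km/h
  and commuting flight at 47 ± 11 km/h);
* else duration < 10 min → **short attendance**;
* else → **true attendance** (prolonged, slow association — feeding at the
  vessel).

Both thresholds are configuration-exposed; the defaults are a
reconstruction of the published categorisation, not a literal rule from it.
Trip exposure is `positive scans × scan interval / trip duration`, in
percent. The slow-fix proportion (speed < 10 km/h, "sitting on water") is
computed over any fix selection, optionally daytime-only.

## Comparative statistics

Welch's unequal-variance t-test is computed from (n, mean, sd) summaries —
the statistic needs nothing else, which is what allows recomputing the
published range comparison from printed summaries alone. The printed
t = −2.917 with df = 17 is consistent with the Welch computation
(a pooled-variance t gives −2.49), which fixes the implemented variant.

The rank-sum test uses the Mann–Whitney U convention (rank sum of the first
sample minus its minimum), since reported "W" values are
convention-dependent. For combined sizes ≤ 25 the null distribution is
exact: a dynamic program over doubled midranks counts all C(N, n_x) group
assignments, ties included; beyond that a tie-corrected normal
approximation with continuity correction is used. P-values are two-sided
(2·min(lower, upper tail), capped at 1) throughout; no multiple-testing
correction is applied. Note that for the configuration n = 7 vs 12 with
U = 9 the exact two-sided p is 0.0037 (one-sided 0.0019), not below 0.001;
a sub-0.001 value at U = 9 requires a larger comparison group.

## The simulator

The simulator is a test harness, not an inference target: it generates the
study conditions so the pipeline can be validated against ground truth, and
simplicity wins wherever the field data give no behavioural model.

A trip is a state machine on a planar azimuthal-equidistant frame centred
on the colony: commute out along a persistent heading to a target range
drawn from a truncated normal (mean 93 km, sd 59 km), then search (tortuous
headings, truncated-normal speeds, mean 20 km/h), rest at night (drift at
0.2–1.5 km/h), and commute back at 47 ± 11 km/h once an exponential
foraging budget (mean 12 h) expires. All speed distributions are normals
truncated at a positive floor. State durations are exponential. Fixes every
60 s (30 s for the plain-GPS birds); scans every 60 s, positive if and only
if any vessel is within the hard 5 km detection footprint — detection
probability is modelled as a step because the at-sea validation reported
all vessels within 5 km detected and gives no decay shape.

Vessels (default 35) move at a constant 13 km/h as a correlated random walk
confined to a shelf polygon; step length is exact, so cumulative path
length equals speed × time. The fleet density default reproduces an
encounter rate of roughly one to one-and-a-half per trip, the regime of a
shelf worked daily by a demersal trawl fleet.

On entering a vessel's footprint a searching or resting bird either begins
attending (probability 0.5 by default) or avoids. **Attendance** is
sit-and-chase: the bird drifts on the water while the vessel opens a gap,
then makes a flight burst to catch up; its time-averaged ground speed
equals the vessel's (13 km/h, the observed attendance speed) while roughly
half its fixes are at sitting speeds — which is what makes the slow-fix
proportion during attendance exceed the daytime average. Bout durations are
exponential (mean 1.7 h). By construction an attending bird stays within
0.55 detection radii of its vessel, so the attendance-implies-detectable
invariant is exact. **Avoidance** is a flight response at commuting speed
directly away from the vessel, continuing to 2.5 detection radii before the
previous behaviour resumes. The displacement matters: with a shorter exit
the bird can graze the footprint edge repeatedly and the merged detection
run can masquerade as slow, long attendance; relocation is also what the
species is reported to do around vessels it does not scavenge from,
including flushing off the water when resting.

What the simulator does **not** emulate: GPS position error, prey fields
and area-restricted search driven by them, wind drift, device failure other
than truncation, vessel fishing/steaming duty cycles, and any radar-range
decay. Passing recovery tests therefore shows the pipeline recovers truth
under clean, regular sampling — not that it is robust to every field
artefact.

## Validation problem sizes

The standing validation uses 30 simulated XGPS trips (one per bird) for
bout recovery, classification and detection exactness; 200 random scan
series of up to 500 positives for the grouping/linkage equivalence; 1000
Gaussian draws for the kernel closed form; and exhaustive enumeration up to
combined n = 12 for the rank-sum oracle. These sizes give stable rates
while keeping the default runs quick.

## Known limitations

* Linear interpolation and planar simulation are chord approximations,
  fine at ≤300 km scales, wrong for basin-scale data.
* The classifier is deliberately simple (two thresholds); it does not use
  detection proportion, which the field data suggest is informative.
* The exact rank-sum DP is quadratic in combined sample size and capped at
  25 by default.
* Chick growth is the unweighted mean of per-interval rates, which equals
  the regression slope only for equally spaced measurements — kept because
  it is the established field formula.
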