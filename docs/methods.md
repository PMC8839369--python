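# Methods

## Data model

A ping is one tracker broadcast: `id` (progressive serial), `deviceId`
(vessel identifier, the role an MMSI plays for AIS), WGS84
latitude/longitude, `deviceTime` (second resolution), course (deg) and
speed (km/h) over ground, `sat` (satellite count), `power` (supply
level), `eventType` (tracker geofence event) and `sensor` (hauler line:
0 = active). Timestamps are naive local wall-clock time exactly as
transmitted; no timezone handling is applied anywhere, because
hour-of-day effort profiles are meaningful in the vessel's local time.
Streams are sorted stably by `(deviceTime, id)` so same-second records
keep serial order. Readers accept `type` as an alias for `eventType`
and match columns case-insensitively; malformed rows abort the read
with their line numbers rather than being dropped silently. Only the
distinction `power == 0` vs `power > 0` is interpreted semantically,
so the unit of `power` (volts vs. a normalized level) does not matter.

## Quality control

Kinematic plausibility: speed > 35 km/h or course outside [0, 360]°
(bounds inclusive; 360 is treated as a valid alias of north rather than
normalized). Boot pings carry no fix and are exempt. QC *annotates*;
whether flagged pings are kept or dropped is a downstream policy
(default: drop). No interpolation is implemented — gaps (inter-ping
interval > `gap_factor` × nominal interval, defaults 3 × 60 s) are
reported only. The 60 s nominal interval reflects the reference
deployment's observed rate (~5.8 k records over ~90 h at sea ≈ 1/min)
and is configurable.

## Trip segmentation

Power-on and power-off both appear as short maximal runs of boot pings
(`sat = 0` and `power = 0`). Boundaries are evaluated on the *off-time
between consecutive normal pings*: a split occurs where that gap
exceeds `min_gap` (default 45 min), with or without boot pings in
between. Consequences of this choice, made deliberately where the exact
boundary rule was open:

- a mid-sea reboot with off-time < `min_gap` does not split a trip;
- a brief port call (< `min_gap`) merges into one trip — the intended
  behaviour of the minimum-stop rule;
- the rule degrades gracefully when shutdown produces no boot run on
  some firmware, since a plain time gap splits too.

Segments with fewer than `min_pings` (default 5) normal pings are
discarded as harbor jitter into a reported residual set, so the
partition accounts for every ping: trips + residual + boot = stream.
This floor is this package's own guard; set `min_pings=1` to disable.
Trips are numbered chronologically per device from 1. Geofence
information is deliberately *not* used for segmentation — digitizing
and maintaining port polygons does not scale across fleets, and
vessels may depart from unregistered spots; the polygon serves only to
validate trips after the fact.

Decreasing `min_gap` can only add boundaries, so the recovered trip
count is monotone non-increasing in `min_gap` (property-tested).

## Geofence

Containment is boundary-inclusive (shapely `covers`); crossings are
containment changes between consecutive fixes, matching how the tracker
itself raises events — at a ~1-min ping rate, segment–polygon
intersection would differ only for a ping landing exactly on the
boundary. Both event sources are supported (recorded `eventType` vs
recomputed from a polygon) with a reconciliation report, because badly
shaped polygons generate false events from edge movements. Validation
reports raw enter/exit counts; `(1,1)` is `valid`, `(0,0)`
`no_crossing`, anything else `multi_crossing` — including unpaired
counts, which arise when a crossing is registered while the device is
off.

## Activity classification

The hauler's inductive sensor is debounced in hardware: once rotation
is detected the line is held high for ≥ 1 min so the state survives the
reporting interval. `condition_hauler_signal` emulates that
microcontroller: a pulse at `t` holds the line over `[t, t + hold)`,
holds merge; pulses at 0 s and 30 s with a 60 s hold give one 90 s
interval.

Steaming is separated by speed: the threshold is the 75th quantile
(linear interpolation between order statistics) of *at-sea* speeds —
computed over all non-in-port trip pings of the analysis window per
device, not per trip, so short trips with few pings do not destabilize
it (per-trip computation remains possible by passing per-trip speeds).
Labels apply with precedence `in_port > steaming > hauling > other`:
steaming overrides an asserted sensor (bounce while in transit), and
`other` covers slow movement with the sensor idle — gear setting and
drifting are not distinguished, since no setting detector is claimed.

Hauling hours credit each hauling ping with its forward interval to the
next ping (the final ping of a slice contributes nothing). At a 1-min
rate this differs from ping-count × interval by at most one ping per
trip. An offset between the hauler's true rotary motion and the
transmitted line state is inherent to the hardware hold; no correction
is attempted.

## Effort metrics

- Duration: end − start of the trip's normal pings, reported to 2
  decimals, computed at full precision. The bundled November 2021
  reference log's 28 printed durations are reproduced exactly to 2
  decimals from their printed timestamps (acceptance-tested).
- Average speed: arithmetic mean of instantaneous GPS speeds. The
  reference log makes the definition unambiguous: its trip 1 covers
  47.27 km in 5.18 h (9.1 km/h made good) yet prints 4.27 km/h, which
  only a per-ping mean including slow/idle pings produces.
- Distance: summed haversine legs, Earth radius 6371.0 km, all trip
  pings included (in-port transit from the quay counts; an at-sea-only
  variant is a filter away). Spherical error < 0.5% at coastal scale.
- Presentation rounding is half-even and applied only at the export
  layer; internal comparisons use full precision.
- Hourly profile: hauling minutes binned by the ping's local hour;
  bins conserve the total. Speed-by-state reports n/median/quartiles.

The reference log's stated ~90.5 h monthly total slightly exceeds the
sum of its printed per-trip durations (≈ 90.05 h); the package pins no
number to that total.

## Synthetic fleet

The simulator emulates the reference deployment's routine: generally
two trips per day, an early-morning window (01:00–06:00) and an
afternoon/evening one (13:00–18:00); each trip is boot run → in-port
pings → steaming leg (6–9 km/h) to a ground 4–10 km out → alternating
hauling bouts (0.3–2 km/h, 15–40 pings) and setting stretches → return
leg → in-port pings → boot run (2–4 pings each). 15% of trips only set
gear (no hauling), mirroring retrieval postponed to the next trip.
Where the routine left values unstated (ground distance, bout/setting
lengths, GPS noise of 5 m, set-only fraction), defaults were chosen
once as fishery-plausible and are config fields, not tuning knobs.

Movement is piecewise-constant speed with heading noise in a local
tangent plane around the port anchor, converted to WGS84 (curvature
error negligible within ~25 km). The hauler line is produced the way
the hardware produces it: rotation pulses every 15 s across each bout
with 15% dropouts, conditioned by the 1-min hold, sampled at ping
times — so the debounce emulation is genuinely exercised, and
occasional ≥ 4-pulse dropouts leave small holes that keep hauling
recovery realistically just below 100%. Hauling speeds are constructed
below the steaming range so the quantile rule is learnable; a config
violating that ordering is rejected. Outliers are injected only into
normal at-sea pings and logged exactly. A `p_double_visit` option
routes a trip back through the port polygon to an opposite ground,
reproducing the double enter/exit pattern of real trips that straddle
a badly shaped geofence.

What the simulator does **not** model: currents and weather, position
drift while idle, multi-gear behaviour, duty-cycled transmission, real
GNSS multipath near harbor structures, and AIS-style message loss.
Passing recovery tests therefore shows the *rules* are implemented
correctly under their stated assumptions, not that the thresholds are
optimal for any particular real fishery.

## Problem sizes and determinism

Tests and the acceptance script use a 14-day × 2-trips simulated month
(~5.5 k pings, matching the reference month's scale) and smaller 1–10
day runs for focused checks; each completes in seconds. All randomness
flows from one explicit seed through `numpy.random.default_rng`; the
analysis pipeline contains no randomness at all, so identical inputs
and configuration yield byte-identical outputs (tested). Property
tests run hypothesis in derandomized mode.

## Known limitations

- Single device per stream; multi-vessel handling is file-per-vessel.
- One port polygon; multi-port fleets need per-vessel geofences.
- No soak-time estimation between a setting trip and the retrieval
  trip, no gear-type identification, and no learned fishing classifier
  for vessels without a hauler sensor — the labeled output is designed
  to train one later.
- The speed-quantile threshold assumes steaming is well separated from
  hauling speeds; fisheries that troll or steam slowly would need a
  different rule.
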