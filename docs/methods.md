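# Methods

## Data model

A track is one flight event: the frame-indexed 2D positions (mm) of a
single mosquito between entering and leaving the camera field of view
(2400 × 1200 mm, with a 100 mm central and two 50 mm lateral blind
zones).  Individual mosquitoes cannot be followed across events, so every
track is analysed independently; a flight crossing a blind zone appears
as separate tracks and no re-linking is attempted.  Frame index is
authoritative and time is derived (`t = frame / frame_rate`, 50 frames/s
by default); all thresholds are stated in both frames and seconds and
must agree (`contact_interval_s × frame_rate` must be an integer).

Coordinates are a 2D side projection: x runs along the bed (host head at
left), y is vertical with the floor at 0.  All speeds are projected
speeds and systematically underestimate 3D speed; this is a property of
the recording geometry, not of the analysis.  Positions are serialised at
0.01 mm, below every threshold in the classifier configuration.

The net box is a required geometry input.  Its dimensions are not
derivable from the recorded tracks, so the defaults (1800 mm long,
800 mm roof height, 700 mm deep, spanning x = 300–2100 mm) are plausible
single-bed values chosen once; all region boundaries and the
geometry-derived high-entry edge fraction follow from them.

## Contact detection

Three detectors, merged per track (priority rest > oscillation > turn for
events within one frame; contacts inside a resting span are absorbed):

**Sharp turns.** The heading change at each interior point (angle between
successive displacement vectors, 0–180°) marks a contact when it is at
least 80° (inclusive) and the vertex lies within `net_proximity_mm` of
the net surface.  The source definition says only "at the net surface";
the 5 mm default exceeds centroid jitter and is below typical bounce
amplitudes, and is configurable.  Runs of consecutive qualifying frames
collapse to the point nearest the net.  A vertex only qualifies if the
*incoming* step is at least `turn_min_step_mm` (1 mm ≈ 50 mm/s): slower
approach means the heading is jitter-dominated.  Only the incoming step
is gated because a genuine contact may end in walking or rest, where the
outgoing step is arbitrarily slow.  Zero-length displacements make the
angle undefined; such frames are never turn contacts by themselves.

**Oscillations.** During bouncing, individual turn angles are often below
80°; repetitive oscillation of x and/or y against the surface is the
signature instead.  Both coordinates are filtered with a 2nd-order
Butterworth band-pass, 2–20 Hz by default (wing-beat is far above, drift
far below), applied forward-backward for zero phase so event timing is
preserved.  Candidate contacts are the negative-going zero crossings of
the filtered signals — one per oscillation cycle, the approach phase —
gated three ways: the mosquito must be within the net-proximity band at
the crossing; the local filtered excursion must reach
`oscillation_min_amplitude_mm` (1 mm, suppressing sub-noise wiggle during
rest); and the crossing must have a neighbouring near-net crossing within
one period of the low corner frequency ("repetitive": a lone crossing is
a fly-by over the net silhouette, not a bout).  Crossings from the two
axes closer together than half the shortest band period are debounced
into one event.  Tracks shorter than one low-corner period are below the
filter warm-up and return no events.

**Resting.** A resting event is a maximal run slower than 1.33 mm/s
(1 mm of net movement over the 0.75 s minimum resting time) lasting at
least 0.75 s.  Speed is estimated as net displacement over a lag of half
the minimum resting time, on positions smoothed over `rest_smooth_points`
(5) frames, rather than frame-to-frame: with 0.1 mm centroid jitter,
frame-to-frame displacement noise alone is ~7 mm/s and would hide every
rest, whereas the lagged estimate targets exactly the net-movement
criterion the threshold encodes and rejects walking (≥ ~20 mm/s) and
flight unambiguously.  Runs longer than 300 s are truncated at the cap
and flagged (the cap excludes dead mosquitoes and spurious joins between
unrelated arrival and departure tracks); flagged events contribute no
resting time beyond the cap.

## Mode segmentation

A track with no contacts and no resting is one swooping segment.
Otherwise: resting events become resting segments; runs of ≥ 2 contacts
with successive gaps strictly below 20 frames (0.4 s) become bouncing
segments spanning first to last contact of the run (a 0.4 s gap is
visiting — the boundary is inclusive on the visiting side); everything
else, including the flight leading into a first contact, is visiting.
Brief sub-resting pauses (walking/probing) inside a bouncing run stay
inside the run because the oscillation detector emits contacts during
probing, keeping successive gaps under the interval.  Segments partition
the track exactly (segment durations sum to track duration); a
contact-bearing track never contains swooping.  Per-frame labels (used
for closed-loop accuracy) assign each frame the mode of the interval it
opens.

Per-test aggregation sums per-mode durations (which may exceed the test
hour because mosquitoes overlap, but never `n_released × duration` —
25 mosquito-hours at defaults), computes mode fractions and the
contact-involving share, and the lag from the first mosquito's appearance
to the first net contact (flagged when no contact occurs).

## Landing kinematics

Tracks with at least one second of flight before a contact contribute a
65-point landing window: 50 approach points, the contact (one-based point
51), and 14 departure points (0.28 s).  A 65-point window cannot hold a
full 0.3 s after contact at 50 frames/s; the contact index is treated as
authoritative and the window ends 0.28 s after contact.  Shorter
pre-contact histories are excluded and counted.

Per-point speed is displacement × frame rate (the first point carries the
first interval's speed).  For onset detection, speed is smoothed with a
centred 3-point moving average **computed over pre-contact samples only**
(the departure must not leak into the approach estimate) and differenced
forward, so the acceleration at a point describes the interval it opens.
The deceleration onset is the start of the maximal run of negative
acceleration persisting to the contact point (latest admissible onset:
the point immediately before contact), with two refinements, both
consequences of smoothing a discrete transition:

1. leading run samples whose deceleration magnitude is below
   `onset_rel_accel_min` (25%) of the run peak are skipped — they are the
   smoothing transition, not deceleration;
2. the onset then advances past samples whose raw speed has not yet
   started to fall.

On noise-free generated approaches this recovers a programmed onset
exactly; a naive "first negative smoothed acceleration" rule is biased
early by half the smoothing window (~2 frames ≈ 14 mm at 350 mm/s).
Onset distance is along-path length from onset to contact; onset speed is
the smoothed speed at onset.

A window is a contact without deceleration when raw speed rises over the
last two pre-contact intervals, the onset is undefined, or the onset lies
within the 3 mm tarsal zone (leg contact cannot be excluded); such
windows are excluded from onset-distance summaries but counted in the
no-deceleration fraction.

Tortuosity is the mean over consecutive non-overlapping 40-point sections
of path length / chord length (≥ 1 by the triangle inequality).  The
trailing remainder is dropped so section statistics stay identically
distributed; sections with chords below 0.1 mm are degenerate and
skipped.

## Spatial regions

Sixteen regions: six equal roof segments (1–6, head to foot), head-end
wall (7), side walls (8, 9 — these project onto the interior of the net
silhouette in a side view), foot-end wall (10), surrounding space (11
head side, 14 foot side, 12/13 the high space above the roof split at
the net midline), and front-of-net flight space (15 left / 16 right
camera field).  Contacts map to the nearest net surface with boundary
ties to the lower-numbered region; points deep inside the silhouette are
side-wall contacts.  Activity is attributed per frame for swooping
(flight regions) and per segment for contact modes (split equally over
the segment's contact regions), which conserves total seconds exactly;
densities are area-scaled (s/m²) using per-region areas from the
geometry.

A track's entry is high when its first point lies above the net roof over
the net (regions 12/13), discarded when it first appears within the
contact-proximity band of the net surface (a likely fragment of an
interrupted track), otherwise low.  Per-test high fractions are compared
with a configured expectation (0.36) by a one-sample two-tailed t-test.
The expectation is configuration, not a derived constant, because it
depends on net dimensions; the geometry-derived counterpart (net length /
entry-edge length, 0.375 at the default geometry, with the entry edge
being the top and both sides of the field of view) is reported beside it.

## Temporal statistics

Activity is binned into half-open 5-minute bins (12 over an hour);
segments spanning an edge are split proportionally, so bins conserve
total activity exactly.  The decay model A(t) = A₀·e^(−kt) (t in
minutes) is fitted by nonlinear least squares at bin midpoints (2.5,
7.5, … — midpoints rather than interval labels, for unbiased placement of
the exponential; switchable by constructing bins differently).
Nonlinear fitting is used instead of log-linear regression because
insecticide arms produce empty late bins by design.  Initialisation is
deterministic (A₀ from the first bin, k from the first/last nonzero bin
ratio); all-zero or fewer-than-three bins give a flagged degenerate fit.
Both activity-seconds and track-count bins are supported; the pipeline
reports both fits.

Group comparison of decay constants uses Welch's t-test with
t-distribution CIs per group, excluding degenerate fits, plus per-bin CI
overlap flags when per-test bins are supplied (locating the interval from
which the groups separate).  Its type-I error on identical-k groups is
calibrated in the acceptance suite (≈ 5%).

Per-mosquito contact time is bracketed: maximum = total contact time /
largest number of tracks simultaneously in a contact mode; minimum =
total / number released, except in first-ten-minute analyses where a
trajectory count below the release count substitutes as divisor.  Total
contact time counts full bouncing and resting durations plus one frame
per visiting contact.  Geometric means use t-distribution CIs in log
space; a skewness/kurtosis screen is reported as a diagnostic, and the
caller chooses the mean type explicitly.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
it is the ground-truth oracle for closed-loop validation, not a flight
simulator.  Movement is a correlated random walk (Gaussian per-step
heading perturbation, σ = 12°) at a per-track cruise speed drawn around
the net-type mean; wandering flight reflects off the field-of-view walls
and steers clear of the net (swooping never contacts it).  Contact-bound
flight stages to a point ~150 mm out along the surface normal and flies
a straight run-in whose final stretch decelerates linearly in speed from
the programmed onset distance, with one sample placed exactly at the
onset (so noise-free recovery is exact).  Bouncing is a train of
out-and-back hops (inter-contact gaps 0.1–0.34 s, descent within ~35° of
the surface normal so each touch is a genuine sharp-turn vertex),
occasionally interrupted by walking/probing pauses below 0.75 s whose
millimetre-scale tangential wiggle sits in the oscillation detector's
band; a landing that starts a walk is truth-labelled `walk`, not `turn`,
because its vertex angle is legitimately unconstrained.  Resting is
sub-threshold positional jitter at the surface for a lognormal duration
(never exceeding the 300 s cap).  Optional Gaussian centroid jitter
(default σ = 0.1 mm) stress-tests thresholds.

Per-5-minute-bin track appearance counts are Poisson with mean
A₀·e^(−k·t); tracks are assembled from four behavioural templates chosen
by a side-effect-aware controller that steers the realised activity-time
mix toward the programmed mode mix (contact templates inevitably add
visiting flight around their contacts; bout and rest durations are capped
by the remaining mode budget so small budgets are not overshot).  Contact
targets are sampled by region weights: the roof share (`roof_bias`,
default 0.6) splits over the six roof segments with emphasis above the
torso, the remainder over the end walls.  Each track carries a latent
mosquito identity (uniform over the released count) so per-mosquito
contact seconds have a ground truth the real assay lacks.

Defaults are calibrated to the magnitudes reported for the reference
laboratory assay and define the study conditions: cruise speeds
321.1 / 355.8 / 322.7 mm/s and deceleration onsets 26.3 / 41.5 / 40.0 mm
for unbaited / untreated-baited / LLIN-baited nets; first-bin track rates
18 / 45 / 80 per 5 minutes with decay constants 0 / 0 / 0.12 per minute
(giving ≈ 210 / 540 / 130 tracks per hour and negligible LLIN activity
by 30 minutes); activity mode mixes (swooping, visiting, bouncing,
resting) of (0.40, 0.57, 0.025, 0.005), (0.06, 0.27, 0.58, 0.09) and
(0.17, 0.345, 0.385, 0.10); lognormal track durations with geometric
mean 4.2 s.  Inter-contact interval and bout-length distributions are
simple stand-ins (uniform / lognormal) — no distributional forms are
known for the real quantities.

What the generator does **not** emulate: 3D flight and depth-dependent
speed bias, odour-plume structure, realistic front-of-net flight (the
net-avoidance rule keeps wandering flight out of the silhouette, so
regions 15/16 see little traffic), track fragmentation at blind zones,
detection dropouts, and any dependence of behaviour on time in contact.
Passing closed-loop tests therefore shows the detectors invert the
generator's statistical structure at realistic magnitudes and noise — not
that they would achieve the same accuracy on real video-derived tracks.

## Validation scorecard and problem sizes

`simulate_and_validate` generates a test, runs the full pipeline and
scores: per-frame mode-label accuracy; turn-contact recall/precision with
±2-frame greedy matching (truth `walk`/`rest` landings are optional
matches — detecting them is not an error, missing them not a miss);
mean absolute onset-distance error on extracted windows; and the decay-k
error from track-count bins.  The acceptance suite runs 10 hour-long
untreated tests per condition (σ = 0 for mode labels, σ = 0.1 mm for turn
contacts), 100 landing tracks for onset recovery, 200 Poisson replicates
for decay recovery and 500 for the type-I calibration; the acceptance
script uses 4 generated tests per condition and 300 type-I replicates,
problem sizes chosen to exercise the full default study conditions while
each run stays in the minutes range.

## Known limitations

- Sub-second rests are near the detection floor under 0.1 mm jitter: the
  lagged speed estimate needs roughly half the minimum resting time of
  clean samples on each side.
- Oscillation contacts during fast, large-amplitude probing can also
  qualify as sharp turns; merging collapses coincident events, but the
  two detectors' counts are not independent.
- The 2D projection makes side-wall (region 8/9) contacts geometrically
  indistinguishable from front-of-net flight; they are only assigned when
  behavioural detectors fire deep inside the silhouette.
- `compare_decay` assumes approximately normal per-test k estimates;
  with very sparse bins the estimates are heavy-tailed and the test is
  conservative.
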