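"""Net-contact detection from 2D flight tracks.

A bed-net contact leaves one of three signatures in a trajectory:

* a **sharp turn** (heading change of 80 degrees or more) with the vertex at
  the net surface — the typical signature of a visiting contact;
* **repetitive oscillation** of the x and/or y coordinate against the net
  surface — the signature of bouncing, where individual turn angles are
  often below the sharp-turn threshold;
* a **resting** interval: static, or moving slower than 1.33 mm/s, for at
  least 0.75 s (truncated at 300 s to exclude dead mosquitoes and spurious
  joins between unrelated arrival and departure flights).

Events from the three detectors are merged into one chronological sequence
per track with duplicates collapsed (rest > oscillation > turn priority).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import ArenaGeometry, ClassifierConfig

__all__ = [
    "ContactEvent", "RestingEvent",
    "turning_angles", "detect_turn_contacts", "detect_oscillation_contacts",
    "detect_resting", "merge_contacts", "detect_contacts",
]

# merge priority: higher wins when events coincide
_TYPE_PRIORITY = {"turn": 0, "oscillation": 1, "rest_start": 2}


@dataclass(frozen=True)
class ContactEvent:
    """One detected net contact."""

    track_id: str
    frame: int
    t: float
    x: float
    y: float
    type: str  # turn | oscillation | rest_start
    region_id: int | None = None


@dataclass(frozen=True)
class RestingEvent:
    """A maximal slow/static run on the net surface."""

    track_id: str
    start_frame: int
    end_frame: int
    duration_s: float
    x: float
    y: float
    truncated: bool = False


def turning_angles(track) -> np.ndarray:
    """Absolute heading change at each interior point, degrees in [0, 180].

    The angle at point ``i`` is between the displacement vectors
    ``(i-1 -> i)`` and ``(i -> i+1)``.  Where either displacement has zero
    length the angle is undefined and returned as NaN (such points are
    never turn contacts by themselves).
    """
    if len(track) < 3:
        raise ValueError("turning angles need at least 3 points")
    dx, dy = np.diff(track.x), np.diff(track.y)
    norm = np.hypot(dx, dy)
    a, b = norm[:-1], norm[1:]
    cross = dx[:-1] * dy[1:] - dy[:-1] * dx[1:]
    dot = dx[:-1] * dx[1:] + dy[:-1] * dy[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        ang = np.degrees(np.abs(np.arctan2(cross, dot)))
    ang[(a == 0) | (b == 0)] = np.nan
    return ang


def detect_turn_contacts(
    track, config: ClassifierConfig, geometry: ArenaGeometry
) -> list[ContactEvent]:
    """Sharp-turn contacts: angle >= ``turn_angle_min`` at the net surface.

    Consecutive qualifying frames are merged into a single event placed at
    the qualifying point nearest the net.  Vertices approached slower than
    ``turn_min_step_mm`` per frame are ignored: at near-zero speed the
    heading is dominated by centroid jitter.  (Only the incoming step is
    gated — a contact may legitimately end in walking or rest.)
    """
    if len(track) < 3:
        return []
    ang = turning_angles(track)
    steps = track.displacements()
    dist = geometry.distance_to_net(track.x[1:-1], track.y[1:-1])
    ok = (
        (ang >= config.turn_angle_min)
        & (dist <= config.net_proximity_mm)
        & (steps[:-1] >= config.turn_min_step_mm)
    )
    ok = np.where(np.isnan(ang), False, ok)
    events: list[ContactEvent] = []
    idx = np.flatnonzero(ok) + 1  # vertex index within the track
    if idx.size == 0:
        return events
    # merge runs of consecutive qualifying vertices into one event
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        d = geometry.distance_to_net(track.x[run], track.y[run])
        i = int(run[int(np.argmin(d))])
        events.append(ContactEvent(
            track_id=track.track_id, frame=int(track.frames[i]),
            t=float(track.t[i]), x=float(track.x[i]), y=float(track.y[i]),
            type="turn",
        ))
    return events


def detect_oscillation_contacts(
    track, config: ClassifierConfig, geometry: ArenaGeometry
) -> list[ContactEvent]:
    """Oscillation contacts from zero crossings of band-passed coordinates.

    Both coordinates are filtered with a 2nd-order Butterworth band-pass
    (default 2-20 Hz) applied forward-backward for zero phase.  Candidate
    contacts are the negative-going zero crossings — one per oscillation
    cycle, the approach phase toward the net — gated to net proximity and
    to a minimum band-passed excursion.  Crossings from the two axes closer
    together than half the shortest band period are debounced into one
    event.

    Tracks shorter than one period of the low corner frequency are below
    the filter warm-up and yield an empty result.
    """
    fr = config.frame_rate
    lo, hi = config.oscillation_band_hz
    warmup = int(np.ceil(fr / lo))
    if len(track) < max(warmup, 3 * 5 + 1):
        return []
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fr, output="sos")
    debounce = max(1, int(round(0.5 * fr / hi)))
    halfper = max(2, int(round(0.5 * fr / lo)))
    near = geometry.distance_to_net(track.x, track.y) <= config.net_proximity_mm

    cand: list[int] = []
    for coord in (track.x, track.y):
        f = signal.sosfiltfilt(sos, coord)
        down = np.flatnonzero((f[:-1] > 0) & (f[1:] <= 0))
        for i in down:
            l0, l1 = max(0, i - halfper), min(len(f), i + halfper + 1)
            if np.max(np.abs(f[l0:l1])) < config.oscillation_min_amplitude_mm:
                continue
            if not near[i]:
                continue
            cand.append(int(i))
    if not cand:
        return []
    cand.sort()
    # repetitive-oscillation gate: an isolated crossing (no neighbouring
    # near-net crossing within one low-band period) is a fly-by, not a bout
    max_gap = int(round(fr / lo))
    cand = [
        c for j, c in enumerate(cand)
        if (j > 0 and c - cand[j - 1] <= max_gap)
        or (j + 1 < len(cand) and cand[j + 1] - c <= max_gap)
    ]
    if not cand:
        return []
    kept = [cand[0]]
    for i in cand[1:]:
        if i - kept[-1] >= debounce:
            kept.append(i)
    return [
        ContactEvent(
            track_id=track.track_id, frame=int(track.frames[i]),
            t=float(track.t[i]), x=float(track.x[i]), y=float(track.y[i]),
            type="oscillation",
        )
        for i in kept
    ]


def detect_resting(track, config: ClassifierConfig) -> list[RestingEvent]:
    """Maximal runs slower than ``rest_velocity_max`` lasting >= ``rest_min_s``.

    Speed is estimated as net displacement over a lag of half the minimum
    resting time (on positions smoothed over ``rest_smooth_points``): the
    sub-threshold criterion (1.33 mm/s is 1 mm over the 0.75 s minimum)
    concerns net movement, and a lagged estimate is robust to centroid
    jitter that would swamp frame-to-frame speeds.  Runs longer than
    ``rest_cap_s`` are truncated at the cap and flagged.
    """
    fr = config.frame_rate
    k = max(1, int(round(config.rest_min_s * fr / 2)))
    if len(track) <= k:
        return []
    xs = _moving_average(track.x, config.rest_smooth_points)
    ys = _moving_average(track.y, config.rest_smooth_points)
    # speed of the k-frame window starting at each point, mm/s
    speed = np.hypot(xs[k:] - xs[:-k], ys[k:] - ys[:-k]) * fr / k
    slow = speed < config.rest_velocity_max
    events: list[RestingEvent] = []
    min_frames = int(np.ceil(config.rest_min_s * fr))
    cap_frames = int(round(config.rest_cap_s * fr))
    for i0, i1 in _runs(slow):  # window-start index range [i0, i1)
        j0, j1 = i0, i1 - 1 + k  # point indices spanned by the slow windows
        n = j1 - j0
        if n < min_frames:
            continue
        truncated = n > cap_frames
        if truncated:
            n = cap_frames
            j1 = j0 + n
        events.append(RestingEvent(
            track_id=track.track_id,
            start_frame=int(track.frames[j0]),
            end_frame=int(track.frames[j1]),
            duration_s=float((track.frames[j1] - track.frames[j0]) / fr),
            x=float(np.mean(track.x[j0:j1 + 1])),
            y=float(np.mean(track.y[j0:j1 + 1])),
            truncated=truncated,
        ))
    return events


def merge_contacts(
    turn_events: list[ContactEvent],
    oscillation_events: list[ContactEvent],
    resting_events: list[RestingEvent],
    frame_rate: float = 50.0,
) -> list[ContactEvent]:
    """Unified chronological contact sequence for one track.

    Resting events contribute a ``rest_start`` contact at their start
    frame.  Events within one frame of each other are collapsed with
    priority rest > oscillation > turn; contacts falling inside a resting
    span are absorbed by it.
    """
    events = list(turn_events) + list(oscillation_events)
    spans = [(r.start_frame, r.end_frame) for r in resting_events]
    events = [
        e for e in events
        if not any(s <= e.frame <= t for s, t in spans)
    ]
    for r in resting_events:
        events.append(ContactEvent(
            track_id=r.track_id, frame=r.start_frame,
            t=r.start_frame / frame_rate, x=r.x, y=r.y, type="rest_start",
        ))
    events.sort(key=lambda e: (e.frame, -_TYPE_PRIORITY[e.type]))
    merged: list[ContactEvent] = []
    for e in events:
        if merged and e.frame - merged[-1].frame <= 1:
            if _TYPE_PRIORITY[e.type] > _TYPE_PRIORITY[merged[-1].type]:
                merged[-1] = e
            continue
        merged.append(e)
    return merged


def detect_contacts(
    track, config: ClassifierConfig, geometry: ArenaGeometry
) -> tuple[list[ContactEvent], list[RestingEvent]]:
    """Run all three detectors on a track and merge the results."""
    rest = detect_resting(track, config)
    turn = detect_turn_contacts(track, config, geometry)
    osc = detect_oscillation_contacts(track, config, geometry)
    return merge_contacts(turn, osc, rest, config.frame_rate), rest


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(v) < window:
        return np.asarray(v, dtype=float)
    kernel = np.ones(window) / window
    out = np.convolve(v, kernel, mode="same")
    # repair edge shrinkage of the centred window
    half = window // 2
    for i in range(half):
        out[i] = np.mean(v[: i + half + 1])
        out[-(i + 1)] = np.mean(v[-(i + half + 1):])
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))
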