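"""Velocity, tortuosity and landing-kinematics analysis.

All speeds are 2D projected speeds (mm/s) and therefore a known
underestimate of true 3D flight speed; depth is not recorded.

The landing analysis extracts a 65-point window around each net contact —
50 points (1 s at 50 fps) of approach, the contact point (one-based index
51), and 14 points (0.28 s) of departure — and locates the deceleration
onset: the point closest to the net from which speed falls monotonically
until contact.  Onsets within the 3 mm tarsal zone, or windows that
accelerate over their final two flight intervals, are classed as contacts
without deceleration (leg contact cannot be excluded) and are left out of
onset-distance summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ClassifierConfig
from .contacts import ContactEvent

__all__ = [
    "LandingWindow", "TortuosityResult",
    "instantaneous_velocity", "tortuosity", "extract_landing_window",
    "deceleration_onset", "classify_contact_deceleration", "approach_summary",
]


@dataclass
class LandingWindow:
    """A 65-point trajectory window centred on one net contact."""

    track_id: str
    x: np.ndarray
    y: np.ndarray
    frames: np.ndarray
    contact_index: int            # 0-based (= one-based 51 - 1)
    speed: np.ndarray             # raw per-point speed, mm/s
    speed_smooth: np.ndarray
    accel: np.ndarray             # forward-differenced smoothed speed, mm/s^2
    onset_index: int | None = None
    onset_distance_mm: float | None = None
    onset_speed_mm_s: float | None = None
    decel_class: str | None = None  # decelerated | no_deceleration


@dataclass(frozen=True)
class TortuosityResult:
    """Sectioned path/chord ratios for one track (each >= 1)."""

    track_id: str
    section_ratios: np.ndarray
    mean: float
    n_sections: int


def instantaneous_velocity(track) -> np.ndarray:
    """Per-point speed in mm/s: displacement per frame times frame rate.

    The first point carries the first interval's speed, so the result has
    one value per track point.
    """
    if len(track) < 2:
        raise ValueError("velocity needs at least 2 points")
    step = track.displacements() * track.frame_rate
    return np.concatenate(([step[0]], step))


def tortuosity(track, config: ClassifierConfig) -> TortuosityResult | None:
    """Sectioned tortuosity: mean path/chord ratio over 40-point sections.

    The track is cut into consecutive non-overlapping sections of
    ``tortuosity_section_points`` positions; the trailing remainder is
    dropped so section statistics stay identically distributed.  Returns
    ``None`` (flagged undefined) for tracks shorter than one section.
    Sections whose endpoints coincide (chord below 0.1 mm) are degenerate
    and skipped.
    """
    m = config.tortuosity_section_points
    n_sections = len(track) // m
    if n_sections == 0:
        return None
    ratios = []
    for k in range(n_sections):
        xs = track.x[k * m:(k + 1) * m]
        ys = track.y[k * m:(k + 1) * m]
        path = float(np.sum(np.hypot(np.diff(xs), np.diff(ys))))
        chord = float(np.hypot(xs[-1] - xs[0], ys[-1] - ys[0]))
        if chord < 0.1:
            continue
        ratios.append(max(path / chord, 1.0))
    if not ratios:
        return None
    ratios = np.asarray(ratios)
    return TortuosityResult(track.track_id, ratios, float(ratios.mean()),
                            len(ratios))


def extract_landing_window(
    track, contact: ContactEvent, config: ClassifierConfig
) -> LandingWindow | None:
    """Extract the 65-point landing window around ``contact``.

    Requires at least one second of recorded flight before the contact
    (50 points) and 14 points after it; otherwise the track is excluded
    from landing analysis and ``None`` is returned (callers count
    exclusions).
    """
    pre, post = config.landing_pre_points, config.landing_post_points
    pos = np.searchsorted(track.frames, contact.frame)
    if pos >= len(track) or track.frames[pos] != contact.frame:
        raise ValueError(
            f"contact frame {contact.frame} not a point of track {track.track_id}"
        )
    if pos < pre or (len(track) - 1 - pos) < post:
        return None
    sl = slice(pos - pre, pos + post + 1)
    x, y, frames = track.x[sl], track.y[sl], track.frames[sl]
    step = np.hypot(np.diff(x), np.diff(y)) * config.frame_rate
    speed = np.concatenate(([step[0]], step))
    smooth = _moving_average(speed, config.accel_smooth_points)
    accel = np.diff(smooth) * config.frame_rate  # forward difference
    win = LandingWindow(
        track_id=track.track_id, x=x, y=y, frames=frames,
        contact_index=pre, speed=speed, speed_smooth=smooth, accel=accel,
    )
    onset = deceleration_onset(win, config)
    if onset is not None:
        win.onset_index, win.onset_distance_mm, win.onset_speed_mm_s = onset
    win.decel_class = classify_contact_deceleration(win, config)
    return win


def deceleration_onset(
    window: LandingWindow, config: ClassifierConfig
) -> tuple[int, float, float] | None:
    """Locate the deceleration onset within a landing window.

    The onset is the start of the maximal run of strictly negative
    (smoothed, forward-differenced) acceleration that persists to the
    contact point, advanced past any leading samples whose deceleration
    magnitude is below ``onset_rel_accel_min`` of the run peak — those
    samples are artefacts of the smoothing transition, not deceleration.
    The latest admissible onset is the point immediately before contact
    (one-based point 50).  Returns ``(onset index, along-path distance to
    the contact point in mm, smoothed speed at onset)``, or ``None`` when
    the approach never decelerates monotonically.
    """
    c = window.contact_index
    # smooth over pre-contact samples only: the departure after contact
    # must not leak into the approach's acceleration estimate
    pre_smooth = _moving_average(window.speed[:c + 1], config.accel_smooth_points)
    a = np.diff(pre_smooth) * config.frame_rate
    # a[i] refers to speed change between points i and i+1; pre-contact
    # deceleration must hold for intervals up to the contact point.
    run_start = None
    for j in range(c - 1, -1, -1):
        if a[j] < 0:
            run_start = j
        else:
            break
    if run_start is None or run_start == c - 1 and a[run_start] >= 0:
        return None
    run = a[run_start:c]
    peak = float(np.max(-run))
    thresh = config.onset_rel_accel_min * peak
    onset = None
    for j in range(run_start, c):
        if -a[j] >= thresh:
            onset = j
            break
    if onset is None:
        onset = run_start
    # smoothing smears the cruise->deceleration transition ~1 sample early;
    # advance past samples whose raw speed has not yet started to fall
    while onset < c - 1 and window.speed[onset + 1] - window.speed[onset] >= 0:
        onset += 1
    steps = np.hypot(np.diff(window.x), np.diff(window.y))
    distance = float(np.sum(steps[onset:c]))
    return onset, distance, float(pre_smooth[onset])


def classify_contact_deceleration(
    window: LandingWindow, config: ClassifierConfig
) -> str:
    """Class a landing as ``decelerated`` or ``no_deceleration``.

    No deceleration is recorded when the raw speed increases over the last
    two pre-contact intervals (the mosquito accelerated into the net), the
    onset is undefined, or the onset lies within the tarsal zone (leg
    contact cannot be excluded).
    """
    c = window.contact_index
    s = window.speed
    accelerating_finish = s[c] > s[c - 1] and s[c - 1] > s[c - 2]
    if accelerating_finish or window.onset_index is None:
        return "no_deceleration"
    if window.onset_distance_mm <= config.tarsal_zone_mm:
        return "no_deceleration"
    return "decelerated"


def approach_summary(test, windows: list[LandingWindow]) -> dict:
    """Per-test landing summary: mean onset distance and speed over
    decelerated windows, and the fraction of contacts without deceleration.

    Returns a flagged empty summary when no windows were extractable.
    """
    if not windows:
        return {"test_id": test.test_id, "n_windows": 0, "empty": True}
    dec = [w for w in windows if w.decel_class == "decelerated"]
    frac_no = 1.0 - len(dec) / len(windows)
    out = {
        "test_id": test.test_id,
        "n_windows": len(windows),
        "n_decelerated": len(dec),
        "fraction_no_deceleration": frac_no,
        "empty": False,
    }
    if dec:
        out["mean_onset_distance_mm"] = float(
            np.mean([w.onset_distance_mm for w in dec]))
        out["mean_onset_speed_mm_s"] = float(
            np.mean([w.onset_speed_mm_s for w in dec]))
    return out


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(v) < window:
        return np.asarray(v, dtype=float)
    kernel = np.ones(window) / window
    out = np.convolve(v, kernel, mode="same")
    half = window // 2
    for i in range(half):
        out[i] = np.mean(v[: i + half + 1])
        out[-(i + 1)] = np.mean(v[-(i + half + 1):])
    return out
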