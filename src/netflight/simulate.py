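"""Synthetic multi-mosquito test generator with ground truth.

The raw video-derived tracks behind the reference assay were never
deposited, so this module generates labelled test datasets with the
statistical structure the analysis assumes: four behavioural modes,
programmed net contacts with known frames and regions, programmed
pre-contact deceleration onsets, roof-biased contact placement, and
treatment-dependent exponential decay of activity over the hour.  Every
downstream stage can therefore be validated closed-loop against known
truth.

Movement model: flight is a correlated random walk (per-step heading
perturbation) at a per-track cruise speed; contact-bound flight follows a
staged straight approach whose final stretch decelerates linearly in speed
from the programmed onset distance down to the contact point, with one
sample placed exactly at the onset.  Bouncing is a train of out-and-back
hops off the surface with inter-contact gaps below the 0.4 s interval;
resting is sub-threshold positional jitter at the surface.  None of this
models aerodynamics or odour plumes — it exercises the detectors.

Default parameters are calibrated to the magnitudes reported for the
reference assay (cruise speeds ~321/356/323 mm/s, deceleration onsets
~26/41 mm, track counts ~212/545/165 per hour, Table-style mode mixes,
LLIN decay constant 0.12/min); they define plausible study conditions,
not reproductions of the original data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .config import ArenaGeometry, ClassifierConfig
from .model import Track, TestRecord
from .regions import RegionMap

__all__ = ["GenerationParams", "GroundTruth", "TruthContact",
           "generate_test", "generate_landing_track", "NET_TYPE_DEFAULTS"]

MODES = ("swooping", "visiting", "bouncing", "resting")

#: Per-net-type defaults: cruise speed (mm/s), deceleration onset (mm),
#: decay constant (/min), first-bin track rate (tracks / 5 min), activity
#: mode mix (swooping, visiting, bouncing, resting).
NET_TYPE_DEFAULTS = {
    "unbaited": dict(speed=321.1, decel=26.3, k=0.0, tracks_per_bin=18.0,
                     mix=(0.40, 0.57, 0.025, 0.005)),
    "untreated": dict(speed=355.8, decel=41.5, k=0.0, tracks_per_bin=45.0,
                      mix=(0.06, 0.27, 0.58, 0.09)),
    "llin": dict(speed=322.7, decel=40.0, k=0.12, tracks_per_bin=80.0,
                 mix=(0.17, 0.345, 0.385, 0.10)),
}

_ROOF_WEIGHTS = np.array([0.08, 0.22, 0.28, 0.20, 0.12, 0.10])


@dataclass
class GenerationParams:
    """Parameters of one synthetic test; ``None`` fields resolve to the
    net-type defaults in :data:`NET_TYPE_DEFAULTS`."""

    seed: int = 0
    net_type: str = "untreated"
    n_mosquitoes: int = 25
    duration_s: float = 3600.0
    mode_mix: tuple[float, float, float, float] | None = None
    mean_flight_speed: float | None = None
    flight_speed_sd: float = 30.0
    decel_start_mm: float | None = None
    decay_k: float | None = None
    tracks_per_bin: float | None = None
    roof_bias: float = 0.6
    jitter_sd_mm: float = 0.1
    bin_s: float = 300.0
    track_duration_gm_s: float = 4.2
    track_duration_sigma_log: float = 1.0

    def __post_init__(self) -> None:
        d = NET_TYPE_DEFAULTS[self.net_type]
        if self.mode_mix is None:
            self.mode_mix = d["mix"]
        if self.mean_flight_speed is None:
            self.mean_flight_speed = d["speed"]
        if self.decel_start_mm is None:
            self.decel_start_mm = d["decel"]
        if self.decay_k is None:
            self.decay_k = d["k"]
        if self.tracks_per_bin is None:
            self.tracks_per_bin = d["tracks_per_bin"]
        if abs(sum(self.mode_mix) - 1.0) > 1e-6:
            raise ValueError("mode_mix fractions must sum to 1")
        if self.mean_flight_speed <= 0 or self.tracks_per_bin <= 0:
            raise ValueError("rates and speeds must be positive")
        if self.decay_k < 0 or self.decel_start_mm < 0:
            raise ValueError("decay_k and decel_start_mm must be >= 0")


@dataclass(frozen=True)
class TruthContact:
    track_id: str
    index: int          # point index within the track
    frame: int
    x: float
    y: float
    region_id: int
    type: str           # turn | rest
    onset_distance_mm: float | None = None


@dataclass
class GroundTruth:
    """Everything the tracking system could not record, known here."""

    labels: dict[str, np.ndarray]
    contacts: list[TruthContact]
    decay_k: float
    bin_counts: np.ndarray
    mosquito_of_track: dict[str, int]
    contact_seconds_by_mosquito: dict[int, float]
    mode_seconds: dict[str, float]
    frame_rate: float = 50.0

    def contacts_for(self, track_id: str) -> list[TruthContact]:
        return [c for c in self.contacts if c.track_id == track_id]

    def onset_distances(self) -> list[float]:
        return [c.onset_distance_mm for c in self.contacts
                if c.onset_distance_mm is not None]

    def to_json(self, path) -> None:
        doc = {
            "decay_k": self.decay_k,
            "frame_rate": self.frame_rate,
            "bin_counts": self.bin_counts.tolist(),
            "mode_seconds": self.mode_seconds,
            "mosquito_of_track": self.mosquito_of_track,
            "contact_seconds_by_mosquito": {
                str(k): v for k, v in self.contact_seconds_by_mosquito.items()},
            "labels_rle": {tid: _rle(lab) for tid, lab in self.labels.items()},
            "contacts": [vars(c) | {} for c in self.contacts],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        labels = {tid: _unrle(r) for tid, r in doc["labels_rle"].items()}
        contacts = [TruthContact(**c) for c in doc["contacts"]]
        return cls(
            labels=labels, contacts=contacts, decay_k=doc["decay_k"],
            bin_counts=np.array(doc["bin_counts"]),
            mosquito_of_track=doc["mosquito_of_track"],
            contact_seconds_by_mosquito={
                int(k): v for k, v in doc["contact_seconds_by_mosquito"].items()},
            mode_seconds=doc["mode_seconds"],
            frame_rate=doc["frame_rate"],
        )


def _rle(labels: np.ndarray) -> list[list]:
    out: list[list] = []
    for lab in labels:
        if out and out[-1][0] == lab:
            out[-1][1] += 1
        else:
            out.append([str(lab), 1])
    return out


def _unrle(runs: list[list]) -> np.ndarray:
    return np.array([lab for lab, n in runs for _ in range(n)], dtype=object)


# ----------------------------------------------------------------- geometry


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.hypot(*v)


def _rot(v: np.ndarray, ang: float) -> np.ndarray:
    c, s = np.cos(ang), np.sin(ang)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _entry_point(rng, geom: ArenaGeometry):
    """Uniform point on the entry edge (top + both sides), with an inward
    initial heading."""
    W, H = geom.fov_width_mm, geom.fov_height_mm
    r = rng.uniform(0, W + 2 * H)
    jit = rng.uniform(-0.9, 0.9)
    if r < H:                      # left edge, heading -> +x
        pos, base = np.array([0.5, r]), 0.0
    elif r < H + W:                # top edge, heading -> -y
        pos, base = np.array([r - H, H - 0.5]), -np.pi / 2
    else:                          # right edge, heading -> -x
        pos, base = np.array([W - 0.5, r - H - W]), np.pi
    return pos, base + jit


def _sample_target(rng, geom: ArenaGeometry, roof_bias: float, region_map: RegionMap):
    """Sample a contact target on the net surface: position, outward
    normal, surface tangent, tangential clamp bounds and region id."""
    w = np.concatenate([roof_bias * _ROOF_WEIGHTS / _ROOF_WEIGHTS.sum(),
                        [(1 - roof_bias) * 0.35, (1 - roof_bias) * 0.65]])
    choice = rng.choice(8, p=w / w.sum())
    h0, h1 = geom.net_floor_clearance_mm, geom.net_roof_mm
    if choice < 6:  # roof sextant
        seg = geom.net_length_mm / 6.0
        x = geom.net_x0_mm + (choice + rng.uniform(0.08, 0.92)) * seg
        T = np.array([x, geom.net_roof_mm])
        n, t = np.array([0.0, 1.0]), np.array([1.0, 0.0])
        bounds = (geom.net_x0_mm + 10, geom.net_x1_mm - 10)
    elif choice == 6:  # head-end wall
        y = h0 + rng.uniform(0.15, 0.85) * (h1 - h0)
        T = np.array([geom.net_x0_mm, y])
        n, t = np.array([-1.0, 0.0]), np.array([0.0, 1.0])
        bounds = (h0 + 10, h1 - 10)
    else:  # foot-end wall
        y = h0 + rng.uniform(0.15, 0.85) * (h1 - h0)
        T = np.array([geom.net_x1_mm, y])
        n, t = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        bounds = (h0 + 10, h1 - 10)
    region = region_map.assign_contact(float(T[0]), float(T[1]))
    return T, n, t, bounds, region


# --------------------------------------------------------------- leg pieces


def _away_from_net(x, y, geom: ArenaGeometry):
    """Rough outward unit direction from the net surface at (x, y)."""
    if x < geom.net_x0_mm:
        return np.array([-1.0, 0.0])
    if x > geom.net_x1_mm:
        return np.array([1.0, 0.0])
    if y > geom.net_roof_mm:
        return np.array([0.0, 1.0])
    # inside the silhouette: retreat from the nearest boundary
    d = {(0.0, -1.0): geom.net_roof_mm - y,
         (1.0, 0.0): x - geom.net_x0_mm,
         (-1.0, 0.0): geom.net_x1_mm - x}
    return np.array(min(d, key=d.get))


def _wander_leg(rng, pos, heading, n, step, geom: ArenaGeometry,
                sigma_rad: float = 0.21, net_margin: float = 8.0):
    """Correlated random walk: n steps at fixed step length, reflecting off
    the field-of-view walls and steering clear of the net surface (swooping
    flight never contacts the net)."""
    W, H = geom.fov_width_mm, geom.fov_height_mm
    turns = rng.normal(0.0, sigma_rad, n)
    pts = np.empty((n, 2))
    x, y = pos
    for i in range(n):
        heading += turns[i]
        dx, dy = step * np.cos(heading), step * np.sin(heading)
        if not 0.5 <= x + dx <= W - 0.5:
            dx = -dx
        if not 0.5 <= y + dy <= H - 0.5:
            dy = -dy
        if float(geom.distance_to_net(x + dx, y + dy)) < net_margin:
            away = _away_from_net(x, y, geom)
            dx, dy = step * away[0], step * away[1]
        heading = np.arctan2(dy, dx)
        x = float(np.clip(x + dx, 0.5, W - 0.5))
        y = float(np.clip(y + dy, 0.5, H - 0.5))
        pts[i] = (x, y)
    return pts, heading


def _straight_leg(p, q, step):
    """Evenly spaced points from just after p to exactly q."""
    d = float(np.hypot(*(q - p)))
    n = max(1, int(round(d / step)))
    f = (np.arange(1, n + 1) / n)[:, None]
    return p + f * (q - p)


def _decel_speeds(v0: float, ds: float, fr: float,
                  min_end_frac: float = 0.18) -> np.ndarray:
    """Linearly decreasing interval speeds whose path lengths sum to
    exactly ``ds`` mm, starting from cruise speed ``v0``."""
    if ds <= 0:
        return np.empty(0)
    m_lo = max(1, int(np.ceil(ds * fr / v0 + 1e-9)))
    best = None
    for m in range(m_lo, m_lo + 60):
        g = 2.0 * (m * v0 - ds * fr) / m ** 2
        s_end = v0 - (m - 0.5) * g
        if s_end <= min_end_frac * v0:
            break
        best = (m, g)
    if best is None:
        m = m_lo
        best = (m, 2.0 * (m * v0 - ds * fr) / m ** 2)
    m, g = best
    return v0 - (np.arange(1, m + 1) - 0.5) * g


def _approach_leg(rng, pos, T, nvec, tvec, v0, ds, fr):
    """Staged approach: cruise to a staging point out along the surface
    normal, then a straight run-in with one sample exactly at the
    programmed deceleration-onset distance."""
    stage = 150.0 + ds
    Q = T + nvec * stage + tvec * rng.uniform(-80, 80)
    pts1 = _straight_leg(np.asarray(pos, float), Q, v0 / fr)
    u = _unit(T - Q)
    speeds = _decel_speeds(v0, ds, fr)
    ds_actual = float(np.sum(speeds)) / fr
    cruise_d = float(np.hypot(*(T - Q))) - ds_actual
    n1 = max(3, int(round(cruise_d * fr / v0)))
    S = T - u * ds_actual
    pts2 = Q + (np.arange(1, n1 + 1) / n1)[:, None] * (S - Q)
    if len(speeds):
        path = np.cumsum(speeds) / fr
        pts3 = S + path[:, None] * u
        pts3[-1] = T
    else:
        pts3 = np.empty((0, 2))
    return np.vstack([pts1, pts2, pts3]), u


def _departure_leg(rng, T, u, nvec, v0, fr, n_cruise, geom: ArenaGeometry):
    """Leave the surface: specular reflection of the arrival direction with
    noise, speeding back up to cruise."""
    w = u - 2 * float(u @ nvec) * nvec
    w = _rot(w, rng.normal(0, 0.17))
    if float(w @ nvec) < 0.25:
        w = _rot(nvec, rng.uniform(-0.5, 0.5))
    w = _unit(w)
    speeds = np.concatenate([np.linspace(0.35 * v0, v0, 6),
                             np.full(n_cruise, v0)])
    path = np.cumsum(speeds) / fr
    pts = T + path[:, None] * w
    W, H = geom.fov_width_mm, geom.fov_height_mm
    pts[:, 0] = np.clip(pts[:, 0], 0.5, W - 0.5)
    pts[:, 1] = np.clip(pts[:, 1], 0.5, H - 0.5)
    heading = float(np.arctan2(w[1], w[0]))
    return pts, heading


def _hop_leg(rng, C, nvec, tvec, gap_frames, fr, bounds):
    """One bounce: out-and-back triangle from contact point C to a nearby
    contact point, lasting ``gap_frames`` frames."""
    k1 = int(np.ceil(gap_frames / 2))
    k2 = gap_frames - k1
    v_b = rng.uniform(130, 260)
    h = max(6.5, v_b * k1 / fr)
    A = C + _rot(nvec, rng.uniform(-0.55, 0.55)) * h
    A[1] = max(A[1], 0.5)  # hops near a wall base must not dip below floor
    # keep the descent within ~35 degrees of the surface normal so the
    # touch is a genuine sharp-turn vertex
    delta = rng.uniform(-0.7, 0.7) * h
    s = float(C @ np.abs(tvec)) + delta
    s = float(np.clip(s, *bounds))
    C2 = C + tvec * (s - float(C @ np.abs(tvec)))
    out = C + (np.arange(1, k1 + 1) / k1)[:, None] * (A - C)
    if k2 > 0:
        back = A + (np.arange(1, k2 + 1) / k2)[:, None] * (C2 - A)
    else:
        back = np.empty((0, 2))
        C2 = A
    return np.vstack([out, back]), C2


def _pause_leg(rng, C, tvec, n, fr, bounds):
    """Walking/probing pause: slow tangential drift plus a probing wiggle
    (millimetre-scale, in the oscillation detector's band)."""
    t = np.arange(1, n + 1)
    drift = rng.uniform(0.1, 0.25) * rng.choice([-1.0, 1.0]) * t
    amp, f = rng.uniform(1.2, 1.6), rng.uniform(3.0, 4.0)
    wig = amp * np.sin(2 * np.pi * f * t / fr + rng.uniform(0, 2 * np.pi))
    s0 = float(C @ np.abs(tvec))
    s = np.clip(s0 + drift + wig, *bounds)
    return C + (s - s0)[:, None] * tvec


def _rest_leg(rng, C, n):
    """Sub-threshold positional jitter while resting."""
    return C + np.cumsum(rng.normal(0, 0.004, (n, 2)), axis=0)


# ----------------------------------------------------------- track builders


class _TrackAccumulator:
    def __init__(self, pos, heading):
        self.pts = [np.asarray(pos, float)[None, :]]
        self.labels: list[str] = ["_first"]
        self.heading = heading
        self.contact_marks: list[tuple[int, float, float, str, float | None, int]] = []

    @property
    def pos(self):
        return self.pts[-1][-1]

    @property
    def n(self):
        return sum(len(p) for p in self.pts)

    def add(self, pts, label):
        if len(pts) == 0:
            return
        self.pts.append(np.asarray(pts, float))
        self.labels.extend([label] * len(pts))

    def mark_contact(self, xy, ctype, onset, region):
        self.contact_marks.append(
            (self.n - 1, float(xy[0]), float(xy[1]), ctype, onset, region))

    def finish(self, default_label):
        pts = np.vstack(self.pts)
        labels = np.array(self.labels, dtype=object)
        labels[0] = labels[1] if len(labels) > 1 else default_label
        return pts, labels


def _build_swooping(rng, ctx):
    dur = float(np.clip(rng.lognormal(np.log(ctx.p.track_duration_gm_s),
                                      ctx.p.track_duration_sigma_log), 1.0, 60.0))
    n = max(2, int(round(dur * ctx.fr)))
    pos, heading = _entry_point(rng, ctx.geom)
    acc = _TrackAccumulator(pos, heading)
    v0 = ctx.draw_speed(rng)
    pts, _ = _wander_leg(rng, pos, heading, n, v0 / ctx.fr, ctx.geom)
    acc.add(pts, "swooping")
    return acc.finish("swooping")[:2] + (acc.contact_marks,)


def _flight_prefix(rng, ctx, lo, hi):
    pos, heading = _entry_point(rng, ctx.geom)
    acc = _TrackAccumulator(pos, heading)
    v0 = ctx.draw_speed(rng)
    n = int(rng.integers(lo, hi))
    pts, heading = _wander_leg(rng, pos, heading, n, v0 / ctx.fr, ctx.geom)
    acc.add(pts, "visiting")
    acc.heading = heading
    return acc, v0


def _approach_and_contact(rng, ctx, acc, v0, ctype):
    T, nvec, tvec, bounds, region = _sample_target(
        rng, ctx.geom, ctx.p.roof_bias, ctx.region_map)
    pts, u = _approach_leg(rng, acc.pos, T, nvec, tvec, v0, ctx.p.decel_start_mm,
                           ctx.fr)
    acc.add(pts, "visiting")
    acc.mark_contact(T, ctype, ctx.p.decel_start_mm, region)
    return T, nvec, tvec, bounds, u


def _build_visiting(rng, ctx):
    acc, v0 = _flight_prefix(rng, ctx, 60, 181)
    n_c = 1 + int(rng.poisson(1.0))
    for i in range(n_c):
        T, nvec, tvec, bounds, u = _approach_and_contact(rng, ctx, acc, v0, "turn")
        pts, heading = _departure_leg(rng, T, u, nvec, v0, ctx.fr, 10, ctx.geom)
        acc.add(pts, "visiting")
        acc.heading = heading
        n_w = int(rng.integers(25, 120))
        pts, heading = _wander_leg(rng, acc.pos, acc.heading, n_w, v0 / ctx.fr,
                                   ctx.geom)
        acc.add(pts, "visiting")
        acc.heading = heading
    return acc.finish("visiting")[:2] + (acc.contact_marks,)


def _build_bouncing(rng, ctx):
    acc, v0 = _flight_prefix(rng, ctx, 50, 151)
    T, nvec, tvec, bounds, u = _approach_and_contact(rng, ctx, acc, v0, "turn")
    first_idx = acc.contact_marks[-1][0]
    C = T
    # bout length in seconds (bouncing can dominate activity at baited nets);
    # capped by the remaining mode budget so small budgets are not overshot
    bout_s = float(np.clip(rng.lognormal(np.log(12.0), 0.9), 1.0, 60.0))
    bout_s = min(bout_s, ctx.bout_budget_s)
    n_hops = max(4, int(round(bout_s * ctx.fr / 11.0)))
    for _ in range(n_hops):
        if rng.uniform() < 0.15:
            p = int(rng.integers(8, 13))
            g = int(rng.integers(5, 8))  # pause + hop stays under the interval
            # the landing that starts a walk is not a sharp-turn vertex
            idx, cx, cy, _t, onset, region = acc.contact_marks[-1]
            acc.contact_marks[-1] = (idx, cx, cy, "walk", onset, region)
            acc.add(_pause_leg(rng, C, tvec, p, ctx.fr, bounds), "visiting")
            C = acc.pos.copy()
        else:
            g = int(rng.integers(5, 18))
        pts, C = _hop_leg(rng, C, nvec, tvec, g, ctx.fr, bounds)
        acc.add(pts, "visiting")
        acc.mark_contact(C, "turn", None, ctx.region_map.assign_contact(*C))
    last_idx = acc.contact_marks[-1][0]
    pts, heading = _departure_leg(rng, C, -nvec, nvec, v0, ctx.fr, 8, ctx.geom)
    acc.add(pts, "visiting")
    acc.heading = heading
    n_w = int(rng.integers(25, 75))
    pts, _ = _wander_leg(rng, acc.pos, acc.heading, n_w, v0 / ctx.fr, ctx.geom)
    acc.add(pts, "visiting")
    pts_all, labels = acc.finish("visiting")
    labels[first_idx:last_idx] = "bouncing"
    return pts_all, labels, acc.contact_marks


def _build_resting(rng, ctx):
    acc, v0 = _flight_prefix(rng, ctx, 50, 151)
    T, nvec, tvec, bounds, u = _approach_and_contact(rng, ctx, acc, v0, "rest")
    start_idx = acc.contact_marks[-1][0]
    dur = float(np.clip(rng.lognormal(np.log(15.0), 1.0), 1.5, 290.0))
    dur = min(dur, ctx.rest_budget_s)
    n = int(round(dur * ctx.fr))
    acc.add(_rest_leg(rng, T, n), "visiting")
    end_idx = acc.n - 1
    pts, heading = _departure_leg(rng, acc.pos, -nvec, nvec, v0, ctx.fr, 8,
                                  ctx.geom)
    acc.add(pts, "visiting")
    acc.heading = heading
    n_w = int(rng.integers(25, 75))
    pts, _ = _wander_leg(rng, acc.pos, acc.heading, n_w, v0 / ctx.fr, ctx.geom)
    acc.add(pts, "visiting")
    pts_all, labels = acc.finish("visiting")
    labels[start_idx:end_idx] = "resting"
    return pts_all, labels, acc.contact_marks


_BUILDERS = {
    "swooping": _build_swooping,
    "visiting": _build_visiting,
    "bouncing": _build_bouncing,
    "resting": _build_resting,
}


class _Ctx:
    def __init__(self, params, config, geom):
        self.p = params
        self.fr = config.frame_rate
        self.geom = geom
        self.region_map = RegionMap(geom)
        self.rest_budget_s = 290.0
        self.bout_budget_s = 60.0

    def draw_speed(self, rng):
        return float(np.clip(
            rng.normal(self.p.mean_flight_speed, self.p.flight_speed_sd),
            150.0, 900.0))


# ------------------------------------------------------------ entry points


def generate_test(
    params: GenerationParams,
    config: ClassifierConfig | None = None,
    geometry: ArenaGeometry | None = None,
    test_id: str | None = None,
) -> tuple[TestRecord, GroundTruth]:
    """Generate one synthetic test with ground truth.

    Track appearance counts per 5-minute bin are Poisson with mean
    ``tracks_per_bin * exp(-decay_k * t_mid)``; each track is built from a
    behavioural template chosen greedily so the realised activity-time mix
    approaches ``mode_mix``.
    """
    config = config or ClassifierConfig()
    geom = geometry or ArenaGeometry()
    if geom.net_roof_mm + 60 > geom.fov_height_mm:
        raise ValueError("geometry too small: no flight space above the net roof")
    rng = np.random.default_rng(params.seed)
    ctx = _Ctx(params, config, geom)
    fr = config.frame_rate
    test_id = test_id or f"{params.net_type}_{params.seed}"

    n_bins = int(np.ceil(params.duration_s / params.bin_s))
    mids = (np.arange(n_bins) + 0.5) * params.bin_s / 60.0
    rates = params.tracks_per_bin * np.exp(-params.decay_k * mids)
    counts = rng.poisson(rates)

    starts = np.sort(np.concatenate([
        b * params.bin_s + rng.uniform(0, params.bin_s, c)
        for b, c in enumerate(counts)
    ])) if counts.sum() else np.empty(0)

    realised = np.full(4, 1e-9)
    target = np.asarray(params.mode_mix, dtype=float)
    # expected seconds each template adds per mode (updated online), so the
    # chooser accounts for the visiting flight around contacts and rests
    expected = {
        "swooping": np.array([10.0, 0.0, 0.0, 0.0]),
        "visiting": np.array([0.0, 8.0, 0.0, 0.0]),
        "bouncing": np.array([0.0, 4.0, 10.0, 0.0]),
        "resting": np.array([0.0, 4.0, 0.0, 25.0]),
    }
    tracks: list[Track] = []
    labels_by_track: dict[str, np.ndarray] = {}
    contacts: list[TruthContact] = []
    mosquito_of: dict[str, int] = {}
    max_frame = int(params.duration_s * fr)

    for i, t_start in enumerate(starts):
        viable = [m for m, w in zip(MODES, target) if w > 0] or ["swooping"]

        def _score(m):
            after = realised + expected[m]
            return float(np.abs(after / after.sum() - target).sum())

        template = min(viable, key=_score)
        tot = float(realised.sum())
        ctx.rest_budget_s = float(np.clip(
            (target[3] * tot - realised[3]) / max(1 - target[3], 0.05) + 5.0,
            3.0, 290.0))
        ctx.bout_budget_s = float(np.clip(
            (target[2] * tot - realised[2]) / max(1 - target[2], 0.05) + 3.0,
            1.5, 60.0))
        pts, labels, marks = _BUILDERS[template](rng, ctx)

        start_frame = int(round(t_start * fr))
        keep = min(len(pts), max_frame - start_frame + 1)
        if keep < 2:
            continue
        pts, labels = pts[:keep], labels[:keep]
        marks = [m for m in marks if m[0] < keep]

        if params.jitter_sd_mm > 0:
            pts = pts + rng.normal(0, params.jitter_sd_mm, pts.shape)
            pts[:, 0] = np.clip(pts[:, 0], 0.0, geom.fov_width_mm)
            pts[:, 1] = np.clip(pts[:, 1], 0.0, geom.fov_height_mm)

        track_id = f"{test_id}_t{i:04d}"
        tr = Track(
            track_id=track_id, test_id=test_id,
            frames=start_frame + np.arange(len(pts)),
            x=pts[:, 0], y=pts[:, 1],
            camera_field="left" if np.mean(pts[:, 0]) < 0.5 * geom.fov_width_mm
            else "right",
            frame_rate=fr,
        )
        tracks.append(tr)
        labels_by_track[track_id] = labels
        mosquito_of[track_id] = int(rng.integers(1, params.n_mosquitoes + 1))
        for idx, cx, cy, ctype, onset, region in marks:
            contacts.append(TruthContact(
                track_id=track_id, index=idx, frame=start_frame + idx,
                x=cx, y=cy, region_id=region, type=ctype,
                onset_distance_mm=onset,
            ))
        added = np.array([np.sum(labels == m) for m in MODES]) / fr
        realised = realised + added
        expected[template] = 0.7 * expected[template] + 0.3 * added

    mode_seconds = dict(zip(MODES, realised))
    contact_s_by_mosq: dict[int, float] = {}
    for tr in tracks:
        lab = labels_by_track[tr.track_id]
        n_visit_contacts = sum(
            1 for c in contacts
            if c.track_id == tr.track_id and lab[c.index] == "visiting")
        cs = (np.sum(lab == "bouncing") + np.sum(lab == "resting")
              + n_visit_contacts) / fr
        mid = mosquito_of[tr.track_id]
        contact_s_by_mosq[mid] = contact_s_by_mosq.get(mid, 0.0) + float(cs)

    record = TestRecord(
        test_id=test_id, net_type=params.net_type,
        n_released=params.n_mosquitoes, duration_s=params.duration_s,
        tracks=tracks, geometry=geom,
    )
    truth = GroundTruth(
        labels=labels_by_track, contacts=contacts, decay_k=params.decay_k,
        bin_counts=counts, mosquito_of_track=mosquito_of,
        contact_seconds_by_mosquito=contact_s_by_mosq,
        mode_seconds=mode_seconds, frame_rate=fr,
    )
    return record, truth


def generate_landing_track(
    speed: float,
    decel_start_mm: float,
    seed: int,
    jitter_sd_mm: float = 0.0,
    decel_duration_s: float | None = None,
    config: ClassifierConfig | None = None,
    geometry: ArenaGeometry | None = None,
) -> tuple[Track, dict]:
    """One clean landing approach onto the net roof, for landing-kinematics
    validation.

    The track cruises at ``speed`` and decelerates from exactly
    ``decel_start_mm`` of along-path distance before the contact point
    (``decel_start_mm = 0`` gives constant speed into contact).  With
    ``decel_duration_s`` set, the deceleration instead lasts a fixed time,
    so its onset distance scales with approach speed.  Returns the track
    and a truth dict with the contact index and programmed onset distance.
    """
    if speed <= 0 or decel_start_mm < 0:
        raise ValueError("speed must be > 0 and decel_start_mm >= 0")
    config = config or ClassifierConfig()
    geom = geometry or ArenaGeometry()
    rng = np.random.default_rng(seed)
    fr = config.frame_rate

    T = np.array([geom.net_mid_x_mm + rng.uniform(-300, 300), geom.net_roof_mm])
    ang = rng.uniform(0.7, 1.05) * rng.choice([-1.0, 1.0])  # tilt from vertical
    u = _rot(np.array([0.0, -1.0]), ang)  # travel direction, downward

    if decel_duration_s is not None:
        m = max(2, int(round(decel_duration_s * fr)))
        speeds = speed - (np.arange(1, m + 1) - 0.5) * (0.8 * speed / m)
    else:
        speeds = _decel_speeds(speed, decel_start_mm, fr)
    ds = float(np.sum(speeds)) / fr
    pre_total = config.landing_pre_points + 25
    n_cruise = pre_total - len(speeds)
    S = T - u * ds
    P = S - u * (n_cruise * speed / fr)

    cruise = P + (np.arange(1, n_cruise + 1) / n_cruise)[:, None] * (S - P)
    if len(speeds):
        decel = S + (np.cumsum(speeds) / fr)[:, None] * u
        decel[-1] = T
    else:
        decel = np.empty((0, 2))
    dep_dir = _rot(np.array([u[0], -u[1]]), rng.normal(0, 0.1))  # reflect off roof
    dep = T + (np.cumsum(np.linspace(0.35 * speed, speed, 20)) / fr)[:, None] * dep_dir

    pts = np.vstack([P[None, :], cruise, decel, dep])
    if jitter_sd_mm > 0:
        pts = pts + rng.normal(0, jitter_sd_mm, pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], 0.0, geom.fov_width_mm)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, geom.fov_height_mm)

    track = Track(
        track_id=f"landing_{seed}", test_id="landing",
        frames=np.arange(len(pts)), x=pts[:, 0], y=pts[:, 1],
        camera_field="both", frame_rate=fr,
    )
    truth = {
        "contact_index": pre_total,  # 0-based point index of the contact
        "contact_frame": pre_total,
        "onset_distance_mm": ds,
        "speed": speed,
    }
    return track, truth
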