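"""Configuration objects shared by every analysis stage.

Every numeric threshold used anywhere in the package lives in
:class:`ClassifierConfig` or :class:`ArenaGeometry`, so that a single YAML
block reproduces an analysis exactly.  Units are fixed throughout the
package: millimetres, seconds, degrees.  Frame index is authoritative;
time stamps are derived as ``frame / frame_rate``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

__all__ = ["ClassifierConfig", "ArenaGeometry", "load_config", "dump_config"]


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the behavioural classifiers.

    Parameters
    ----------
    frame_rate
        Recording rate in frames per second (50 in the reference assay).
    turn_angle_min
        Minimum absolute heading change, in degrees, for a sharp turn at
        the net surface to count as a contact (inclusive, ``>= 80``).
    contact_interval_s
        Boundary between *visiting* (inter-contact gaps of at least this
        interval) and *bouncing* (gaps shorter than it); 0.4 s = 20 frames.
    rest_min_s
        Minimum duration of a resting event (0.75 s).
    rest_velocity_max
        Speed below which a mosquito is considered at rest, mm/s.  The
        reference value 1.33 mm/s is one millimetre of movement over the
        minimum resting time.
    rest_cap_s
        Maximum duration credited to a single resting event (300 s); longer
        events are truncated and flagged (excludes dead mosquitoes and
        spurious arrival/departure joins).
    tarsal_zone_mm
        Band above the net surface within which leg contact cannot be
        excluded (3 mm); deceleration onsets inside it are classed as
        contacts without deceleration.
    landing_window_points
        Length of the landing analysis window (65 points).
    landing_contact_index
        One-based index of the contact point within the window (51).
    tortuosity_section_points
        Section length for tortuosity (40 sequential positions).
    net_proximity_mm
        Distance gate for counting a sharp turn / oscillation crossing as a
        net contact.  The source assay states only "at the net surface";
        5 mm exceeds centroid jitter and is below typical bounce amplitudes.
    oscillation_band_hz
        Band-pass corner frequencies (Hz) for the oscillation detector.
    oscillation_min_amplitude_mm
        Minimum band-passed excursion for a zero crossing to qualify;
        suppresses sub-noise wiggle while at rest.
    turn_min_step_mm
        Minimum adjacent displacement for a turn vertex to qualify; rules
        out jitter-dominated angles while effectively stationary.
    accel_smooth_points
        Centred moving-average window (points) applied to speed before
        differencing in the landing analysis.
    onset_rel_accel_min
        Fraction of the peak deceleration below which leading
        (smoothing-transition) samples are not credited as the onset.
    rest_smooth_points
        Centred moving-average window applied to positions before the
        resting-speed test.
    high_entry_expected_fraction
        Expected fraction of tracks first appearing above the net under
        spatially uniform entry (0.36 in the reference assay geometry).
    """

    frame_rate: float = 50.0
    turn_angle_min: float = 80.0
    contact_interval_s: float = 0.4
    rest_min_s: float = 0.75
    rest_velocity_max: float = 1.33
    rest_cap_s: float = 300.0
    tarsal_zone_mm: float = 3.0
    landing_window_points: int = 65
    landing_contact_index: int = 51
    tortuosity_section_points: int = 40
    net_proximity_mm: float = 5.0
    oscillation_band_hz: tuple[float, float] = (2.0, 20.0)
    oscillation_min_amplitude_mm: float = 1.0
    turn_min_step_mm: float = 1.0
    accel_smooth_points: int = 3
    onset_rel_accel_min: float = 0.25
    rest_smooth_points: int = 5
    high_entry_expected_fraction: float = 0.36

    def __post_init__(self) -> None:
        numeric = (
            self.frame_rate, self.turn_angle_min, self.contact_interval_s,
            self.rest_min_s, self.rest_velocity_max, self.rest_cap_s,
            self.tarsal_zone_mm, self.landing_window_points,
            self.landing_contact_index, self.tortuosity_section_points,
            self.net_proximity_mm, self.oscillation_min_amplitude_mm,
            self.turn_min_step_mm, self.accel_smooth_points,
            self.onset_rel_accel_min, self.rest_smooth_points,
            self.high_entry_expected_fraction,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("all classifier thresholds must be strictly positive")
        lo, hi = self.oscillation_band_hz
        if not 0 < lo < hi < self.frame_rate / 2:
            raise ValueError("oscillation band must satisfy 0 < low < high < Nyquist")
        n = self.contact_interval_s * self.frame_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("contact_interval_s x frame_rate must be an integer")

    @property
    def contact_interval_frames(self) -> int:
        """Visiting/bouncing boundary expressed in frames (20 at defaults)."""
        return int(round(self.contact_interval_s * self.frame_rate))

    @property
    def landing_pre_points(self) -> int:
        """Points strictly before contact in the landing window (50)."""
        return self.landing_contact_index - 1

    @property
    def landing_post_points(self) -> int:
        """Points strictly after contact in the landing window (14)."""
        return self.landing_window_points - self.landing_contact_index


@dataclass(frozen=True)
class ArenaGeometry:
    """Field-of-view and bed-net box geometry, all lengths in mm.

    The recorded plane is a 2D side projection: ``x`` runs along the bed
    (host head at left, head-to-foot positive), ``y`` is vertical with the
    floor at 0.  The net box is a required configuration input: the source
    assay never published its dimensions, so the defaults here are plausible
    single-bed values, not measured constants.
    """

    fov_width_mm: float = 2400.0
    fov_height_mm: float = 1200.0
    blind_centre_width_mm: float = 100.0
    blind_side_width_mm: float = 50.0
    net_x0_mm: float = 300.0
    net_x1_mm: float = 2100.0
    net_roof_mm: float = 800.0
    net_depth_mm: float = 700.0
    net_floor_clearance_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.net_x0_mm < self.net_x1_mm <= self.fov_width_mm):
            raise ValueError("net box must fit inside the field of view (x)")
        if not (0 <= self.net_floor_clearance_mm < self.net_roof_mm <= self.fov_height_mm):
            raise ValueError("net box must fit inside the field of view (y)")

    @property
    def net_length_mm(self) -> float:
        return self.net_x1_mm - self.net_x0_mm

    @property
    def net_mid_x_mm(self) -> float:
        return 0.5 * (self.net_x0_mm + self.net_x1_mm)

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.fov_width_mm) & (y >= 0) & (y <= self.fov_height_mm)

    def in_net_silhouette(self, x, y) -> np.ndarray:
        """True where a 2D point projects onto the net box silhouette."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.net_x0_mm) & (x <= self.net_x1_mm)
            & (y >= self.net_floor_clearance_mm) & (y <= self.net_roof_mm)
        )

    def distance_to_net(self, x, y) -> np.ndarray:
        """Euclidean distance (mm) to the net surface polyline.

        The surface visible in the 2D projection is the roof line plus the
        head- and foot-end walls; points inside the silhouette are measured
        to the nearest of those boundaries (a mosquito there may be on a
        side-wall face, which projects onto the interior).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        segs = [
            ((self.net_x0_mm, self.net_roof_mm), (self.net_x1_mm, self.net_roof_mm)),
            ((self.net_x0_mm, self.net_floor_clearance_mm), (self.net_x0_mm, self.net_roof_mm)),
            ((self.net_x1_mm, self.net_floor_clearance_mm), (self.net_x1_mm, self.net_roof_mm)),
        ]
        d = np.full(np.broadcast(x, y).shape, np.inf, dtype=float)
        for (ax, ay), (bx, by) in segs:
            d = np.minimum(d, _point_segment_distance(x, y, ax, ay, bx, by))
        return d

    @property
    def entry_edge_high_fraction(self) -> float:
        """Fraction of the field-of-view entry edge lying above the net roof.

        The entry edge is the top edge plus both side edges (mosquitoes do
        not enter through the floor); the 'high' portion is the part of the
        top edge spanning the net.  Reported alongside the configured
        ``high_entry_expected_fraction``.
        """
        entry = self.fov_width_mm + 2 * self.fov_height_mm
        return self.net_length_mm / entry


def _point_segment_distance(x, y, ax, ay, bx, by) -> np.ndarray:
    vx, vy = bx - ax, by - ay
    L2 = vx * vx + vy * vy
    t = np.clip(((x - ax) * vx + (y - ay) * vy) / L2, 0.0, 1.0)
    return np.hypot(x - (ax + t * vx), y - (ay + t * vy))


def _from_mapping(cls, mapping: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    if "oscillation_band_hz" in kwargs:
        kwargs["oscillation_band_hz"] = tuple(kwargs["oscillation_band_hz"])
    return cls(**kwargs)


def load_config(path) -> tuple[ClassifierConfig, ArenaGeometry]:
    """Load a YAML file with optional ``classifier`` and ``geometry`` blocks."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    cfg = _from_mapping(ClassifierConfig, doc.get("classifier", {}) or {})
    geom = _from_mapping(ArenaGeometry, doc.get("geometry", {}) or {})
    return cfg, geom


def dump_config(cfg: ClassifierConfig, geom: ArenaGeometry, path) -> None:
    doc = {"classifier": asdict(cfg), "geometry": asdict(geom)}
    doc["classifier"]["oscillation_band_hz"] = list(cfg.oscillation_band_hz)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def config_hash(cfg: ClassifierConfig, geom: ArenaGeometry) -> str:
    """Stable hash of a configuration, for report provenance."""
    doc = {"classifier": asdict(cfg), "geometry": asdict(geom)}
    blob = json.dumps(doc, sort_keys=True, default=list).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
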