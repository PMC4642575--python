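"""The 16-region partition of the bed net and surrounding space.

Regions 1-10 are net surfaces: 1-6 six equal-length segments of the
horizontal roof (head to foot), 7 the vertical head-end wall, 8 and 9 the
side walls (which project onto the interior of the net silhouette in the
2D side view), 10 the foot-end wall.  Regions 11-14 are the surrounding
flight space (11 beyond the head end, 14 beyond the foot end, 12 and 13
the 'high' space above the net roof, split at the net midline).  Regions
15 and 16 record contact-free flight in front of the net silhouette, in
the left and right camera fields respectively.

Contacts are assigned to the nearest net surface (1-10); flight points map
to 11-16.  Per-region areas (m^2) scale raw activity seconds into
densities so regions of different size are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import ArenaGeometry, ClassifierConfig

__all__ = [
    "RegionMap", "assign_region", "activity_density",
    "first_contact_distribution", "classify_approach", "left_right_bias",
    "attribute_segments", "ROOF_REGIONS", "HIGH_REGIONS",
]

ROOF_REGIONS = (1, 2, 3, 4, 5, 6)
HIGH_REGIONS = (12, 13)

# default grouping for first-contact analysis with sparse counts
DEFAULT_REGION_GROUPS = {
    "roof": ROOF_REGIONS,
    "head_wall": (7,),
    "side_walls": (8, 9),
    "foot_wall": (10,),
}


@dataclass(frozen=True)
class RegionMap:
    """Region partition derived from an :class:`ArenaGeometry`."""

    geometry: ArenaGeometry

    @property
    def areas_m2(self) -> dict[int, float]:
        g = self.geometry
        h_net = g.net_roof_mm - g.net_floor_clearance_mm
        seg = g.net_length_mm / 6.0
        mm2 = 1e-6
        areas = {}
        for r in ROOF_REGIONS:
            areas[r] = seg * g.net_depth_mm * mm2
        areas[7] = g.net_depth_mm * h_net * mm2
        areas[8] = g.net_length_mm * h_net * mm2
        areas[9] = g.net_length_mm * h_net * mm2
        areas[10] = g.net_depth_mm * h_net * mm2
        areas[11] = g.net_x0_mm * g.fov_height_mm * mm2
        above = g.fov_height_mm - g.net_roof_mm
        areas[12] = 0.5 * g.net_length_mm * above * mm2
        areas[13] = 0.5 * g.net_length_mm * above * mm2
        areas[14] = (g.fov_width_mm - g.net_x1_mm) * g.fov_height_mm * mm2
        areas[15] = 0.5 * g.net_length_mm * h_net * mm2
        areas[16] = 0.5 * g.net_length_mm * h_net * mm2
        if any(a <= 0 for a in areas.values()):
            raise ValueError("all region areas must be positive")
        return areas

    def roof_segment_of(self, x: float) -> int:
        g = self.geometry
        seg = g.net_length_mm / 6.0
        # boundary points assign to the lower-numbered region
        i = int(np.floor((np.clip(x, g.net_x0_mm, g.net_x1_mm) - g.net_x0_mm)
                         / seg - 1e-12))
        return 1 + int(np.clip(i, 0, 5))

    def assign_contact(self, x: float, y: float,
                       proximity_mm: float = 5.0) -> int:
        """Nearest net-surface region (1-10) for a contact position.

        Points deep inside the net silhouette (further than ``proximity_mm``
        from the roof or end walls) are on a side-wall face: region 8 (left
        camera field) or 9 (right).  Equidistant boundary points take the
        lower-numbered region.
        """
        g = self.geometry
        if not g.contains(x, y):
            raise ValueError(f"position ({x}, {y}) outside the field of view")
        d_roof = abs(y - g.net_roof_mm) if g.net_x0_mm <= x <= g.net_x1_mm \
            else float(np.hypot(x - np.clip(x, g.net_x0_mm, g.net_x1_mm),
                                y - g.net_roof_mm))
        d_head = float(np.hypot(x - g.net_x0_mm,
                                y - np.clip(y, g.net_floor_clearance_mm, g.net_roof_mm)))
        d_foot = float(np.hypot(x - g.net_x1_mm,
                                y - np.clip(y, g.net_floor_clearance_mm, g.net_roof_mm)))
        dmin = min(d_roof, d_head, d_foot)
        if g.in_net_silhouette(x, y) and dmin > proximity_mm:
            return 8 if x <= 0.5 * g.fov_width_mm else 9
        if d_roof <= d_head and d_roof <= d_foot:
            return self.roof_segment_of(x)
        if d_head <= d_foot:
            return 7
        return 10

    def assign_flight(self, x: float, y: float) -> int:
        """Flight-space region (11-16) for a non-contact position."""
        g = self.geometry
        if not g.contains(x, y):
            raise ValueError(f"position ({x}, {y}) outside the field of view")
        mid = 0.5 * g.fov_width_mm
        if x < g.net_x0_mm:
            return 11
        if x > g.net_x1_mm:
            return 14
        if y > g.net_roof_mm:
            return 12 if x <= g.net_mid_x_mm else 13
        return 15 if x <= mid else 16

    def assign_flight_array(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        g = self.geometry
        out = np.full(len(x), 15, dtype=int)
        out[np.asarray(x) > 0.5 * g.fov_width_mm] = 16
        above = np.asarray(y) > g.net_roof_mm
        out[above & (np.asarray(x) <= g.net_mid_x_mm)] = 12
        out[above & (np.asarray(x) > g.net_mid_x_mm)] = 13
        out[np.asarray(x) < g.net_x0_mm] = 11
        out[np.asarray(x) > g.net_x1_mm] = 14
        return out


def assign_region(position: tuple[float, float], kind: str,
                  region_map: RegionMap,
                  proximity_mm: float = 5.0) -> int:
    """Assign a position to its region: ``kind='contact'`` -> 1-10,
    ``kind='flight'`` -> 11-16."""
    x, y = position
    if kind == "contact":
        return region_map.assign_contact(x, y, proximity_mm)
    if kind == "flight":
        return region_map.assign_flight(x, y)
    raise ValueError(f"unknown kind {kind!r}")


def attribute_segments(test, segments_by_track: dict, contacts_by_track: dict,
                       rest_by_track: dict, region_map: RegionMap,
                       config: ClassifierConfig) -> dict[int, float]:
    """Per-region activity seconds for one test (conserves total activity).

    Swooping segments are attributed frame by frame to the flight regions
    (11-16); contact-mode segments split their duration equally over the
    net-surface regions of their contacts.
    """
    seconds: dict[int, float] = {r: 0.0 for r in range(1, 17)}
    tracks = {tr.track_id: tr for tr in test.tracks}
    for track_id, segments in segments_by_track.items():
        tr = tracks[track_id]
        contacts = contacts_by_track.get(track_id, [])
        for seg in segments:
            if seg.duration_s <= 0:
                continue
            if seg.mode == "swooping":
                sel = (tr.frames >= seg.start_frame) & (tr.frames < seg.end_frame)
                regs = region_map.assign_flight_array(tr.x[sel], tr.y[sel])
                ids, counts = np.unique(regs, return_counts=True)
                scale = seg.duration_s / counts.sum()
                for r, c in zip(ids, counts):
                    seconds[int(r)] += float(c) * scale
            else:
                evs = [e for e in contacts
                       if seg.start_frame <= e.frame <= seg.end_frame]
                if not evs:
                    # contact-mode time with no located contact: nearest surface
                    sel = (tr.frames >= seg.start_frame) & (tr.frames <= seg.end_frame)
                    cx, cy = float(np.mean(tr.x[sel])), float(np.mean(tr.y[sel]))
                    evs = [type("E", (), {"x": cx, "y": cy})]
                regs = [region_map.assign_contact(e.x, e.y, config.net_proximity_mm)
                        for e in evs]
                for r in regs:
                    seconds[r] += seg.duration_s / len(regs)
    return seconds


def activity_density(test, seconds_by_region: dict[int, float],
                     region_map: RegionMap) -> dict[int, dict]:
    """Raw seconds and area-scaled density (s/m^2) per region."""
    areas = region_map.areas_m2
    return {
        r: {"seconds": seconds_by_region.get(r, 0.0),
            "seconds_per_m2": seconds_by_region.get(r, 0.0) / areas[r]}
        for r in sorted(areas)
    }


def first_contact_distribution(test, contacts_by_track: dict,
                               region_map: RegionMap,
                               config: ClassifierConfig,
                               window_s: float = 600.0,
                               groups: dict | None = None) -> dict:
    """Counts of first net contacts per region within the opening window.

    Each track contributes at most one count (its first contact), only if
    that contact falls within ``window_s`` of the test start.  The roof
    share (regions 1-6 combined) is reported; an optional grouping map
    pools regions for sparse-count analyses.
    """
    counts: dict[int, int] = {}
    for track_id, events in contacts_by_track.items():
        if not events:
            continue
        first = min(events, key=lambda e: e.frame)
        if first.t > window_s:
            continue
        r = region_map.assign_contact(first.x, first.y, config.net_proximity_mm)
        counts[r] = counts.get(r, 0) + 1
    total = sum(counts.values())
    roof = sum(counts.get(r, 0) for r in ROOF_REGIONS)
    out = {
        "counts": counts,
        "n_first_contacts": total,
        "roof_share": (roof / total) if total else None,
    }
    groups = groups or DEFAULT_REGION_GROUPS
    out["grouped_counts"] = {
        name: sum(counts.get(r, 0) for r in rs) for name, rs in groups.items()
    }
    return out


def classify_approach(track, region_map: RegionMap,
                      config: ClassifierConfig) -> str:
    """Class a track's first appearance as ``high``/``low``/``discarded``.

    Tracks first appearing on the net surface (within the contact proximity
    gate) are likely fragments of interrupted tracks and are discarded.
    High means first appearing in the space above the net roof (regions
    12/13).
    """
    x, y = float(track.x[0]), float(track.y[0])
    g = region_map.geometry
    if float(g.distance_to_net(x, y)) <= config.net_proximity_mm:
        return "discarded"
    if region_map.assign_flight(x, y) in HIGH_REGIONS:
        return "high"
    return "low"


def high_approach_test(per_test_high_fractions, expected: float) -> dict:
    """One-sample two-tailed t-test of per-test high-entry fractions against
    the expected fraction under spatially uniform entry."""
    vals = np.asarray(list(per_test_high_fractions), dtype=float)
    out = {"mean_fraction": float(vals.mean()), "expected": expected,
           "n_tests": len(vals)}
    if len(vals) >= 2 and np.std(vals) > 0:
        t, p = stats.ttest_1samp(vals, expected)
        out.update(t=float(t), p=float(p))
    else:
        out.update(t=None, p=None)
    return out


def left_right_bias(test) -> dict:
    """Camera-field activity split and a two-sided test against 50:50.

    Each track contributes its fraction of points in the left half of the
    field of view; the test is a one-sample t-test of those fractions
    against 0.5.
    """
    mid = 0.5 * test.geometry.fov_width_mm
    fracs = np.array([float(np.mean(tr.x < mid)) for tr in test.tracks])
    weights = np.array([tr.duration_s for tr in test.tracks])
    split = float(np.average(fracs, weights=weights)) if len(fracs) else None
    out = {"left_fraction": split, "n_tracks": len(fracs)}
    if len(fracs) >= 2 and np.std(fracs) > 0:
        t, p = stats.ttest_1samp(fracs, 0.5)
        out.update(t=float(t), p=float(p), significant=bool(p < 0.05))
    else:
        out.update(t=None, p=None, significant=None)
    return out
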