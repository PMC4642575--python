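"""Spatial region map: assignment, densities, approaches, bias tests."""

import numpy as np
import pytest

from netflight.config import ArenaGeometry, ClassifierConfig
from netflight.contacts import detect_contacts
from netflight.model import TestRecord
from netflight.modes import segment_track
from netflight.regions import (RegionMap, activity_density, assign_region,
                               attribute_segments, classify_approach,
                               first_contact_distribution, high_approach_test,
                               left_right_bias)

from conftest import make_track

GEOM = ArenaGeometry()
ROOF, X0, X1 = GEOM.net_roof_mm, GEOM.net_x0_mm, GEOM.net_x1_mm


class TestAssignment:
    def test_roof_centre_splits_by_x(self, region_map):
        seg = GEOM.net_length_mm / 6
        # middle of sextants 3 and 4
        assert region_map.assign_contact(X0 + 2.5 * seg, ROOF) == 3
        assert region_map.assign_contact(X0 + 3.5 * seg, ROOF) == 4

    def test_boundary_assigns_lower_region(self, region_map):
        seg = GEOM.net_length_mm / 6
        assert region_map.assign_contact(X0 + seg, ROOF) == 1
        assert region_map.assign_contact(X0 + 2 * seg, ROOF) == 2

    def test_end_walls(self, region_map):
        assert region_map.assign_contact(X0, ROOF / 2) == 7
        assert region_map.assign_contact(X1, ROOF / 2) == 10

    def test_deep_silhouette_is_side_wall(self, region_map):
        assert region_map.assign_contact(900.0, 400.0) == 8
        assert region_map.assign_contact(1500.0, 400.0) == 9

    def test_flight_regions(self, region_map):
        assert assign_region((900.0, 400.0), "flight", region_map) == 15
        assert assign_region((1500.0, 400.0), "flight", region_map) == 16
        assert assign_region((900.0, ROOF + 100), "flight", region_map) == 12
        assert assign_region((1500.0, ROOF + 100), "flight", region_map) == 13
        assert assign_region((100.0, 600.0), "flight", region_map) == 11
        assert assign_region((2300.0, 600.0), "flight", region_map) == 14

    def test_outside_fov_raises(self, region_map):
        with pytest.raises(ValueError, match="outside the field of view"):
            region_map.assign_flight(-5.0, 100.0)

    def test_areas_positive_and_roof_tiles_net(self, region_map):
        areas = region_map.areas_m2
        assert len(areas) == 16 and all(a > 0 for a in areas.values())
        roof_total = sum(areas[r] for r in range(1, 7))
        expected = GEOM.net_length_mm * GEOM.net_depth_mm * 1e-6
        assert roof_total == pytest.approx(expected)


class TestDensity:
    def test_density_scales_with_area(self, region_map):
        test = TestRecord(test_id="x")
        out = activity_density(test, {12: 10.0}, region_map)
        area = region_map.areas_m2[12]
        assert out[12]["seconds_per_m2"] == pytest.approx(10.0 / area)
        # doubling the area (halving the net length halves region 12's area)
        assert out[12]["seconds"] == 10.0

    def test_conservation_on_synthetic_test(self, small_test, config, region_map):
        test, _ = small_test
        segments_by_track, contacts_by_track, rest_by_track = {}, {}, {}
        for tr in test.tracks:
            contacts, rests = detect_contacts(tr, config, test.geometry)
            contacts_by_track[tr.track_id] = contacts
            rest_by_track[tr.track_id] = rests
            segments_by_track[tr.track_id] = segment_track(tr, contacts, rests,
                                                           config)
        seconds = attribute_segments(test, segments_by_track, contacts_by_track,
                                     rest_by_track, region_map, config)
        total_segments = sum(s.duration_s
                             for segs in segments_by_track.values()
                             for s in segs)
        assert sum(seconds.values()) == pytest.approx(total_segments, rel=1e-9)


class TestFirstContacts:
    def test_track_counted_once_at_first_contact(self, config, region_map):
        from netflight.contacts import ContactEvent
        test = TestRecord(test_id="x")
        events = {"t0": [
            ContactEvent("t0", 1500, 30.0, 900.0, ROOF, "turn"),
            ContactEvent("t0", 4500, 90.0, X1, 400.0, "turn"),
        ]}
        out = first_contact_distribution(test, events, region_map, config)
        assert out["n_first_contacts"] == 1
        assert out["roof_share"] == 1.0

    def test_contact_outside_window_not_counted(self, config, region_map):
        from netflight.contacts import ContactEvent
        test = TestRecord(test_id="x")
        events = {"t0": [ContactEvent("t0", 35000, 700.0, 900.0, ROOF, "turn")]}
        out = first_contact_distribution(test, events, region_map, config)
        assert out["n_first_contacts"] == 0
        assert out["roof_share"] is None

    def test_roof_bias_recovered(self, config, geometry, region_map):
        """With roof-biased contact placement the first-contact roof share
        approaches the programmed bias."""
        from netflight.simulate import GenerationParams, generate_test
        shares, biases = [], 0.6
        for seed in range(3):
            params = GenerationParams(seed=seed, net_type="untreated",
                                      duration_s=600.0, tracks_per_bin=20.0,
                                      roof_bias=biases)
            test, truth = generate_test(params, config, geometry)
            firsts = {}
            for c in truth.contacts:
                firsts.setdefault(c.track_id, c)
            n = len(firsts)
            roof = sum(1 for c in firsts.values() if c.region_id <= 6)
            shares.append(roof / n)
        assert np.mean(shares) == pytest.approx(biases, abs=0.12)


class TestApproach:
    def test_high_low_discarded(self, config, region_map):
        high = make_track([1000, 1010], [ROOF + 200, ROOF + 200])
        low = make_track([100, 110], [300, 300])
        on_net = make_track([900, 910], [ROOF + 1, ROOF + 1])
        assert classify_approach(high, region_map, config) == "high"
        assert classify_approach(low, region_map, config) == "low"
        assert classify_approach(on_net, region_map, config) == "discarded"

    def test_entry_edge_fraction_from_geometry(self, geometry):
        entry = geometry.fov_width_mm + 2 * geometry.fov_height_mm
        assert geometry.entry_edge_high_fraction == pytest.approx(
            geometry.net_length_mm / entry)

    def test_uniform_entry_matches_geometry_fraction(self, config, geometry,
                                                     region_map):
        """Entry points sampled uniformly on the entry edge give a high
        fraction near the geometry-derived edge fraction."""
        from netflight.simulate import _entry_point
        rng = np.random.default_rng(0)
        n, high = 4000, 0
        for _ in range(n):
            pos, _h = _entry_point(rng, geometry)
            tr = make_track([pos[0], pos[0] + 1], [pos[1], pos[1]])
            if classify_approach(tr, region_map, config) == "high":
                high += 1
        expected = geometry.entry_edge_high_fraction
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(high / n - expected) < 4 * se

    def test_high_approach_t_test(self):
        out = high_approach_test([0.40, 0.35, 0.38, 0.33], expected=0.36)
        assert out["p"] > 0.05
        out2 = high_approach_test([0.60, 0.62, 0.61, 0.63], expected=0.36)
        assert out2["p"] < 0.01


class TestLeftRight:
    def test_all_left_test(self):
        tracks = [make_track(np.linspace(100, 400, 60), np.full(60, 600.0),
                             track_id=f"t{i}") for i in range(3)]
        test = TestRecord(test_id="test0", tracks=tracks)
        out = left_right_bias(test)
        assert out["left_fraction"] == pytest.approx(1.0)

    def test_even_split_not_significant(self):
        rng = np.random.default_rng(5)
        tracks = []
        for i in range(40):
            x = 1200 + rng.normal(0, 400, 80).cumsum() * 0.1 \
                + rng.uniform(-600, 600)
            tracks.append(make_track(np.clip(x, 0, 2400), np.full(80, 600.0),
                                     track_id=f"t{i}"))
        out = left_right_bias(TestRecord(test_id="test0", tracks=tracks))
        assert out["p"] > 0.05
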