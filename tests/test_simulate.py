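"""Synthetic test generator: determinism, ground-truth invariants, decay."""

import numpy as np
import pytest
from scipy import stats

from netflight.simulate import (GenerationParams, generate_landing_track,
                                generate_test)


def _small(seed=0, **kw):
    kw.setdefault("net_type", "untreated")
    kw.setdefault("duration_s", 600.0)
    kw.setdefault("tracks_per_bin", 10.0)
    return GenerationParams(seed=seed, **kw)


class TestDeterminism:
    def test_same_seed_identical_output(self, config, geometry):
        a, _ = generate_test(_small(3), config, geometry)
        b, _ = generate_test(_small(3), config, geometry)
        assert a.n_tracks == b.n_tracks
        for ta, tb in zip(a.tracks, b.tracks):
            assert np.array_equal(ta.frames, tb.frames)
            assert np.array_equal(ta.x, tb.x)
            assert np.array_equal(ta.y, tb.y)

    def test_different_seeds_differ(self, config, geometry):
        a, _ = generate_test(_small(3), config, geometry)
        b, _ = generate_test(_small(4), config, geometry)
        assert any(not np.array_equal(ta.x, tb.x)
                   for ta, tb in zip(a.tracks, b.tracks))


class TestGroundTruth:
    def test_labels_cover_every_frame(self, small_test):
        test, truth = small_test
        for tr in test.tracks:
            lab = truth.labels[tr.track_id]
            assert len(lab) == len(tr)
            assert set(np.unique(lab)) <= {"swooping", "visiting",
                                           "bouncing", "resting"}

    def test_mode_durations_sum_to_track_durations(self, small_test):
        test, truth = small_test
        total_label_s = sum(len(lab) for lab in truth.labels.values()) / 50.0
        total_track_s = sum(len(tr) for tr in test.tracks) / 50.0
        assert total_label_s == pytest.approx(total_track_s)

    def test_contacts_lie_on_net_surface(self, small_test, geometry):
        _, truth = small_test
        assert truth.contacts
        for c in truth.contacts:
            assert float(geometry.distance_to_net(c.x, c.y)) < 1e-6
            assert 1 <= c.region_id <= 10

    def test_resting_never_exceeds_cap(self, config, geometry):
        params = _small(9, mode_mix=(0.0, 0.0, 0.0, 1.0), duration_s=1200.0,
                        tracks_per_bin=3.0)
        test, truth = generate_test(params, config, geometry)
        for lab in truth.labels.values():
            rest = np.flatnonzero(lab == "resting")
            if len(rest):
                # each resting stretch is one event; all below the 300 s cap
                runs = np.split(rest, np.flatnonzero(np.diff(rest) > 1) + 1)
                for r in runs:
                    assert len(r) / 50.0 <= config.rest_cap_s

    def test_pure_swooping_has_no_contacts(self, config, geometry):
        params = _small(5, mode_mix=(1.0, 0.0, 0.0, 0.0))
        test, truth = generate_test(params, config, geometry)
        assert truth.contacts == []
        assert all(np.all(lab == "swooping")
                   for lab in truth.labels.values())

    def test_swooping_keeps_clear_of_net(self, config, geometry):
        params = _small(6, mode_mix=(1.0, 0.0, 0.0, 0.0), jitter_sd_mm=0.0)
        test, _ = generate_test(params, config, geometry)
        for tr in test.tracks:
            assert np.min(geometry.distance_to_net(tr.x, tr.y)) > \
                config.net_proximity_mm

    def test_mode_mix_realised(self, config, geometry):
        """The programmed activity mix is realised within a few points."""
        mix = (0.6, 0.2, 0.15, 0.05)
        params = _small(8, mode_mix=mix, duration_s=1200.0,
                        tracks_per_bin=25.0)
        _, truth = generate_test(params, config, geometry)
        total = sum(truth.mode_seconds.values())
        for m, target in zip(("swooping", "visiting", "bouncing", "resting"),
                             mix):
            assert truth.mode_seconds[m] / total == pytest.approx(target,
                                                                  abs=0.05)

    def test_truth_roundtrips_through_json(self, small_test, tmp_path):
        from netflight.simulate import GroundTruth
        _, truth = small_test
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back.decay_k == truth.decay_k
        assert len(back.contacts) == len(truth.contacts)
        tid = next(iter(truth.labels))
        assert np.array_equal(back.labels[tid], truth.labels[tid])


class TestActivityDecay:
    def test_zero_k_no_monotone_trend(self, config, geometry):
        """With decay_k = 0 the per-bin track counts show no trend: the
        regression slope CI covers 0 across seeds."""
        slopes = []
        for seed in range(8):
            params = GenerationParams(seed=seed, net_type="untreated",
                                      duration_s=3600.0, tracks_per_bin=6.0,
                                      decay_k=0.0)
            _, truth = generate_test(params, config, geometry)
            res = stats.linregress(np.arange(12), truth.bin_counts)
            slopes.append(res.slope)
        lo = np.mean(slopes) - 2.5 * stats.sem(slopes)
        hi = np.mean(slopes) + 2.5 * stats.sem(slopes)
        assert lo < 0 < hi

    def test_positive_k_decays_bin_counts(self, config, geometry):
        params = _small(11, net_type="llin", duration_s=3600.0,
                        tracks_per_bin=60.0, decay_k=0.15)
        _, truth = generate_test(params, config, geometry)
        first, last = truth.bin_counts[:3].sum(), truth.bin_counts[-3:].sum()
        assert last < first / 4

    def test_mean_swooping_speed_converges(self, config, geometry):
        from netflight.kinematics import instantaneous_velocity
        speeds = []
        for seed in range(4):
            params = _small(seed, mode_mix=(1.0, 0, 0, 0), jitter_sd_mm=0.0,
                            tracks_per_bin=8.0)
            test, _ = generate_test(params, config, geometry)
            for tr in test.tracks:
                speeds.append(float(np.mean(instantaneous_velocity(tr))))
        assert np.mean(speeds) == pytest.approx(355.8, abs=10.0)


class TestLandingTrackGenerator:
    def test_param_validation(self):
        with pytest.raises(ValueError):
            generate_landing_track(-5.0, 10.0, seed=0)
        with pytest.raises(ValueError):
            generate_landing_track(300.0, -1.0, seed=0)

    def test_enough_precontact_points(self, config):
        for seed in range(5):
            tr, truth = generate_landing_track(350.0, 40.0, seed=seed)
            assert truth["contact_index"] >= config.landing_contact_index - 1
            assert len(tr) > truth["contact_index"] + config.landing_post_points

    def test_zero_decel_constant_speed(self):
        tr, truth = generate_landing_track(300.0, 0.0, seed=1)
        steps = tr.displacements()[:truth["contact_index"]]
        assert np.allclose(steps * 50.0, 300.0, atol=1e-6)

    def test_contact_lands_on_roof(self, geometry):
        tr, truth = generate_landing_track(350.0, 40.0, seed=2)
        i = truth["contact_index"]
        assert tr.y[i] == pytest.approx(geometry.net_roof_mm)
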