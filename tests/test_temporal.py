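"""Binned activity, decay fitting, contact bounds, summary statistics."""

import numpy as np
import pytest
from scipy import stats

from netflight.model import TestRecord
from netflight.modes import ModeSegment
from netflight.temporal import (ActivityBins, bin_activity, compare_decay,
                                contact_time_bounds, contact_time_s,
                                fit_decay, geometric_mean_ci,
                                max_simultaneous_contacts, max_total_activity)

from conftest import make_track


def _seg(start_s, end_s, mode="visiting", n_contacts=0):
    a, b = int(start_s * 50), int(end_s * 50)
    return ModeSegment("t0", mode, a, b, (b - a) / 50.0, n_contacts)


def _test(duration=3600.0):
    tr = make_track([0, 1], [100, 100])
    return TestRecord(test_id="test0", tracks=[tr], duration_s=duration)


class TestBinning:
    def test_single_segment_one_bin(self):
        bins = bin_activity(_test(), [_seg(100, 110)])
        assert bins.values[0] == pytest.approx(10.0)
        assert bins.values[1:].sum() == 0

    def test_segment_split_across_edge(self):
        bins = bin_activity(_test(), [_seg(295, 305)])
        assert bins.values[0] == pytest.approx(5.0)
        assert bins.values[1] == pytest.approx(5.0)

    def test_conservation(self):
        rng = np.random.default_rng(1)
        durs = rng.uniform(0.2, 80, 100)
        segs = [_seg(a, a + d) for a, d in
                zip(rng.uniform(0, 3600 - durs), durs)]
        bins = bin_activity(_test(), segs)
        assert bins.total == pytest.approx(sum(s.duration_s for s in segs))

    def test_mode_filter(self):
        segs = [_seg(10, 20, "swooping"), _seg(30, 45, "bouncing")]
        assert bin_activity(_test(), segs, mode="bouncing").total == \
            pytest.approx(15.0)


class TestDecayFit:
    def test_noiseless_recovery_to_three_decimals(self):
        t = (np.arange(12) + 0.5) * 5.0
        bins = ActivityBins(300.0, 200.0 * np.exp(-0.1 * t))
        fit = fit_decay(bins)
        assert fit.converged
        assert fit.k == pytest.approx(0.1, abs=5e-4)
        assert fit.A0 == pytest.approx(200.0, rel=1e-3)

    def test_constant_bins_give_zero_k(self):
        fit = fit_decay(ActivityBins(300.0, np.full(12, 80.0)))
        assert fit.k == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_bins_degenerate(self):
        fit = fit_decay(ActivityBins(300.0, np.zeros(12)))
        assert fit.degenerate and not fit.converged

    def test_poisson_noise_median_recovery(self):
        t = (np.arange(12) + 0.5) * 5.0
        rng = np.random.default_rng(7)
        ks = []
        for _ in range(60):
            y = rng.poisson(200.0 * np.exp(-0.1 * t))
            ks.append(fit_decay(ActivityBins(300.0, y.astype(float))).k)
        assert np.median(ks) == pytest.approx(0.1, rel=0.1)


class TestCompareDecay:
    def _fits(self, k, n, rng):
        t = (np.arange(12) + 0.5) * 5.0
        out = []
        for _ in range(n):
            y = rng.poisson(200.0 * np.exp(-k * t)).astype(float)
            out.append(fit_decay(ActivityBins(300.0, y)))
        return out

    def test_identical_groups_not_separated(self):
        rng = np.random.default_rng(3)
        out = compare_decay(self._fits(0.1, 10, rng), self._fits(0.1, 10, rng))
        ci_lo = out["k_mean_a"] - out["k_mean_b"]
        assert out["p"] > 0.001  # no systematic difference

    def test_distinct_groups_detected(self):
        rng = np.random.default_rng(4)
        detected = 0
        for _ in range(20):
            out = compare_decay(self._fits(0.0, 10, rng),
                                self._fits(0.2, 10, rng))
            detected += out["significant"]
        assert detected >= 19

    def test_ci_width_shrinks_with_more_tests(self):
        rng = np.random.default_rng(5)
        small = compare_decay(self._fits(0.1, 5, rng), self._fits(0.1, 5, rng))
        big = compare_decay(self._fits(0.1, 40, rng), self._fits(0.1, 40, rng))
        w = lambda ci: ci[1] - ci[0]
        assert w(big["k_ci_a"]) < w(small["k_ci_a"])

    def test_bin_overlap_flags(self):
        rng = np.random.default_rng(6)
        t = (np.arange(12) + 0.5) * 5.0
        ba = [ActivityBins(300.0, rng.poisson(200 * np.exp(-0.0 * t)).astype(float))
              for _ in range(10)]
        bb = [ActivityBins(300.0, rng.poisson(200 * np.exp(-0.3 * t)).astype(float))
              for _ in range(10)]
        out = compare_decay(self._fits(0.0, 10, rng), self._fits(0.3, 10, rng),
                            ba, bb)
        assert any(out["bin_ci_separated"])


class TestContactBounds:
    def test_stated_arithmetic(self):
        b = contact_time_bounds(100.0, 4, 60, n_released=25)
        assert b.max_per_mosquito_s == pytest.approx(25.0)
        assert b.min_per_mosquito_s == pytest.approx(4.0)

    def test_first_ten_minute_substitution(self):
        b = contact_time_bounds(50.0, 2, 10, n_released=25, first_ten_min=True)
        assert b.min_per_mosquito_s == pytest.approx(5.0)
        assert b.max_per_mosquito_s == pytest.approx(25.0)

    def test_identities_hold(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            total = float(rng.uniform(1, 2000))
            m = int(rng.integers(1, 12))
            ntraj = int(rng.integers(1, 600))
            b = contact_time_bounds(total, m, ntraj)
            assert b.min_per_mosquito_s <= b.max_per_mosquito_s + 1e-9
            assert b.max_per_mosquito_s * m == pytest.approx(total)

    def test_inconsistent_input_raises(self):
        with pytest.raises(ValueError, match="zero simultaneous"):
            contact_time_bounds(10.0, 0, 5)

    def test_max_simultaneous_sweep(self):
        segs = {
            "a": [_seg(0, 10, "bouncing")],
            "b": [_seg(5, 15, "resting")],
            "c": [_seg(20, 30, "bouncing")],
            "d": [_seg(0, 50, "swooping")],  # no contact: not counted
        }
        assert max_simultaneous_contacts(segs) == 2

    def test_contact_time_from_segments(self):
        segs = [_seg(0, 10, "bouncing"), _seg(20, 25, "resting"),
                _seg(30, 60, "visiting", n_contacts=5)]
        assert contact_time_s(segs, 50.0) == pytest.approx(15.0 + 5 / 50.0)


class TestSummaryStats:
    def test_geometric_mean_constant(self):
        gm, ci = geometric_mean_ci([7.0, 7.0, 7.0])
        assert gm == pytest.approx(7.0)
        assert ci == (pytest.approx(7.0), pytest.approx(7.0))

    def test_geometric_mean_two_values(self):
        gm, _ = geometric_mean_ci([1.0, 100.0])
        assert gm == pytest.approx(10.0)

    def test_matches_log_domain_oracle(self):
        rng = np.random.default_rng(9)
        v = rng.lognormal(1.0, 0.8, 15)
        gm, (lo, hi) = geometric_mean_ci(v)
        logs = np.log(v)
        se = logs.std(ddof=1) / np.sqrt(len(v))
        q = stats.t.ppf(0.975, len(v) - 1)
        assert gm == pytest.approx(np.exp(logs.mean()))
        assert lo == pytest.approx(np.exp(logs.mean() - q * se))
        assert hi == pytest.approx(np.exp(logs.mean() + q * se))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            geometric_mean_ci([1.0, 0.0])

    def test_activity_ceiling(self):
        assert max_total_activity(25, 1.0) == 25.0
        assert max_total_activity(1, 1.0) == 1.0
        with pytest.raises(ValueError):
            max_total_activity(0, 1.0)
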