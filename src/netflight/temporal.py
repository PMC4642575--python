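"""Time-binned activity, exponential decay fitting and summary statistics.

Activity over a 60-minute test is grouped into 12 five-minute bins and
fitted to an exponential decay A(t) = A0 * exp(-k t) (t in minutes) by
nonlinear least squares; the decay constant k measures how quickly host
seeking collapses (k ~ 0 at untreated nets, k > 0 at insecticide-treated
nets).  Nonlinear fitting is used rather than a log-linear regression
because insecticidal arms produce empty late bins by design.

Per-mosquito net-contact time cannot be observed directly (individuals
cannot be followed between flights), so it is bracketed: the maximum
assumes only the largest simultaneously-observed cohort was responding,
the minimum assumes all released mosquitoes were.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ActivityBins", "DecayFit", "ContactTimeBounds",
    "bin_activity", "bin_track_counts", "fit_decay", "compare_decay",
    "contact_time_bounds", "geometric_mean_ci", "max_total_activity",
    "max_simultaneous_contacts", "contact_time_s",
]

CONTACT_MODES = ("visiting", "bouncing", "resting")


@dataclass
class ActivityBins:
    """Per-bin activity over a test (half-open bins covering [0, duration))."""

    bin_s: float
    values: np.ndarray  # seconds of activity (or track counts) per bin
    mode: str | None = None  # None = all modes

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def midpoints_min(self) -> np.ndarray:
        edges = np.arange(self.n_bins) * self.bin_s
        return (edges + 0.5 * self.bin_s) / 60.0

    @property
    def total(self) -> float:
        return float(np.sum(self.values))


@dataclass
class DecayFit:
    """Fitted exponential activity decay A(t) = A0 * exp(-k t), t in min."""

    A0: float
    k: float
    residuals: np.ndarray
    converged: bool
    degenerate: bool = False


@dataclass(frozen=True)
class ContactTimeBounds:
    """Per-mosquito net-contact time bracket for one test."""

    total_contact_s: float
    max_simultaneous: int
    n_trajectories: int
    n_released: int
    min_per_mosquito_s: float
    max_per_mosquito_s: float


def bin_activity(test, segments, bin_s: float = 300.0,
                 mode: str | None = None) -> ActivityBins:
    """Bin segmented activity seconds; segments spanning a bin edge are
    split proportionally, so the bins conserve total activity exactly."""
    n_bins = int(np.ceil(test.duration_s / bin_s))
    vals = np.zeros(n_bins)
    fr = test.tracks[0].frame_rate if test.tracks else 50.0
    for seg in segments:
        if mode is not None and seg.mode != mode:
            continue
        t0 = seg.start_frame / fr
        t1 = seg.end_frame / fr
        b = int(t0 // bin_s)
        while t0 < t1 - 1e-12 and b < n_bins:
            edge = (b + 1) * bin_s
            vals[b] += min(t1, edge) - t0
            t0 = edge
            b += 1
    return ActivityBins(bin_s=bin_s, values=vals, mode=mode)


def bin_track_counts(test, bin_s: float = 300.0) -> ActivityBins:
    """Per-bin counts of tracks by first appearance time."""
    n_bins = int(np.ceil(test.duration_s / bin_s))
    vals = np.zeros(n_bins)
    for tr in test.tracks:
        b = min(int(tr.t[0] // bin_s), n_bins - 1)
        vals[b] += 1
    return ActivityBins(bin_s=bin_s, values=vals, mode="track_counts")


def fit_decay(bins: ActivityBins) -> DecayFit:
    """Fit A(t) = A0 * exp(-k t) to bin values at bin midpoints (minutes).

    Initialisation is deterministic: A0 from the first bin, k from the
    first/last nonzero bin ratio.  All-zero bins give a degenerate flagged
    fit.
    """
    y = np.asarray(bins.values, dtype=float)
    t = bins.midpoints_min
    nz = np.flatnonzero(y > 0)
    if len(nz) == 0 or len(y) < 3:
        # nothing to fit: all-empty bins, or fewer than 3 bins
        return DecayFit(A0=float(y[0]) if len(y) else 0.0, k=0.0,
                        residuals=np.zeros_like(y),
                        converged=False, degenerate=True)
    a0 = max(y[0], y[nz[0]])
    if len(nz) >= 2 and y[nz[-1]] < y[nz[0]]:
        k0 = np.log(y[nz[0]] / y[nz[-1]]) / (t[nz[-1]] - t[nz[0]])
    else:
        k0 = 0.0
    model = lambda tt, A0, k: A0 * np.exp(-k * tt)
    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=[a0, k0], maxfev=5000)
        converged = True
    except RuntimeError:
        popt, converged = (a0, k0), False
    A0, k = float(popt[0]), float(popt[1])
    return DecayFit(A0=A0, k=k, residuals=y - model(t, A0, k),
                    converged=converged)


def compare_decay(fits_a: list[DecayFit], fits_b: list[DecayFit],
                  bins_a: list[ActivityBins] | None = None,
                  bins_b: list[ActivityBins] | None = None,
                  alpha: float = 0.05) -> dict:
    """Compare decay constants between two groups of tests.

    Degenerate fits are excluded (with a warning flag).  Returns group
    means of k with t-distribution CIs, a two-sided Welch t-test, and —
    when per-test bins are supplied — per-bin CI overlap flags marking the
    intervals where the groups' mean activity separates.
    """
    ka = np.array([f.k for f in fits_a if not f.degenerate])
    kb = np.array([f.k for f in fits_b if not f.degenerate])
    if len(ka) < 2 or len(kb) < 2:
        raise ValueError("compare_decay needs >= 2 non-degenerate fits per group")
    out = {
        "k_mean_a": float(ka.mean()), "k_mean_b": float(kb.mean()),
        "k_ci_a": _t_ci(ka, alpha), "k_ci_b": _t_ci(kb, alpha),
        "n_excluded": (len(fits_a) - len(ka)) + (len(fits_b) - len(kb)),
    }
    t, p = stats.ttest_ind(ka, kb, equal_var=False)
    out.update(t=float(t), p=float(p), significant=bool(p < alpha))
    if bins_a and bins_b:
        va = np.vstack([b.values for b in bins_a])
        vb = np.vstack([b.values for b in bins_b])
        flags = []
        for j in range(va.shape[1]):
            ca, cb = _t_ci(va[:, j], alpha), _t_ci(vb[:, j], alpha)
            flags.append(bool(ca[1] < cb[0] or cb[1] < ca[0]))
        out["bin_ci_separated"] = flags
    return out


def contact_time_bounds(contacts_total_s: float, max_simultaneous: int,
                        n_trajectories: int, n_released: int = 25,
                        first_ten_min: bool = False) -> ContactTimeBounds:
    """Bracket per-mosquito contact time for one test.

    max = total / (largest number observed attacking simultaneously);
    min = total / n_released, except in first-ten-minute analyses where
    fewer trajectories than released mosquitoes substitutes the trajectory
    count as the divisor.
    """
    if max_simultaneous <= 0:
        if contacts_total_s > 0:
            raise ValueError("nonzero contact time with zero simultaneous mosquitoes")
        return ContactTimeBounds(0.0, 0, n_trajectories, n_released, 0.0, 0.0)
    divisor = n_released
    if first_ten_min and n_trajectories < n_released:
        divisor = max(n_trajectories, 1)
    return ContactTimeBounds(
        total_contact_s=contacts_total_s,
        max_simultaneous=max_simultaneous,
        n_trajectories=n_trajectories,
        n_released=n_released,
        min_per_mosquito_s=contacts_total_s / divisor,
        max_per_mosquito_s=contacts_total_s / max_simultaneous,
    )


def geometric_mean_ci(values, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Geometric mean with a t-distribution CI computed in log space."""
    v = np.asarray(list(values), dtype=float)
    if np.any(v <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    logs = np.log(v)
    gm = float(np.exp(logs.mean()))
    if len(v) < 2 or np.std(logs) == 0:
        return gm, (gm, gm)
    se = logs.std(ddof=1) / np.sqrt(len(v))
    q = stats.t.ppf(1 - alpha / 2, df=len(v) - 1)
    return gm, (float(np.exp(logs.mean() - q * se)),
                float(np.exp(logs.mean() + q * se)))


def max_total_activity(n_released: int, duration_h: float) -> float:
    """Ceiling on aggregate activity: n mosquitoes x test hours."""
    if n_released <= 0 or duration_h <= 0:
        raise ValueError("inputs must be positive")
    return n_released * duration_h


def normality_screen(values) -> dict:
    """Skewness/kurtosis diagnostic used to choose between arithmetic and
    geometric means (reported, not an automatic switch)."""
    v = np.asarray(list(values), dtype=float)
    return {
        "skewness": float(stats.skew(v)) if len(v) > 2 else None,
        "excess_kurtosis": float(stats.kurtosis(v)) if len(v) > 3 else None,
        "n": len(v),
    }


def contact_time_s(segments, frame_rate: float = 50.0) -> float:
    """Total net-contact seconds implied by a segment list: full duration of
    bouncing and resting segments plus one frame per visiting contact."""
    total = 0.0
    for seg in segments:
        if seg.mode in ("bouncing", "resting"):
            total += seg.duration_s
        elif seg.mode == "visiting":
            total += seg.n_contacts / frame_rate
    return total


def max_simultaneous_contacts(segments_by_track: dict) -> int:
    """Largest number of tracks simultaneously in a contact-involving mode."""
    events = []
    for segments in segments_by_track.values():
        spans = [(s.start_frame, s.end_frame) for s in segments
                 if s.mode in CONTACT_MODES]
        if not spans:
            continue
        # one mosquito per track: merge its contact spans
        a = min(s for s, _ in spans)
        b = max(e for _, e in spans)
        events.append((a, 1))
        events.append((b, -1))
    events.sort()
    best = cur = 0
    for _, d in events:
        cur += d
        best = max(best, cur)
    return best


def _t_ci(v: np.ndarray, alpha: float) -> tuple[float, float]:
    m = float(v.mean())
    if len(v) < 2 or np.std(v) == 0:
        return (m, m)
    se = v.std(ddof=1) / np.sqrt(len(v))
    q = stats.t.ppf(1 - alpha / 2, df=len(v) - 1)
    return (m - q * se, m + q * se)
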