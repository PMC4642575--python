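"""End-to-end orchestration: classify tests, export tidy tables, validate.

``analyse_test`` runs every stage on one test; ``run_pipeline`` reads a
trajectory file, analyses every test in it and writes the per-test tables
(segments, contacts, landing windows, region densities, decay fits,
contact-time bounds) plus a machine-readable summary with provenance.
``simulate_and_validate`` generates a synthetic test, runs the same
pipeline, and scores the result against the generator's ground truth.

Statistical comparison between net types (mixed-effect GLMs, survival
analysis) is deliberately out of scope: the exported tidy tables are the
interface to external statistical software.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ArenaGeometry, ClassifierConfig, config_hash, load_config
from .contacts import detect_contacts, detect_turn_contacts
from .kinematics import approach_summary, extract_landing_window, tortuosity
from .model import TestRecord, read_metadata, read_tracks, write_tracks
from .modes import aggregate_modes, frame_labels, lag_to_first_contact, segment_track
from .regions import (RegionMap, activity_density, attribute_segments,
                      classify_approach, first_contact_distribution,
                      left_right_bias)
from .simulate import GenerationParams, generate_test
from .temporal import (bin_activity, bin_track_counts, contact_time_bounds,
                       contact_time_s, fit_decay, max_simultaneous_contacts)

__all__ = ["analyse_test", "run_pipeline", "simulate_and_validate",
           "PipelineReport"]


@dataclass
class PipelineReport:
    """All stage outputs for a set of tests, plus provenance."""

    tests: dict
    provenance: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = ("segments", "contacts", "landing", "region_density",
                 "decay", "mode_summary", "activity_bins")
        frames = {name: [] for name in names}
        for test_id, res in self.tests.items():
            for name in names:
                frames[name].append(res["tables"].get(name))
        for name, parts in frames.items():
            parts = [p for p in parts if p is not None and len(p)]
            df = pd.concat(parts, ignore_index=True) if parts \
                else pd.DataFrame()
            df.to_csv(out / f"{name}.csv", index=False)
        summary = {
            "provenance": self.provenance,
            "tests": {tid: res["summary"] for tid, res in self.tests.items()},
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def analyse_test(test: TestRecord, config: ClassifierConfig | None = None,
                 bin_s: float = 300.0) -> dict:
    """Run the full analysis on one test; returns tables and a summary."""
    config = config or ClassifierConfig()
    geom = test.geometry
    region_map = RegionMap(geom)

    contacts_by_track, rest_by_track, segments_by_track = {}, {}, {}
    windows, n_landing_excluded = [], 0
    seg_rows, con_rows, land_rows = [], [], []
    all_segments = []
    fr = config.frame_rate

    for tr in test.tracks:
        contacts, rests = detect_contacts(tr, config, geom)
        segments = segment_track(tr, contacts, rests, config)
        contacts_by_track[tr.track_id] = contacts
        rest_by_track[tr.track_id] = rests
        segments_by_track[tr.track_id] = segments
        all_segments.extend(segments)

        for seg in segments:
            seg_rows.append((test.test_id, tr.track_id, seg.mode,
                             seg.start_frame / fr, seg.end_frame / fr,
                             seg.duration_s, seg.n_contacts))
        for e in contacts:
            region = region_map.assign_contact(e.x, e.y, config.net_proximity_mm)
            con_rows.append((test.test_id, tr.track_id, e.frame, e.t,
                             e.x, e.y, e.type, region))
        if contacts:
            first = min(contacts, key=lambda e: e.frame)
            win = extract_landing_window(tr, first, config)
            if win is None:
                n_landing_excluded += 1
            else:
                windows.append(win)
                land_rows.append((
                    test.test_id, tr.track_id,
                    win.onset_index, win.onset_distance_mm,
                    win.onset_speed_mm_s, win.decel_class))

    modes = aggregate_modes(test, all_segments)
    lag = lag_to_first_contact(test, contacts_by_track) if test.tracks else None
    approach = approach_summary(test, windows)

    region_seconds = attribute_segments(
        test, segments_by_track, contacts_by_track, rest_by_track,
        region_map, config)
    density = activity_density(test, region_seconds, region_map)
    first_contacts = first_contact_distribution(
        test, contacts_by_track, region_map, config)
    approach_classes = {
        tr.track_id: classify_approach(tr, region_map, config)
        for tr in test.tracks
    }
    n_by_class = {c: sum(1 for v in approach_classes.values() if v == c)
                  for c in ("high", "low", "discarded")}
    n_hl = n_by_class["high"] + n_by_class["low"]
    lr = left_right_bias(test)

    bins = bin_activity(test, all_segments, bin_s=bin_s)
    mode_bins = {m: bin_activity(test, all_segments, bin_s=bin_s, mode=m)
                 for m in ("swooping", "visiting", "bouncing", "resting")}
    track_bins = bin_track_counts(test, bin_s=bin_s)
    decay = fit_decay(bins)
    decay_tracks = fit_decay(track_bins)

    total_contact = contact_time_s(all_segments, fr)
    max_sim = max_simultaneous_contacts(segments_by_track)
    bounds = contact_time_bounds(total_contact, max_sim,
                                 test.n_tracks, test.n_released)

    torts = [t for t in (tortuosity(tr, config) for tr in test.tracks)
             if t is not None]

    tables = {
        "segments": pd.DataFrame(seg_rows, columns=[
            "test_id", "track_id", "mode", "start_s", "end_s",
            "duration_s", "n_contacts"]),
        "contacts": pd.DataFrame(con_rows, columns=[
            "test_id", "track_id", "frame", "t_s", "x_mm", "y_mm",
            "type", "region_id"]),
        "landing": pd.DataFrame(land_rows, columns=[
            "test_id", "track_id", "onset_index", "onset_distance_mm",
            "onset_speed_mm_s", "class"]),
        "region_density": pd.DataFrame(
            [(test.test_id, r, v["seconds"], v["seconds_per_m2"])
             for r, v in density.items()],
            columns=["test_id", "region_id", "seconds", "seconds_per_m2"]),
        "decay": pd.DataFrame(
            [(test.test_id, test.net_type, decay.A0, decay.k,
              decay.converged, decay.degenerate)],
            columns=["test_id", "net_type", "A0", "k", "converged",
                     "degenerate"]),
        "mode_summary": pd.DataFrame(
            [(test.test_id, test.net_type, m, modes["minutes"][m],
              modes["fractions"][m])
             for m in ("swooping", "visiting", "bouncing", "resting")],
            columns=["test_id", "net_type", "mode", "minutes", "fraction"]),
        "activity_bins": pd.DataFrame(
            [(test.test_id, b * bin_s / 60.0, m, float(v))
             for m, mb in (("all", bins),) + tuple(mode_bins.items())
             for b, v in enumerate(mb.values)],
            columns=["test_id", "bin_start_min", "mode", "seconds"]),
    }
    summary = {
        "net_type": test.net_type,
        "n_tracks": test.n_tracks,
        "modes": modes,
        "lag_to_first_contact_s": lag,
        "no_contact": lag is None,
        "approach": approach,
        "n_landing_excluded": n_landing_excluded,
        "first_contacts": first_contacts,
        "high_entry_fraction": (n_by_class["high"] / n_hl) if n_hl else None,
        "high_entry_expected": config.high_entry_expected_fraction,
        "high_entry_geometry_fraction": geom.entry_edge_high_fraction,
        "n_discarded_entries": n_by_class["discarded"],
        "left_right": lr,
        "activity_bins_s": bins.values.tolist(),
        "track_count_bins": track_bins.values.tolist(),
        "decay": {"A0": decay.A0, "k": decay.k,
                  "converged": decay.converged,
                  "degenerate": decay.degenerate},
        "decay_track_counts": {"A0": decay_tracks.A0, "k": decay_tracks.k},
        "contact_time": asdict(bounds),
        "mean_tortuosity": float(np.mean([t.mean for t in torts]))
        if torts else None,
    }
    return {
        "tables": tables, "summary": summary,
        "contacts_by_track": contacts_by_track,
        "segments_by_track": segments_by_track,
        "rest_by_track": rest_by_track,
        "windows": windows,
        "bins": bins, "mode_bins": mode_bins, "track_bins": track_bins,
    }


def run_pipeline(tracks_path, config_path=None, out_dir=None,
                 metadata_path=None, bin_s: float = 300.0) -> PipelineReport:
    """Read a trajectory file, analyse every test, write all tables."""
    if config_path:
        config, geom = load_config(config_path)
    else:
        config, geom = ClassifierConfig(), ArenaGeometry()
    metadata = read_metadata(metadata_path) if metadata_path else {}
    tests = read_tracks(tracks_path, config, metadata)
    for t in tests:
        if not metadata:
            t.geometry = geom
    results = {}
    for test in tests:
        try:
            results[test.test_id] = analyse_test(test, config, bin_s=bin_s)
        except Exception as exc:  # noqa: BLE001 - name the failing stage
            raise RuntimeError(
                f"pipeline failed on test {test.test_id}: {exc}") from exc
    report = PipelineReport(
        tests=results,
        provenance={
            "version": __version__,
            "config_hash": config_hash(config, geom),
            "input": str(tracks_path),
        },
    )
    if out_dir:
        report.write(out_dir)
    return report


def simulate_and_validate(
    params: GenerationParams,
    config: ClassifierConfig | None = None,
    geometry: ArenaGeometry | None = None,
    out_dir=None,
) -> dict:
    """Generate a test, run the pipeline, and score it against ground truth.

    The scorecard reports per-frame mode-label accuracy, turn-contact
    recall and precision (±2-frame matching), the mean absolute error of
    recovered deceleration-onset distances, and the error of the fitted
    decay constant.
    """
    config = config or ClassifierConfig()
    geom = geometry or ArenaGeometry()
    test, truth = generate_test(params, config, geom)
    res = analyse_test(test, config)

    # per-frame mode-label accuracy
    agree = total = 0
    for tr in test.tracks:
        pred = frame_labels(tr, res["segments_by_track"][tr.track_id])
        true = truth.labels[tr.track_id]
        agree += int(np.sum(pred == true))
        total += len(true)
    accuracy = agree / total if total else None

    # turn-contact detector recall / precision
    tp = fp = fn = 0
    onset_errors = []
    for tr in test.tracks:
        det = [e.frame for e in detect_turn_contacts(tr, config, geom)]
        cs = truth.contacts_for(tr.track_id)
        tru = [c.frame for c in cs if c.type == "turn"]
        # a landing into walking or rest may or may not show a sharp turn:
        # detecting it is not an error, missing it is not a miss
        optional = [c.frame for c in cs if c.type != "turn"]
        m_tp, m_fp, m_fn = _match_events(det, tru, tol=2, optional=optional)
        tp, fp, fn = tp + m_tp, fp + m_fp, fn + m_fn
    recall = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None

    # onset recovery on extracted landing windows (first contacts)
    truth_first = {}
    for c in truth.contacts:
        if c.onset_distance_mm is not None:
            truth_first.setdefault(c.track_id, c)
    for win in res["windows"]:
        c = truth_first.get(win.track_id)
        if c is None or win.onset_distance_mm is None:
            continue
        if abs(win.frames[win.contact_index] - c.frame) <= 2:
            onset_errors.append(win.onset_distance_mm - c.onset_distance_mm)
    onset_mae = float(np.mean(np.abs(onset_errors))) if onset_errors else None

    k_hat = res["summary"]["decay_track_counts"]["k"]
    scorecard = {
        "seed": params.seed,
        "net_type": params.net_type,
        "n_tracks": test.n_tracks,
        "mode_label_accuracy": accuracy,
        "turn_contact_recall": recall,
        "turn_contact_precision": precision,
        "onset_distance_mae_mm": onset_mae,
        "n_onset_windows": len(onset_errors),
        "decay_k_true": truth.decay_k,
        "decay_k_hat": k_hat,
        "decay_k_error": (k_hat - truth.decay_k) if k_hat is not None else None,
    }
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tracks([test], out / "tracks.csv")
        truth.to_json(out / "truth.json")
        PipelineReport(
            tests={test.test_id: res},
            provenance={"version": __version__, "seed": params.seed,
                        "config_hash": config_hash(config, geom)},
        ).write(out)
        with open(out / "scorecard.json", "w") as fh:
            json.dump(scorecard, fh, indent=2, default=_jsonable)
    return scorecard


def _match_events(detected: list[int], truth: list[int], tol: int = 2,
                  optional: list[int] | None = None):
    """Greedy one-to-one frame matching; returns (tp, fp, fn).

    Detections within ``tol`` frames of an ``optional`` truth event are
    neither true nor false positives.
    """
    truth_left = sorted(truth)
    optional_left = sorted(optional or [])
    tp = neutral = 0
    for f in sorted(detected):
        hit = next((i for i, g in enumerate(truth_left) if abs(f - g) <= tol),
                   None)
        if hit is not None:
            truth_left.pop(hit)
            tp += 1
            continue
        opt = next((i for i, g in enumerate(optional_left)
                    if abs(f - g) <= tol), None)
        if opt is not None:
            optional_left.pop(opt)
            neutral += 1
    fp = len(detected) - tp - neutral
    fn = len(truth_left)
    return tp, fp, fn
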