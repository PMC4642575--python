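"""Behavioural-mode segmentation of flight tracks.

Each track is partitioned into four mutually exclusive modes:

* **swooping** — flight with no net contact (a contact-bearing track never
  contains a swooping segment);
* **visiting** — flight with isolated contacts separated by at least the
  contact interval (0.4 s = 20 frames at 50 fps, inclusive on the visiting
  side);
* **bouncing** — runs of two or more contacts with successive gaps shorter
  than the contact interval, spanning first to last contact of the run and
  absorbing sub-resting pauses (< 0.75 s, walking/probing on the net);
* **resting** — continuous net contact, static or slower than 1.33 mm/s,
  for at least 0.75 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ClassifierConfig
from .contacts import ContactEvent, RestingEvent

__all__ = ["ModeSegment", "segment_track", "frame_labels", "aggregate_modes",
           "lag_to_first_contact", "MODES"]

MODES = ("swooping", "visiting", "bouncing", "resting")


@dataclass(frozen=True)
class ModeSegment:
    track_id: str
    mode: str
    start_frame: int
    end_frame: int
    duration_s: float
    n_contacts: int = 0


def segment_track(
    track,
    contacts: list[ContactEvent],
    resting: list[RestingEvent],
    config: ClassifierConfig,
) -> list[ModeSegment]:
    """Partition one track into mode segments.

    The segments are non-overlapping, cover the track exactly, and are
    derived from the merged contact sequence: resting events become resting
    segments; contact runs with gaps below the contact interval become
    bouncing segments; all remaining time of a contact-bearing track is
    visiting; a contact-free track is a single swooping segment.
    """
    f0, f1 = int(track.frames[0]), int(track.frames[-1])
    for e in contacts:
        if not f0 <= e.frame <= f1:
            raise ValueError(
                f"contact at frame {e.frame} outside track "
                f"{track.track_id} range [{f0}, {f1}]"
            )
    fr = config.frame_rate
    if not contacts and not resting:
        return [ModeSegment(track.track_id, "swooping", f0, f1,
                            (f1 - f0) / fr, 0)]

    labels = _interval_labels(track, contacts, resting, config)
    # build segments from interval-label runs
    spans: list[list] = []
    frames = track.frames
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        spans.append([labels[i], int(frames[i]), int(frames[j]), 0])
        i = j
    # attribute each contact to its span; boundary contacts prefer the
    # contact-defined segment (bouncing/resting), then the earlier span
    prio = {"bouncing": 0, "resting": 1, "visiting": 2, "swooping": 3}
    for e in contacts:
        holders = [k for k, (_, a, b, _c) in enumerate(spans)
                   if a <= e.frame <= b]
        k = min(holders, key=lambda k: (prio[spans[k][0]], k))
        spans[k][3] += 1
    return [ModeSegment(track.track_id, lab, a, b, (b - a) / fr, c)
            for lab, a, b, c in spans]


def _interval_labels(track, contacts, resting, config) -> list[str]:
    """Mode label of each inter-frame interval of the track."""
    frames = track.frames
    n_int = len(frames) - 1
    idx_of = {int(f): i for i, f in enumerate(frames)}
    labels = np.array(["visiting"] * n_int, dtype=object)

    gap_frames = config.contact_interval_frames
    spans = [(r.start_frame, r.end_frame) for r in resting]
    free = [e for e in contacts
            if not any(s <= e.frame <= t for s, t in spans)]
    free.sort(key=lambda e: e.frame)
    # bouncing runs: >= 2 contacts with successive gaps < the interval
    run: list[ContactEvent] = []
    for e in free + [None]:
        if e is not None and (not run or e.frame - run[-1].frame < gap_frames):
            run.append(e)
            continue
        if len(run) >= 2:
            a, b = idx_of[run[0].frame], idx_of[run[-1].frame]
            labels[a:b] = "bouncing"
        run = [e] if e is not None else []
    for s, t in spans:
        labels[idx_of[s]:idx_of[t]] = "resting"
    return list(labels)


def frame_labels(track, segments: list[ModeSegment]) -> np.ndarray:
    """Per-frame mode labels (a frame takes the label of the interval it
    opens; the final frame takes the last interval's label)."""
    out = np.empty(len(track), dtype=object)
    for seg in segments:
        sel = (track.frames >= seg.start_frame) & (track.frames < seg.end_frame)
        out[sel] = seg.mode
    out[-1] = segments[-1].mode
    return out


def aggregate_modes(test, segments: list[ModeSegment]) -> dict:
    """Per-test mode totals (minutes), fractions, and contact-mode share.

    Totals may exceed the test duration because several mosquitoes can be
    active at once; they can never exceed ``n_released x duration``.
    """
    totals = {m: 0.0 for m in MODES}
    for seg in segments:
        totals[seg.mode] += seg.duration_s
    total = sum(totals.values())
    ceiling = test.n_released * test.duration_s
    if total > ceiling + 1e-6:
        raise ValueError(
            f"test {test.test_id}: activity {total:.0f}s exceeds ceiling "
            f"{ceiling:.0f}s (n_released x duration)"
        )
    fractions = {m: (totals[m] / total if total > 0 else 0.0) for m in MODES}
    contact_fraction = sum(fractions[m] for m in ("visiting", "bouncing", "resting"))
    return {
        "minutes": {m: totals[m] / 60.0 for m in MODES},
        "seconds": totals,
        "fractions": fractions,
        "contact_fraction": contact_fraction,
        "total_minutes": total / 60.0,
    }


def lag_to_first_contact(test, contacts_by_track: dict[str, list[ContactEvent]]) -> float | None:
    """Seconds from the first mosquito's appearance to the first net contact.

    Returns ``None`` (flagged: no contact) when no contact occurs in the
    test.  Raises on an empty test.
    """
    if not test.tracks:
        raise ValueError(f"test {test.test_id}: no tracks")
    first_appearance = min(tr.t[0] for tr in test.tracks)
    contact_times = [
        e.t for events in contacts_by_track.values() for e in events
    ]
    if not contact_times:
        return None
    return float(min(contact_times) - first_appearance)
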