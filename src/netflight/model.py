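"""Core trajectory data types and plain-text trajectory I/O.

A :class:`Track` is one flight event: the ordered 2D positions of a single
mosquito between entering and leaving the camera field of view.  Because
individual mosquitoes cannot be followed across events, every track is
analysed independently.  Tracks are grouped into :class:`TestRecord`\\ s, one
per 60-minute assay (one net, typically 25 released mosquitoes).

The on-disk format is a comma-separated table with header
``test_id,track_id,frame,t_s,x_mm,y_mm,camera_field``, one row per point,
tracks contiguous and frame-sorted, positions serialised at 0.01 mm.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .config import ArenaGeometry, ClassifierConfig, _from_mapping

__all__ = [
    "TrackPoint", "Track", "TestRecord",
    "read_tracks", "write_tracks", "TrackValidationError", "TrajectoryFormatError",
]

POSITION_DECIMALS = 2  # serialised precision: 0.01 mm, below every threshold

CAMERA_FIELDS = ("left", "right", "both")
NET_TYPES = ("unbaited", "untreated", "llin")

TrackPoint = namedtuple("TrackPoint", ["t", "x", "y", "frame"])


class TrackValidationError(ValueError):
    """A track violates a structural invariant (named in the message)."""


class TrajectoryFormatError(ValueError):
    """A trajectory file does not follow the documented tabular format."""


@dataclass
class Track:
    """One flight event: frame-indexed 2D positions in mm.

    ``frames`` is authoritative; time stamps are derived as
    ``frames / frame_rate``.
    """

    track_id: str
    test_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    camera_field: str = "both"
    frame_rate: float = 50.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.frames)
        if n < 2:
            raise TrackValidationError(f"track {self.track_id}: needs >= 2 points")
        if not (len(self.x) == len(self.y) == n):
            raise TrackValidationError(f"track {self.track_id}: ragged arrays")
        if np.any(np.diff(self.frames) <= 0):
            raise TrackValidationError(
                f"track {self.track_id}: frames not strictly increasing"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise TrackValidationError(f"track {self.track_id}: non-finite positions")
        if np.any(self.y < 0):
            raise TrackValidationError(f"track {self.track_id}: y below floor")
        if self.camera_field not in CAMERA_FIELDS:
            raise TrackValidationError(
                f"track {self.track_id}: camera_field {self.camera_field!r}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def t(self) -> np.ndarray:
        """Time stamps in seconds, derived from frame index."""
        return self.frames / self.frame_rate

    @property
    def duration_s(self) -> float:
        return float((self.frames[-1] - self.frames[0]) / self.frame_rate)

    @property
    def points(self) -> list[TrackPoint]:
        t = self.t
        return [
            TrackPoint(t=float(t[i]), x=float(self.x[i]), y=float(self.y[i]),
                       frame=int(self.frames[i]))
            for i in range(len(self))
        ]

    def displacements(self) -> np.ndarray:
        """Per-interval displacement lengths (mm), length ``len(self) - 1``."""
        return np.hypot(np.diff(self.x), np.diff(self.y))


@dataclass
class TestRecord:
    """One assay: a net type, released mosquitoes, and its tracks."""

    test_id: str
    net_type: str = "untreated"
    n_released: int = 25
    duration_s: float = 3600.0
    tracks: list[Track] = field(default_factory=list)
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)

    def __post_init__(self) -> None:
        if self.net_type not in NET_TYPES:
            raise TrackValidationError(f"unknown net_type {self.net_type!r}")
        for tr in self.tracks:
            if tr.test_id != self.test_id:
                raise TrackValidationError(
                    f"track {tr.track_id} references test {tr.test_id!r}, "
                    f"expected {self.test_id!r}"
                )
            if tr.t[0] < 0 or tr.t[-1] > self.duration_s:
                raise TrackValidationError(
                    f"track {tr.track_id}: time stamps outside [0, {self.duration_s}]"
                )

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def total_activity_s(self) -> float:
        return float(sum(tr.duration_s for tr in self.tracks))


REQUIRED_COLUMNS = ["test_id", "track_id", "frame", "t_s", "x_mm", "y_mm", "camera_field"]


def write_tracks(tests: Iterable[TestRecord], path) -> None:
    """Serialise tests to the documented CSV format (0.01 mm precision)."""
    rows = []
    for rec in tests:
        for tr in rec.tracks:
            rows.append(pd.DataFrame({
                "test_id": rec.test_id,
                "track_id": tr.track_id,
                "frame": tr.frames,
                "t_s": tr.t,
                "x_mm": np.round(tr.x, POSITION_DECIMALS),
                "y_mm": np.round(tr.y, POSITION_DECIMALS),
                "camera_field": tr.camera_field,
            }))
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(columns=REQUIRED_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_tracks(
    path,
    config: ClassifierConfig | None = None,
    metadata: dict | None = None,
) -> list[TestRecord]:
    """Read a trajectory CSV into validated :class:`TestRecord` objects.

    Parameters
    ----------
    path
        Trajectory file in the documented format.
    config
        Classifier configuration; supplies the frame rate that converts
        frame indices into seconds.
    metadata
        Optional per-test metadata mapping ``test_id -> dict`` (net_type,
        n_released, duration_s, geometry), e.g. from :func:`read_metadata`.

    Raises
    ------
    TrajectoryFormatError
        Missing required columns, or malformed rows (reported with line
        numbers).
    TrackValidationError
        Structural violations such as duplicated frames within a track.
    """
    config = config or ClassifierConfig()
    metadata = metadata or {}
    try:
        df = pd.read_csv(path, dtype={"test_id": str, "track_id": str})
    except pd.errors.EmptyDataError:
        raise TrajectoryFormatError(f"{path}: empty file, expected header row")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing required columns {missing}")

    bad = df.index[
        df[["frame", "x_mm", "y_mm"]].isna().any(axis=1)
        | df["test_id"].isna() | df["track_id"].isna()
    ]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise TrajectoryFormatError(f"{path}: malformed rows at lines {lines}")

    tests: list[TestRecord] = []
    for test_id, tdf in df.groupby("test_id", sort=False):
        tracks = []
        for track_id, g in tdf.groupby("track_id", sort=False):
            frames = g["frame"].to_numpy(dtype=np.int64)
            if np.any(np.diff(frames) <= 0):
                raise TrackValidationError(
                    f"track {track_id}: non-monotone or duplicated frames"
                )
            tracks.append(Track(
                track_id=str(track_id), test_id=str(test_id),
                frames=frames,
                x=g["x_mm"].to_numpy(dtype=float),
                y=g["y_mm"].to_numpy(dtype=float),
                camera_field=str(g["camera_field"].iloc[0]),
                frame_rate=config.frame_rate,
            ))
        meta = dict(metadata.get(str(test_id), {}))
        geom = meta.pop("geometry", None)
        if isinstance(geom, dict):
            geom = _from_mapping(ArenaGeometry, geom)
        tests.append(TestRecord(
            test_id=str(test_id),
            net_type=meta.get("net_type", "untreated"),
            n_released=int(meta.get("n_released", 25)),
            duration_s=float(meta.get("duration_s", 3600.0)),
            tracks=tracks,
            geometry=geom or ArenaGeometry(),
        ))
    return tests


def read_metadata(path) -> dict:
    """Read a YAML test-metadata file: ``tests: {test_id: {...}}``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return {str(k): v for k, v in (doc.get("tests", doc) or {}).items()}
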