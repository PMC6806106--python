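"""Core sequence/interval types and CSV readers/writers.

All tables are plain delimited text:

* trajectories: ``subject_id,frame,x,y[,z]``
* skeletons:    ``frame,joint_id,x,y`` with ``joint_id`` in 1..8
* annotations / predictions: ``label,start_frame,end_frame[,score]``
* descriptors:  ``[subject_id,]start_frame,end_frame,d1..dD`` (one row per
  descriptor vector; rows sharing an interval form one segment)

Frames are 0-based and intervals are closed ``[start, end]``; the duration of
an interval in frames is ``end - start``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

DEFAULT_FPS = 25.0

N_JOINTS = 8


@dataclass(frozen=True)
class TrajectoryPoint:
    """One tracked position of one subject at one frame."""

    subject_id: str
    frame: int
    x: float
    y: float
    z: float | None = None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise DataError(f"frame must be >= 0, got {self.frame}")
        for c in (self.x, self.y) + (() if self.z is None else (self.z,)):
            if not math.isfinite(c):
                raise DataError(f"non-finite coordinate in {self!r}")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class FrameInterval:
    """Closed frame interval [start_frame, end_frame], 0-based."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise DataError(
                f"interval start {self.start_frame} > end {self.end_frame}"
            )

    @property
    def length(self) -> int:
        """Duration in frames (end - start)."""
        return self.end_frame - self.start_frame

    @property
    def n_frames(self) -> int:
        """Number of frames covered by the closed interval."""
        return self.end_frame - self.start_frame + 1

    def duration_s(self, fps: float) -> float:
        return self.length / fps

    def overlaps(self, other: "FrameInterval") -> bool:
        """Non-empty closed-interval intersection.

        Equivalent to the four-clause start/end disjunction used to decide
        whether a finer-level event is a sub-activity of a coarser one.
        """
        return self.start_frame <= other.end_frame and other.start_frame <= self.end_frame

    def intersection_frames(self, other: "FrameInterval") -> int:
        """Number of shared frames (0 if disjoint)."""
        lo = max(self.start_frame, other.start_frame)
        hi = min(self.end_frame, other.end_frame)
        return max(0, hi - lo + 1)

    def distance_frames(self, other: "FrameInterval") -> int:
        """Frame gap between two intervals; 0 when they overlap."""
        if self.overlaps(other):
            return 0
        if self.end_frame < other.start_frame:
            return other.start_frame - self.end_frame
        return self.start_frame - other.end_frame


class TrajectorySequence:
    """Ordered trajectory of one subject.

    Stored column-wise (frame and coordinate arrays) so that clustering and
    event encoding can operate on whole sequences without per-point objects.
    """

    def __init__(
        self,
        subject_id: str,
        frames: np.ndarray,
        xy: np.ndarray,
        z: np.ndarray | None = None,
        fps: float = DEFAULT_FPS,
    ) -> None:
        frames = np.asarray(frames, dtype=np.int64)
        xy = np.asarray(xy, dtype=float)
        if fps <= 0:
            raise DataError(f"fps must be positive, got {fps}")
        if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] != frames.shape[0]:
            raise DataError("xy must be an (n, 2) array aligned with frames")
        if frames.size and frames[0] < 0:
            raise DataError("frames must be non-negative")
        if np.any(np.diff(frames) <= 0):
            bad = int(np.flatnonzero(np.diff(frames) <= 0)[0])
            raise DataError(
                f"frames must be strictly increasing for subject {subject_id!r} "
                f"(violation after frame {int(frames[bad])})"
            )
        if not np.all(np.isfinite(xy)):
            raise DataError(f"non-finite coordinates for subject {subject_id!r}")
        self.subject_id = str(subject_id)
        self.frames = frames
        self.xy = xy
        self.z = None if z is None else np.asarray(z, dtype=float)
        self.fps = float(fps)

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrajectorySequence):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.fps == other.fps
            and np.array_equal(self.frames, other.frames)
            and np.array_equal(self.xy, other.xy)
            and (
                (self.z is None and other.z is None)
                or (self.z is not None and other.z is not None and np.array_equal(self.z, other.z))
            )
        )

    @property
    def points(self) -> list[TrajectoryPoint]:
        zs = [None] * len(self) if self.z is None else self.z
        return [
            TrajectoryPoint(self.subject_id, int(f), float(p[0]), float(p[1]),
                            None if zv is None else float(zv))
            for f, p, zv in zip(self.frames, self.xy, zs)
        ]

    @classmethod
    def from_points(
        cls, points: list[TrajectoryPoint], fps: float = DEFAULT_FPS
    ) -> "TrajectorySequence":
        if not points:
            raise DataError("cannot build a sequence from zero points")
        sid = points[0].subject_id
        if any(p.subject_id != sid for p in points):
            raise DataError("all points in a sequence must share subject_id")
        frames = np.array([p.frame for p in points], dtype=np.int64)
        xy = np.array([[p.x, p.y] for p in points], dtype=float)
        z = None
        if all(p.z is not None for p in points):
            z = np.array([p.z for p in points], dtype=float)
        return cls(sid, frames, xy, z=z, fps=fps)

    @property
    def frame_range(self) -> FrameInterval:
        return FrameInterval(int(self.frames[0]), int(self.frames[-1]))


@dataclass
class SkeletonFrame:
    """Eight 2-D joint positions for one frame."""

    frame: int
    joints: np.ndarray  # (8, 2)

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.shape != (N_JOINTS, 2):
            raise DataError(
                f"expected {N_JOINTS} planar joints, got shape {self.joints.shape}"
            )


@dataclass
class DescriptorSegment:
    """Local-descriptor rows covering one frame interval."""

    interval: FrameInterval
    vectors: np.ndarray  # (n_rows, D)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.size and self.vectors.shape[1] < 1:
            raise DataError("descriptor rows must have dimensionality > 0")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_rows(self) -> int:
        return 0 if self.vectors.size == 0 else self.vectors.shape[0]


@dataclass
class AnnotationTrack:
    """Labeled frame intervals (ground truth or predictions)."""

    entries: list[tuple[str, FrameInterval]] = field(default_factory=list)
    scores: list[float] | None = None

    def validate_overlap(self, tolerance_frames: int = 0) -> None:
        """Reject intervals within the track overlapping by more than tolerance."""
        ordered = sorted(self.entries, key=lambda e: (e[1].start_frame, e[1].end_frame))
        for (_, a), (_, b) in zip(ordered, ordered[1:]):
            if a.intersection_frames(b) > tolerance_frames:
                raise DataError(f"intervals {a} and {b} overlap beyond tolerance")

    @property
    def labels(self) -> list[str]:
        return sorted({lab for lab, _ in self.entries})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTrack):
            return NotImplemented
        return self.entries == other.entries


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_trajectories(path, fps: float = DEFAULT_FPS) -> list[TrajectorySequence]:
    """Read a trajectory table into one sequence per subject, frame-sorted.

    Duplicate ``(subject_id, frame)`` rows are rejected; row order in the
    file is irrelevant.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["subject_id", "frame", "x", "y"], str(path))
    has_z = "z" in df.columns
    sequences = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("frame")
        dup = grp["frame"].duplicated()
        if dup.any():
            f = int(grp.loc[dup.idxmax(), "frame"])
            raise DataError(f"{path}: duplicate (subject {sid!r}, frame {f}) row")
        z = grp["z"].to_numpy() if has_z and grp["z"].notna().all() else None
        sequences.append(
            TrajectorySequence(
                str(sid),
                grp["frame"].to_numpy(),
                grp[["x", "y"]].to_numpy(),
                z=z,
                fps=fps,
            )
        )
    return sequences


def write_trajectories(sequences: list[TrajectorySequence], path) -> None:
    frames_cols: dict[str, list] = {"subject_id": [], "frame": [], "x": [], "y": []}
    with_z = all(s.z is not None for s in sequences) and len(sequences) > 0
    if with_z:
        frames_cols["z"] = []
    for seq in sequences:
        n = len(seq)
        frames_cols["subject_id"] += [seq.subject_id] * n
        frames_cols["frame"] += [int(f) for f in seq.frames]
        frames_cols["x"] += [float(v) for v in seq.xy[:, 0]]
        frames_cols["y"] += [float(v) for v in seq.xy[:, 1]]
        if with_z:
            frames_cols["z"] += [float(v) for v in seq.z]
    pd.DataFrame(frames_cols).to_csv(path, index=False, float_format="%.17g")


def read_annotations(path) -> AnnotationTrack:
    """Read a ``label,start_frame,end_frame[,score]`` table."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["label", "start_frame", "end_frame"], str(path))
    entries = []
    scores = [] if "score" in df.columns else None
    for _, row in df.iterrows():
        s, e = int(row["start_frame"]), int(row["end_frame"])
        if s > e:
            raise DataError(f"{path}: interval end {e} < start {s} for {row['label']!r}")
        entries.append((str(row["label"]), FrameInterval(s, e)))
        if scores is not None:
            scores.append(float(row["score"]))
    return AnnotationTrack(entries, scores=scores)


def write_predictions(track: AnnotationTrack, path) -> None:
    """Write a track so that :func:`read_annotations` round-trips it exactly."""
    order = sorted(
        range(len(track.entries)),
        key=lambda i: (track.entries[i][1].start_frame, track.entries[i][1].end_frame),
    )
    cols: dict[str, list] = {
        "label": [track.entries[i][0] for i in order],
        "start_frame": [track.entries[i][1].start_frame for i in order],
        "end_frame": [track.entries[i][1].end_frame for i in order],
    }
    if track.scores is not None:
        cols["score"] = [track.scores[i] for i in order]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_skeletons(path) -> list[SkeletonFrame]:
    """Read a ``frame,joint_id,x,y`` table into per-frame joint sets."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["frame", "joint_id", "x", "y"], str(path))
    frames = []
    for f, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("joint_id")
        ids = grp["joint_id"].to_numpy()
        if len(ids) != N_JOINTS or not np.array_equal(ids, np.arange(1, N_JOINTS + 1)):
            raise DataError(f"{path}: frame {f} must carry joints 1..{N_JOINTS}")
        frames.append(SkeletonFrame(int(f), grp[["x", "y"]].to_numpy()))
    return frames


def write_skeletons(frames: list[SkeletonFrame], path) -> None:
    cols: dict[str, list] = {"frame": [], "joint_id": [], "x": [], "y": []}
    for fr in frames:
        for j in range(N_JOINTS):
            cols["frame"].append(fr.frame)
            cols["joint_id"].append(j + 1)
            cols["x"].append(float(fr.joints[j, 0]))
            cols["y"].append(float(fr.joints[j, 1]))
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_descriptors(path) -> dict[str, list[DescriptorSegment]]:
    """Read descriptor rows grouped into segments by (subject, interval).

    Returns a mapping ``subject_id -> segments``. Files without a
    ``subject_id`` column are returned under the single key ``""``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["start_frame", "end_frame"], str(path))
    dcols = [c for c in df.columns if c.startswith("d") and c[1:].isdigit()]
    if not dcols:
        raise FormatError(f"{path}: no descriptor columns d1..dD found")
    dcols = sorted(dcols, key=lambda c: int(c[1:]))
    has_subject = "subject_id" in df.columns
    out: dict[str, list[DescriptorSegment]] = {}
    keys = ["subject_id", "start_frame", "end_frame"] if has_subject else ["start_frame", "end_frame"]
    for key, grp in df.groupby(keys, sort=True):
        if has_subject:
            sid, s, e = str(key[0]), int(key[1]), int(key[2])
        else:
            sid, (s, e) = "", (int(key[0]), int(key[1]))
        seg = DescriptorSegment(FrameInterval(s, e), grp[dcols].to_numpy())
        out.setdefault(sid, []).append(seg)
    for segs in out.values():
        segs.sort(key=lambda s: (s.interval.start_frame, s.interval.end_frame))
    return out


def write_descriptors(segments_by_subject: dict[str, list[DescriptorSegment]], path) -> None:
    dims = {seg.dim for segs in segments_by_subject.values() for seg in segs if seg.n_rows}
    if len(dims) > 1:
        raise DataError(f"mixed descriptor dimensionalities {sorted(dims)}")
    dim = dims.pop() if dims else 1
    cols: dict[str, list] = {"subject_id": [], "start_frame": [], "end_frame": []}
    dcols = [f"d{i + 1}" for i in range(dim)]
    for c in dcols:
        cols[c] = []
    for sid in sorted(segments_by_subject):
        for seg in segments_by_subject[sid]:
            for row in seg.vectors:
                cols["subject_id"].append(sid)
                cols["start_frame"].append(seg.interval.start_frame)
                cols["end_frame"].append(seg.interval.end_frame)
                for c, v in zip(dcols, row):
                    cols[c].append(float(v))
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
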