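"""Primitive events and coarse activity discovery.

A trajectory is translated into primitive events (PEs) against one topology:
each consecutive point pair is a *Stay* (both points in the same region) or a
*Change* (region transition). Maximal runs of same-region Stay pairs merge
into one Stay event; a Change spans exactly the two frames of the transition.
The resulting events tile the frame span of the sequence.

Activity discovery happens only at the coarse level: every coarse PE becomes
a discovered activity (DA), the unit that is clipped, described and
recognized; mid/low PEs that temporally overlap the DA are attached as its
hierarchical children.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .scene_model import Topology, assign_points
from .trajectory_io import DescriptorSegment, FrameInterval, TrajectorySequence

STAY = "Stay"
CHANGE = "Change"


def type_key(kind: str, regions: tuple[int, ...]) -> str:
    """Canonical type label, e.g. ``Stay_2`` or ``Change_2_4``."""
    return "_".join([kind, *map(str, regions)])


@dataclass(frozen=True)
class PrimitiveEvent:
    kind: str                  # STAY or CHANGE
    regions: tuple[int, ...]   # (P,) for Stay, (P, Q) for Change
    level: str
    interval: FrameInterval
    fps: float

    def __post_init__(self) -> None:
        if self.kind == STAY and len(self.regions) != 1:
            raise DataError("Stay event needs exactly one region")
        if self.kind == CHANGE:
            if len(self.regions) != 2 or self.regions[0] == self.regions[1]:
                raise DataError("Change event needs two distinct regions")

    @property
    def type_key(self) -> str:
        return type_key(self.kind, self.regions)

    @property
    def duration_s(self) -> float:
        return self.interval.duration_s(self.fps)


@dataclass
class PESequence:
    level: str
    events: list[PrimitiveEvent]
    topology_ref: str = ""

    def __post_init__(self) -> None:
        for a, b in zip(self.events, self.events[1:]):
            if a.interval.end_frame > b.interval.start_frame:
                raise DataError("primitive events must be ordered and tiling")
            if a.kind == STAY and b.kind == STAY and a.regions == b.regions:
                raise DataError("consecutive Stay events must not share a region")

    @property
    def frame_range(self) -> FrameInterval | None:
        if not self.events:
            return None
        return FrameInterval(
            self.events[0].interval.start_frame, self.events[-1].interval.end_frame
        )


@dataclass
class DiscoveredActivity:
    """A coarse segment (maximal Stay run or single Change) plus children."""

    kind: str
    regions: tuple[int, ...]
    interval: FrameInterval
    fps: float
    children: dict[str, list[PrimitiveEvent]] = field(default_factory=dict)
    descriptor: DescriptorSegment | None = None
    descriptor_less: bool = True
    subject_id: str = ""

    @property
    def type_key(self) -> str:
        return type_key(self.kind, self.regions)

    @property
    def duration_s(self) -> float:
        return self.interval.duration_s(self.fps)


def overlaps(a: FrameInterval, b: FrameInterval) -> bool:
    """Temporal-overlap predicate linking levels of the hierarchy.

    True iff the closed intervals share at least one frame; equivalent to
    the four-clause disjunction over start/end orderings.
    """
    return a.overlaps(b)


def _absorb_short_runs(labels: np.ndarray, min_run: int) -> np.ndarray:
    """Merge label runs shorter than ``min_run`` points into the previous run
    (the following run at the sequence start); suppresses border jitter."""
    labels = labels.copy()
    while True:
        runs = []  # (start, stop, label)
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                runs.append((start, i, labels[start]))
                start = i
        short = [r for r in runs if r[1] - r[0] < min_run]
        if not short or len(runs) == 1:
            return labels
        for idx, (s, e, _) in enumerate(runs):
            if e - s < min_run:
                neighbor = runs[idx - 1][2] if idx > 0 else runs[idx + 1][2]
                labels[s:e] = neighbor
                break  # restart: merging may concatenate runs


def encode_primitive_events(
    seq: TrajectorySequence,
    topology: Topology,
    topology_ref: str = "",
    min_stay_frames: int = 1,
) -> PESequence:
    """Translate one sequence into primitive events at one topology level."""
    if len(seq) < 2:
        warnings.warn(
            f"sequence {seq.subject_id!r} has fewer than 2 points; no events",
            stacklevel=2,
        )
        return PESequence(topology.level, [], topology_ref)
    labels = assign_points(seq.xy, topology)
    if min_stay_frames > 1:
        labels = _absorb_short_runs(labels, min_stay_frames)
    frames = seq.frames
    events: list[PrimitiveEvent] = []
    run_start: int | None = None  # start frame of the current Stay run
    for i in range(len(labels) - 1):
        p, q = int(labels[i]), int(labels[i + 1])
        if p == q:
            if run_start is None:
                run_start = int(frames[i])
        else:
            if run_start is not None:
                events.append(
                    PrimitiveEvent(
                        STAY, (p,), topology.level,
                        FrameInterval(run_start, int(frames[i])), seq.fps,
                    )
                )
                run_start = None
            events.append(
                PrimitiveEvent(
                    CHANGE, (p, q), topology.level,
                    FrameInterval(int(frames[i]), int(frames[i + 1])), seq.fps,
                )
            )
    if run_start is not None:
        events.append(
            PrimitiveEvent(
                STAY, (int(labels[-1]),), topology.level,
                FrameInterval(run_start, int(frames[-1])), seq.fps,
            )
        )
    return PESequence(topology.level, events, topology_ref)


def discover_activities(
    coarse: PESequence, mid: PESequence, low: PESequence,
    subject_id: str = "",
) -> list[DiscoveredActivity]:
    """One DA per coarse PE, with overlapping mid/low PEs attached as children."""
    ranges = [s.frame_range for s in (coarse, mid, low)]
    if any(r is None for r in ranges):
        return []
    if len({(r.start_frame, r.end_frame) for r in ranges}) != 1:
        raise DataError(f"mismatched frame ranges across levels: {ranges}")
    das = []
    for pe in coarse.events:
        da = DiscoveredActivity(
            kind=pe.kind,
            regions=pe.regions,
            interval=pe.interval,
            fps=pe.fps,
            children={
                "mid": [e for e in mid.events if overlaps(e.interval, pe.interval)],
                "low": [e for e in low.events if overlaps(e.interval, pe.interval)],
            },
            subject_id=subject_id,
        )
        das.append(da)
    return das


def attach_descriptors(
    das: list[DiscoveredActivity], segments: list[DescriptorSegment]
) -> list[DiscoveredActivity]:
    """Attach to each DA the rows of every segment overlapping its interval."""
    dims = {s.dim for s in segments if s.n_rows}
    if len(dims) > 1:
        raise DataError(f"descriptor segments disagree on dimensionality: {sorted(dims)}")
    for da in das:
        rows = [
            s.vectors for s in segments
            if s.n_rows and overlaps(s.interval, da.interval)
        ]
        if rows:
            da.descriptor = DescriptorSegment(da.interval, np.vstack(rows))
            da.descriptor_less = False
        else:
            da.descriptor = None
            da.descriptor_less = True
    return das


def das_to_track(das: list[DiscoveredActivity]):
    """Export DAs as an annotation track labeled by type key."""
    from .trajectory_io import AnnotationTrack

    return AnnotationTrack([(da.type_key, da.interval) for da in das])
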