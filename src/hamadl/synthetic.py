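"""Synthetic smart-room scenarios with full ground truth.

The generator emulates what a person tracker delivers in an observation
room: a subject dwells at task stations (zones), producing smooth, zone-
concentrated position jitter (an Ornstein-Uhlenbeck process around the zone
center), and moves between stations either along a straight, noisy walk
("walk" transit) or with the tracker dropping the fast-moving target so the
trajectory simply resumes at the next zone ("gap" transit — missed
detections during quick traversal are common for RGBD trackers).

Each stay executes one activity class with a Gaussian duration law and a
class-conditional Gaussian descriptor cloud (a stand-in for dense-trajectory
/ HOG / HOF-style features, whose extraction from pixels is out of scope).
Skeletons are eight joints rigidly offset from the trajectory point plus a
class-specific oscillation — enough to make the geometric descriptor class-
informative without pretending biomechanical realism.

Ground truth labels stays with their class name and transit phases with
``Walk_<P>_<Q>`` so that every frame of the schedule is annotated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import DataError
from .trajectory_io import (
    AnnotationTrack,
    DescriptorSegment,
    FrameInterval,
    SkeletonFrame,
    TrajectorySequence,
    N_JOINTS,
)

# relative joint offsets (head, shoulders, hands, hips, feet), scene units
_JOINT_OFFSETS = 0.2 * np.array(
    [[0.0, 1.6], [-0.4, 1.2], [0.4, 1.2], [-0.6, 0.7],
     [0.6, 0.7], [-0.2, 0.0], [0.2, 0.0], [0.0, 0.8]]
)


@dataclass(frozen=True)
class ActivityClass:
    name: str
    home_zone: int
    duration_mean_s: float
    duration_std_s: float
    descriptor_mean: tuple[float, ...]
    descriptor_std: float = 1.0


@dataclass(frozen=True)
class ScenarioConfig:
    room_size: tuple[float, float]
    zones: tuple[tuple[tuple[float, float], float], ...]  # ((cx, cy), sigma)
    activity_classes: tuple[ActivityClass, ...]
    walk_speed: float = 1.4          # scene units / s
    path_noise: float = 0.05         # per-frame walk position noise (units)
    transit: str = "walk"            # "walk" | "gap"
    fps: float = 25.0
    n_sequences: int = 8
    n_activities: int = 6            # stays per sequence
    points_per_sequence: int | None = None  # if set, truncate to this many points
    descriptor_rate: float = 10.0    # descriptor rows per second of stay
    jitter_tau_s: float = 1.0        # OU time constant of dwell jitter
    min_stay_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.room_size
        for (cx, cy), sig in self.zones:
            if not (0 <= cx <= w and 0 <= cy <= h):
                raise DataError(f"zone center ({cx}, {cy}) outside room {self.room_size}")
            if sig <= 0:
                raise DataError("zone sigma must be > 0")
        if self.transit not in ("walk", "gap"):
            raise DataError(f"transit must be 'walk' or 'gap', got {self.transit!r}")
        for ac in self.activity_classes:
            if not 0 <= ac.home_zone < len(self.zones):
                raise DataError(f"class {ac.name!r} references unknown zone {ac.home_zone}")
            if ac.duration_mean_s <= 0:
                raise DataError("durations must be positive")
        centers = np.array([c for c, _ in self.zones])
        sigs = np.array([s for _, s in self.zones])
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = float(np.linalg.norm(centers[i] - centers[j]))
                if d < 3 * (sigs[i] + sigs[j]):
                    warnings.warn(
                        f"zones {i} and {j} are only {d:.2f} apart (< 3x sigma sum); "
                        "scenario may be unidentifiable",
                        stacklevel=2,
                    )

    @property
    def descriptor_dim(self) -> int:
        return len(self.activity_classes[0].descriptor_mean)

    @property
    def zone_centers(self) -> np.ndarray:
        return np.array([c for c, _ in self.zones], dtype=float)


@dataclass
class SequenceTruth:
    sequence: TrajectorySequence
    skeleton: list[SkeletonFrame]
    descriptor_segments: list[DescriptorSegment]
    annotations: AnnotationTrack
    zone_of_frame: dict[int, int]              # planted zone per stay frame
    transitions: list[FrameInterval]           # planted transit intervals


@dataclass
class ScenarioTruth:
    config: ScenarioConfig
    sequences: list[SequenceTruth] = field(default_factory=list)


def walk_label(p: int, q: int) -> str:
    return f"Walk_{p}_{q}"


def _ou_jitter(rng: np.random.Generator, n: int, sigma: float, rho: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck jitter, per-axis sd ``sigma``."""
    out = np.empty((n, 2))
    out[0] = rng.normal(0.0, sigma, 2)
    step_sd = sigma * np.sqrt(max(1.0 - rho * rho, 1e-12))
    steps = rng.normal(0.0, step_sd, (n - 1, 2)) if n > 1 else np.empty((0, 2))
    for i in range(1, n):
        out[i] = rho * out[i - 1] + steps[i - 1]
    return out


def _class_oscillation(class_idx: int, frames: np.ndarray, fps: float) -> np.ndarray:
    """(n, 8, 2) class-specific joint wiggle making poses class-informative."""
    amp = 0.05 * (1 + class_idx % 3)
    freq = 0.5 + 0.3 * class_idx
    t = frames / fps
    phases = np.linspace(0.0, np.pi, N_JOINTS)
    osc = amp * np.sin(2 * np.pi * freq * t[:, None] + phases[None, :])
    return np.stack([osc, 0.5 * osc], axis=2)


def simulate_scenario(config: ScenarioConfig) -> ScenarioTruth:
    """Generate all sequences of a scenario, deterministic given the config."""
    rng = np.random.default_rng(config.seed)
    fps = config.fps
    rho = float(np.exp(-1.0 / (config.jitter_tau_s * fps)))
    centers = config.zone_centers
    sigmas = [s for _, s in config.zones]
    classes = config.activity_classes
    truth = ScenarioTruth(config)
    for s in range(config.n_sequences):
        frames: list[int] = []
        xy: list[np.ndarray] = []
        entries: list[tuple[str, FrameInterval]] = []
        seg_list: list[DescriptorSegment] = []
        skel: list[SkeletonFrame] = []
        zone_of_frame: dict[int, int] = {}
        transitions: list[FrameInterval] = []
        cursor = 0
        cls_idx = int(rng.integers(len(classes)))
        n_done = 0
        target_pts = config.points_per_sequence
        while True:
            ac = classes[cls_idx]
            zone = ac.home_zone
            dur_s = max(config.min_stay_s, rng.normal(ac.duration_mean_s, ac.duration_std_s))
            nf = max(2, int(round(dur_s * fps)))
            stay_frames = np.arange(cursor, cursor + nf)
            jit = _ou_jitter(rng, nf, sigmas[zone], rho)
            stay_xy = centers[zone] + jit
            frames.extend(int(f) for f in stay_frames)
            xy.append(stay_xy)
            iv = FrameInterval(cursor, cursor + nf - 1)
            entries.append((ac.name, iv))
            for f in stay_frames:
                zone_of_frame[int(f)] = zone
            n_rows = max(1, int(round(dur_s * config.descriptor_rate)))
            mean = np.asarray(ac.descriptor_mean, dtype=float)
            seg_list.append(
                DescriptorSegment(iv, rng.normal(mean, ac.descriptor_std, (n_rows, mean.size)))
            )
            osc = _class_oscillation(classes.index(ac), stay_frames, fps)
            for i, f in enumerate(stay_frames):
                skel.append(
                    SkeletonFrame(int(f), stay_xy[i] + _JOINT_OFFSETS + osc[i])
                )
            cursor += nf
            n_done += 1
            total_pts = sum(len(a) for a in xy)
            if target_pts is not None:
                if total_pts >= target_pts:
                    break
            elif n_done >= config.n_activities:
                break
            # pick the next activity in a different zone when possible
            others = [i for i, c in enumerate(classes) if c.home_zone != zone]
            pool = others if others else list(range(len(classes)))
            nxt_idx = pool[int(rng.integers(len(pool)))]
            nxt_zone = classes[nxt_idx].home_zone
            dist = float(np.linalg.norm(centers[nxt_zone] - centers[zone]))
            wf = max(2, int(round(dist / config.walk_speed * fps)))
            transit_iv = FrameInterval(cursor, cursor + wf - 1)
            entries.append((walk_label(zone, nxt_zone), transit_iv))
            transitions.append(transit_iv)
            if config.transit == "walk":
                t = np.linspace(0.0, 1.0, wf)[:, None]
                path = centers[zone] * (1 - t) + centers[nxt_zone] * t
                path = path + rng.normal(0.0, config.path_noise, (wf, 2))
                walk_frames = np.arange(cursor, cursor + wf)
                frames.extend(int(f) for f in walk_frames)
                xy.append(path)
                for i, f in enumerate(walk_frames):
                    skel.append(SkeletonFrame(int(f), path[i] + _JOINT_OFFSETS))
            cursor += wf
            cls_idx = nxt_idx
        all_xy = np.vstack(xy)
        all_frames = np.array(frames, dtype=np.int64)
        if target_pts is not None and len(all_frames) > target_pts:
            all_xy = all_xy[:target_pts]
            all_frames = all_frames[:target_pts]
            last = int(all_frames[-1])
            entries = [
                (lab, FrameInterval(iv.start_frame, min(iv.end_frame, last)))
                for lab, iv in entries
                if iv.start_frame <= last
            ]
            transitions = [
                FrameInterval(iv.start_frame, min(iv.end_frame, last))
                for iv in transitions
                if iv.start_frame <= last
            ]
            skel = [fr for fr in skel if fr.frame <= last]
            seg_list = [
                DescriptorSegment(
                    FrameInterval(sg.interval.start_frame, min(sg.interval.end_frame, last)),
                    sg.vectors,
                )
                for sg in seg_list
                if sg.interval.start_frame <= last
            ]
            zone_of_frame = {f: z for f, z in zone_of_frame.items() if f <= last}
        truth.sequences.append(
            SequenceTruth(
                sequence=TrajectorySequence(f"seq{s:03d}", all_frames, all_xy, fps=fps),
                skeleton=skel,
                descriptor_segments=seg_list,
                annotations=AnnotationTrack(entries),
                zone_of_frame=zone_of_frame,
                transitions=transitions,
            )
        )
    return truth


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

def _unit_mean(dim: int, axis: int, scale: float = 6.0) -> tuple[float, ...]:
    v = np.zeros(dim)
    v[axis] = scale
    return tuple(v)


_D = 16
_ZONES3 = (((1.0, 1.0), 0.25), ((5.0, 1.0), 0.25), ((3.0, 4.0), 0.25))


def _fixture_registry() -> dict[str, ScenarioConfig]:
    easy3 = ScenarioConfig(
        room_size=(6.0, 5.0),
        zones=_ZONES3,
        activity_classes=(
            ActivityClass("Prepare Drink", 0, 30.0, 5.0, _unit_mean(_D, 0)),
            ActivityClass("Read Article", 1, 30.0, 5.0, _unit_mean(_D, 1)),
            ActivityClass("Answer Phone", 2, 30.0, 5.0, _unit_mean(_D, 2)),
        ),
    )
    zones3 = ScenarioConfig(
        room_size=(6.0, 5.0),
        zones=_ZONES3,
        activity_classes=easy3.activity_classes,
        transit="gap",
        n_sequences=5,
        points_per_sequence=2000,
    )
    twin = ScenarioConfig(
        room_size=(6.0, 5.0),
        zones=(((1.0, 1.0), 0.25), ((5.0, 1.0), 0.25)),
        activity_classes=(
            ActivityClass("Prepare Drink", 0, 30.0, 5.0, _unit_mean(_D, 0)),
            ActivityClass("Prepare Drug Box", 0, 30.0, 5.0, _unit_mean(_D, 1)),
            ActivityClass("Read Article", 1, 30.0, 5.0, _unit_mean(_D, 2)),
        ),
    )
    noisy = ScenarioConfig(
        room_size=(6.0, 5.0),
        zones=(((1.0, 1.0), 0.45), ((5.0, 1.0), 0.45), ((3.0, 4.0), 0.45)),
        activity_classes=easy3.activity_classes,
        path_noise=0.15,
    )
    return {"easy3": easy3, "zones3": zones3, "twin_zone": twin, "noisy": noisy}


def scenario_fixtures(name: str) -> ScenarioConfig:
    """Canned scenario configs: easy3, zones3, twin_zone, noisy."""
    registry = _fixture_registry()
    if name not in registry:
        raise LookupError(f"unknown fixture {name!r}; available: {sorted(registry)}")
    return registry[name]


def with_seed(config: ScenarioConfig, seed: int, **overrides) -> ScenarioConfig:
    """Copy of a config with a new seed (and optional field overrides)."""
    d = asdict(config)
    d["seed"] = seed
    d.update(overrides)
    d["activity_classes"] = tuple(
        ac if isinstance(ac, ActivityClass) else ActivityClass(**ac)
        for ac in d["activity_classes"]
    )
    d["zones"] = tuple((tuple(c), s) for c, s in d["zones"])
    d["room_size"] = tuple(d["room_size"])
    return ScenarioConfig(**d)
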