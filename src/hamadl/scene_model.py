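"""Multi-resolution scene topologies learned from trajectories.

A scene region is a Gaussian-modeled spatial zone ``SR ~ (mu, sigma)``
estimated from trajectory-point density. Regions are found by two-stage
clustering: stage 1 clusters each subject's own trajectory points (which
densifies candidate centers and damps the influence of stray points from any
single subject), stage 2 merges all subjects' stage-1 centers into the final
regions with k-means. The scene model holds three topologies — high, mid and
low abstraction — whose region counts default to ``k``, ``2k`` and ``3k``.

The number of coarse regions may be chosen automatically by sweeping k and
maximizing a spherical-Gaussian k-means BIC (the x-means criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import DataError, ParameterError
from .trajectory_io import TrajectoryPoint, TrajectorySequence

SIGMA_FLOOR = 1e-6  # scene units; avoids zero-variance degenerate regions
LEVELS = ("high", "mid", "low")

KMEANS_RESTARTS = 10
KMEANS_TOL = 1e-6
DEFAULT_K_STAGE1 = 8


def _kmeans(points: np.ndarray, k: int, seed: int) -> KMeans:
    return KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=KMEANS_RESTARTS,
        tol=KMEANS_TOL,
        random_state=seed,
    ).fit(points)


@dataclass(frozen=True)
class SceneRegion:
    region_id: int
    mu: np.ndarray      # (2,)
    sigma: np.ndarray   # (2,) per-axis standard deviation
    weight: float       # fraction of training points assigned

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma < 0):
            raise DataError(f"region {self.region_id}: sigma must be >= 0")
        if not 0.0 <= self.weight <= 1.0 + 1e-9:
            raise DataError(f"region {self.region_id}: weight outside [0, 1]")


@dataclass
class Topology:
    """A set of scene regions at one resolution level."""

    level: str
    regions: list[SceneRegion]

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise DataError(f"level must be one of {LEVELS}, got {self.level!r}")
        if not self.regions:
            raise DataError("a topology needs at least one region")
        ids = [r.region_id for r in self.regions]
        if ids != list(range(len(ids))):
            raise DataError("region ids must be unique and contiguous from 0")

    @property
    def k(self) -> int:
        return len(self.regions)

    @property
    def centers(self) -> np.ndarray:
        return np.stack([r.mu for r in self.regions])


@dataclass
class SceneModel:
    """Three topologies (high/mid/low) plus the training metadata."""

    topologies: dict[str, Topology]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.topologies) != set(LEVELS):
            raise DataError(f"scene model needs exactly the levels {LEVELS}")
        ks = [self.topologies[lvl].k for lvl in LEVELS]
        if not ks[0] <= ks[1] <= ks[2]:
            raise DataError(f"expected k_high <= k_mid <= k_low, got {ks}")

    def __getitem__(self, level: str) -> Topology:
        return self.topologies[level]

    def to_dict(self) -> dict:
        return {
            "levels": [
                {
                    "level": lvl,
                    "k": self.topologies[lvl].k,
                    "regions": [
                        {
                            "id": r.region_id,
                            "mu": [float(v) for v in r.mu],
                            "sigma": [float(v) for v in r.sigma],
                            "weight": float(r.weight),
                        }
                        for r in self.topologies[lvl].regions
                    ],
                }
                for lvl in LEVELS
            ],
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneModel":
        topologies = {}
        for lvl in d["levels"]:
            regions = [
                SceneRegion(r["id"], np.array(r["mu"]), np.array(r["sigma"]), r["weight"])
                for r in lvl["regions"]
            ]
            topologies[lvl["level"]] = Topology(lvl["level"], regions)
        return cls(topologies, meta=d.get("meta", {}))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_stage1(
    seq: TrajectorySequence, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cluster one subject's trajectory points.

    Returns ``(centers, labels, sigmas)`` where ``sigmas[j]`` is the per-axis
    standard deviation of the points assigned to center ``j``.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if len(seq) < k:
        raise ParameterError(
            f"subject {seq.subject_id!r} has {len(seq)} points, fewer than k={k}"
        )
    km = _kmeans(seq.xy, k, seed)
    sigmas = np.empty((k, 2))
    for j in range(k):
        member = seq.xy[km.labels_ == j]
        sigmas[j] = member.std(axis=0) if len(member) else 0.0
    return km.cluster_centers_, km.labels_, np.maximum(sigmas, 0.0)


def kmeans_bic(points: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Spherical-Gaussian BIC of a k-means partition (x-means form).

    The model is a mixture of k spherical Gaussians with a shared variance
    estimated from the within-cluster sum of squares; the parameter count is
    ``k (d + 1) + 1`` (centers, mixing weights, shared variance). Larger is
    better.
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    k = centers.shape[0]
    sse = 0.0
    for j in range(k):
        member = points[labels == j]
        if len(member):
            sse += ((member - centers[j]) ** 2).sum()
    var = sse / (d * max(n - k, 1))
    if var <= 0:
        return np.inf  # degenerate: all points on their centers
    ll = 0.0
    for j in range(k):
        nj = int((labels == j).sum())
        if nj > 0:
            ll += nj * np.log(nj / n)
    ll += -(n * d / 2.0) * np.log(2.0 * np.pi * var) - d * (n - k) / 2.0
    p = k * (d + 1) + 1
    return ll - (p / 2.0) * np.log(n)


def select_k_bic(
    points: np.ndarray, k_min: int, k_max: int, seed: int
) -> tuple[int, dict[int, float], bool]:
    """Choose the cluster count maximizing the k-means BIC over a range.

    Returns ``(k, trace, degenerate)``; ``degenerate`` flags an all-identical
    point set, for which k = 1 is returned without a sweep.
    """
    points = np.asarray(points, dtype=float)
    if k_min < 1 or k_max < k_min:
        raise ParameterError(f"invalid k range [{k_min}, {k_max}]")
    if len(points) <= k_max:
        raise ParameterError(f"need more than k_max={k_max} points, got {len(points)}")
    if np.allclose(points, points[0]):
        return 1, {1: np.inf}, True
    trace = {}
    for k in range(k_min, k_max + 1):
        km = _kmeans(points, k, seed)
        trace[k] = kmeans_bic(points, km.labels_, km.cluster_centers_)
    best = max(trace, key=lambda k: (trace[k], -k))
    return best, trace, False


def learn_topology(
    sequences: list[TrajectorySequence],
    k: int,
    seed: int,
    level: str = "high",
    k_stage1: int = DEFAULT_K_STAGE1,
) -> Topology:
    """Two-stage learning of one topology.

    Stage-1 centers from all subjects are re-clustered into ``k`` regions;
    each region's ``mu`` is the stage-2 centroid, its ``sigma`` the per-axis
    standard deviation of all trajectory points assigned transitively to it,
    and its weight the fraction of training points it owns.
    """
    if not sequences:
        raise ParameterError("need at least one sequence")
    centers_per_subject = []
    labels_per_subject = []
    for seq in sequences:
        ks = min(k_stage1, len(seq))
        c, lab, _ = cluster_stage1(seq, ks, seed)
        centers_per_subject.append(c)
        labels_per_subject.append(lab)
    all_centers = np.vstack(centers_per_subject)
    if len(all_centers) < k:
        raise ParameterError(
            f"only {len(all_centers)} stage-1 centers for k={k} regions"
        )
    km2 = _kmeans(all_centers, k, seed)

    # transitive assignment: point -> its stage-1 center -> stage-2 region
    n_total = 0
    member_points: list[list[np.ndarray]] = [[] for _ in range(k)]
    offset = 0
    for seq, c1, lab1 in zip(sequences, centers_per_subject, labels_per_subject):
        region_of_center = km2.labels_[offset:offset + len(c1)]
        offset += len(c1)
        point_region = region_of_center[lab1]
        for j in range(k):
            pts = seq.xy[point_region == j]
            if len(pts):
                member_points[j].append(pts)
        n_total += len(seq)

    regions = []
    for j in range(k):
        pts = np.vstack(member_points[j]) if member_points[j] else np.empty((0, 2))
        sigma = pts.std(axis=0) if len(pts) else np.zeros(2)
        regions.append(
            SceneRegion(
                region_id=j,
                mu=km2.cluster_centers_[j],
                sigma=np.maximum(sigma, SIGMA_FLOOR),
                weight=len(pts) / n_total,
            )
        )
    return Topology(level, regions)


def learn_scene_model(
    sequences: list[TrajectorySequence],
    k_high: int | str = "auto",
    multipliers: tuple[int, int] = (2, 3),
    seed: int = 0,
    k_stage1: int = DEFAULT_K_STAGE1,
    k_max_auto: int = 8,
) -> SceneModel:
    """Learn the three-level scene model.

    With ``k_high="auto"`` the coarse region count is selected by the BIC
    sweep over all trajectory points pooled across subjects.
    """
    meta: dict = {"seed": seed, "k_stage1": k_stage1, "multipliers": list(multipliers)}
    if k_high == "auto":
        all_points = np.vstack([s.xy for s in sequences])
        k_sel, trace, degenerate = select_k_bic(
            all_points, 1, min(k_max_auto, len(all_points) - 1), seed
        )
        meta["bic_trace"] = {int(k): float(v) for k, v in trace.items()}
        meta["bic_degenerate"] = degenerate
        k_high = k_sel
    k_high = int(k_high)
    if k_high < 1:
        raise ParameterError(f"k_high must be >= 1, got {k_high}")
    ks = {"high": k_high, "mid": multipliers[0] * k_high, "low": multipliers[1] * k_high}
    meta["k"] = ks
    topologies = {
        lvl: learn_topology(sequences, ks[lvl], seed, level=lvl, k_stage1=k_stage1)
        for lvl in LEVELS
    }
    return SceneModel(topologies, meta=meta)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def assign_region(point: TrajectoryPoint | np.ndarray, topology: Topology) -> int:
    """Nearest-center region of a single point (ties: lowest region id)."""
    xy = point.xy if isinstance(point, TrajectoryPoint) else np.asarray(point, dtype=float)
    d2 = ((topology.centers - xy) ** 2).sum(axis=1)
    return int(np.argmin(d2))  # argmin returns the first (lowest id) on ties


def assign_points(xy: np.ndarray, topology: Topology) -> np.ndarray:
    """Vectorized nearest-center assignment for an (n, 2) array."""
    xy = np.asarray(xy, dtype=float)
    d2 = ((xy[:, None, :] - topology.centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)
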