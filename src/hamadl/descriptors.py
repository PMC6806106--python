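"""Skeleton geometry features, per-region visual codebooks and histogram matching.

The geometric descriptor encodes body pose over a temporal sliding window:
for every ordered joint pair (i < j) and every lag within the window, the
Euclidean distance and the polar angle between the two joint positions are
computed. Rows are laid out as all distances followed by all angles, each
block in pair-major / lag-minor order; lags reaching before the first frame
are zero-padded so every row has the same width.

Codebooks are k-means codeword sets learned per scene region. A segment is
encoded by hard nearest-word assignment into a counting histogram; histogram
similarity uses the Bhattacharyya coefficient, turned into the Hellinger
distance ``sqrt(1 - BC)`` so that the minimum distance marks the most similar
codebook.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .errors import DataError, ParameterError
from .trajectory_io import DescriptorSegment, SkeletonFrame, N_JOINTS

DEFAULT_CODEBOOK_SIZES = (16, 32, 64, 128, 256, 512)

_PAIRS = [(i, j) for i in range(N_JOINTS) for j in range(i + 1, N_JOINTS)]


def geometric_features(frames: list[SkeletonFrame], w: int = 0) -> np.ndarray:
    """Distance/angle pose descriptor rows, one per frame.

    Row width is ``2 * C(8, 2) * (w + 1)``: for each pair (i, j), i < j, and
    lag ``l`` in ``0..w`` the distance between joint i at t and joint j at
    t - l, then the matching ``arctan2(dx, dy)`` angles in the same order.
    """
    if not frames:
        raise DataError("need at least one skeleton frame")
    if w < 0:
        raise ParameterError(f"window size must be >= 0, got {w}")
    J = np.stack([f.joints for f in frames])  # (T, 8, 2)
    T = J.shape[0]
    n_pairs = len(_PAIRS)
    fd = np.zeros((T, n_pairs, w + 1))
    fa = np.zeros((T, n_pairs, w + 1))
    for lag in range(w + 1):
        for p, (i, j) in enumerate(_PAIRS):
            t = np.arange(lag, T)
            d = J[t, i] - J[t - lag, j]
            fd[t, p, lag] = np.hypot(d[:, 0], d[:, 1])
            fa[t, p, lag] = np.arctan2(d[:, 0], d[:, 1])
    return np.concatenate([fd.reshape(T, -1), fa.reshape(T, -1)], axis=1)


@dataclass
class Codebook:
    region_id: int
    words: np.ndarray       # (size, D)
    norm_hist: np.ndarray   # (size,) normalized training-assignment histogram

    def __post_init__(self) -> None:
        self.words = np.atleast_2d(np.asarray(self.words, dtype=float))
        self.norm_hist = np.asarray(self.norm_hist, dtype=float)
        if self.norm_hist.shape != (self.size,):
            raise DataError("norm_hist length must equal codebook size")
        if abs(self.norm_hist.sum() - 1.0) > 1e-9:
            raise DataError("norm_hist must sum to 1")

    @property
    def size(self) -> int:
        return self.words.shape[0]

    @property
    def dim(self) -> int:
        return self.words.shape[1]

    def to_dict(self) -> dict:
        return {
            "region_id": self.region_id,
            "size": self.size,
            "words": self.words.tolist(),
            "norm_hist": self.norm_hist.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        return cls(d["region_id"], np.array(d["words"]), np.array(d["norm_hist"]))


@dataclass
class SegmentHistogram:
    counts: np.ndarray
    normalized: np.ndarray
    empty: bool = False

    @property
    def size(self) -> int:
        return self.counts.shape[0]


def learn_codebook(
    descriptors: np.ndarray, size: int, seed: int, region_id: int = 0
) -> Codebook:
    """k-means codewords plus the normalized training-assignment histogram."""
    descriptors = np.atleast_2d(np.asarray(descriptors, dtype=float))
    if descriptors.shape[0] < size:
        raise ParameterError(
            f"{descriptors.shape[0]} descriptor rows cannot support a codebook "
            f"of size {size}; use a smaller size"
        )
    km = KMeans(n_clusters=size, n_init=10, random_state=seed).fit(descriptors)
    counts = np.bincount(km.labels_, minlength=size).astype(float)
    return Codebook(region_id, km.cluster_centers_, counts / counts.sum())


def encode_histogram(segment: DescriptorSegment | np.ndarray, codebook: Codebook) -> SegmentHistogram:
    """Hard nearest-word assignment counts, normalized.

    An empty segment yields the uniform histogram flagged ``empty`` so that
    downstream scoring can neutralize the distance term.
    """
    vectors = segment.vectors if isinstance(segment, DescriptorSegment) else np.atleast_2d(segment)
    if vectors.size == 0:
        uniform = np.full(codebook.size, 1.0 / codebook.size)
        return SegmentHistogram(np.zeros(codebook.size), uniform, empty=True)
    if vectors.shape[1] != codebook.dim:
        raise DataError(
            f"descriptor dim {vectors.shape[1]} != codebook dim {codebook.dim}"
        )
    labels = np.argmin(cdist(vectors, codebook.words), axis=1)
    counts = np.bincount(labels, minlength=codebook.size).astype(float)
    return SegmentHistogram(counts, counts / counts.sum(), empty=False)


def bhattacharyya_coefficient(h: np.ndarray, v: np.ndarray) -> float:
    """``BC = sum_bins sqrt(h * v)`` for two normalized histograms."""
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    if h.shape != v.shape:
        raise DataError(f"histogram lengths differ: {h.shape} vs {v.shape}")
    return float(np.minimum(np.sqrt(h * v).sum(), 1.0))


def hellinger_distance(h: np.ndarray, v: np.ndarray) -> float:
    """``sqrt(1 - BC)``; 0 for identical histograms, 1 for disjoint support."""
    return float(np.sqrt(max(0.0, 1.0 - bhattacharyya_coefficient(h, v))))


def codebook_distance(
    h: SegmentHistogram, cb: Codebook, reference: np.ndarray | None = None
) -> float:
    """Bhattacharyya-based distance between a segment and a codebook.

    The segment's normalized assignment histogram is compared to the
    codebook's training-assignment histogram (or an explicit reference
    histogram encoded against the same codebook); lower is more similar.
    """
    ref = cb.norm_hist if reference is None else np.asarray(reference, dtype=float)
    if h.size != ref.shape[0]:
        raise DataError(f"histogram size {h.size} != codebook size {ref.shape[0]}")
    return hellinger_distance(h.normalized, ref)


def nearest_codebook(
    segment: DescriptorSegment, codebooks: list[Codebook]
) -> tuple[int, dict[int, float]]:
    """Encode against every codebook and return the minimum-distance region.

    Ties break toward the lowest region id.
    """
    if not codebooks:
        raise ParameterError("need at least one codebook")
    distances = {}
    for cb in codebooks:
        distances[cb.region_id] = codebook_distance(encode_histogram(segment, cb), cb)
    winner = min(sorted(distances), key=lambda r: distances[r])
    return winner, distances
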