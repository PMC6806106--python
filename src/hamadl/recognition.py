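"""MAP recognition of a test activity against trained HAMs.

A test DA is turned into a single-instance HAM and compared to every trained
model whose root type matches. The score is a recursive log-likelihood over
the tree: per matched node, a 0/1 type factor, an exponential duration factor
``exp(-|d* - mu_d| / sigma_d)`` and, at the root only, a one-hot descriptor
distance factor awarded to the model whose class histogram is Bhattacharyya-
closest to the test segment. Mismatches pay a small epsilon instead of a hard
zero so that partially matching trees remain comparable; the winner is the
argmax of ``log prior + log likelihood`` (MAP with priors taken as training
class frequencies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .descriptors import Codebook, encode_histogram, hellinger_distance
from .event_encoding import DiscoveredActivity
from .ham import HAMModel, HAMNode, build_neighborhood, cluster_nodes, fit_attributes

EPS = 1e-6  # score floor for type mismatches below the root
LOG_EPS = math.log(EPS)


@dataclass(frozen=True)
class NodeScore:
    type_match: int
    duration_term: float
    distance_term: float
    log_score: float


@dataclass
class RecognitionResult:
    ranked: list[tuple[str, float]]
    winner: str
    per_node_trace: dict[str, dict] = field(default_factory=dict)
    distance_ranking: dict[str, float] = field(default_factory=dict)

    @property
    def unknown(self) -> bool:
        return self.winner == "unknown"


def build_test_ham(da: DiscoveredActivity, fps: float) -> HAMNode:
    """Single-instance HAM tree of a test DA (exact durations, floored vars)."""
    return fit_attributes(cluster_nodes([build_neighborhood(da)]), fps)


def duration_term(test_duration: float, mu_d: float, sigma_d: float) -> float:
    """``exp(-|d* - mu_d| / sigma_d)``, bounded in (0, 1]."""
    return math.exp(-abs(test_duration - mu_d) / max(sigma_d, 1e-12))


def node_likelihood(
    model_node: HAMNode,
    test_node: HAMNode,
    is_root: bool = False,
    distance_winner: bool = False,
    has_distance: bool = False,
) -> NodeScore:
    """Three-factor likelihood of one test node under one model node."""
    type_match = 1 if model_node.node_type == test_node.node_type else 0
    dur = duration_term(test_node.mu_d, model_node.mu_d, model_node.sigma_d)
    if is_root and has_distance:
        dist = 1.0 if distance_winner else 0.0
    else:
        dist = 1.0
    product = type_match * dur * dist
    return NodeScore(type_match, dur, dist, math.log(max(product, EPS)))


def recursive_score(
    model: HAMModel,
    test_root: HAMNode,
    distance_winner: bool = False,
    has_distance: bool = False,
    trace: dict | None = None,
) -> float:
    """Level-by-level log-likelihood plus log prior.

    Nodes are paired across trees by (level, type key); test nodes with no
    same-type model node contribute ``log eps``, unmatched model nodes are
    ignored. The recursion covers all levels down to the leaves.
    """
    model_levels = model.nodes_by_level()
    total = math.log(max(model.prior, EPS))
    test_levels: dict[int, dict[str, HAMNode]] = {1: {}, 2: {}, 3: {}}
    for node in test_root.walk():
        test_levels[node.level][node.node_type] = node
    for level in (1, 2, 3):
        for tkey, tnode in test_levels[level].items():
            mnode = model_levels[level].get(tkey)
            if mnode is None:
                total += LOG_EPS
                if trace is not None:
                    trace.setdefault(level, {})[tkey] = None
                continue
            score = node_likelihood(
                mnode,
                tnode,
                is_root=(level == 1),
                distance_winner=distance_winner,
                has_distance=has_distance,
            )
            total += score.log_score
            if trace is not None:
                trace.setdefault(level, {})[tkey] = score
    return total


def distance_ranking(
    da: DiscoveredActivity,
    models: list[HAMModel],
    codebooks: dict[int, Codebook],
) -> tuple[str | None, dict[str, float]]:
    """Hellinger distance of the test segment to every model's class histogram.

    Returns the winning model id (``None`` when the DA carries no descriptors
    or no model exposes a class histogram) and all computed distances.
    """
    if da.descriptor_less or da.descriptor is None:
        return None, {}
    distances: dict[str, float] = {}
    hist_cache: dict[int, np.ndarray] = {}
    for m in models:
        if m.class_hist is None or m.codebook_ref is None:
            continue
        cb = codebooks.get(m.codebook_ref)
        if cb is None:
            continue
        if m.codebook_ref not in hist_cache:
            hist_cache[m.codebook_ref] = encode_histogram(da.descriptor, cb).normalized
        distances[m.model_id] = hellinger_distance(
            hist_cache[m.codebook_ref], m.class_hist
        )
    if not distances:
        return None, {}
    winner = min(sorted(distances), key=lambda mid: distances[mid])
    return winner, distances


def recognize(
    da: DiscoveredActivity,
    models: list[HAMModel],
    codebooks: dict[int, Codebook],
    fps: float | None = None,
    with_trace: bool = False,
) -> RecognitionResult:
    """MAP model of a test DA; ``winner="unknown"`` if no root type matches."""
    if not models:
        raise ValueError("need at least one trained model")
    fps = da.fps if fps is None else fps
    test_root = build_test_ham(da, fps)
    dist_winner, distances = distance_ranking(da, models, codebooks)
    has_distance = dist_winner is not None
    candidates = [m for m in models if m.root.node_type == test_root.node_type]
    if not candidates:
        return RecognitionResult([], "unknown", {}, distances)
    scored = []
    traces: dict[str, dict] = {}
    for m in candidates:
        trace: dict | None = {} if with_trace else None
        s = recursive_score(
            m,
            test_root,
            distance_winner=(m.model_id == dist_winner),
            has_distance=has_distance,
            trace=trace,
        )
        scored.append((m.model_id, s, m.prior))
        if with_trace:
            traces[m.model_id] = trace or {}
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    ranked = [(mid, s) for mid, s, _ in scored]
    return RecognitionResult(ranked, ranked[0][0], traces, distances)
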