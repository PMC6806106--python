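"""Hierarchical Activity Models (HAMs) built from unlabeled discovered activities.

A HAM is a three-level tree. The root represents a class of discovered
activities (e.g. all "Activity 1 in Zone 2" instances); deeper levels group
the mid- and low-resolution primitive events of those instances by type, so
one node stands for all same-type primitives observed across training
instances. Nodes carry Gaussian duration attributes, plus *mixture* (how much
of a node's span each child type occupies) and *timelapse* (duration law of
each child type) statistics describing sub-structure.

Model classes are themselves found without labels: Stay activities inside one
scene region are sub-clustered by their codebook histograms (so two different
actions performed at the same place can be told apart), and each directed
region transition forms its own class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .descriptors import Codebook, encode_histogram
from .event_encoding import CHANGE, STAY, DiscoveredActivity, PrimitiveEvent, overlaps
from .scene_model import select_k_bic
from .trajectory_io import FrameInterval

LEVEL_OF = {"root": 1, "mid": 2, "low": 3}


@dataclass
class Neighborhood:
    """Recursive link structure of one DA: (mid PE, overlapping low PEs)."""

    root_type: str
    root_interval: FrameInterval
    fps: float
    entries: list[tuple[PrimitiveEvent, list[PrimitiveEvent]]]


def build_neighborhood(da: DiscoveredActivity) -> Neighborhood:
    """Nest a DA's children: each mid PE with the low PEs overlapping it."""
    mids = da.children.get("mid", [])
    lows = da.children.get("low", [])
    entries = [
        (m, [l for l in lows if overlaps(l.interval, m.interval)]) for m in mids
    ]
    return Neighborhood(da.type_key, da.interval, da.fps, entries)


@dataclass(eq=False)
class HAMNode:
    """One node of the activity tree: all same-type primitives at one level."""

    node_type: str
    level: int  # 1 (root), 2, 3
    instances: list[tuple[int, FrameInterval]] = field(default_factory=list)
    mu_d: float = 0.0
    sigma_d2: float = 0.0
    parent: "HAMNode | None" = None
    children: list["HAMNode"] = field(default_factory=list)
    mixture: dict[str, tuple[float, float]] = field(default_factory=dict)
    timelapse: dict[str, tuple[float, float]] = field(default_factory=dict)
    link_counts: dict[str, int] = field(default_factory=dict)

    @property
    def sigma_d(self) -> float:
        return float(np.sqrt(self.sigma_d2))

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_dict(self) -> dict:
        return {
            "node_type": self.node_type,
            "level": self.level,
            "n_instances": len(self.instances),
            "instances": [[i, iv.start_frame, iv.end_frame] for i, iv in self.instances],
            "duration": {"mu": self.mu_d, "sigma2": self.sigma_d2},
            "mixture": {k: list(v) for k, v in sorted(self.mixture.items())},
            "timelapse": {k: list(v) for k, v in sorted(self.timelapse.items())},
            "link_counts": dict(sorted(self.link_counts.items())),
            "children": [c.to_dict() for c in self.children],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HAMNode":
        node = cls(
            node_type=d["node_type"],
            level=d["level"],
            instances=[(i, FrameInterval(s, e)) for i, s, e in d["instances"]],
            mu_d=d["duration"]["mu"],
            sigma_d2=d["duration"]["sigma2"],
            mixture={k: tuple(v) for k, v in d["mixture"].items()},
            timelapse={k: tuple(v) for k, v in d["timelapse"].items()},
            link_counts=dict(d["link_counts"]),
        )
        for cd in d["children"]:
            child = cls.from_dict(cd)
            child.parent = node
            node.children.append(child)
        return node


@dataclass(eq=False)
class HAMModel:
    model_id: str
    root: HAMNode
    prior: float
    codebook_ref: int | None = None
    class_hist: np.ndarray | None = None
    n_instances: int = 0
    degenerate: bool = False

    def nodes_by_level(self) -> dict[int, dict[str, HAMNode]]:
        out: dict[int, dict[str, HAMNode]] = {1: {}, 2: {}, 3: {}}
        for node in self.root.walk():
            out[node.level][node.node_type] = node
        return out

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "prior": self.prior,
            "codebook_ref": self.codebook_ref,
            "class_hist": None if self.class_hist is None else [float(v) for v in self.class_hist],
            "n_instances": self.n_instances,
            "degenerate": self.degenerate,
            "tree": self.root.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HAMModel":
        return cls(
            model_id=d["model_id"],
            root=HAMNode.from_dict(d["tree"]),
            prior=d["prior"],
            codebook_ref=d["codebook_ref"],
            class_hist=None if d["class_hist"] is None else np.array(d["class_hist"]),
            n_instances=d["n_instances"],
            degenerate=d["degenerate"],
        )


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def cluster_nodes(neighborhoods: list[Neighborhood]) -> HAMNode:
    """Group same-type primitives of all instances into one node per level.

    Level-2 and level-3 nodes are keyed purely by primitive type; a level-3
    node's parent is the level-2 node it is most often linked with in the
    neighborhoods (majority of overlap links, ties to the earlier node), and
    the full link counts are retained in the node association.
    """
    if not neighborhoods:
        raise ValueError("need at least one training instance")
    root_types = {n.root_type for n in neighborhoods}
    if len(root_types) != 1:
        raise ValueError(f"instances of one model class must share a type, got {root_types}")
    root = HAMNode(node_type=root_types.pop(), level=1)
    mid_nodes: dict[str, HAMNode] = {}
    low_nodes: dict[str, HAMNode] = {}
    links: dict[tuple[str, str], int] = {}
    for idx, nb in enumerate(neighborhoods):
        root.instances.append((idx, nb.root_interval))
        seen_low: set[PrimitiveEvent] = set()
        for mid_pe, low_pes in nb.entries:
            mnode = mid_nodes.setdefault(mid_pe.type_key, HAMNode(mid_pe.type_key, 2))
            mnode.instances.append((idx, mid_pe.interval))
            for low_pe in low_pes:
                lnode = low_nodes.setdefault(low_pe.type_key, HAMNode(low_pe.type_key, 3))
                if low_pe not in seen_low:
                    # a low PE overlapping several mid PEs is one member, not
                    # one per link
                    seen_low.add(low_pe)
                    lnode.instances.append((idx, low_pe.interval))
                links[(mid_pe.type_key, low_pe.type_key)] = (
                    links.get((mid_pe.type_key, low_pe.type_key), 0) + 1
                )
    mid_order = list(mid_nodes)
    for key in mid_order:
        node = mid_nodes[key]
        node.parent = root
        root.children.append(node)
    for lkey, lnode in low_nodes.items():
        counts = {mkey: links.get((mkey, lkey), 0) for mkey in mid_order}
        lnode.link_counts = {k: v for k, v in counts.items() if v}
        best = max(mid_order, key=lambda mkey: (counts[mkey], -mid_order.index(mkey)))
        lnode.parent = mid_nodes[best]
        mid_nodes[best].children.append(lnode)
    return root


def sigma_floor2(fps: float) -> float:
    """Variance floor: one frame squared, in seconds^2."""
    return (1.0 / fps) ** 2


def fit_attributes(root: HAMNode, fps: float) -> HAMNode:
    """Fit duration, mixture and timelapse Gaussians on a built skeleton.

    Durations are interval lengths (end - start frames) in seconds; variances
    are population variances with a one-frame floor. Mixture is, per
    instance, the fraction of the node's member span occupied by child
    primitives of each type; timelapse is the duration law of each child
    type's members.
    """
    floor = sigma_floor2(fps)
    for node in root.walk():
        durs = np.array([iv.length / fps for _, iv in node.instances], dtype=float)
        if durs.size:
            node.mu_d = float(durs.mean())
            node.sigma_d2 = float(max(durs.var(), floor))
        else:
            node.mu_d, node.sigma_d2 = 0.0, floor
        node.mixture = {}
        node.timelapse = {}
        if not node.children:
            continue
        span_by_inst: dict[int, int] = {}
        parent_ivs: dict[int, list[FrameInterval]] = {}
        for idx, iv in node.instances:
            span_by_inst[idx] = span_by_inst.get(idx, 0) + iv.length
            parent_ivs.setdefault(idx, []).append(iv)
        for child in node.children:
            cover: dict[int, int] = {}
            cdurs = []
            for idx, iv in child.instances:
                # only the part of the child lying inside the parent's span
                # counts toward composition (children are linked by overlap,
                # not containment)
                inside = sum(
                    max(0, min(iv.end_frame, p.end_frame) - max(iv.start_frame, p.start_frame))
                    for p in parent_ivs.get(idx, [])
                )
                cover[idx] = cover.get(idx, 0) + inside
                cdurs.append(iv.length / fps)
            fracs = np.array(
                [cover.get(idx, 0) / span for idx, span in span_by_inst.items() if span > 0],
                dtype=float,
            )
            if fracs.size:
                node.mixture[child.node_type] = (
                    float(fracs.mean()),
                    float(max(fracs.var(), floor)),
                )
            cdurs = np.array(cdurs, dtype=float)
            node.timelapse[child.node_type] = (
                float(cdurs.mean()),
                float(max(cdurs.var(), floor)),
            )
    return root


# ---------------------------------------------------------------------------
# unsupervised model classes
# ---------------------------------------------------------------------------

def stay_model_id(region: int, j: int) -> str:
    return f"Activity {j} in Zone {region}"


def change_model_id(p: int, q: int) -> str:
    return f"Transition {p}->{q}"


def discover_model_classes(
    das: list[DiscoveredActivity],
    codebooks: dict[int, Codebook],
    per_region_k: int | str = "auto",
    seed: int = 0,
    max_classes: int = 4,
) -> list[str]:
    """Assign every DA to a model class, without labels.

    Change DAs form one class per directed region pair. Stay DAs in region P
    are sub-clustered by their encoded descriptor histograms (BIC-selected k
    in auto mode); regions without descriptors fall back to a single
    global-motion class. Cluster indices are renumbered by order of first
    appearance so the assignment is deterministic.
    """
    classes: list[str | None] = [None] * len(das)
    stay_by_region: dict[int, list[int]] = {}
    for i, da in enumerate(das):
        if da.kind == CHANGE:
            classes[i] = change_model_id(*da.regions)
        else:
            stay_by_region.setdefault(da.regions[0], []).append(i)
    for region, idxs in sorted(stay_by_region.items()):
        cb = codebooks.get(region)
        with_desc = [i for i in idxs if not das[i].descriptor_less]
        if cb is None or not with_desc:
            for i in idxs:
                classes[i] = stay_model_id(region, 0)
            continue
        hists = np.stack(
            [encode_histogram(das[i].descriptor, cb).normalized for i in with_desc]
        )
        if per_region_k == "auto":
            k_hi = min(max_classes, len(with_desc) - 1)
            if k_hi < 1:
                k = 1
            else:
                k, _, _ = select_k_bic(hists, 1, k_hi, seed)
        else:
            k = min(int(per_region_k), len(with_desc))
        if k == 1:
            labels = np.zeros(len(with_desc), dtype=int)
        else:
            from sklearn.cluster import KMeans

            labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(hists)
        # renumber by first appearance for determinism
        remap: dict[int, int] = {}
        for lab in labels:
            if int(lab) not in remap:
                remap[int(lab)] = len(remap)
        for i, lab in zip(with_desc, labels):
            classes[i] = stay_model_id(region, remap[int(lab)])
        if len(with_desc) < len(idxs):
            # descriptor-less stays join the region's most frequent class
            counts = np.bincount([remap[int(l)] for l in labels])
            majority = int(np.argmax(counts))
            for i in idxs:
                if classes[i] is None:
                    classes[i] = stay_model_id(region, majority)
    return [c for c in classes]  # type: ignore[misc]


def train_models(
    das: list[DiscoveredActivity],
    classes: list[str],
    codebooks: dict[int, Codebook],
    fps: float,
) -> list[HAMModel]:
    """One HAM per model class; priors are class frequencies in training."""
    if len(das) != len(classes):
        raise ValueError("classes must cover all DAs")
    groups: dict[str, list[DiscoveredActivity]] = {}
    for da, cls_name in zip(das, classes):
        groups.setdefault(cls_name, []).append(da)
    models = []
    for cls_name in sorted(groups):
        members = groups[cls_name]
        if not members:
            warnings.warn(f"model class {cls_name!r} has no members; skipped", stacklevel=2)
            continue
        root = fit_attributes(cluster_nodes([build_neighborhood(d) for d in members]), fps)
        region = members[0].regions[0]
        cb = codebooks.get(region)
        class_hist = None
        if cb is not None:
            hists = [
                encode_histogram(d.descriptor, cb).normalized
                for d in members
                if not d.descriptor_less
            ]
            if hists:
                mean_hist = np.mean(hists, axis=0)
                class_hist = mean_hist / mean_hist.sum()
        models.append(
            HAMModel(
                model_id=cls_name,
                root=root,
                prior=len(members) / len(das),
                codebook_ref=region if cb is not None else None,
                class_hist=class_hist,
                n_instances=len(members),
                degenerate=len(members) < 2,
            )
        )
    return models
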