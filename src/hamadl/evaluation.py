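"""Correspondence-matrix mapping and detection / frame-wise metrics.

Unsupervised output carries internal labels ("Activity 1 in Zone 2"), so
before scoring, recognized labels are mapped one-to-one onto ground-truth
labels by maximizing total frame co-occurrence (Hungarian assignment on the
correspondence matrix). Detection metrics count a ground-truth interval as a
true positive when a same-mapped-label prediction covers strictly more than
``overlap_frac`` (default 80%) of it; frame metrics report frame accuracy
(FA1), the mean per-class F-score and the mean per-class intersection over
union of predicted vs ground-truth frame sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .trajectory_io import AnnotationTrack, FrameInterval

NEUTRAL_LABEL = "Neutral"
UNMAPPED = "none"


@dataclass
class CorrespondenceMatrix:
    rows: list[str]            # recognized-activity labels
    cols: list[str]            # ground-truth labels
    counts: np.ndarray         # frame co-occurrences

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.rows), len(self.cols)):
            raise ValueError("counts shape must match label lists")


@dataclass
class MetricsReport:
    per_class: dict[str, dict[str, float]]
    precision: float
    recall: float
    f_score: float
    frame_accuracy: float
    iou: float
    mapping: dict[str, str]
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "frame_accuracy": self.frame_accuracy,
            "iou": self.iou,
            "mapping": self.mapping,
            "notes": self.notes,
        }


def track_frame_labels(track: AnnotationTrack) -> dict[int, str]:
    """Per-frame labels of a track; on shared boundary frames the earlier
    interval wins (deterministic frame accounting)."""
    labels: dict[int, str] = {}
    for lab, iv in sorted(track.entries, key=lambda e: (e[1].start_frame, e[1].end_frame)):
        for f in range(iv.start_frame, iv.end_frame + 1):
            labels.setdefault(f, lab)
    return labels


def correspondence_matrix(
    pred: AnnotationTrack, gt: AnnotationTrack
) -> CorrespondenceMatrix:
    """Frame co-occurrence counts between predicted and ground-truth labels."""
    return pooled_correspondence_matrix([(pred, gt)])


def pooled_correspondence_matrix(
    pairs: list[tuple[AnnotationTrack, AnnotationTrack]]
) -> CorrespondenceMatrix:
    """Co-occurrence counts summed over several (pred, gt) track pairs."""
    rows = sorted({lab for p, _ in pairs for lab in p.labels})
    cols = sorted({lab for _, g in pairs for lab in g.labels})
    if not rows or not cols:
        warnings.warn("empty track(s): correspondence matrix is empty", stacklevel=2)
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    ri = {lab: i for i, lab in enumerate(rows)}
    ci = {lab: j for j, lab in enumerate(cols)}
    for pred, gt in pairs:
        pl = track_frame_labels(pred)
        gl = track_frame_labels(gt)
        for f, lab in pl.items():
            g = gl.get(f)
            if g is not None:
                counts[ri[lab], ci[g]] += 1
    return CorrespondenceMatrix(rows, cols, counts)


def map_labels(cor: CorrespondenceMatrix) -> dict[str, str]:
    """Maximum-total-co-occurrence one-to-one mapping RA -> GT.

    Recognized labels left without a partner map to ``"none"``.
    """
    mapping = {lab: UNMAPPED for lab in cor.rows}
    if cor.counts.size == 0:
        return mapping
    row_ind, col_ind = linear_sum_assignment(-cor.counts)
    for i, j in zip(row_ind, col_ind):
        if cor.counts[i, j] > 0:
            mapping[cor.rows[i]] = cor.cols[j]
    return mapping


def apply_mapping(track: AnnotationTrack, mapping: dict[str, str]) -> AnnotationTrack:
    return AnnotationTrack(
        [(mapping.get(lab, UNMAPPED), iv) for lab, iv in track.entries],
        scores=track.scores,
    )


def _interval_overlap(a: FrameInterval, b: FrameInterval) -> int:
    return a.intersection_frames(b)


def detection_metrics(
    pred: AnnotationTrack,
    gt: AnnotationTrack,
    mapping: dict[str, str],
    overlap_frac: float = 0.8,
) -> dict[str, dict[str, float]]:
    """Interval-level precision/recall/F per class under the overlap rule.

    A ground-truth interval is a TP when its greedily matched prediction
    (same mapped label, matched by descending overlap, one GT per
    prediction) covers strictly more than ``overlap_frac`` of its frames.
    """
    if not 0.0 < overlap_frac <= 1.0:
        raise ValueError(f"overlap_frac must be in (0, 1], got {overlap_frac}")
    mapped = apply_mapping(pred, mapping)
    out: dict[str, dict[str, float]] = {}
    for cls in sorted({lab for lab, _ in gt.entries}):
        gt_ivs = [iv for lab, iv in gt.entries if lab == cls]
        pred_ivs = [iv for lab, iv in mapped.entries if lab == cls]
        cand = sorted(
            (
                (_interval_overlap(p, g), pi, gi)
                for pi, p in enumerate(pred_ivs)
                for gi, g in enumerate(gt_ivs)
                if _interval_overlap(p, g) > 0
            ),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        used_p: set[int] = set()
        used_g: set[int] = set()
        tp = 0
        for ov, pi, gi in cand:
            if pi in used_p or gi in used_g:
                continue
            used_p.add(pi)
            used_g.add(gi)
            if ov > overlap_frac * gt_ivs[gi].n_frames:
                tp += 1
        fn = len(gt_ivs) - tp
        fp = len(pred_ivs) - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        out[cls] = {
            "tp": float(tp), "fp": float(fp), "fn": float(fn),
            "precision": precision, "recall": recall, "f_score": f,
        }
    return out


def frame_metrics(
    pred: AnnotationTrack,
    gt: AnnotationTrack,
    mapping: dict[str, str],
    neutral_label: str = NEUTRAL_LABEL,
    include_neutral_in_fa: bool = True,
) -> tuple[float, float, float, dict[str, dict[str, float]]]:
    """FA1, mean per-class F-score and mean IoU over one (pred, gt) pair."""
    return pooled_frame_metrics(
        [(pred, gt)], mapping,
        neutral_label=neutral_label,
        include_neutral_in_fa=include_neutral_in_fa,
    )


def pooled_frame_metrics(
    pairs: list[tuple[AnnotationTrack, AnnotationTrack]],
    mapping: dict[str, str],
    neutral_label: str = NEUTRAL_LABEL,
    include_neutral_in_fa: bool = True,
) -> tuple[float, float, float, dict[str, dict[str, float]]]:
    """Frame metrics with counts pooled over several track pairs.

    Evaluated frames are those labeled in the ground truth. The neutral /
    background class, when present, is excluded from the per-class averages
    but (by default) still counted in the FA1 denominator.
    """
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    n_eval = 0
    n_correct = 0
    classes: set[str] = set()
    for pred, gt in pairs:
        pl = track_frame_labels(apply_mapping(pred, mapping))
        gl = track_frame_labels(gt)
        for f, g in gl.items():
            p = pl.get(f)
            if not include_neutral_in_fa and g == neutral_label:
                pass
            else:
                n_eval += 1
                if p == g:
                    n_correct += 1
            classes.add(g)
            if p is not None:
                classes.add(p)
            if p == g:
                tp[g] = tp.get(g, 0) + 1
            else:
                fn[g] = fn.get(g, 0) + 1
                if p is not None:
                    fp[p] = fp.get(p, 0) + 1
    classes.discard(UNMAPPED)
    avg_classes = sorted(c for c in classes if c != neutral_label)
    per_class: dict[str, dict[str, float]] = {}
    f_sum = 0.0
    iou_sum = 0.0
    for c in avg_classes:
        tpc, fpc, fnc = tp.get(c, 0), fp.get(c, 0), fn.get(c, 0)
        prec = tpc / (tpc + fpc) if tpc + fpc else 0.0
        rec = tpc / (tpc + fnc) if tpc + fnc else 0.0
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        iou = tpc / (tpc + fpc + fnc) if tpc + fpc + fnc else 0.0
        per_class[c] = {"precision": prec, "recall": rec, "f_score": f, "iou": iou}
        f_sum += f
        iou_sum += iou
    n_cls = len(avg_classes)
    fa1 = n_correct / n_eval if n_eval else 0.0
    return (
        fa1,
        f_sum / n_cls if n_cls else 0.0,
        iou_sum / n_cls if n_cls else 0.0,
        per_class,
    )


def boundary_match_rate(
    boundaries: list[int],
    transitions: list[FrameInterval],
    tol_frames: int = 12,
) -> float:
    """Fraction of segment boundaries lying within ``tol_frames`` of a
    transition interval (distance 0 when the boundary falls inside one)."""
    if not boundaries:
        return 0.0
    hits = 0
    for b in boundaries:
        point = FrameInterval(b, b)
        if any(point.distance_frames(t) <= tol_frames for t in transitions):
            hits += 1
    return hits / len(boundaries)


def segment_boundaries(track_or_intervals) -> list[int]:
    """Interior boundary frames of a tiling segmentation (endpoints of the
    whole timeline excluded)."""
    if isinstance(track_or_intervals, AnnotationTrack):
        ivs = [iv for _, iv in track_or_intervals.entries]
    else:
        ivs = list(track_or_intervals)
    if len(ivs) < 2:
        return []
    ivs = sorted(ivs, key=lambda iv: iv.start_frame)
    bounds: list[int] = []
    for a, b in zip(ivs, ivs[1:]):
        bounds.append(b.start_frame)
    return bounds


def evaluate_tracks(
    pairs: list[tuple[AnnotationTrack, AnnotationTrack]],
    overlap_frac: float = 0.8,
    neutral_label: str = NEUTRAL_LABEL,
    include_neutral_in_fa: bool = True,
) -> MetricsReport:
    """Full evaluation: mapping, detection metrics and frame metrics."""
    cor = pooled_correspondence_matrix(pairs)
    mapping = map_labels(cor)
    det: dict[str, dict[str, float]] = {}
    tp = fp = fn = 0.0
    for pred, gt in pairs:
        for cls, m in detection_metrics(pred, gt, mapping, overlap_frac).items():
            acc = det.setdefault(cls, {"tp": 0.0, "fp": 0.0, "fn": 0.0})
            for k in ("tp", "fp", "fn"):
                acc[k] += m[k]
    per_class: dict[str, dict[str, float]] = {}
    p_sum = r_sum = f_sum = 0.0
    eval_cls = [c for c in sorted(det) if c != neutral_label]
    for cls in eval_cls:
        tpc, fpc, fnc = det[cls]["tp"], det[cls]["fp"], det[cls]["fn"]
        prec = tpc / (tpc + fpc) if tpc + fpc else 0.0
        rec = tpc / (tpc + fnc) if tpc + fnc else 0.0
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[cls] = {
            "tp": tpc, "fp": fpc, "fn": fnc,
            "precision": prec, "recall": rec, "f_score": f,
        }
        p_sum += prec
        r_sum += rec
        f_sum += f
    n = len(eval_cls)
    fa1, frame_f, iou, frame_per_class = pooled_frame_metrics(
        pairs, mapping,
        neutral_label=neutral_label,
        include_neutral_in_fa=include_neutral_in_fa,
    )
    for cls, m in frame_per_class.items():
        per_class.setdefault(cls, {}).update({f"frame_{k}": v for k, v in m.items()})
    return MetricsReport(
        per_class=per_class,
        precision=p_sum / n if n else 0.0,
        recall=r_sum / n if n else 0.0,
        f_score=f_sum / n if n else 0.0,
        frame_accuracy=fa1,
        iou=iou,
        mapping=mapping,
        notes={
            "overlap_frac": overlap_frac,
            "neutral_label": neutral_label,
            "include_neutral_in_fa": include_neutral_in_fa,
            "frame_f_score": frame_f,
        },
    )
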