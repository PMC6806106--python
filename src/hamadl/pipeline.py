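"""End-to-end training and detection flow.

Training: learn the three-level scene model from all training trajectories,
discover activities per sequence, learn one codebook per coarse region from
the descriptor rows observed there, sub-cluster stay activities into model
classes, and fit one HAM per class. Detection replays the same encoding on
unseen sequences and recognizes each closed DA by MAP score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from .config import MODEL_SCHEMA_VERSION, PipelineConfig
from .descriptors import Codebook, learn_codebook
from .errors import DataError
from .event_encoding import (
    STAY,
    DiscoveredActivity,
    attach_descriptors,
    discover_activities,
    encode_primitive_events,
)
from .ham import HAMModel, discover_model_classes, train_models
from .scene_model import SceneModel, learn_scene_model
from .trajectory_io import AnnotationTrack, DescriptorSegment, TrajectorySequence


@dataclass
class TrainedModel:
    """Bundle of everything detection needs, serializable to one JSON file."""

    scene_model: SceneModel
    codebooks: dict[int, Codebook]
    models: list[HAMModel]
    config: PipelineConfig
    meta: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "scene_model": self.scene_model.to_dict(),
            "codebooks": [self.codebooks[r].to_dict() for r in sorted(self.codebooks)],
            "models": [m.to_dict() for m in self.models],
            "config": self.config.to_dict(),
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TrainedModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise DataError(
                f"model file schema {doc.get('schema_version')} != {MODEL_SCHEMA_VERSION}"
            )
        return cls(
            scene_model=SceneModel.from_dict(doc["scene_model"]),
            codebooks={cb["region_id"]: Codebook.from_dict(cb) for cb in doc["codebooks"]},
            models=[HAMModel.from_dict(m) for m in doc["models"]],
            config=PipelineConfig.from_dict(doc["config"]),
            meta=doc.get("meta", {}),
        )


def sequence_das(
    seq: TrajectorySequence,
    scene_model: SceneModel,
    segments: list[DescriptorSegment] | None = None,
    min_stay_frames: int = 1,
) -> list[DiscoveredActivity]:
    """Encode one sequence at all three levels and discover its activities."""
    pes = {
        lvl: encode_primitive_events(
            seq, scene_model[lvl], topology_ref=lvl, min_stay_frames=min_stay_frames
        )
        for lvl in ("high", "mid", "low")
    }
    das = discover_activities(pes["high"], pes["mid"], pes["low"], subject_id=seq.subject_id)
    attach_descriptors(das, segments or [])
    return das


def train(
    sequences: list[TrajectorySequence],
    descriptors_by_subject: dict[str, list[DescriptorSegment]] | None = None,
    config: PipelineConfig | None = None,
) -> TrainedModel:
    """Learn scene model, codebooks and HAMs from unlabeled training data."""
    config = config or PipelineConfig()
    descriptors_by_subject = descriptors_by_subject or {}
    if not sequences:
        raise DataError("no training sequences")
    if not descriptors_by_subject:
        warnings.warn(
            "no descriptors supplied: training global-motion-only models",
            stacklevel=2,
        )
    scene = learn_scene_model(
        sequences,
        k_high=config.k_high,
        multipliers=config.multipliers,
        seed=config.seed,
        k_stage1=config.k_stage1,
        k_max_auto=config.k_max_auto,
    )
    das: list[DiscoveredActivity] = []
    for seq in sequences:
        segs = descriptors_by_subject.get(seq.subject_id) or descriptors_by_subject.get("")
        das.extend(sequence_das(seq, scene, segs, config.min_stay_frames))

    # one codebook per coarse region, from the stay DAs observed there
    codebooks: dict[int, Codebook] = {}
    rows_by_region: dict[int, list] = {}
    for da in das:
        if da.kind == STAY and not da.descriptor_less:
            rows_by_region.setdefault(da.regions[0], []).append(da.descriptor.vectors)
    import numpy as np

    meta: dict = {"codebook_sizes": {}}
    for region in sorted(rows_by_region):
        rows = np.vstack(rows_by_region[region])
        size = min(config.codebook_size, len(rows))
        codebooks[region] = learn_codebook(rows, size, config.seed, region_id=region)
        meta["codebook_sizes"][str(region)] = size

    classes = discover_model_classes(
        das,
        codebooks,
        per_region_k=config.per_region_k,
        seed=config.seed,
        max_classes=config.max_classes_per_region,
    )
    models = train_models(das, classes, codebooks, config.fps)
    meta["n_training_das"] = len(das)
    meta["n_models"] = len(models)
    meta["class_counts"] = {
        m.model_id: m.n_instances for m in models
    }
    return TrainedModel(scene, codebooks, models, config, meta)


def detect(
    trained: TrainedModel,
    sequences: list[TrajectorySequence],
    descriptors_by_subject: dict[str, list[DescriptorSegment]] | None = None,
) -> dict[str, AnnotationTrack]:
    """Discover and recognize activities on unseen sequences.

    Returns one prediction track per subject; each entry is a recognized DA
    labeled with the winning model id and scored with its total log score.
    """
    from .recognition import recognize

    descriptors_by_subject = descriptors_by_subject or {}
    out: dict[str, AnnotationTrack] = {}
    for seq in sequences:
        segs = descriptors_by_subject.get(seq.subject_id) or descriptors_by_subject.get("")
        das = sequence_das(seq, trained.scene_model, segs, trained.config.min_stay_frames)
        entries = []
        scores = []
        for da in das:
            result = recognize(da, trained.models, trained.codebooks, fps=trained.config.fps)
            entries.append((result.winner, da.interval))
            scores.append(result.ranked[0][1] if result.ranked else float("-inf"))
        out[seq.subject_id] = AnnotationTrack(entries, scores=scores)
    return out
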