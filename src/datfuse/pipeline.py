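"""End-to-end experiment driver: cohort → normalize → features → ensemble.

An :class:`ExperimentSpec` names the sources to combine (mirroring the idea
of running a grid of source-subset experiments on one cohort), the fusion
rule and the cross-validation scheme. Subjects are restricted to those
complete for every chosen source — a subject with any missing cell in a
chosen biomarker table, or without a volume when an image source is
requested, is excluded before classification.

Image sources are special-cased by name: ``VAF`` (striatal
voxels-as-features) and ``Morp`` (the 55-element morphological descriptor)
are computed from the volumes after α-stable intensity normalization; any
other source name must match a biomarker table of the cohort.

Every result bundle embeds a configuration hash and the cohort's seeds, so
an identical invocation reproduces it exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import morph, stable_norm
from .ensemble import (
    EnsembleConfig,
    EnsembleResult,
    KNNLearner,
    LinearMarginLearner,
    SourceBlock,
    nested_loo_ensemble,
)
from .evaluate import confusion, metrics, roc_curve
from .io import Cohort

__all__ = ["ExperimentSpec", "FUSION_CHOICES", "build_blocks", "run_experiment"]

logger = logging.getLogger("datfuse")

IMAGE_SOURCES = ("VAF", "Morp")

#: CLI-facing fusion names → (rule, window kind).
FUSION_CHOICES = {
    "majority": ("majority", "none"),
    "performance": ("performance", "none"),
    "linear": ("windowed", "linear"),
    "quadratic": ("windowed", "quadratic"),
    "exponential": ("windowed", "exponential"),
    "margin": ("margin", "none"),
}


@dataclass(frozen=True)
class ExperimentSpec:
    """A named source subset plus fusion/validation settings."""

    name: str
    sources: tuple[str, ...]
    fusion: str = "quadratic"
    cv: str = "loo"
    learner: str = "svm"
    knn_k: int = 5

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("an experiment needs at least one source")
        if self.fusion not in FUSION_CHOICES:
            raise ValueError(
                f"unknown fusion {self.fusion!r}; choose from {sorted(FUSION_CHOICES)}"
            )
        if self.cv != "loo":
            raise ValueError("only leave-one-out ('loo') cross-validation is supported")
        if self.learner not in ("svm", "knn"):
            raise ValueError("learner must be 'svm' or 'knn'")

    def ensemble_config(self, classes: tuple[str, ...]) -> EnsembleConfig:
        rule, window_kind = FUSION_CHOICES[self.fusion]
        learner = (
            LinearMarginLearner() if self.learner == "svm" else KNNLearner(self.knn_k)
        )
        return EnsembleConfig(
            fusion=rule, window=window_kind, learner=learner, classes=classes
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def complete_subjects(spec: ExperimentSpec, cohort: Cohort) -> list[str]:
    """Subjects with a volume (if image sources are used) and no missing
    cells in any chosen biomarker source."""
    keep = list(cohort.subject_ids)
    if any(s in IMAGE_SOURCES for s in spec.sources):
        keep = [sid for sid in keep if sid in cohort.volumes]
    for source in spec.sources:
        if source in IMAGE_SOURCES:
            continue
        if source not in cohort.sources:
            raise ValueError(
                f"source {source!r} not in cohort (have {sorted(cohort.sources)})"
            )
        table = cohort.sources[source]
        complete = set(table.dropna(axis=0, how="any").index)
        keep = [sid for sid in keep if sid in complete]
    return keep


def build_blocks(
    spec: ExperimentSpec, cohort: Cohort, normalize: bool = True
) -> tuple[list[SourceBlock], pd.Series]:
    """Feature blocks for the chosen sources, restricted to complete subjects."""
    subjects = complete_subjects(spec, cohort)
    logger.info(
        "experiment %s: %d/%d subjects complete for sources %s",
        spec.name, len(subjects), len(cohort), ",".join(spec.sources),
    )
    if len(subjects) < 4:
        raise ValueError(
            f"only {len(subjects)} subjects complete for {spec.sources}; need >= 4"
        )
    labels = cohort.labels.loc[subjects]

    volumes = None
    if any(s in IMAGE_SOURCES for s in spec.sources):
        raw = [cohort.volumes[sid] for sid in subjects]
        if normalize:
            volumes, _, ref = stable_norm.normalize_cohort(
                raw, cohort.atlas, subject_ids=subjects
            )
            logger.info(
                "normalized %d volumes to reference (gamma*=%.4g, delta*=%.4g)",
                len(volumes), ref.gamma_star, ref.delta_star,
            )
        else:
            volumes = raw

    blocks: list[SourceBlock] = []
    for source in spec.sources:
        if source == "VAF":
            X = np.stack([
                morph.extract_vaf(vol, cohort.atlas) for vol in volumes
            ])
        elif source == "Morp":
            X = np.stack([
                morph.morph_vector(vol, cohort.atlas).as_array() for vol in volumes
            ])
        else:
            X = cohort.sources[source].loc[subjects].to_numpy(dtype=float)
        blocks.append(SourceBlock(source, X, tuple(subjects)))
        logger.info("block %s: %d subjects x %d features", source, *X.shape)
    return blocks, labels


def _metric_dict(predictions, labels, positive_class: str) -> dict:
    m = metrics(confusion(predictions, labels, positive_class))
    out = {k: (None if np.isnan(v) else v) for k, v in m.as_dict().items()}
    out["undefined"] = sorted(m.undefined)
    return out


def summarize(result: EnsembleResult, positive_class: str) -> dict:
    """Metric summary (fused + per-source + fused ROC AUC) of a driver run."""
    out = {
        "fused": _metric_dict(result.fused, result.labels, positive_class),
        "per_source": {
            name: _metric_dict(preds, result.labels, positive_class)
            for name, preds in result.per_source.items()
        },
    }
    try:
        out["fused_auc"] = roc_curve(
            result.fused_scores, result.labels, positive_class
        ).auc
    except ValueError:
        out["fused_auc"] = None
    return out


def run_experiment(
    spec: ExperimentSpec, cohort: Cohort, normalize: bool = True
) -> dict:
    """Execute the full pipeline for one experiment; returns a JSON-able
    results bundle with metrics, per-fold weights and provenance."""
    blocks, labels = build_blocks(spec, cohort, normalize=normalize)
    classes = tuple(cohort.classes)
    result = nested_loo_ensemble(blocks, labels, spec.ensemble_config(classes))
    logger.info(
        "ensemble %s: fused %d subjects, %d fallback fold(s)",
        spec.name, len(result.subject_ids), len(result.fallback_subjects),
    )
    positive = classes[1]
    bundle = {
        "experiment": spec.name,
        "sources": list(spec.sources),
        "fusion": spec.fusion,
        "cv": spec.cv,
        "learner": spec.learner,
        "config_hash": spec.config_hash(),
        "cohort": cohort.name,
        "cohort_provenance": cohort.provenance,
        "classes": list(classes),
        "n_subjects": len(result.subject_ids),
        "subjects": list(result.subject_ids),
        "metrics": summarize(result, positive),
        "alphas": {k: v.tolist() for k, v in result.alphas.items()},
        "weights": {k: v.tolist() for k, v in result.weights.items()},
        "predictions": {
            "fused": result.fused.tolist(),
            **{k: v.tolist() for k, v in result.per_source.items()},
        },
        "fused_scores": result.fused_scores.tolist(),
        "labels": result.labels.tolist(),
        "fallback_subjects": list(result.fallback_subjects),
    }
    return bundle
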