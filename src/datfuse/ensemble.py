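"""Performance-weighted classifier fusion under nested leave-one-out.

One base classifier is trained per data source (VAF, Morp, CSF, RNA, Serum,
or any user-defined block); no classifier ever mixes features from different
sources. The fusion stage combines the per-source class votes with weights
derived from each source's *internal* accuracy α_i, estimated by an inner
leave-one-out loop that never sees the held-out test subject:

- **majority**: every source votes with weight 1;
- **performance**: w_i = α_i / Σ_j α_j (weights sum to 1);
- **windowed**: w_i = f(α_i) for α_i ≥ 0.5 and w_i = 0 below, where f is the
  linear (2α − 1), quadratic (α² + 0.5α − 0.5) or exponential
  (e^{0.9624α} − 1.618) window — all satisfy f(1) = 1 and f(0.5) ≈ 0, so
  near-chance sources are suppressed entirely. Windowed weights are used
  unnormalized: the fused argmax is invariant to their scale;
- **margin**: the signed distances to each source's decision hyperplane are
  made commensurable by dividing by s_i, the median absolute training-fold
  margin of source i, and summed; the fused class is the sign of the sum.

The nested driver runs an outer leave-one-out over subjects for honest test
predictions; within each outer fold, an inner leave-one-out over the N−1
training subjects (each inner fit uses N−2) yields the α_i that become the
fold's weights. Feature standardization is fit on training rows only, so no
information from the held-out subject enters any fit, scaling or weight.

Ties (equal fused scores, or an exactly zero margin sum) resolve to the
first class in the configured class ordering — deterministic and
seed-independent. A fold in which every windowed weight is zero falls back
to an unweighted majority vote and is recorded in the result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SourceBlock",
    "SupportProfile",
    "BaseLearner",
    "LinearMarginLearner",
    "KNNLearner",
    "EnsembleConfig",
    "EnsembleResult",
    "window",
    "performance_weights",
    "fuse_vote",
    "fuse_margin",
    "inner_accuracy",
    "nested_loo_ensemble",
    "refuse",
]

WINDOW_KINDS = ("none", "linear", "quadratic", "exponential")
FUSION_RULES = ("majority", "performance", "windowed", "margin")


@dataclass(frozen=True)
class SourceBlock:
    """One source's feature matrix: rows are subjects, columns features."""

    name: str
    X: np.ndarray
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        if self.X.ndim != 2:
            raise ValueError(f"block {self.name!r}: X must be 2-D")
        if self.X.shape[0] != len(self.subject_ids):
            raise ValueError(f"block {self.name!r}: rows != subject count")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError(f"block {self.name!r}: duplicate subject ids")
        if not np.all(np.isfinite(self.X)):
            raise ValueError(f"block {self.name!r}: non-finite features")

    def reorder(self, subject_ids: Sequence[str]) -> "SourceBlock":
        index = {sid: i for i, sid in enumerate(self.subject_ids)}
        missing = [sid for sid in subject_ids if sid not in index]
        if missing:
            raise ValueError(f"block {self.name!r} missing subjects: {missing}")
        rows = [index[sid] for sid in subject_ids]
        return SourceBlock(self.name, self.X[rows], tuple(subject_ids))


@dataclass(frozen=True)
class SupportProfile:
    """Per-class supports of one prediction; entries in [0, 1], summing to 1."""

    values: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.classes),):
            raise ValueError("one support per class required")
        if np.any(values < -1e-9) or np.any(values > 1 + 1e-9):
            raise ValueError("supports must lie in [0, 1]")
        if abs(values.sum() - 1.0) > 1e-9:
            raise ValueError(f"supports must sum to 1, got {values.sum()!r}")


class FittedModel(Protocol):
    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (class labels, supports (n, k), signed margins (n,))."""


class BaseLearner(Protocol):
    """Deterministic per-source classifier contract."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> FittedModel: ...


class _SVMModel:
    def __init__(self, pipeline: Pipeline, classes: np.ndarray) -> None:
        self._pipeline = pipeline
        self.classes = tuple(classes)

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        margins = self._pipeline.decision_function(X)
        labels = self._pipeline.predict(X)
        # Supports via logistic squashing of the signed margin — a documented
        # convention turning a maximum-margin output into a support profile.
        p_pos = expit(margins)
        supports = np.column_stack([1.0 - p_pos, p_pos])
        return labels, supports, margins


class LinearMarginLearner:
    """Linear-kernel maximum-margin classifier (SVC, C = 1 by default).

    Features are standardized per column with training-fold statistics. The
    signed margin is the distance to the separating hyperplane; positive
    margins point at the second of the (sorted) training classes.
    """

    def __init__(self, C: float = 1.0) -> None:
        self.C = C

    def fit(self, X: np.ndarray, y: np.ndarray) -> _SVMModel:
        pipeline = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="linear", C=self.C)),
        ])
        pipeline.fit(np.asarray(X, dtype=float), np.asarray(y))
        return _SVMModel(pipeline, pipeline.named_steps["svm"].classes_)


class _KNNModel:
    def __init__(self, pipeline: Pipeline, classes: np.ndarray) -> None:
        self._pipeline = pipeline
        self.classes = tuple(classes)

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        supports = self._pipeline.predict_proba(X)
        labels = self._pipeline.predict(X)
        margins = supports[:, 1] - supports[:, 0]
        return labels, supports, margins


class KNNLearner:
    """k-nearest-neighbour alternative behind the same contract (off by
    default in the pipeline; kept for comparison experiments)."""

    def __init__(self, k: int = 5) -> None:
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> _KNNModel:
        pipeline = Pipeline([
            ("scale", StandardScaler()),
            ("knn", KNeighborsClassifier(n_neighbors=min(self.k, len(y)))),
        ])
        pipeline.fit(np.asarray(X, dtype=float), np.asarray(y))
        return _KNNModel(pipeline, pipeline.named_steps["knn"].classes_)


def window(alpha: float, kind: str) -> float:
    """Windowing weight of an internal accuracy α in [0, 1].

    ``kind="none"`` applies no window (the weight is α itself); the other
    kinds are zero below α = 0.5 and follow their closed forms above.
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"accuracy must be in [0, 1], got {alpha}")
    if kind not in WINDOW_KINDS:
        raise ValueError(f"unknown window kind {kind!r}; choose from {WINDOW_KINDS}")
    if kind == "none":
        return float(alpha)
    if alpha < 0.5:
        return 0.0
    if kind == "linear":
        return 2.0 * alpha - 1.0
    if kind == "quadratic":
        return alpha**2 + 0.5 * alpha - 0.5
    return math.exp(0.9624 * alpha) - 1.618


def performance_weights(accuracies: Sequence[float]) -> np.ndarray:
    """Weights proportional to accuracies, normalized to sum to 1."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size == 0:
        raise ValueError("no accuracies given")
    if np.any(acc < 0) or np.any(acc > 1):
        raise ValueError("accuracies must lie in [0, 1]")
    total = acc.sum()
    if total <= 0:
        raise ValueError("all accuracies are zero; weights undefined")
    return acc / total


def fuse_vote(
    predictions: Sequence[str],
    weights: Sequence[float],
    classes: Sequence[str],
) -> tuple[str, float]:
    """Weighted vote: the class with the highest summed weight wins.

    Returns (class, score margin), where the score margin is the winning
    score minus the best competing score (0 at an exact tie, which resolves
    to the first class in ``classes``). The decision is invariant to positive
    rescaling of the weight vector.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("no predictions to fuse")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(predictions),):
        raise ValueError("one weight per prediction required")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    scores = {c: 0.0 for c in classes}
    for pred, w in zip(predictions, weights):
        if pred not in scores:
            raise ValueError(f"prediction {pred!r} outside classes {tuple(classes)}")
        scores[pred] += float(w)
    ordered = list(classes)
    best = max(ordered, key=lambda c: (scores[c], -ordered.index(c)))
    runner_up = max((scores[c] for c in ordered if c != best), default=0.0)
    return best, scores[best] - runner_up


def fuse_margin(
    margins: Sequence[float],
    weights: Sequence[float] | None = None,
    scales: Sequence[float] | None = None,
    classes: Sequence[str] = ("HC", "PD"),
) -> tuple[str, float]:
    """Sign-of-weighted-sum fusion of per-source signed margins.

    Each margin is divided by its source's scale s_i (median absolute
    training margin; 1 if not given) before the weighted sum. A positive sum
    selects the second class of ``classes``; zero resolves to the first.
    Returns (class, fused score).
    """
    margins = np.asarray(margins, dtype=float)
    if margins.size == 0:
        raise ValueError("no margins to fuse")
    if not np.all(np.isfinite(margins)):
        raise ValueError("margins must be finite")
    w = np.ones_like(margins) if weights is None else np.asarray(weights, dtype=float)
    s = np.ones_like(margins) if scales is None else np.asarray(scales, dtype=float)
    if np.any(s <= 0):
        raise ValueError("margin scales must be positive")
    score = float(np.sum(w * margins / s))
    return (list(classes)[1] if score > 0 else list(classes)[0]), score


def inner_accuracy(
    block: SourceBlock, labels: Sequence[str], learner: BaseLearner
) -> float:
    """Leave-one-out accuracy of one source over the given subjects.

    With N subjects this fits N models on N−1 subjects each; in the nested
    driver it is called on an outer training fold of N−1, so every inner fit
    uses N−2 subjects, matching the two-loop scheme.
    """
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise ValueError("inner leave-one-out needs at least 3 subjects")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    correct = 0
    for i in range(n):
        train = np.arange(n) != i
        if len(np.unique(y[train])) < 2:
            # fold degenerate (lone member of a class held out): count as miss
            continue
        model = learner.fit(block.X[train], y[train])
        pred, _, _ = model.predict(block.X[i : i + 1])
        correct += int(pred[0] == y[i])
    return correct / n


@dataclass(frozen=True)
class EnsembleConfig:
    """Fusion rule, window kind, base learner and class ordering."""

    fusion: str = "windowed"
    window: str = "quadratic"
    learner: BaseLearner = field(default_factory=LinearMarginLearner)
    classes: tuple[str, ...] = ("HC", "PD")

    def __post_init__(self) -> None:
        if self.fusion not in FUSION_RULES:
            raise ValueError(f"unknown fusion rule {self.fusion!r}")
        if self.window not in WINDOW_KINDS:
            raise ValueError(f"unknown window kind {self.window!r}")
        if len(self.classes) != 2:
            raise ValueError("binary classification only: exactly 2 classes")


@dataclass
class EnsembleResult:
    """Everything the nested driver produced, aligned to ``subject_ids``."""

    subject_ids: tuple[str, ...]
    labels: np.ndarray
    fused: np.ndarray                       # fused class per subject
    fused_scores: np.ndarray                # signed fused score (ROC input)
    per_source: dict[str, np.ndarray]       # per-source class predictions
    alphas: dict[str, np.ndarray]           # inner-loop accuracies per fold
    weights: dict[str, np.ndarray]          # fusion weights per fold
    margins: dict[str, np.ndarray]          # per-source signed margins
    scales: dict[str, np.ndarray]           # per-source margin scales per fold
    supports: dict[str, list[SupportProfile]]
    fallback_subjects: tuple[str, ...]      # folds where all weights were 0
    config: EnsembleConfig


def _fold_weights(
    alphas: np.ndarray, fusion: str, window_kind: str
) -> tuple[np.ndarray, bool]:
    """Weights for one fold; second value flags the all-zero fallback."""
    if fusion == "majority" or fusion == "margin":
        return np.ones_like(alphas), False
    if fusion == "performance":
        return performance_weights(alphas), False
    w = np.array([window(a, window_kind) for a in alphas])
    if np.all(w == 0):
        return np.ones_like(alphas), True
    return w, False


def nested_loo_ensemble(
    blocks: Sequence[SourceBlock],
    labels: pd.Series,
    config: EnsembleConfig | None = None,
) -> EnsembleResult:
    """Two-loop leave-one-out ensemble over all subjects.

    ``labels`` must be indexed by subject id; every block must cover exactly
    those subjects (rows are aligned internally). See the module docstring
    for the scheme.
    """
    config = config or EnsembleConfig()
    if not blocks:
        raise ValueError("no source blocks given")
    subject_ids = tuple(labels.index)
    y = labels.to_numpy()
    present = set(np.unique(y))
    if present != set(config.classes):
        raise ValueError(
            f"labels {sorted(present)} do not match classes {config.classes}"
        )
    blocks = [b.reorder(subject_ids) for b in blocks]
    n = len(subject_ids)
    if n < 4:
        raise ValueError("nested leave-one-out needs at least 4 subjects")

    names = [b.name for b in blocks]
    fused = np.empty(n, dtype=object)
    fused_scores = np.zeros(n)
    per_source = {m: np.empty(n, dtype=object) for m in names}
    alphas = {m: np.zeros(n) for m in names}
    weights = {m: np.zeros(n) for m in names}
    margins = {m: np.zeros(n) for m in names}
    scales = {m: np.ones(n) for m in names}
    supports: dict[str, list[SupportProfile]] = {m: [] for m in names}
    fallbacks: list[str] = []

    for i in range(n):
        train = np.arange(n) != i
        y_train = y[train]
        fold_alpha = np.array([
            inner_accuracy(
                SourceBlock(b.name, b.X[train], tuple(np.array(subject_ids)[train])),
                y_train,
                config.learner,
            )
            for b in blocks
        ])
        fold_w, fell_back = _fold_weights(fold_alpha, config.fusion, config.window)
        if fell_back:
            fallbacks.append(subject_ids[i])

        fold_preds: list[str] = []
        fold_margins = np.zeros(len(blocks))
        fold_scales = np.ones(len(blocks))
        for j, b in enumerate(blocks):
            model = config.learner.fit(b.X[train], y_train)
            pred, sup, marg = model.predict(b.X[i : i + 1])
            _, _, train_margins = model.predict(b.X[train])
            s = float(np.median(np.abs(train_margins)))
            fold_scales[j] = s if s > 0 else 1.0
            fold_preds.append(str(pred[0]))
            fold_margins[j] = float(marg[0])
            supports[b.name].append(
                SupportProfile(sup[0], tuple(map(str, model.classes)))
            )
            per_source[b.name][i] = str(pred[0])
            alphas[b.name][i] = fold_alpha[j]
            weights[b.name][i] = fold_w[j]
            margins[b.name][i] = fold_margins[j]
            scales[b.name][i] = fold_scales[j]

        if config.fusion == "margin":
            fused[i], fused_scores[i] = fuse_margin(
                fold_margins, fold_w, fold_scales, config.classes
            )
        else:
            cls, score = fuse_vote(fold_preds, fold_w, config.classes)
            fused[i] = cls
            # signed score: positive toward the second (positive) class
            fused_scores[i] = score if cls == config.classes[1] else -score

    if fallbacks:
        warnings.warn(
            f"all windowed weights were zero for {len(fallbacks)} fold(s); "
            "fell back to unweighted majority vote",
            stacklevel=2,
        )
    return EnsembleResult(
        subject_ids=subject_ids,
        labels=y,
        fused=fused.astype(str),
        fused_scores=fused_scores,
        per_source={m: v.astype(str) for m, v in per_source.items()},
        alphas=alphas,
        weights=weights,
        margins=margins,
        scales=scales,
        supports=supports,
        fallback_subjects=tuple(fallbacks),
        config=config,
    )


def refuse(
    result: EnsembleResult, fusion: str, window_kind: str = "quadratic"
) -> tuple[np.ndarray, np.ndarray]:
    """Re-fuse a driver result under a different rule without refitting.

    The per-source predictions, inner accuracies, margins and scales stored
    in ``result`` are all computed per fold from training data only, so any
    fusion rule can be evaluated on them after the fact. Returns (fused
    classes, fused scores) aligned to ``result.subject_ids``.
    """
    names = list(result.per_source)
    classes = result.config.classes
    n = len(result.subject_ids)
    fused = np.empty(n, dtype=object)
    scores = np.zeros(n)
    for i in range(n):
        fold_alpha = np.array([result.alphas[m][i] for m in names])
        fold_w, _ = _fold_weights(fold_alpha, fusion, window_kind)
        if fusion == "margin":
            fold_margins = [result.margins[m][i] for m in names]
            fold_scales = [result.scales[m][i] for m in names]
            fused[i], scores[i] = fuse_margin(
                fold_margins, fold_w, fold_scales, classes
            )
        else:
            preds = [result.per_source[m][i] for m in names]
            cls, score = fuse_vote(preds, fold_w, classes)
            fused[i] = cls
            scores[i] = score if cls == classes[1] else -score
    return fused.astype(str), scores
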