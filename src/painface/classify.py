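"""Per-stream classifiers, majority-vote fusion and subject-independent evaluation.

Each feature stream is embedded by SLPP and classified by its own RBF
support-vector machine; the signed decision score carries the vote (sign)
and its confidence (magnitude). Streams are combined by majority voting —
the label with more than half the votes wins; on a tie the single most
confident voter decides.

Evaluation is leave-one-subject-out (LOSO): one fold per subject, all of a
subject's epochs held out together, so no subject identity leaks between
training and testing. Accuracy is pooled over instances; the ROC/AUC uses
the fused confidence score (confidence-weighted vote sum, positive for
pain).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from . import embedding, geometry, pipeline
from .data import PainInstance, Prediction

__all__ = [
    "ClassifierConfig",
    "SUBGROUP_CRITERIA",
    "StreamClassifier",
    "FusionModel",
    "LosoResult",
    "train_stream",
    "majority_vote",
    "train_fusion",
    "loso_evaluate",
    "roc_auc",
    "subgroup_filter",
]

PAIN, NO_PAIN = "pain", "no_pain"


@dataclass(frozen=True)
class ClassifierConfig:
    """Embedding and SVM hyperparameters shared by all streams.

    ``d_out=None`` lets the embedding pick ``min(30, rank)``; ``gamma=None``
    sets the RBF width to ``1/d_out``.
    """

    d_out: int | None = None
    k: int = 5
    t_mode: str | float = "auto"
    pca_variance: float = 0.98
    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | None = None


@dataclass
class StreamClassifier:
    """One stream's SLPP embedding plus its fitted margin classifier."""

    stream: str
    slpp: embedding.SlppModel
    svc: SVC
    emb_mean_: np.ndarray
    emb_scale_: np.ndarray
    mask: np.ndarray | None = None  # optional hemiface feature mask

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.mask is not None:
            X = X[:, self.mask]
        emb = (embedding.transform(self.slpp, X) - self.emb_mean_) / self.emb_scale_
        return np.asarray(self.svc.decision_function(emb), dtype=float)

    def predict(self, X: np.ndarray) -> tuple[list[str], np.ndarray]:
        """Labels and confidences (absolute decision scores)."""
        scores = self.decision_scores(X)
        labels = [PAIN if s > 0 else NO_PAIN for s in scores]
        return labels, np.abs(scores)


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "SUO":
        return (labels == PAIN).astype(int)
    return labels.astype(int)


def train_stream(
    X: np.ndarray,
    labels,
    stream: str = "",
    config: ClassifierConfig | None = None,
    mask: np.ndarray | None = None,
) -> StreamClassifier:
    """Fit the SLPP embedding and the SVM for one feature stream."""
    config = config or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    if mask is not None:
        X = X[:, mask]
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training a stream classifier requires both classes")
    slpp = embedding.fit_slpp(
        X, y, d_out=config.d_out, k=config.k, t_mode=config.t_mode, pca_variance=config.pca_variance
    )
    emb = embedding.transform(slpp, X)
    # standardize the embedded coordinates so the 1/d_out kernel width is on
    # a unit-variance scale regardless of the eigenvector normalization
    emb_mean = emb.mean(axis=0)
    emb_scale = emb.std(axis=0)
    emb_scale[emb_scale == 0] = 1.0
    gamma = config.gamma if config.gamma is not None else 1.0 / slpp.d_out
    svc = SVC(kernel=config.kernel, C=config.C, gamma=gamma)
    svc.fit((emb - emb_mean) / emb_scale, y)
    return StreamClassifier(
        stream=stream, slpp=slpp, svc=svc, emb_mean_=emb_mean, emb_scale_=emb_scale, mask=mask
    )


def majority_vote(votes: list[str], confidences) -> str:
    """Fuse per-stream votes: strict majority, else the most confident voter."""
    if len(votes) == 0:
        raise ValueError("majority_vote needs at least one vote")
    confidences = np.asarray(confidences, dtype=float)
    if confidences.shape[0] != len(votes):
        raise ValueError("votes and confidences must have equal length")
    label, count = Counter(votes).most_common(1)[0]
    if 2 * count > len(votes):
        return label
    return votes[int(np.argmax(confidences))]


@dataclass
class FusionModel:
    """Trained per-stream classifiers plus the majority-voting rule."""

    classifiers: list[StreamClassifier]

    def predict(self, streams: dict[str, np.ndarray]) -> Prediction:
        votes: dict[str, str] = {}
        confs: dict[str, float] = {}
        for clf in self.classifiers:
            labels, conf = clf.predict(streams[clf.stream])
            votes[clf.stream] = labels[0]
            confs[clf.stream] = float(conf[0])
        label = majority_vote(list(votes.values()), list(confs.values()))
        fused = sum(c if votes[s] == PAIN else -c for s, c in confs.items())
        return Prediction(label=label, votes=votes, confidences=confs, fused_score=fused)


def train_fusion(
    instances: list[PainInstance],
    streams: tuple[str, ...],
    config: ClassifierConfig | None = None,
    side: str = "whole",
) -> FusionModel:
    """Train one classifier per stream (optionally hemiface-restricted) and bundle them."""
    classifiers = []
    for s in streams:
        mask = None
        if side != "whole":
            mask = geometry.hemiface_mask(pipeline.stream_feature_names(s), side)
        X = np.stack([inst.streams[s] for inst in instances])
        classifiers.append(
            train_stream(X, [inst.label for inst in instances], stream=s, config=config, mask=mask)
        )
    return FusionModel(classifiers=classifiers)


@dataclass
class LosoResult:
    """Leave-one-subject-out outcome: per-instance predictions and pooled metrics."""

    instances: list[PainInstance]
    predictions: list[Prediction | None]
    accuracy: float
    auc: float | None
    skipped_subjects: list[str] = field(default_factory=list)

    @property
    def evaluated(self) -> list[tuple[PainInstance, Prediction]]:
        return [(i, p) for i, p in zip(self.instances, self.predictions) if p is not None]


def loso_evaluate(
    instances: list[PainInstance],
    streams: tuple[str, ...] = ("DG_DisFace", "DG_DisPose", "DA_LBP-TOP"),
    config: ClassifierConfig | None = None,
    side: str = "whole",
) -> LosoResult:
    """Leave-one-subject-out cross-validation of the fused model.

    One fold per subject; a fold whose training labels collapse to a single
    class is skipped with a warning and reported in ``skipped_subjects``.
    """
    subjects = sorted({inst.subject.subject_id for inst in instances})
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    predictions: list[Prediction | None] = [None] * len(instances)
    skipped: list[str] = []
    for subject_id in subjects:
        test_idx = [i for i, inst in enumerate(instances) if inst.subject.subject_id == subject_id]
        train = [inst for inst in instances if inst.subject.subject_id != subject_id]
        if len({inst.label for inst in train}) < 2:
            warnings.warn(
                f"LOSO fold for subject {subject_id!r} skipped: training labels are single-class",
                stacklevel=2,
            )
            skipped.append(subject_id)
            continue
        model = train_fusion(train, streams, config=config, side=side)
        for i in test_idx:
            predictions[i] = model.predict(instances[i].streams)

    pairs = [(inst, p) for inst, p in zip(instances, predictions) if p is not None]
    if not pairs:
        raise ValueError("every LOSO fold was skipped; no predictions to score")
    correct = sum(inst.label == p.label for inst, p in pairs)
    accuracy = correct / len(pairs)
    labels = [inst.label for inst, _ in pairs]
    auc = None
    if len(set(labels)) == 2:
        auc = roc_auc([p.fused_score for _, p in pairs], labels)
    return LosoResult(
        instances=instances,
        predictions=predictions,
        accuracy=accuracy,
        auc=auc,
        skipped_subjects=skipped,
    )


def roc_auc(scores, labels) -> float:
    """Trapezoidal area under the ROC curve (pain is the positive class).

    Equals the Mann–Whitney probability that a random pain instance scores
    above a random no-pain instance, with half credit for ties.
    """
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


SUBGROUP_CRITERIA = {
    "male": lambda s: s.gender == "male",
    "female": lambda s: s.gender == "female",
    "preterm": lambda s: s.preterm,
    "full_term": lambda s: s.full_term,
    "white": lambda s: s.race == "white",
    "black": lambda s: s.race == "black",
    "asian": lambda s: s.race == "asian",
}


def subgroup_filter(instances: list[PainInstance], criterion: str) -> list[PainInstance]:
    """Instances whose subject matches one gender / gestational-age / race group.

    The gestational-age split follows the clinical cut: preterm < 37 weeks,
    full-term 37–42 weeks.
    """
    try:
        predicate = SUBGROUP_CRITERIA[criterion]
    except KeyError:
        raise ValueError(f"unknown subgroup criterion {criterion!r}; valid: {sorted(SUBGROUP_CRITERIA)}")
    selected = [inst for inst in instances if predicate(inst.subject)]
    if not selected:
        warnings.warn(f"subgroup {criterion!r} matched no instances", stacklevel=2)
    return selected
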