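"""Confusion matrices, accuracy metrics, and dataset-level evaluation.

Two accuracy figures summarise the system.  The three-class accuracy treats
ADL, Fall and Warning as distinct outcomes and is the fraction of correct
predictions among classified sequences — a sequence in which no person was
ever recognised is excluded from the denominator.  The two-class accuracy
groups Fall and Warning into a single positive class against ADL::

    Ac(2) = 100 * (TP + TN) / (TP + FP + TN + FN)

with an unrecognised-person sequence whose truth is positive counted as a
false negative (a missed alarm); an unrecognised ADL sequence is excluded
(it raises no alarm and no ground truth of interest — documented
convention).  Accuracies are reported to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import ActionCode, DetectorParams, SequenceLabel, SubjectProfile
from .classifier import (
    SVMFrameClassifier,
    TrainedModel,
    TrainingSet,
    balance_classes,
    build_training_set,
    loao_folds,
    train,
)
from .io import DepthFrame
from .simulate import SceneSpec, iter_sequences
from .state_machine import run_sequence

__all__ = [
    "ConfusionMatrix",
    "collapse_two_class",
    "accuracy_two_class",
    "accuracy_multiclass",
    "evaluate",
    "loao_evaluate",
]

_CLASSES = (SequenceLabel.ADL.value, SequenceLabel.FALL.value,
            SequenceLabel.WARNING.value)
_POSITIVE = {SequenceLabel.FALL.value, SequenceLabel.WARNING.value}


@dataclass
class ConfusionMatrix:
    """Sequence-level 3-class confusion matrix with an unclassified bucket."""

    classes: tuple[str, ...] = _CLASSES
    counts: np.ndarray = field(default_factory=lambda: np.zeros((3, 3),
                                                                dtype=np.int64))
    unclassified_by_truth: dict = field(default_factory=dict)

    def add(self, truth: str, prediction: Optional[str]) -> None:
        if truth not in self.classes:
            raise ValueError(f"unknown truth class {truth!r}")
        if prediction is None:
            self.unclassified_by_truth[truth] = \
                self.unclassified_by_truth.get(truth, 0) + 1
            return
        if prediction not in self.classes:
            raise ValueError(f"unknown predicted class {prediction!r}")
        i = self.classes.index(truth)
        j = self.classes.index(prediction)
        self.counts[i, j] += 1

    @property
    def unclassified(self) -> int:
        return int(sum(self.unclassified_by_truth.values()))

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.unclassified

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "counts": self.counts.tolist(),
            "unclassified_by_truth": dict(self.unclassified_by_truth),
        }


def collapse_two_class(cm3: ConfusionMatrix) -> tuple[int, int, int, int]:
    """Collapse to (TP, TN, FP, FN) with positive = Fall or Warning.

    Unclassified sequences with a positive truth become false negatives;
    unclassified ADLs are excluded (see module docstring).
    """
    if tuple(cm3.classes) != _CLASSES:
        raise ValueError(f"expected class vocabulary {_CLASSES}")
    tp = tn = fp = fn = 0
    for i, truth in enumerate(cm3.classes):
        for j, pred in enumerate(cm3.classes):
            n = int(cm3.counts[i, j])
            if truth in _POSITIVE:
                if pred in _POSITIVE:
                    tp += n
                else:
                    fn += n
            else:
                if pred in _POSITIVE:
                    fp += n
                else:
                    tn += n
    for truth, n in cm3.unclassified_by_truth.items():
        if truth in _POSITIVE:
            fn += n
    return tp, tn, fp, fn


def accuracy_two_class(tp: int, tn: int, fp: int, fn: int) -> float:
    """Two-class accuracy in percent, one decimal."""
    for name, v in (("TP", tp), ("TN", tn), ("FP", fp), ("FN", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("cannot compute an accuracy over zero sequences")
    return round(100.0 * (tp + tn) / total, 1)


def accuracy_multiclass(cm: ConfusionMatrix) -> float:
    """Multiclass accuracy in percent over classified sequences, one decimal."""
    total = int(cm.counts.sum())
    if total == 0:
        raise ValueError("cannot compute an accuracy over zero sequences")
    return round(100.0 * float(np.trace(cm.counts)) / total, 1)


# ---------------------------------------------------------------------------
# Dataset-level evaluation
# ---------------------------------------------------------------------------


def evaluate(dataset: Iterable[tuple[dict, Sequence[DepthFrame],
                                     Sequence[DepthFrame]]],
             params: DetectorParams,
             model: Optional[TrainedModel] = None) -> dict:
    """Run the detector over every sequence and aggregate metrics.

    ``dataset`` yields ``(manifest_row, frames, background)`` triples.  A
    sequence in which no person was ever recognised counts as unclassified.
    Returns a JSON-serialisable report.
    """
    classifier = SVMFrameClassifier(model, params) if model else None
    cm = ConfusionMatrix()
    verdicts = []
    unclassified = []
    for row, frames, background in dataset:
        result = run_sequence(frames, background, params,
                              classifier=classifier)
        truth = row["label"]
        if result.no_person:
            cm.add(truth, None)
            unclassified.append(row["sequence_dir"])
            prediction = None
        else:
            prediction = result.label.value
            cm.add(truth, prediction)
        verdicts.append({
            "sequence_dir": row["sequence_dir"],
            "subject_id": row["subject_id"],
            "truth": truth,
            "prediction": prediction,
            "no_person": result.no_person,
            "events": [e.to_dict() for e in result.events],
        })
    tp, tn, fp, fn = collapse_two_class(cm)
    report = {
        "report_version": 1,
        "n_sequences": len(verdicts),
        "confusion_matrix": cm.to_dict(),
        "two_class": {"TP": tp, "TN": tn, "FP": fp, "FN": fn,
                      "accuracy_pct": accuracy_two_class(tp, tn, fp, fn)},
        "unclassified": unclassified,
        "verdicts": verdicts,
    }
    if int(cm.counts.sum()) > 0:
        report["three_class_accuracy_pct"] = accuracy_multiclass(cm)
    return report


def loao_evaluate(subjects: Sequence[SubjectProfile],
                  codes: Optional[Sequence[ActionCode]] = None,
                  scene: SceneSpec = SceneSpec(),
                  params: DetectorParams = DetectorParams(),
                  master_seed: int = 0,
                  kind: str = "binary",
                  balance_strategy: str = "augment_noise",
                  regularization: float = 1.0) -> dict:
    """Leave-one-actor-out evaluation on the synthetic dataset.

    For each subject, a frame classifier is trained on every other subject's
    sequences (with class balancing) and the full detector — height rules
    plus that classifier — is run over the held-out subject's sequences.
    Rendering is deterministic in ``master_seed``, so the dataset is
    streamed twice (feature pass, then detection pass) instead of being held
    in memory.
    """
    params_ts = build_training_set(
        iter_sequences(subjects, codes, scene, params, master_seed),
        params, kind=kind)

    models: dict[str, TrainedModel] = {}
    for train_ids, test_id in loao_folds([s.subject_id for s in subjects]):
        mask = np.isin(params_ts.subjects, train_ids)
        fold = TrainingSet(X=params_ts.X[mask], y=params_ts.y[mask],
                           subjects=params_ts.subjects[mask],
                           areas=params_ts.areas[mask])
        fold = balance_classes(fold, strategy=balance_strategy, params=params,
                               seed=master_seed)
        models[test_id] = train(fold.X, fold.y, kind=kind,
                                regularization=regularization,
                                seed=master_seed)

    cm = ConfusionMatrix()
    verdicts = []
    for row, frames, background in iter_sequences(subjects, codes, scene,
                                                  params, master_seed):
        classifier = SVMFrameClassifier(models[row["subject_id"]], params)
        result = run_sequence(frames, background, params,
                              classifier=classifier)
        prediction = None if result.no_person else result.label.value
        cm.add(row["label"], prediction)
        verdicts.append({"sequence_dir": row["sequence_dir"],
                         "truth": row["label"], "prediction": prediction})

    tp, tn, fp, fn = collapse_two_class(cm)
    truths = [v["truth"] for v in verdicts]
    n_positive = sum(1 for t in truths if t in _POSITIVE)
    baseline = round(100.0 * max(n_positive, len(truths) - n_positive)
                     / len(truths), 1)
    report = {
        "report_version": 1,
        "n_sequences": len(verdicts),
        "n_subjects": len(subjects),
        "confusion_matrix": cm.to_dict(),
        "two_class": {"TP": tp, "TN": tn, "FP": fp, "FN": fn,
                      "accuracy_pct": accuracy_two_class(tp, tn, fp, fn)},
        "majority_baseline_pct": baseline,
        "verdicts": verdicts,
        "skipped_training_sequences": list(params_ts.skipped),
    }
    if int(cm.counts.sum()) > 0:
        report["three_class_accuracy_pct"] = accuracy_multiclass(cm)
    return report
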