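"""Linear-SVM frame classification over DVH features.

Frames are classified individually from their 256-bin depth histograms and a
strict majority over the window decides the sequence-level answer.  For the
binary system the two frame classes are Fall and ADL, with Warning sequences
contributing Fall frames (a recovered fall still contains fall frames); the
multiclass variant keeps ADL / Fall / Warning apart and is trained
one-vs-rest.  Frame labels are inherited from the sequence ground truth —
the study labels sequences, not frames, so this is an approximation whose
noise the majority vote absorbs.

Models are standard scikit-learn pipelines (per-feature standardisation
followed by a linear-kernel maximum-margin classifier) wrapped with enough
metadata to round-trip exactly through joblib.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .config import DetectorParams, SequenceLabel
from .features import feature_matrix
from .io import DepthFrame
from .segmentation import build_background
from .state_machine import track_frames

__all__ = [
    "FALL_FRAME",
    "ADL_FRAME",
    "TrainingSet",
    "TrainedModel",
    "SVMFrameClassifier",
    "extract_sequence_features",
    "build_training_set",
    "balance_classes",
    "train",
    "majority_vote",
    "loao_folds",
]

FALL_FRAME = "Fall"
ADL_FRAME = "ADL"

#: Fallback blob area (px) when a feature row has no recorded pixel count.
_DEFAULT_AREA_PX = 1500


@dataclass
class TrainingSet:
    """Frame-level DVH training data."""

    X: np.ndarray                 # (n_frames, num_bins), unit-sum rows
    y: np.ndarray                 # frame labels (str)
    subjects: np.ndarray          # subject id per frame
    areas: np.ndarray             # source blob pixel count per frame
    skipped: list[str] = field(default_factory=list)   # sequences w/o person


def extract_sequence_features(frames: Sequence[DepthFrame],
                              background: Sequence[DepthFrame],
                              params: DetectorParams,
                              ) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """DVH columns and blob areas of a sequence's last sit_time person frames.

    Returns ``None`` when no person frame exists (sequence skipped).
    """
    bg = build_background(background)
    observations = track_frames(frames, bg, params)
    person_frames = [(o.frame, o.person.mask, o.person.area_px)
                     for o in observations if o.person is not None]
    if not person_frames:
        return None
    n_window = int(round(params.sit_time_s * params.fps))
    person_frames = person_frames[-n_window:]
    X, _ = feature_matrix([(f, m) for f, m, _ in person_frames], params)
    areas = np.array([a for _, _, a in person_frames], dtype=np.int64)
    return X.T, areas


def _frame_label(sequence_label: str, kind: str) -> str:
    if kind == "multiclass":
        return sequence_label
    return ADL_FRAME if sequence_label == SequenceLabel.ADL.value else FALL_FRAME


def build_training_set(dataset: Iterable[tuple[dict, Sequence[DepthFrame],
                                               Sequence[DepthFrame]]],
                       params: DetectorParams,
                       kind: str = "binary") -> TrainingSet:
    """Assemble frame-level features over an iterable of rendered sequences.

    ``dataset`` yields ``(manifest_row, frames, background)`` triples (e.g.
    from :func:`depthfall.simulate.iter_sequences` or a disk loader).  Each
    sequence contributes its last ``sit_time`` seconds of person frames,
    labelled with the sequence's ground truth.
    """
    blocks, labels, subjects, areas, skipped = [], [], [], [], []
    for row, frames, background in dataset:
        extracted = extract_sequence_features(frames, background, params)
        if extracted is None:
            skipped.append(row["sequence_dir"])
            continue
        X_seq, a_seq = extracted
        blocks.append(X_seq)
        labels.extend([_frame_label(row["label"], kind)] * len(X_seq))
        subjects.extend([row["subject_id"]] * len(X_seq))
        areas.append(a_seq)
    if not blocks:
        raise ValueError("no sequence contributed any person frame")
    return TrainingSet(X=np.vstack(blocks), y=np.array(labels),
                       subjects=np.array(subjects),
                       areas=np.concatenate(areas), skipped=skipped)


# ---------------------------------------------------------------------------
# Class balancing
# ---------------------------------------------------------------------------


def _jitter_kernel(params: DetectorParams, sigma_mm: float) -> np.ndarray:
    """Discrete Gaussian over bin offsets for depth-jitter augmentation."""
    bin_width_mm = params.sensor_height_mm / params.num_bins
    sigma_bins = max(sigma_mm / bin_width_mm, 1e-3)
    radius = max(int(np.ceil(3 * sigma_bins)), 1)
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / sigma_bins) ** 2)
    return kernel / kernel.sum()


def balance_classes(ts: TrainingSet, strategy: str = "augment_noise",
                    params: DetectorParams = DetectorParams(),
                    noise_sigma_mm: float = 10.0,
                    seed: int = 0,
                    tolerance: float = 0.10) -> TrainingSet:
    """Bring the minority frame count within ``tolerance`` of the majority.

    Strategies:

    - ``subsample``: seeded shuffle-and-truncate of majority classes.
    - ``augment_rotation``: replicate minority frames through right-angle
      rotations.  Because the DVH depends only on the depth multiset, each
      rotated replica has an identical feature vector; the strategy is kept
      for fidelity to the original balancing recipe but adds no variety.
    - ``augment_noise`` (default): replicate minority frames with depth
      jitter — bin counts are blurred by a Gaussian of ``noise_sigma_mm``
      and multinomially resampled at the blob's pixel count.
    """
    classes, counts = np.unique(ts.y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balancing needs at least two classes")
    rng = np.random.default_rng(seed)
    n_min, n_max = counts.min(), counts.max()
    if n_min >= (1.0 - tolerance) * n_max:
        return ts

    if strategy == "subsample":
        target = int(np.ceil(n_min * (1.0 + tolerance)))
        keep = np.zeros(len(ts.y), dtype=bool)
        for cls, count in zip(classes, counts):
            idx = np.flatnonzero(ts.y == cls)
            if count > target:
                idx = rng.permutation(idx)[:target]
            keep[idx] = True
        return TrainingSet(X=ts.X[keep], y=ts.y[keep],
                           subjects=ts.subjects[keep], areas=ts.areas[keep],
                           skipped=list(ts.skipped))

    if strategy not in ("augment_rotation", "augment_noise"):
        raise ValueError(f"unknown balancing strategy {strategy!r}")

    kernel = _jitter_kernel(params, noise_sigma_mm)
    radius = len(kernel) // 2
    X_new, y_new, s_new, a_new = [ts.X], [ts.y], [ts.subjects], [ts.areas]
    target = int(np.floor(n_max * (1.0 - tolerance)))
    for cls, count in zip(classes, counts):
        deficit = target - count
        if deficit <= 0:
            continue
        idx = np.flatnonzero(ts.y == cls)
        picks = rng.choice(idx, size=deficit, replace=True)
        if strategy == "augment_rotation":
            X_new.append(ts.X[picks].copy())
        else:
            rows = []
            for i in picks:
                area = max(int(ts.areas[i]), 1)
                blurred = np.convolve(ts.X[i], kernel, mode="full")
                blurred = blurred[radius:radius + ts.X.shape[1]]
                blurred = np.clip(blurred, 0, None)
                blurred /= blurred.sum()
                counts_i = rng.multinomial(area, blurred)
                rows.append(counts_i / area)
            X_new.append(np.array(rows))
        y_new.append(np.full(deficit, cls))
        s_new.append(ts.subjects[picks])
        a_new.append(ts.areas[picks])
    return TrainingSet(X=np.vstack(X_new), y=np.concatenate(y_new),
                       subjects=np.concatenate(s_new),
                       areas=np.concatenate(a_new), skipped=list(ts.skipped))


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A fitted linear-SVM frame classifier with its preprocessing."""

    kind: str                       # "binary" | "multiclass"
    pipeline: Pipeline
    feature_dim: int
    classes: tuple[str, ...]
    training_digest: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if X.shape[1] != self.feature_dim:
            raise ValueError(
                f"expected {self.feature_dim} features, got {X.shape[1]}")
        return self.pipeline.predict(X)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump({"format": "depthfall-model", "version": 1,
                     "kind": self.kind, "pipeline": self.pipeline,
                     "feature_dim": self.feature_dim,
                     "classes": self.classes,
                     "training_digest": self.training_digest}, path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        data = joblib.load(path)
        if data.get("format") != "depthfall-model":
            raise ValueError(f"{path} is not a depthfall model archive")
        return cls(kind=data["kind"], pipeline=data["pipeline"],
                   feature_dim=data["feature_dim"],
                   classes=tuple(data["classes"]),
                   training_digest=data["training_digest"])


def train(X: np.ndarray, y: Sequence[str], kind: str = "binary",
          regularization: float = 1.0, seed: int = 0) -> TrainedModel:
    """Fit the standardise-then-linear-SVM pipeline.

    Multiclass problems are handled one-vs-rest.  Training is deterministic
    given the data order and seed.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    pipeline = Pipeline([
        ("scale", StandardScaler()),
        ("svm", LinearSVC(C=regularization, random_state=seed, tol=1e-4)),
    ])
    pipeline.fit(X, y)
    digest = hashlib.sha256(
        np.ascontiguousarray(X).tobytes() + y.tobytes()).hexdigest()[:16]
    return TrainedModel(kind=kind, pipeline=pipeline,
                        feature_dim=X.shape[1],
                        classes=tuple(str(c) for c in classes),
                        training_digest=digest)


def majority_vote(frame_labels: Sequence[str]) -> str:
    """Strict majority: Fall only if fall frames exceed half the window."""
    if len(frame_labels) == 0:
        raise ValueError("majority vote over an empty window")
    n_fall = sum(1 for lab in frame_labels if lab == FALL_FRAME)
    return FALL_FRAME if n_fall > len(frame_labels) / 2 else ADL_FRAME


class SVMFrameClassifier:
    """Adapter: buffered (frame, mask) window -> 'Fall'/'ADL' decision.

    Classifies each buffered frame from its DVH and applies the strict
    majority criterion.  This is the ``frame_classifier`` the state machine
    consults on sustained low-posture episodes.
    """

    def __init__(self, model: TrainedModel, params: DetectorParams):
        self.model = model
        self.params = params

    def __call__(self, window: list[tuple[DepthFrame, np.ndarray]]) -> str:
        if not window:
            return ADL_FRAME
        try:
            X, _ = feature_matrix(window, self.params)
        except ValueError:
            return ADL_FRAME
        preds = self.model.predict(X.T)
        if self.model.kind == "multiclass":
            preds = [ADL_FRAME if p == SequenceLabel.ADL.value else FALL_FRAME
                     for p in preds]
        return majority_vote(list(preds))


def loao_folds(subject_ids: Sequence[str]) -> list[tuple[list[str], str]]:
    """Leave-one-actor-out folds over the distinct subject ids."""
    unique = sorted(set(subject_ids))
    if len(unique) < 2:
        raise ValueError("leave-one-actor-out needs at least two subjects")
    return [([s for s in unique if s != test], test) for test in unique]
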