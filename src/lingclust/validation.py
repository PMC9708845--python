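"""Cluster-solution validation with linear discriminant analysis.

Two protocols probe whether the k-means partition is linearly recoverable
in component-score space: (a) repeated stratified random splits (training
fractions 0.75 / 0.50 / 0.25, 50 iterations each) reporting mean ± sd
training and testing accuracy, and (b) leave-one-out cross-validation
reporting the fraction of participants whose held-out LDA prediction
agrees with their k-means assignment.

The discriminant is Gaussian LDA with pooled within-class covariance and
priors proportional to training class frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

DEFAULT_N_ITER = 50
DEFAULT_TRAIN_FRACTIONS = (0.75, 0.50, 0.25)


class ValidationError(ValueError):
    """Degenerate validation request."""


@dataclass(frozen=True)
class SplitReport:
    train_fraction: float
    n_iterations: int
    mean_train: float
    sd_train: float
    mean_test: float
    sd_test: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "train_fraction": self.train_fraction,
            "n_iter": self.n_iterations,
            "mean_train": self.mean_train,
            "sd_train": self.sd_train,
            "mean_test": self.mean_test,
            "sd_test": self.sd_test,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class LooReport:
    agreement: float
    predictions: pd.DataFrame  # columns: assigned, predicted

    def to_csv(self, path: str | Path) -> None:
        self.predictions.to_csv(path)


def _check_classes(y: np.ndarray, min_per_class: int = 2) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    if counts.min() < min_per_class:
        small = classes[counts < min_per_class].tolist()
        raise ValidationError(f"classes {small} have fewer than {min_per_class} members")
    return classes


def lda_fit(scores, labels) -> LinearDiscriminantAnalysis:
    """Fit pooled-covariance Gaussian LDA (priors = class frequencies)."""
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _check_classes(y)
    model = LinearDiscriminantAnalysis(solver="svd")
    try:
        model.fit(X, y)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises rarely
        raise ValidationError(f"singular pooled covariance: {exc}") from exc
    return model


def lda_predict(model: LinearDiscriminantAnalysis, scores) -> np.ndarray:
    return model.predict(np.asarray(scores, dtype=float))


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split keeping each class represented in training."""
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        members = rng.permutation(members)
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 2), len(members) - 1)  # both sides non-empty
        train_idx.extend(members[:n_train].tolist())
        test_idx.extend(members[n_train:].tolist())
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def random_split_validation(
    scores,
    labels,
    train_fraction: float,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> SplitReport:
    """Repeated stratified random-split LDA validation.

    Each iteration draws a fresh stratified split, fits on the training
    part and scores both parts; the report summarizes accuracies as
    mean ± sd (ddof=1) over iterations.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if not 0 < train_fraction < 1:
        raise ValidationError(f"train_fraction {train_fraction} outside (0, 1)")
    _check_classes(y, min_per_class=3)
    rng = np.random.default_rng(seed)
    train_acc = np.empty(n_iter)
    test_acc = np.empty(n_iter)
    for i in range(n_iter):
        tr, te = _stratified_split(y, train_fraction, rng)
        model = lda_fit(X[tr], y[tr])
        train_acc[i] = float(np.mean(lda_predict(model, X[tr]) == y[tr]))
        test_acc[i] = float(np.mean(lda_predict(model, X[te]) == y[te]))
    sd = lambda a: float(np.std(a, ddof=1)) if n_iter > 1 else 0.0
    return SplitReport(
        train_fraction=train_fraction,
        n_iterations=n_iter,
        mean_train=float(np.mean(train_acc)),
        sd_train=sd(train_acc),
        mean_test=float(np.mean(test_acc)),
        sd_test=sd(test_acc),
        seed=seed,
    )


def loo_validation(scores, labels, participant_ids=None) -> LooReport:
    """Leave-one-out LDA agreement with the cluster assignment."""
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise ValidationError(f"need n >= 3, got {n}")
    _check_classes(y)
    if participant_ids is None and isinstance(scores, pd.DataFrame):
        participant_ids = [str(i) for i in scores.index]
    if participant_ids is None:
        participant_ids = [str(i) for i in range(n)]
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = lda_fit(X[mask], y[mask])
        preds[i] = lda_predict(model, X[i : i + 1])[0]
    frame = pd.DataFrame(
        {"assigned": y, "predicted": preds},
        index=pd.Index(participant_ids, name="participant_id"),
    )
    return LooReport(agreement=float(np.mean(preds == y)), predictions=frame)


def write_split_reports(reports, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in reports], indent=1), encoding="utf-8"
    )
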