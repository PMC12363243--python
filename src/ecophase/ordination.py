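"""Supervised 2D ordination of tetranucleotide signatures.

Linear discriminant analysis projects the 9,316-dimensional signature onto
the two axes that maximise between-ecosystem separation relative to
within-ecosystem scatter.  Because the feature count far exceeds any
realistic sample count, the within-class scatter is singular and the
projection is obtained from scikit-learn's SVD (least-squares) solver,
which never forms or inverts the scatter matrix.

Axis signs are arbitrary in LDA; for reproducibility each axis is flipped,
if needed, so that the lexicographically first class has a nonnegative mean
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import accuracy_score, f1_score, precision_score
from sklearn.model_selection import train_test_split


@dataclass
class LDAModel:
    """Fitted discriminant projection; re-projects any signature matrix
    deterministically."""

    estimator: LinearDiscriminantAnalysis
    feature_names: tuple[str, ...] | None
    axis_signs: np.ndarray  # +-1 per output axis
    n_axes: int

    def transform(self, features) -> np.ndarray:
        X = _as_matrix(features, self.feature_names)
        z = self.estimator.transform(X)[:, : self.n_axes] * self.axis_signs
        if z.shape[1] < 2:  # two-class fit has a single discriminant axis
            z = np.column_stack([z, np.zeros(len(z))])
        return z


@dataclass
class DiagramCoordinates:
    """Per-sample 2D stability-diagram coordinates with their labels."""

    sample_ids: list[str]
    xy: np.ndarray  # (n, 2)
    labels: list[str]
    model: LDAModel

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.xy[:, 0], "y": self.xy[:, 1], "group_key": self.labels},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


@dataclass(frozen=True)
class SplitMetrics:
    """Held-out classification quality of the discriminant model."""

    accuracy: float
    precision: float
    f1: float
    split: tuple[float, int]


def _as_matrix(features, expected_names: tuple[str, ...] | None = None) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        if expected_names is not None:
            if tuple(features.columns) != expected_names:
                raise ValueError("feature columns do not match the training feature order")
        return features.to_numpy(dtype=np.float64)
    X = np.asarray(features, dtype=np.float64)
    if expected_names is not None and X.shape[1] != len(expected_names):
        raise ValueError(
            f"expected {len(expected_names)} features, got {X.shape[1]}"
        )
    return X


def _check_labels(labels: Sequence[str]) -> np.ndarray:
    y = np.asarray(labels, dtype=object)
    uniq, counts = np.unique(y, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("at least 2 distinct group labels are required")
    small = [str(u) for u, c in zip(uniq, counts) if c < 2]
    if small:
        raise ValueError(f"group(s) with fewer than 2 samples: {', '.join(small)}")
    return y


def fit_lda(features, labels: Sequence[str], sample_ids: Sequence[str] | None = None) -> DiagramCoordinates:
    """Fit the discriminant projection and return 2D diagram coordinates.

    ``features`` is a samples x features DataFrame (or array) and ``labels``
    the per-sample ``"category>type"`` group keys.  Requires >=2 classes with
    >=2 samples each.  Deterministic given identical input order.
    """
    y = _check_labels(labels)
    names = tuple(features.columns) if isinstance(features, pd.DataFrame) else None
    if sample_ids is None:
        sample_ids = (
            list(features.index) if isinstance(features, pd.DataFrame) else [str(i) for i in range(len(y))]
        )
    X = _as_matrix(features)
    n_axes = min(2, len(np.unique(y)) - 1)
    est = LinearDiscriminantAnalysis(solver="svd", n_components=n_axes)
    est.fit(X, y)

    # Orientation convention: the lexicographically first class gets a
    # nonnegative mean coordinate on every axis.
    first = sorted(np.unique(y))[0]
    raw = est.transform(X)[:, :n_axes]
    ref_mean = raw[y == first].mean(axis=0)
    signs = np.where(ref_mean < 0, -1.0, 1.0)

    model = LDAModel(estimator=est, feature_names=names, axis_signs=signs, n_axes=n_axes)
    xy = model.transform(features)
    return DiagramCoordinates(
        sample_ids=[str(s) for s in sample_ids], xy=xy, labels=[str(v) for v in y], model=model
    )


def project(model: LDAModel, features) -> np.ndarray:
    """Apply a fitted projection to new signatures; re-projecting the
    training matrix reproduces the training coordinates exactly."""
    return model.transform(features)


def evaluate_split(
    features,
    labels: Sequence[str],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitMetrics:
    """Held-out evaluation of the discriminant classifier.

    Stratified train/test split (default 80/20), fit on the training part,
    predict classes for the held-out part, and report accuracy plus
    class-weighted precision and F1.
    """
    y = _check_labels(labels)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    X = _as_matrix(features)
    n_test = int(round(len(y) * (1 - train_fraction)))
    uniq, counts = np.unique(y, return_counts=True)
    if n_test < len(uniq) or counts.min() < 2:
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(
            "split infeasible for stratification"
            + (f"; group(s) too small: {', '.join(small)}" if small else "")
        )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, random_state=seed, stratify=y
    )
    est = LinearDiscriminantAnalysis(solver="svd")
    est.fit(X_tr, y_tr)
    pred = est.predict(X_te)
    return SplitMetrics(
        accuracy=float(accuracy_score(y_te, pred)),
        precision=float(precision_score(y_te, pred, average="weighted", zero_division=0)),
        f1=float(f1_score(y_te, pred, average="weighted", zero_division=0)),
        split=(train_fraction, seed),
    )
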