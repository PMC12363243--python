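"""Random-forest ranking of ecosystem-differentiating gene identifiers.

A forest is trained on normalised gene abundances against ecosystem group
keys (stratified 75/25 train/test split) and features are ranked by mean
decrease in impurity.  Per-ecosystem rankings come from one-vs-rest
forests, each entry tagged "abundance" if the ecosystem's mean abundance
of the gene exceeds the rest-of-data mean, else "sparsity".  Missing
abundances (samples without annotation files) are imputed as zero for the
model only — missingness tracks annotation availability, not biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split

DEFAULT_N_ESTIMATORS = 500
DEFAULT_TRAIN_FRACTION = 0.75


@dataclass(frozen=True)
class ImportanceEntry:
    gene_id: str
    importance: float
    direction: str | None = None  # "abundance" | "sparsity" for per-class scope


@dataclass
class ImportanceList:
    scope: str  # "overall" or "per_class:<group_key>"
    entries: list[ImportanceEntry]
    heldout_accuracy: float
    split: tuple[float, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scope": self.scope,
                "rank": np.arange(1, len(self.entries) + 1),
                "gene_id": [e.gene_id for e in self.entries],
                "importance": [e.importance for e in self.entries],
                "direction": [e.direction or "" for e in self.entries],
            }
        )


def _prepare(table: pd.DataFrame, labels: Sequence[str]):
    if len(labels) != len(table):
        raise ValueError("labels must align with table rows")
    y = np.asarray(labels, dtype=object)
    if len(np.unique(y)) < 2:
        raise ValueError("at least 2 classes are required")
    X = table.fillna(0.0).to_numpy(dtype=np.float64)
    return X, y, list(table.columns)


def _fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    train_fraction: float,
    n_estimators: int,
) -> tuple[RandomForestClassifier, float]:
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, random_state=seed, stratify=y
    )
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", random_state=seed, n_jobs=1
    )
    forest.fit(X_tr, y_tr)
    acc = float(accuracy_score(y_te, forest.predict(X_te)))
    return forest, acc


def _sorted_entries(
    gene_ids: Sequence[str], importances: np.ndarray, directions: dict[str, str] | None = None
) -> list[ImportanceEntry]:
    # descending importance; exact ties broken lexicographically by gene id
    order = sorted(range(len(gene_ids)), key=lambda i: (-importances[i], gene_ids[i]))
    return [
        ImportanceEntry(
            gene_id=gene_ids[i],
            importance=float(importances[i]),
            direction=directions.get(gene_ids[i]) if directions else None,
        )
        for i in order
    ]


def rank_importances(
    table: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> ImportanceList:
    """Overall gene-importance ranking by mean decrease in impurity.

    Trains one multiclass forest on the stratified training split and
    returns genes sorted by impurity importance (sklearn-normalised to sum
    to 1 when any splits occur), with held-out accuracy alongside.
    """
    X, y, gene_ids = _prepare(table, labels)
    forest, acc = _fit_forest(X, y, seed, train_fraction, n_estimators)
    return ImportanceList(
        scope="overall",
        entries=_sorted_entries(gene_ids, forest.feature_importances_),
        heldout_accuracy=acc,
        split=(train_fraction, seed),
    )


def per_class_rankings(
    table: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> list[ImportanceList]:
    """One-vs-rest importance ranking per ecosystem with direction tags.

    For each class a binary forest (class vs rest) is trained and its genes
    ranked; each entry is tagged "abundance" when the class mean of the
    (zero-imputed) abundance exceeds the rest-of-data mean, else "sparsity".
    """
    X, y, gene_ids = _prepare(table, labels)
    results = []
    for cls in sorted(np.unique(y)):
        y_bin = np.where(y == cls, str(cls), "rest")
        if min((y_bin == str(cls)).sum(), (y_bin == "rest").sum()) < 2:
            raise ValueError(f"class {cls!r} cannot be stratified one-vs-rest")
        forest, acc = _fit_forest(X, y_bin, seed, train_fraction, n_estimators)
        in_cls = X[y == cls].mean(axis=0)
        rest = X[y != cls].mean(axis=0)
        directions = {
            g: ("abundance" if in_cls[i] > rest[i] else "sparsity")
            for i, g in enumerate(gene_ids)
        }
        results.append(
            ImportanceList(
                scope=f"per_class:{cls}",
                entries=_sorted_entries(gene_ids, forest.feature_importances_, directions),
                heldout_accuracy=acc,
                split=(train_fraction, seed),
            )
        )
    return results
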