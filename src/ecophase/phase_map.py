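"""KNN ecosystem "phase" mapping over the stability diagram.

A grid of background cells spanning the 2D ordination is labelled by
majority vote among the k nearest metagenomes (Euclidean distance in
diagram coordinates), delineating the regions — phases, by analogy with
mineral stability diagrams — where the local metagenome composition
resembles one ecosystem.  Votes are uniform (unweighted).  Majority ties
are resolved by the smallest summed distance to the tied class's voters,
then by lexicographic group key, so cell labels are fully deterministic.
k clamps to the number of training samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ordination import DiagramCoordinates

DEFAULT_K = 500  # neighbourhood size used for the full-corpus diagram
DEFAULT_RESOLUTION = 200
DEFAULT_MARGIN = 0.05


@dataclass
class PhaseGrid:
    """Background cell labels over the diagram bounding box (plus margin)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    cell_labels: np.ndarray  # (ny, nx) object array of group_keys
    k: int

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        xc, yc = np.meshgrid(self.x_centers, self.y_centers)
        return pd.DataFrame(
            {"x": xc.ravel(), "y": yc.ravel(), "knn_label": self.cell_labels.ravel()}
        )


@dataclass(frozen=True)
class PhaseAssignment:
    """A sample's KNN phase versus its declared (GOLD) label."""

    sample_id: str
    knn_label: str
    gold_label: str

    @property
    def concordant(self) -> bool:
        return self.knn_label == self.gold_label


def _vote(labels: np.ndarray, dists: np.ndarray, order: np.ndarray, k: int) -> str:
    """Majority vote among the k nearest; ties by smallest summed distance,
    then lexicographic group key."""
    nearest = order[:k]
    votes: dict[str, int] = {}
    sums: dict[str, float] = {}
    for i in nearest:
        lab = labels[i]
        votes[lab] = votes.get(lab, 0) + 1
        sums[lab] = sums.get(lab, 0.0) + dists[i]
    best = max(votes.values())
    tied = [lab for lab, v in votes.items() if v == best]
    if len(tied) == 1:
        return tied[0]
    min_sum = min(sums[lab] for lab in tied)
    closest = [lab for lab in tied if sums[lab] == min_sum]
    return min(closest)


def _classify_batch(
    train_xy: np.ndarray, train_labels: np.ndarray, queries: np.ndarray, k: int
) -> list[str]:
    k = min(k, len(train_xy))
    out = []
    for q in queries:
        d = np.hypot(train_xy[:, 0] - q[0], train_xy[:, 1] - q[1])
        # stable ordering: by distance, then by training index
        order = np.lexsort((np.arange(len(d)), d))
        out.append(_vote(train_labels, d, order, k))
    return out


def classify_point(coords: DiagramCoordinates, query_xy: Sequence[float], k: int = DEFAULT_K) -> str:
    """KNN ecosystem classification of one diagram coordinate."""
    if len(coords.sample_ids) == 0:
        raise ValueError("empty training set")
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.asarray(coords.labels, dtype=object)
    q = np.asarray(query_xy, dtype=np.float64).reshape(1, 2)
    return _classify_batch(coords.xy, labels, q, k)[0]


def build_phase_grid(
    coords: DiagramCoordinates,
    k: int = DEFAULT_K,
    resolution: int = DEFAULT_RESOLUTION,
    margin: float = DEFAULT_MARGIN,
) -> PhaseGrid:
    """Label a resolution x resolution grid of background cells by KNN vote.

    The grid spans the coordinate bounding box expanded by ``margin``
    (fractional) on every side; each cell centre is classified by the k
    nearest metagenomes.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if len(coords.sample_ids) == 0:
        raise ValueError("empty training set")
    if k < 1:
        raise ValueError("k must be >= 1")
    xy = coords.xy
    labels = np.asarray(coords.labels, dtype=object)
    spans = xy.max(axis=0) - xy.min(axis=0)
    pad = np.where(spans > 0, spans * margin, 1.0)
    lo = xy.min(axis=0) - pad
    hi = xy.max(axis=0) + pad
    x_edges = np.linspace(lo[0], hi[0], resolution + 1)
    y_edges = np.linspace(lo[1], hi[1], resolution + 1)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    qx, qy = np.meshgrid(xc, yc)
    queries = np.column_stack([qx.ravel(), qy.ravel()])
    flat = _classify_batch(xy, labels, queries, k)
    cell_labels = np.asarray(flat, dtype=object).reshape(resolution, resolution)
    return PhaseGrid(x_edges=x_edges, y_edges=y_edges, cell_labels=cell_labels, k=min(k, len(xy)))


def assign_phases(coords: DiagramCoordinates, grid: PhaseGrid) -> list[PhaseAssignment]:
    """KNN phase assignment for every plotted sample.

    Each sample is classified at its own coordinates (not by its containing
    grid cell) with the grid's k, and concordance is recorded against its
    declared group key.
    """
    labels = np.asarray(coords.labels, dtype=object)
    knn_labels = _classify_batch(coords.xy, labels, coords.xy, grid.k)
    return [
        PhaseAssignment(sample_id=sid, knn_label=knn, gold_label=gold)
        for sid, knn, gold in zip(coords.sample_ids, knn_labels, coords.labels)
    ]


def assignments_to_frame(assignments: Sequence[PhaseAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in assignments],
            "knn_label": [a.knn_label for a in assignments],
            "gold_label": [a.gold_label for a in assignments],
            "concordant": [a.concordant for a in assignments],
        }
    )
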