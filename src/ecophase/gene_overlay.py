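"""Gene-annotation abundance overlays and group-comparison statistics.

Raw identifier counts are normalised to counts per 10^9 assembled bases so
metagenomes of different assembly sizes are comparable.  A sample without
an annotation file is *missing* (NaN), never zero — zero is a biological
claim, missing is an availability fact; a gene absent from a sample that
does have an annotation file is a true zero.

Group comparisons follow the unequal-variance pathway: Welch's
heteroscedastic one-way ANOVA with Welch–Satterthwaite degrees of freedom,
Games–Howell pairwise post hoc tests on the studentized-range distribution,
and the Welch two-sample t-test for single pairings.  Significance stars
use P <= 0.05 (*), <= 0.01 (**), <= 0.001 (***).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import AnnotationCounts, SampleMetadata

NORMALIZATION_CONSTANT = 1e9

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_tag(p: float) -> str:
    for threshold, tag in STAR_THRESHOLDS:
        if p <= threshold:
            return tag
    return "ns"


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    p: float

    @property
    def star(self) -> str:
        return star_tag(self.p)


@dataclass
class GroupComparison:
    gene_id: str
    groups: list[str]
    welch_F: float
    welch_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)


def normalize_abundance(raw_count: float, assembled_bases: int) -> float:
    """Counts per 10^9 assembled bases: ``raw_count / assembled_bases * 1e9``."""
    if assembled_bases <= 0:
        raise ValueError("assembled_bases must be positive")
    if raw_count < 0:
        raise ValueError("raw_count must be nonnegative")
    return raw_count / assembled_bases * NORMALIZATION_CONSTANT


def build_abundance_table(
    annotations: Sequence[AnnotationCounts],
    metadata: Sequence[SampleMetadata],
) -> pd.DataFrame:
    """Normalised gene-abundance table over all metadata samples.

    Rows are every metadata sample (so samples lacking an annotation file
    appear as all-missing rows); columns are the union of observed gene
    identifiers, sorted.  An annotated sample with no ``assembled_bases``
    in the metadata raises, naming the sample.
    """
    bases = {m.sample_id: m.assembled_bases for m in metadata}
    sample_ids = [m.sample_id for m in metadata]
    gene_ids = sorted({g for ann in annotations for g in ann.counts})
    table = pd.DataFrame(
        np.nan, index=pd.Index(sample_ids, name="sample_id"), columns=gene_ids, dtype=float
    )
    for ann in annotations:
        if ann.sample_id not in bases:
            raise ValueError(f"annotated sample {ann.sample_id!r} absent from metadata")
        b = bases[ann.sample_id]
        if b is None or b <= 0:
            raise ValueError(
                f"annotated sample {ann.sample_id!r} has no positive assembled_bases in metadata"
            )
        row = np.zeros(len(gene_ids))
        for j, g in enumerate(gene_ids):
            row[j] = normalize_abundance(ann.counts.get(g, 0), b)
        table.loc[ann.sample_id] = row
    return table


def _group_stats(values: Mapping[str, Sequence[float]]):
    names = list(values.keys())
    arrays = []
    for name in names:
        arr = np.asarray(values[name], dtype=np.float64)
        arr = arr[~np.isnan(arr)]
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        if np.var(arr, ddof=1) == 0 and len(values) > 1:
            raise ValueError(f"group {name!r} has zero variance")
        arrays.append(arr)
    if len(names) < 2:
        raise ValueError("at least 2 groups are required")
    n = np.array([len(a) for a in arrays], dtype=np.float64)
    m = np.array([a.mean() for a in arrays])
    v = np.array([a.var(ddof=1) for a in arrays])
    return names, n, m, v


def welch_anova_stat(values: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (F statistic and p-value)."""
    _, n, m, v = _group_stats(values)
    k = len(n)
    w = n / v
    sw = w.sum()
    mw = (w * m).sum() / sw
    a = ((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = 3.0 * (((1 - w / sw) ** 2 / (n - 1)).sum()) / (k**2 - 1)
    F = a / (1 + 2 * lam * (k - 2) / 3)
    df1 = k - 1
    df2 = 1.0 / lam
    p = float(stats.f.sf(F, df1, df2)) if F > 0 else 1.0
    return float(F), p


def games_howell(values: Mapping[str, Sequence[float]]) -> list[PairwiseResult]:
    """Games–Howell pairwise comparisons for unequal-variance groups.

    For groups (i, j): q = |mi - mj| / sqrt((vi/ni + vj/nj) / 2), compared
    against the studentized-range distribution with k groups and
    Welch–Satterthwaite degrees of freedom.
    """
    names, n, m, v = _group_stats(values)
    k = len(names)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se2 = v[i] / n[i] + v[j] / n[j]
            q = abs(m[i] - m[j]) / math.sqrt(se2 / 2.0)
            df = se2**2 / ((v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1))
            p = float(stats.studentized_range.sf(q, k, df)) if q > 0 else 1.0
            out.append(
                PairwiseResult(group_a=names[i], group_b=names[j], mean_diff=float(m[i] - m[j]), p=min(p, 1.0))
            )
    return out


def welch_games_howell(values: Mapping[str, Sequence[float]], gene_id: str = "") -> GroupComparison:
    """Welch's ANOVA plus Games–Howell post hoc tests over named groups.

    ``values`` maps group keys to observation lists (NaNs are dropped
    listwise per group).  Every group needs >= 2 observations and nonzero
    variance.
    """
    F, p = welch_anova_stat(values)
    return GroupComparison(
        gene_id=gene_id,
        groups=list(values.keys()),
        welch_F=F,
        welch_p=p,
        pairwise=games_howell(values),
    )


def two_tailed_t(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float, str]:
    """Welch two-sample two-tailed t-test; returns (t, p, star tag)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # both samples constant and equal
        t, p = 0.0, 1.0
    return t, p, star_tag(p)


@dataclass
class OverlayValues:
    """Abundances of one gene mapped onto colormap positions in [0, 1]."""

    gene_id: str
    positions: pd.Series  # NaN where hidden
    hidden: pd.Series  # bool: sample lacks an annotation file
    range: tuple[float, float]


def overlay_values(
    table: pd.DataFrame,
    gene_id: str,
    colormap_range: tuple[float, float] | None = None,
    heat_midpoint: float | None = None,
) -> OverlayValues:
    """Map one gene's abundances to colormap positions.

    Linear map of abundance onto [0, 1] within ``colormap_range`` (defaults
    to the observed min/max), clipped; missing values are flagged hidden.
    ``heat_midpoint`` rescales the map piecewise-linearly so that the given
    abundance lands at colormap position 0.5 (the static counterpart of an
    interactive heat slider).
    """
    if gene_id not in table.columns:
        raise KeyError(f"unknown gene_id: {gene_id!r}")
    ab = table[gene_id]
    hidden = ab.isna()
    present = ab[~hidden]
    if colormap_range is None:
        if present.empty:
            colormap_range = (0.0, 1.0)
        else:
            colormap_range = (float(present.min()), float(present.max()))
    lo, hi = colormap_range
    if hi <= lo:
        pos = pd.Series(np.where(hidden, np.nan, 0.5), index=table.index)
        return OverlayValues(gene_id=gene_id, positions=pos, hidden=hidden, range=(lo, hi))
    pos = ((ab - lo) / (hi - lo)).clip(0.0, 1.0)
    if heat_midpoint is not None:
        mid = min(max((heat_midpoint - lo) / (hi - lo), 1e-9), 1 - 1e-9)
        below = pos <= mid
        pos = pd.Series(
            np.where(below, 0.5 * pos / mid, 0.5 + 0.5 * (pos - mid) / (1 - mid)),
            index=table.index,
        )
    pos[hidden] = np.nan
    return OverlayValues(gene_id=gene_id, positions=pos, hidden=hidden, range=(lo, hi))
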