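"""Canonical tetranucleotide signatures.

A tetranucleotide (4-mer) and its reverse complement are counted as the same
feature, because shotgun reads sample both strands of every molecule at
random: of the 256 possible 4-mers over {A,C,G,T}, 16 are their own reverse
complement and the remaining 240 pair up, giving 136 canonical equivalence
classes.  A metagenome's signature is the vector of canonical-class
frequencies plus the ratio of every unordered pair of frequencies —
136 + C(136,2) = 9,316 features in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

N_CLASSES = 136
N_FEATURES = 9316  # 136 frequencies + 9180 unordered pairwise ratios

# ASCII byte -> base code (A=0, C=1, G=2, T=3), anything else -1.
_BASE_CODES = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODES[ord(_b)] = _i
    _BASE_CODES[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, eq=False)
class CanonicalTetramerIndex:
    """Fixed mapping of all 256 tetranucleotides onto 136 canonical classes.

    Attributes
    ----------
    classes
        The 136 canonical representatives (lexicographic minimum of each
        {s, revcomp(s)} pair), sorted lexicographically.
    lookup
        Map from every 4-mer string to its class position in ``classes``.
    code_to_class
        Same map keyed by the 4-mer's base-4 integer code, for vectorised
        counting.
    """

    classes: tuple[str, ...]
    lookup: Mapping[str, int]
    code_to_class: np.ndarray

    def canonical(self, tetramer: str) -> str:
        """Canonical representative of a 4-mer's reverse-complement class."""
        return self.classes[self.lookup[tetramer.upper()]]

    @property
    def palindromes(self) -> tuple[str, ...]:
        """The self-reverse-complementary classes (exactly 16)."""
        return tuple(c for c in self.classes if c == revcomp(c))


@dataclass
class TetraProfile:
    """Canonical 4-mer counts for one metagenome."""

    sample_id: str
    counts: np.ndarray  # int64, aligned to CanonicalTetramerIndex.classes
    total_windows: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES,):
            raise ValueError(f"profile must have {N_CLASSES} classes")
        if int(self.counts.sum()) != self.total_windows:
            raise ValueError("counts must sum to total_windows")


@dataclass
class FeatureVector:
    """The 9,316-element signature: frequencies then pairwise ratios."""

    sample_id: str
    values: np.ndarray
    names: tuple[str, ...]


@lru_cache(maxsize=1)
def build_canonical_index() -> CanonicalTetramerIndex:
    """Enumerate all 256 tetranucleotides and collapse reverse complements.

    The canonical representative of each class is the lexicographic minimum
    of the 4-mer and its reverse complement; classes are returned in
    lexicographic order.
    """
    canon = sorted({min(s, revcomp(s)) for s in ("".join(p) for p in product(BASES, repeat=4))})
    classes = tuple(canon)
    pos = {c: i for i, c in enumerate(classes)}
    lookup: dict[str, int] = {}
    code_to_class = np.empty(256, dtype=np.int64)
    for codes in product(range(4), repeat=4):
        s = "".join(BASES[c] for c in codes)
        idx = pos[min(s, revcomp(s))]
        lookup[s] = idx
        code = codes[0] * 64 + codes[1] * 16 + codes[2] * 4 + codes[3]
        code_to_class[code] = idx
    return CanonicalTetramerIndex(classes=classes, lookup=lookup, code_to_class=code_to_class)


def _window_codes(sequence: str) -> np.ndarray:
    """Base-4 codes of every valid width-4 window of ``sequence``.

    Windows containing any character outside {A,C,G,T} (case-insensitive)
    are dropped; they never contribute a count.
    """
    if len(sequence) < 4:
        return np.empty(0, dtype=np.int64)
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    b = _BASE_CODES[raw].astype(np.int64)
    b0, b1, b2, b3 = b[:-3], b[1:-2], b[2:-1], b[3:]
    valid = (b0 >= 0) & (b1 >= 0) & (b2 >= 0) & (b3 >= 0)
    codes = b0 * 64 + b1 * 16 + b2 * 4 + b3
    return codes[valid]


def count_tetramers(
    reads: Iterable,
    index: CanonicalTetramerIndex | None = None,
    sample_id: str = "",
) -> TetraProfile:
    """Count canonical 4-mers over a stream of reads.

    A width-4 window slides with step 1 over each read's sequence; each
    valid window increments its canonical class.  ``reads`` may yield
    objects with a ``sequence`` attribute (:class:`~ecophase.sequence_io.ReadRecord`)
    or plain strings.  Empty input yields an all-zero profile.
    """
    if index is None:
        index = build_canonical_index()
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        codes = _window_codes(seq)
        if codes.size:
            counts += np.bincount(index.code_to_class[codes], minlength=N_CLASSES)
    return TetraProfile(sample_id=sample_id, counts=counts, total_windows=int(counts.sum()))


def to_frequencies(profile: TetraProfile, pseudocount_policy: str = "add_one") -> np.ndarray:
    """Convert canonical counts to frequencies summing to 1.

    Real metagenomes are assumed to contain every tetranucleotide, but tiny
    inputs can miss classes, which would make downstream ratios undefined.
    Under the default ``add_one`` policy, if any class count is zero one
    pseudocount is added to *every* class (logged); under ``error`` a zero
    count raises, naming the class.
    """
    if pseudocount_policy not in ("add_one", "error"):
        raise ValueError(f"unknown pseudocount policy: {pseudocount_policy!r}")
    if profile.total_windows == 0:
        raise ValueError(f"sample {profile.sample_id!r}: no valid tetranucleotide windows")
    counts = profile.counts
    if (counts == 0).any():
        if pseudocount_policy == "error":
            index = build_canonical_index()
            zero = [index.classes[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(
                f"sample {profile.sample_id!r}: zero count for class(es) {', '.join(zero)}"
            )
        logger.info(
            "sample %r: %d zero-count classes; adding 1 pseudocount to all classes",
            profile.sample_id,
            int((counts == 0).sum()),
        )
        counts = counts + 1
    return counts / counts.sum()


@lru_cache(maxsize=1)
def feature_names() -> tuple[str, ...]:
    """Stable names for the 9,316 features: ``freq:<class>`` then
    ``ratio:<class_i>/<class_j>`` for every unordered pair i<j."""
    classes = build_canonical_index().classes
    iu, ju = np.triu_indices(N_CLASSES, k=1)
    names = [f"freq:{c}" for c in classes]
    names += [f"ratio:{classes[i]}/{classes[j]}" for i, j in zip(iu, ju)]
    return tuple(names)


def build_feature_vector(freqs: Sequence[float], sample_id: str = "") -> FeatureVector:
    """Assemble the 9,316-element feature vector from 136 frequencies.

    Emits the 136 frequencies followed by, for every unordered class pair
    (i, j) with i<j in lexicographic class order, the single ratio
    ``freqs[i] / freqs[j]`` (numerator the lexicographically earlier class).
    All frequencies must be strictly positive.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} frequencies, got {freqs.shape}")
    if (freqs <= 0).any():
        index = build_canonical_index()
        bad = [index.classes[i] for i in np.flatnonzero(freqs <= 0)]
        raise ValueError(f"nonpositive frequency for class(es) {', '.join(bad)}")
    iu, ju = np.triu_indices(N_CLASSES, k=1)
    values = np.concatenate([freqs, freqs[iu] / freqs[ju]])
    return FeatureVector(sample_id=sample_id, values=values, names=feature_names())


def feature_matrix(
    profiles: Sequence[TetraProfile], pseudocount_policy: str = "add_one"
) -> pd.DataFrame:
    """Feature vectors for many profiles as a samples x 9,316 DataFrame."""
    rows = []
    ids = []
    for profile in profiles:
        freqs = to_frequencies(profile, pseudocount_policy)
        rows.append(build_feature_vector(freqs, profile.sample_id).values)
        ids.append(profile.sample_id)
    return pd.DataFrame(np.asarray(rows), index=ids, columns=list(feature_names()))


def profiles_to_table(profiles: Sequence[TetraProfile]) -> pd.DataFrame:
    """Canonical counts for many profiles as a samples x 136 DataFrame."""
    index = build_canonical_index()
    data = np.vstack([p.counts for p in profiles]) if profiles else np.empty((0, N_CLASSES))
    return pd.DataFrame(data, index=[p.sample_id for p in profiles], columns=list(index.classes))
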