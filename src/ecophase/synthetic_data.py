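"""Synthetic metagenome cohorts with controllable ecosystem structure.

Each ecosystem group is an order-3 Markov chain over {A,C,G,T}: the
probability of the next base depends on the previous three, so canonical
4-mer frequencies are exactly the chain's sufficient statistics and the
stationary tetranucleotide distribution of every group is computable in
closed form — the generator's structure matches the feature space under
test.  All groups share one base transition table; each group perturbs the
base table with logit-space Gaussian noise of scale ``separation``
(``separation=0`` gives identical groups, i.e. a null cohort).

Gene-annotation fixtures draw per-sample identifier counts from a negative
binomial (overdispersed, to exercise the unequal-variance statistics
pathway) whose mean is a panel-wide base mean times a per-group multiplier,
and emit them as minimal valid GFF3.

Everything is reproducible from (parameters, seed); per-sample RNG streams
are spawned deterministically from the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import AnnotationCounts, EcosystemLabel, SampleMetadata
from .tetra_features import N_CLASSES, build_canonical_index

#: Default group keys, mirroring the commonest GOLD "category>type" labels.
DEFAULT_GROUP_KEYS = (
    "Terrestrial>Soil",
    "Aquatic>Freshwater",
    "Aquatic>Marine",
    "Aquatic>Non-marine Saline and Alkaline",
    "Aquatic>Thermal springs",
    "Aquatic>Deep subsurface",
)

# Study-condition defaults for desk-scale cohorts.
DEFAULT_SAMPLES_PER_GROUP = 40
DEFAULT_READS_PER_SAMPLE = 300
DEFAULT_READ_LENGTH = 150
DEFAULT_SEPARATION = 0.25

N_STATES = 64  # 3-mer contexts


@dataclass
class EcosystemModel:
    """Order-3 Markov model of one ecosystem's base composition."""

    group_key: str
    transition: np.ndarray  # (64, 4): P(next base | previous 3-mer)
    gene_bias: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=np.float64)
        if self.transition.shape != (N_STATES, 4):
            raise ValueError("transition must be 64 x 4")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each conditional distribution must sum to 1")
        if any(m <= 0 for m in self.gene_bias.values()):
            raise ValueError("gene_bias multipliers must be positive")


@dataclass
class SyntheticCohort:
    """A fully parameterised synthetic study: groups x samples x reads."""

    models: list[EcosystemModel]
    samples_per_group: int = DEFAULT_SAMPLES_PER_GROUP
    reads_per_sample: int = DEFAULT_READS_PER_SAMPLE
    read_length: int = DEFAULT_READ_LENGTH
    separation: float = DEFAULT_SEPARATION
    seed: int = 0

    @property
    def sample_ids(self) -> list[str]:
        ids = []
        for model in self.models:
            slug = _slug(model.group_key)
            ids.extend(f"{slug}_{s:03d}" for s in range(self.samples_per_group))
        return ids

    @property
    def sample_labels(self) -> list[str]:
        return [m.group_key for m in self.models for _ in range(self.samples_per_group)]


def _slug(group_key: str) -> str:
    return (
        group_key.replace(">", "_").replace(" ", "-").replace("(", "").replace(")", "").lower()
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def make_ecosystem_models(
    n_groups: int,
    separation: float,
    seed: int = 0,
    group_keys: Sequence[str] | None = None,
    gene_bias: Mapping[str, Sequence[float]] | None = None,
    base_logit_scale: float = 0.4,
) -> list[EcosystemModel]:
    """Draw one shared base transition table and per-group perturbations.

    The base table's logits are Gaussian with scale ``base_logit_scale``
    (moderately non-uniform composition); each group adds logit noise of
    scale ``separation`` before renormalisation, so ``separation=0`` yields
    identical groups and larger values monotonically more divergent ones.
    ``gene_bias`` maps gene ids to per-group abundance multipliers.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if group_keys is None:
        group_keys = list(DEFAULT_GROUP_KEYS[:n_groups])
        group_keys += [f"Environmental>Group{i + 1}" for i in range(len(group_keys), n_groups)]
    if len(group_keys) != n_groups:
        raise ValueError("group_keys length must equal n_groups")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, base_logit_scale, size=(N_STATES, 4))
    models = []
    for g, key in enumerate(group_keys):
        noise = rng.normal(0.0, 1.0, size=(N_STATES, 4))
        bias = {gene: float(mult[g]) for gene, mult in (gene_bias or {}).items()}
        models.append(
            EcosystemModel(group_key=key, transition=_softmax(base + separation * noise), gene_bias=bias)
        )
    return models


def _sample_rng(cohort_seed: int, group_index: int, sample_index: int, stream: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=cohort_seed, spawn_key=(stream, group_index, sample_index))
    return np.random.default_rng(ss)


def simulate_sample_reads(
    model: EcosystemModel, n_reads: int, read_length: int, rng: np.random.Generator
) -> list[str]:
    """Simulate reads from an ecosystem model as plain sequence strings.

    Each read starts from a uniformly random 3-mer context and extends one
    base at a time from the model's conditional distributions.  Vectorised
    across reads.
    """
    if read_length < 1 or n_reads < 1:
        return []
    bases = np.empty((n_reads, read_length), dtype=np.uint8)
    states = rng.integers(0, N_STATES, size=n_reads)
    for pos in range(min(3, read_length)):
        bases[:, pos] = (states >> (2 * (2 - pos))) & 3
    cum = np.cumsum(model.transition, axis=1)
    for pos in range(3, read_length):
        u = rng.random(n_reads)
        nxt = (u[:, None] > cum[states]).sum(axis=1).clip(0, 3)
        bases[:, pos] = nxt
        states = (states & 0b1111) * 4 + nxt
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [bytes(alphabet[row]).decode("ascii") for row in bases]


def cohort_reads(cohort: SyntheticCohort):
    """Yield (sample_id, group_key, reads) for every sample in the cohort."""
    for g, model in enumerate(cohort.models):
        slug = _slug(model.group_key)
        for s in range(cohort.samples_per_group):
            rng = _sample_rng(cohort.seed, g, s, stream=0)
            reads = simulate_sample_reads(model, cohort.reads_per_sample, cohort.read_length, rng)
            yield f"{slug}_{s:03d}", model.group_key, reads


def cohort_metadata(cohort: SyntheticCohort, assembled_bases: int | None = None) -> list[SampleMetadata]:
    """Metadata records for a cohort; assembled_bases defaults to
    reads_per_sample x read_length."""
    if assembled_bases is None:
        assembled_bases = cohort.reads_per_sample * cohort.read_length
    records = []
    for model in cohort.models:
        category, _, eco_type = model.group_key.partition(">")
        slug = _slug(model.group_key)
        for s in range(cohort.samples_per_group):
            records.append(
                SampleMetadata(
                    sample_id=f"{slug}_{s:03d}",
                    label=EcosystemLabel(path=(category, eco_type)),
                    assembled_bases=assembled_bases,
                )
            )
    return records


def simulate_reads(cohort: SyntheticCohort, out_dir: str | Path) -> tuple[list[Path], Path]:
    """Write per-sample FASTA files and a metadata TSV.

    Returns (fasta paths, metadata path).  Byte-identical for identical
    (cohort, seed).
    """
    out_dir = Path(out_dir)
    reads_dir = out_dir / "reads"
    reads_dir.mkdir(parents=True, exist_ok=True)
    fasta_paths = []
    meta_rows = []
    assembled = cohort.reads_per_sample * cohort.read_length
    for sample_id, group_key, reads in cohort_reads(cohort):
        path = reads_dir / f"{sample_id}.fasta"
        with open(path, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f">{sample_id}.read{i}\n{seq}\n")
        fasta_paths.append(path)
        category, _, eco_type = group_key.partition(">")
        meta_rows.append(
            {
                "sample_id": sample_id,
                "ecosystem_category": category,
                "ecosystem_type": eco_type,
                "assembled_bases": assembled,
            }
        )
    meta_path = out_dir / "metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)
    return fasta_paths, meta_path


def _attribute_key(gene_id: str) -> str:
    if gene_id.startswith("COG"):
        return "cog"
    if gene_id.startswith("KO:"):
        return "ko"
    if gene_id.startswith("PF"):
        return "pfam"
    if gene_id.startswith("EC:"):
        return "ec_number"
    return "cog"


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial counts with var = mean + dispersion * mean^2
    (Poisson when dispersion = 0)."""
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_annotation_counts(
    cohort: SyntheticCohort,
    gene_panel: Sequence[str],
    seed: int | None = None,
    base_mean: float = 50.0,
    dispersion: float = 0.3,
) -> list[AnnotationCounts]:
    """Per-sample gene-identifier counts with ecosystem-biased means.

    Each gene's count in a sample of group g is negative binomial with
    mean ``base_mean x model.gene_bias.get(gene, 1.0)``.
    """
    if not gene_panel:
        raise ValueError("gene_panel must be nonempty")
    seed = cohort.seed if seed is None else seed
    out = []
    for g, model in enumerate(cohort.models):
        slug = _slug(model.group_key)
        for s in range(cohort.samples_per_group):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(1, g, s))
            )
            ann = AnnotationCounts(sample_id=f"{slug}_{s:03d}")
            for gene in gene_panel:
                mean = base_mean * model.gene_bias.get(gene, 1.0)
                ann.counts[gene] = int(_nb_counts(rng, mean, dispersion, 1)[0])
            out.append(ann)
    return out


def simulate_annotations(
    cohort: SyntheticCohort,
    gene_panel: Sequence[str],
    out_dir: str | Path,
    seed: int | None = None,
    base_mean: float = 50.0,
    dispersion: float = 0.3,
) -> list[Path]:
    """Write per-sample GFF3 annotation files with ecosystem-biased counts.

    Each identifier occurrence becomes one CDS feature line carrying the
    identifier in the IMG-style attribute key for its namespace.
    """
    out_dir = Path(out_dir)
    ann_dir = out_dir / "annotations"
    ann_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    counts = simulate_annotation_counts(cohort, gene_panel, seed, base_mean, dispersion)
    for ann in counts:
        path = ann_dir / f"{ann.sample_id}.gff3"
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            feature = 0
            for gene in gene_panel:
                key = _attribute_key(gene)
                for _ in range(ann.counts[gene]):
                    feature += 1
                    start = feature * 100
                    fh.write(
                        f"{ann.sample_id}_contig1\tsynthetic\tCDS\t{start}\t{start + 90}\t.\t+\t0\t"
                        f"ID={ann.sample_id}.g{feature};{key}={gene}\n"
                    )
        paths.append(path)
    return paths


def stationary_tetramer_frequencies(model: EcosystemModel) -> np.ndarray:
    """Closed-form canonical 4-mer distribution of an ecosystem model.

    The 3-mer context chain has transition M[s, s'] = P(d | s) for
    s' = (s mod 16)*4 + d; its stationary vector pi gives 4-mer
    probabilities pi(s) * P(d | s), collapsed over reverse complements.
    """
    M = np.zeros((N_STATES, N_STATES))
    for s in range(N_STATES):
        for d in range(4):
            M[s, (s & 0b1111) * 4 + d] += model.transition[s, d]
    # stationary distribution: left null vector of (M - I)
    w, v = np.linalg.eig(M.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi) / np.abs(pi).sum()
    p256 = (pi[:, None] * model.transition).ravel()  # index = s*4 + d = base-4 code
    index = build_canonical_index()
    return np.bincount(index.code_to_class, weights=p256, minlength=N_CLASSES)


def transition_total_variation(a: EcosystemModel, b: EcosystemModel) -> float:
    """Mean total-variation distance between two models' conditional
    distributions, averaged over the 64 contexts."""
    return float(0.5 * np.abs(a.transition - b.transition).sum(axis=1).mean())
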