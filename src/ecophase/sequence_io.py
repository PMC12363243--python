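"""Input parsing: sequencing reads, ecosystem metadata, GFF3 annotations.

Metagenomes arrive as unassembled reads (FASTA/FASTQ, optionally gzipped),
a metadata table carrying GOLD-style ecosystem classification paths, and
per-sample GFF3 annotation files whose column-9 attributes carry
COG/KO/Pfam/EC gene identifiers.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

#: Default GFF3 attribute keys carrying gene identifiers, keyed by the
#: namespace they belong to (IMG-pipeline dialect; configurable because
#: GFF3 attribute conventions vary between annotation pipeline versions).
DEFAULT_ANNOTATION_KEYS: dict[str, str] = {
    "cog": "COG",
    "ko": "KO",
    "pfam": "Pfam",
    "ec_number": "EC",
}

#: GOLD-style classification level columns expected in metadata tables,
#: in path order.  Category and type are required; deeper levels optional.
LEVEL_COLUMNS = (
    "ecosystem_category",
    "ecosystem_type",
    "ecosystem_subtype",
    "specific_ecosystem",
    "ecosystem_detail",
)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; non-ACGT characters are retained but never
    contribute tetranucleotide windows downstream."""

    id: str
    sequence: str


@dataclass(frozen=True)
class EcosystemLabel:
    """GOLD-style classification path (category, type, subtype, ...)."""

    path: tuple[str, ...]

    @property
    def group_key(self) -> str:
        """The grouping label ``"category>type"`` used throughout the
        pipeline (e.g. ``"Aquatic>Marine"``)."""
        return f"{self.path[0]}>{self.path[1]}"


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    label: EcosystemLabel
    assembled_bases: int | None = None


@dataclass
class AnnotationCounts:
    """Occurrence counts of namespaced gene identifiers for one sample."""

    sample_id: str
    counts: Counter = field(default_factory=Counter)


class SequenceFormatError(ValueError):
    pass


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _detect_format(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    suffix = Path(name).suffix.lower()
    if suffix in (".fasta", ".fa", ".fna"):
        return "fasta"
    if suffix in (".fastq", ".fq"):
        return "fastq"
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise SequenceFormatError(f"{path}: cannot auto-detect sequence format")


def read_sequences(path: str | Path, format: str = "auto") -> Iterator[ReadRecord]:
    """Stream reads from a FASTA or FASTQ file (plain or gzipped).

    Records are yielded in file order with sequences uppercased.  With
    ``format="auto"`` the format is inferred from the file extension, or
    from the first character when the extension is uninformative.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)
    if format not in ("fasta", "fastq"):
        raise SequenceFormatError(f"unknown sequence format: {format!r}")
    with _open_text(path) as fh:
        n = 0
        try:
            for record in SeqIO.parse(fh, format):
                n += 1
                yield ReadRecord(id=record.id, sequence=str(record.seq).upper())
        except ValueError as exc:
            raise SequenceFormatError(f"{path}: malformed {format} near record {n + 1}: {exc}") from exc


def load_metadata(
    path: str | Path,
    delimiter: str = "\t",
    sample_column: str = "sample_id",
    level_columns: Sequence[str] = LEVEL_COLUMNS,
    assembled_bases_column: str = "assembled_bases",
) -> list[SampleMetadata]:
    """Load a delimited metadata table into :class:`SampleMetadata` records.

    The table must carry a sample-id column plus at least the first two
    classification-level columns (category and type); deeper levels are
    optional and empty cells truncate the path.  Duplicate sample ids and
    missing category/type values raise.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if sample_column not in df.columns:
        raise ValueError(f"{path}: missing required column {sample_column!r}")
    for col in level_columns[:2]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df[sample_column][df[sample_column].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate sample_id(s): {', '.join(sorted(set(dup)))}")

    records = []
    for _, row in df.iterrows():
        path_levels = []
        for col in level_columns:
            if col in df.columns and isinstance(row[col], str) and row[col].strip():
                path_levels.append(row[col].strip())
            else:
                break
        if len(path_levels) < 2:
            raise ValueError(
                f"{path}: sample {row[sample_column]!r} lacks ecosystem category and/or type"
            )
        bases = None
        if assembled_bases_column in df.columns:
            raw = row[assembled_bases_column]
            if isinstance(raw, str) and raw.strip():
                bases = int(float(raw))
                if bases < 0:
                    raise ValueError(f"{path}: negative assembled_bases for {row[sample_column]!r}")
        records.append(
            SampleMetadata(
                sample_id=str(row[sample_column]),
                label=EcosystemLabel(path=tuple(path_levels)),
                assembled_bases=bases,
            )
        )
    return records


def filter_metadata(
    records: Sequence[SampleMetadata],
    exclude_categories: Sequence[str] = ("Engineered", "Host-associated"),
    exclude_types: Sequence[str] = ("Nest",),
    case_sensitive: bool = True,
) -> list[SampleMetadata]:
    """Drop samples from non-natural or host-restricted environments.

    Removes any record whose top classification level is in
    ``exclude_categories`` (default Engineered, Host-associated) or whose
    type level is in ``exclude_types`` (default Nest), preserving order.
    Matching is exact and case-sensitive unless ``case_sensitive=False``.
    """
    def norm(s: str) -> str:
        return s if case_sensitive else s.lower()

    cats = {norm(c) for c in exclude_categories}
    types = {norm(t) for t in exclude_types}
    kept = []
    for rec in records:
        if norm(rec.label.path[0]) in cats:
            continue
        if len(rec.label.path) > 1 and norm(rec.label.path[1]) in types:
            continue
        kept.append(rec)
    return kept


def _parse_attributes(column9: str) -> list[tuple[str, str]]:
    pairs = []
    for chunk in column9.strip().split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        pairs.append((key.strip(), value.strip()))
    return pairs


def parse_gff3_annotations(
    path: str | Path,
    keys: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> AnnotationCounts:
    """Count gene-identifier occurrences in a GFF3 annotation file.

    ``keys`` maps GFF3 attribute keys to identifier namespaces (defaults:
    cog/ko/pfam/ec_number -> COG/KO/Pfam/EC).  Each matching attribute value
    on each feature line counts one occurrence; comma-separated multi-values
    each count once; a feature carrying several namespaces increments each.
    Lines with no recognised keys are skipped silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    attr_keys = set((keys or DEFAULT_ANNOTATION_KEYS).keys())
    counts: Counter = Counter()
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            for key, value in _parse_attributes(fields[8]):
                if key in attr_keys and value:
                    for ident in value.split(","):
                        ident = ident.strip()
                        if ident:
                            counts[ident] += 1
    return AnnotationCounts(sample_id=sample_id or path.stem, counts=counts)
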