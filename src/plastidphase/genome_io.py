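"""Reading genomes and annotations into a normalized internal model.

A :class:`GenomeRecord` is a linear four-letter sequence plus a list of
annotated regions.  "Coding" is understood widely throughout the package:
protein-coding genes, tRNA, rRNA and other RNA genes all count as coding
regions for phase labeling; the category is retained so that RNA-gene-dense
stretches (the *tail* phase) can be told apart from protein genes.

Coordinates are 1-based inclusive everywhere (GenBank convention); GFF3
input, also 1-based inclusive, maps directly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO


class Strand(str, enum.Enum):
    FORWARD = "forward"
    BACKWARD = "backward"


class Category(str, enum.Enum):
    PROTEIN_CODING = "protein_coding"
    TRNA = "tRNA"
    RRNA = "rRNA"
    OTHER_RNA = "other_RNA"


#: feature-type keys (GenBank feature keys and GFF3 type column) that count
#: as coding regions, mapped to the internal category.
FEATURE_CATEGORIES = {
    "CDS": Category.PROTEIN_CODING,
    "tRNA": Category.TRNA,
    "rRNA": Category.RRNA,
    "ncRNA": Category.OTHER_RNA,
    "tmRNA": Category.OTHER_RNA,
    "misc_RNA": Category.OTHER_RNA,
}

#: categories whose regions make up the RNA-gene-dense "tail" stretches
RNA_CATEGORIES = frozenset({Category.TRNA, Category.RRNA, Category.OTHER_RNA})


class FormatError(ValueError):
    """An input file could not be parsed in any supported format."""


class ValidationError(ValueError):
    """Annotation coordinates are inconsistent with the sequence."""


@dataclass(frozen=True, order=True)
class AnnotatedRegion:
    """One annotated coding region, 1-based inclusive coordinates."""

    start: int
    end: int
    strand: Strand
    category: Category

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"invalid region coordinates {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """A genome sequence plus its annotated regions."""

    id: str
    sequence: str
    regions: list[AnnotatedRegion] = field(default_factory=list)
    is_circular: bool = False
    #: 1-based positions of non-ACGT symbols (kept in the sequence; triplets
    #: covering them are skipped when counting)
    ambiguous_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.length == 0:
            raise ValidationError(f"genome {self.id!r} has empty sequence")
        self.ambiguous_positions = tuple(
            i + 1 for i, c in enumerate(self.sequence) if c not in "ACGT"
        )
        for r in self.regions:
            if r.end > self.length:
                raise ValidationError(
                    f"region {r.start}..{r.end} exceeds genome length {self.length}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


def _category_for(feature_type: str) -> Category | None:
    if feature_type in FEATURE_CATEGORIES:
        return FEATURE_CATEGORIES[feature_type]
    # any other *RNA feature kind counts as other_RNA
    if feature_type.endswith("RNA"):
        return Category.OTHER_RNA
    return None


def _regions_from_seqrecord(record, n: int) -> list[AnnotatedRegion]:
    """Extract coding regions from Biopython SeqFeatures.

    Compound locations (joins, origin-spanning features on circular
    records) are split into one region per part.
    """
    regions: list[AnnotatedRegion] = []
    for feat in record.features:
        category = _category_for(feat.type)
        if category is None:
            continue
        strand = Strand.BACKWARD if feat.location.strand == -1 else Strand.FORWARD
        for part in feat.location.parts:
            start = int(part.start) + 1  # 0-based half-open -> 1-based inclusive
            end = int(part.end)
            if end > n or start < 1:
                raise ValidationError(
                    f"feature {feat.type} {start}..{end} outside sequence of length {n}"
                )
            regions.append(AnnotatedRegion(start, end, strand, category))
    regions.sort()
    return regions


def _read_gff3_regions(path: Path, n: int, seqid: str | None = None) -> list[AnnotatedRegion]:
    """Read coding regions from a GFF3 file (1-based inclusive coordinates)."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # malformed file
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc
    regions: list[AnnotatedRegion] = []
    for feat in db.all_features():
        if seqid is not None and feat.seqid != seqid:
            continue
        category = _category_for(feat.featuretype)
        if category is None:
            continue
        if feat.end > n:
            raise ValidationError(
                f"{path}: feature {feat.start}..{feat.end} exceeds genome length {n}"
            )
        strand = Strand.BACKWARD if feat.strand == "-" else Strand.FORWARD
        regions.append(AnnotatedRegion(feat.start, feat.end, strand, category))
    regions.sort()
    return regions


def read_genome(seq_source: str | Path, annot_source: str | Path | None = None) -> GenomeRecord:
    """Read a genome plus annotation into a :class:`GenomeRecord`.

    ``seq_source`` may be a FASTA file (then ``annot_source`` must be a GFF3
    file) or a GenBank/EMBL flat file carrying its own features (then
    ``annot_source`` may be omitted).  Only the first record of a
    multi-record file is read.
    """
    seq_source = Path(seq_source)
    record = None
    fmt_used = None
    for fmt in ("genbank", "embl", "fasta"):
        try:
            record = next(SeqIO.parse(str(seq_source), fmt), None)
        except Exception:
            record = None
        if record is not None and len(record.seq) > 0:
            fmt_used = fmt
            break
    if record is None:
        raise FormatError(f"{seq_source}: not parseable as GenBank, EMBL or FASTA")

    sequence = str(record.seq).upper()
    n = len(sequence)
    is_circular = record.annotations.get("topology", "") == "circular"

    if annot_source is not None:
        regions = _read_gff3_regions(Path(annot_source), n, seqid=None)
    elif fmt_used in ("genbank", "embl"):
        regions = _regions_from_seqrecord(record, n)
    else:
        regions = []

    return GenomeRecord(
        id=record.id or seq_source.stem,
        sequence=sequence,
        regions=regions,
        is_circular=is_circular,
    )


def regions_to_rows(record: GenomeRecord) -> pd.DataFrame:
    """GFF3-like tabular view of a record's regions (round-trippable)."""
    return pd.DataFrame(
        {
            "seqid": record.id,
            "type": [
                "CDS" if r.category is Category.PROTEIN_CODING else r.category.value
                for r in record.regions
            ],
            "start": [r.start for r in record.regions],
            "end": [r.end for r in record.regions],
            "strand": ["-" if r.strand is Strand.BACKWARD else "+" for r in record.regions],
        }
    )


def rows_to_regions(rows: pd.DataFrame) -> list[AnnotatedRegion]:
    regions = []
    for row in rows.itertuples(index=False):
        category = _category_for(row.type)
        if category is None:
            raise ValidationError(f"unknown feature type {row.type!r}")
        strand = Strand.BACKWARD if row.strand == "-" else Strand.FORWARD
        regions.append(AnnotatedRegion(int(row.start), int(row.end), strand, category))
    return sorted(regions)


def write_table(rows: pd.DataFrame | Sequence[dict] | Iterable[dict], path: str | Path) -> None:
    """Write tabular data as TSV (header row, UTF-8, '.' decimal separator).

    Column order is taken from the input and is stable across runs.
    Empty input is an error and creates no file.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    if rows.empty:
        raise ValueError("refusing to write an empty table")
    rows.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
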