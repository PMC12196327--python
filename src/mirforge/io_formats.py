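"""Readers/writers for the plain-text formats the pipeline touches.

All internal coordinates are 0-based half-open on the plus strand;
conversion to/from 1-based inclusive (GFF3) happens only at file
boundaries.  Quality strings are Phred+33 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")

#: default mapping from GFF3 feature types to the five-way internal enum;
#: annotation dialects vary, so callers may pass their own table.
DEFAULT_GFF_ALIASES: dict[str, str] = {
    "gene": "gene",
    "protein_coding_gene": "gene",
    "exon": "exon",
    "CDS": "exon",
    "ncRNA": "ncRNA",
    "tRNA": "ncRNA",
    "rRNA": "ncRNA",
    "snoRNA": "ncRNA",
    "snRNA": "ncRNA",
    "lnc_RNA": "ncRNA",
    "ncRNA_gene": "ncRNA",
    "repeat": "repeat",
    "repeat_region": "repeat",
    "dispersed_repeat": "repeat",
    "transposable_element": "repeat",
    "pseudogene": "pseudogene",
    "pseudogenic_transcript": "pseudogene",
}

FEATURE_TYPES = ("gene", "exon", "ncRNA", "repeat", "pseudogene")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Scaffold-anchored 0-based half-open stranded span."""

    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping nucleotides (strand-agnostic); 0 if on
        different scaffolds or disjoint."""
        if self.scaffold != other.scaffold:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(slots=True)
class SeqRecord:
    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SeqRecord {self.id!r}: empty sequence")


@dataclass(slots=True)
class Read:
    """A small-RNA sequencing read with its Phred+33 quality string."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FormatError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )
        if len(self.seq) < 1:
            raise FormatError(f"read {self.id!r}: empty sequence")

    def mean_quality(self) -> float:
        return sum(ord(c) - 33 for c in self.qual) / len(self.qual)


@dataclass(slots=True)
class Feature:
    interval: GenomicInterval
    ftype: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")


_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space (U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Normalize an RNA/DNA string to upper-case DNA (U→T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path, alphabet: frozenset[str] = DNA_ALPHABET) -> list[SeqRecord]:
    """Parse a FASTA file into records; sequences are case-folded to upper.

    Raises :class:`FormatError` for records with empty sequences or
    characters outside *alphabet*.
    """
    records: list[SeqRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - alphabet
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        records.append(SeqRecord(id=rec.id, seq=seq, description=rec.description))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a 4-line-record FASTQ file (Phred+33).

    Yields :class:`Read` objects in file order; a sequence/quality length
    mismatch raises :class:`FormatError` naming the record.
    """
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"{path}: expected '@' header, got {header!r}")
            seq = fh.readline().rstrip("\n").upper()
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise FormatError(f"{path}: truncated record {header[1:]!r}")
            rid = header[1:].split()[0]
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}: record {rid!r}: seq length {len(seq)} != qual length {len(qual)}"
                )
            yield Read(id=rid, seq=seq, qual=qual)


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


# ---------------------------------------------------------------------------
# GFF3 / BED / TSV


def read_gff3(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> list[Feature]:
    """Read a 9-column GFF3 into internal Features.

    File coordinates (1-based inclusive) are converted to 0-based
    half-open.  Feature types are mapped through *aliases* (default
    :data:`DEFAULT_GFF_ALIASES`); rows with unknown types are skipped with
    a logged warning.  ``end < start`` in the file is a format error.
    """
    aliases = dict(DEFAULT_GFF_ALIASES if aliases is None else aliases)
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            scaffold, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            start, end = int(start_s), int(end_s)
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            mapped = aliases.get(ftype)
            if mapped is None:
                log.warning("%s:%d: skipping unknown feature type %r", path, lineno, ftype)
                continue
            gene_id = ""
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    if k in ("ID", "Parent") and not gene_id:
                        gene_id = v
                    if k == "Parent":  # exons point at their gene
                        gene_id = v
            if strand not in ("+", "-"):
                strand = "+"
            features.append(
                Feature(
                    interval=GenomicInterval(scaffold, start - 1, end, strand),
                    ftype=mapped,
                    gene_id=gene_id,
                )
            )
    return features


def write_gff3(features: Iterable[Feature], path: str | Path) -> None:
    """Write Features back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            attrs = f"ID={f.gene_id}" if f.gene_id else "."
            if f.ftype == "exon" and f.gene_id:
                attrs = f"Parent={f.gene_id}"
            fh.write(
                f"{iv.scaffold}\t.\t{f.ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def write_bed(
    items: Sequence[Feature | GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED6 (0-based half-open, same as internal)."""
    with open(path, "w") as fh:
        for i, item in enumerate(items):
            iv = item.interval if isinstance(item, Feature) else item
            name = names[i] if names else (item.gene_id if isinstance(item, Feature) else ".")
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{name or '.'}\t0\t{iv.strand}\n")


def write_tsv(table: "object", path: str | Path) -> None:
    """Write a pandas DataFrame as a header-bearing TSV."""
    table.to_csv(path, sep="\t", index=False)
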