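"""Seed-and-verify short-read mapping with ≤1 mismatch, plus the
size/5′-nucleotide profile of the mapped small-RNA population.

The mapper indexes plus-strand k-mers and searches the reverse
complement of a read for minus-strand hits, so every alignment lives in
plus-strand coordinates: for strand '−', ``read_seq`` equals the reverse
complement of the genome slice.  Two disjoint seeds per read give the
pigeonhole guarantee that any alignment with at most one mismatch is
found, provided reads are at least twice the seed length.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, Read, SeqRecord, revcomp

MIN_LEN, MAX_LEN = 15, 35
BASES = "ACGT"


class ConfigError(ValueError):
    pass


@dataclass(slots=True)
class Alignment:
    read_id: str
    interval: GenomicInterval
    n_mismatch: int
    read_seq: str


@dataclass
class Index:
    """Exact k-mer → plus-strand positions lookup."""

    k: int
    scaffolds: dict[str, str]
    positions: dict[str, list[tuple[str, int]]]


def build_index(genome: Sequence[SeqRecord] | Mapping[str, str], k: int = 7) -> Index:
    """Index every plus-strand k-mer of the genome.

    ``k=7`` keeps two seeds disjoint for the shortest read considered
    (15 nt), which is what makes 1-mismatch search exhaustive.
    """
    if k < 4:
        raise ConfigError(f"k={k} too small (minimum 4)")
    if 2 * k > MIN_LEN:
        raise ConfigError(f"k={k}: two disjoint seeds need 2k <= {MIN_LEN}")
    scaffolds = (
        {r.id: r.seq for r in genome} if not isinstance(genome, Mapping) else dict(genome)
    )
    positions: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for name, seq in scaffolds.items():
        for i in range(len(seq) - k + 1):
            positions[seq[i : i + k]].append((name, i))
    return Index(k=k, scaffolds=scaffolds, positions=dict(positions))


def _hamming_le(a: str, b: str, max_mm: int) -> int:
    """Hamming distance if ≤ max_mm, else max_mm + 1 (early exit)."""
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > max_mm:
                return mm
    return mm


def _candidate_starts(pattern: str, index: Index) -> set[tuple[str, int]]:
    L, k = len(pattern), index.k
    starts: set[tuple[str, int]] = set()
    for off in (0, L - k):
        seed = pattern[off : off + k]
        for scaffold, pos in index.positions.get(seed, ()):
            start = pos - off
            if start >= 0 and start + L <= len(index.scaffolds[scaffold]):
                starts.add((scaffold, start))
    return starts


def map_read(
    read: Read | str,
    index: Index,
    max_mm: int = 1,
    max_hits: int = 5,
) -> list[Alignment]:
    """All minimum-mismatch alignments of a read (both strands).

    Returns the loci with the smallest mismatch count (0 preferred over
    1).  Reads with more than *max_hits* equally-best loci are treated as
    multi-mappers and discarded (empty list).
    """
    if isinstance(read, str):
        read = Read(id=read, seq=read, qual="I" * len(read))
    seq = read.seq
    if len(seq) < 2 * index.k:
        return []
    hits: list[tuple[int, str, int, str]] = []  # (mm, scaffold, start, strand)
    for strand, pattern in (("+", seq), ("-", revcomp(seq))):
        for scaffold, start in _candidate_starts(pattern, index):
            ref = index.scaffolds[scaffold][start : start + len(pattern)]
            mm = _hamming_le(pattern, ref, max_mm)
            if mm <= max_mm:
                hits.append((mm, scaffold, start, strand))
    if not hits:
        return []
    best = min(h[0] for h in hits)
    best_hits = sorted(h for h in hits if h[0] == best)
    if len(best_hits) > max_hits:
        return []
    return [
        Alignment(
            read_id=read.id,
            interval=GenomicInterval(scaffold, start, start + len(seq), strand),
            n_mismatch=mm,
            read_seq=seq,
        )
        for mm, scaffold, start, strand in best_hits
    ]


def map_reads(
    reads: Iterable[Read],
    index: Index,
    max_mm: int = 1,
    max_hits: int = 5,
) -> tuple[list[Alignment], dict[str, int]]:
    """Map a read collection, caching by sequence (small-RNA libraries are
    massively duplicated).  Returns all alignments plus mapping stats."""
    cache: dict[str, list[Alignment]] = {}
    alignments: list[Alignment] = []
    stats = {"n_reads": 0, "n_mapped": 0, "n_unmapped_or_multi": 0}
    for read in reads:
        stats["n_reads"] += 1
        hit = cache.get(read.seq)
        if hit is None:
            hit = map_read(read, index, max_mm=max_mm, max_hits=max_hits)
            cache[read.seq] = hit
        if hit:
            stats["n_mapped"] += 1
            for a in hit:
                alignments.append(
                    Alignment(read.id, a.interval, a.n_mismatch, a.read_seq)
                )
        else:
            stats["n_unmapped_or_multi"] += 1
    return alignments, stats


@dataclass
class SizeProfile:
    """Read counts by length (15–35) × 5′ nucleotide."""

    counts: np.ndarray  # shape (21, 4), rows length 15..35, cols A C G T

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, index=range(MIN_LEN, MAX_LEN + 1), columns=list(BASES)
        )
        df.index.name = "length"
        return df

    def modal_length(self) -> int:
        return MIN_LEN + int(self.counts.sum(axis=1).argmax())

    def top_5p_base(self, length: int) -> str:
        return BASES[int(self.counts[length - MIN_LEN].argmax())]


def profile_mapped(alignments: Iterable[Alignment]) -> SizeProfile:
    """Tally each mapped read once by read length and 5′ base.

    Multi-locus reads contribute a single count; lengths outside 15–35
    are ignored.
    """
    counts = np.zeros((MAX_LEN - MIN_LEN + 1, 4), dtype=np.int64)
    seen: set[str] = set()
    base_idx = {b: i for i, b in enumerate(BASES)}
    for a in alignments:
        if a.read_id in seen:
            continue
        seen.add(a.read_id)
        L = len(a.read_seq)
        if MIN_LEN <= L <= MAX_LEN and a.read_seq[0] in base_idx:
            counts[L - MIN_LEN, base_idx[a.read_seq[0]]] += 1
    return SizeProfile(counts=counts)


def alignments_to_tsv(alignments: Iterable[Alignment]) -> pd.DataFrame:
    rows = [
        {
            "read_id": a.read_id,
            "scaffold": a.interval.scaffold,
            "start": a.interval.start,
            "end": a.interval.end,
            "strand": a.interval.strand,
            "mismatches": a.n_mismatch,
        }
        for a in alignments
    ]
    return pd.DataFrame(
        rows, columns=["read_id", "scaffold", "start", "end", "strand", "mismatches"]
    )
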