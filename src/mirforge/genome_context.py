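"""Genomic context of curated miRNAs: overlap removal, origin
classification (exonic/intronic/intergenic/pseudogene), per-scaffold
counts and 5 kb clusters.

Overlap and clustering are strand-agnostic; the context precedence is
most-specific-first (pseudogene > exonic > intronic > intergenic).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .discovery import MatureMiRNA
from .io_formats import Feature, GenomicInterval

CONTEXTS = ("exonic", "intronic", "intergenic", "pseudogene")


@dataclass(slots=True)
class ContextCall:
    mirna: str
    context: str


@dataclass(slots=True)
class Cluster:
    scaffold: str
    members: list[str]  # miRNA names sorted by precursor start
    span: GenomicInterval


def drop_overlapping(
    mirnas: Sequence[MatureMiRNA],
) -> tuple[list[MatureMiRNA], list[MatureMiRNA]]:
    """Resolve precursor overlaps, keeping the best-supported miRNA.

    Same-scaffold precursors overlapping by ≥1 nt (any strand) compete;
    within each overlap chain miRNAs are admitted in descending read
    count (ties → smallest start), dropping any that overlaps an
    already-admitted one.  A miRNA overlapping nothing is never dropped.
    """
    order = sorted(
        range(len(mirnas)),
        key=lambda i: (
            -mirnas[i].read_count,
            mirnas[i].candidate.precursor_interval.scaffold,
            mirnas[i].candidate.precursor_interval.start,
        ),
    )
    kept_idx: list[int] = []
    dropped_idx: list[int] = []
    for i in order:
        iv = mirnas[i].candidate.precursor_interval
        if any(
            iv.overlap(mirnas[j].candidate.precursor_interval) >= 1 for j in kept_idx
        ):
            dropped_idx.append(i)
        else:
            kept_idx.append(i)
    kept = [mirnas[i] for i in sorted(kept_idx)]
    dropped = [mirnas[i] for i in sorted(dropped_idx)]
    return kept, dropped


def classify_context(
    mirna: MatureMiRNA, annotation: Sequence[Feature]
) -> ContextCall:
    """One context per precursor, strand-agnostic ≥1 nt overlap, with
    precedence pseudogene > exonic > intronic > intergenic (a precursor
    overlapping a gene without touching an exon lies in an intron)."""
    iv = mirna.candidate.precursor_interval
    overlaps = {"pseudogene": False, "exon": False, "gene": False}
    for f in annotation:
        if f.ftype in overlaps and f.interval.overlap(iv) >= 1:
            overlaps[f.ftype] = True
    if overlaps["pseudogene"]:
        ctx = "pseudogene"
    elif overlaps["exon"]:
        ctx = "exonic"
    elif overlaps["gene"]:
        ctx = "intronic"
    else:
        ctx = "intergenic"
    return ContextCall(mirna=mirna.name, context=ctx)


def context_fractions(calls: Iterable[ContextCall]) -> dict[str, float]:
    """Percentage of classified miRNAs per context (sums to 100)."""
    calls = list(calls)
    if not calls:
        return {c: 0.0 for c in CONTEXTS}
    n = len(calls)
    return {
        c: 100.0 * sum(1 for call in calls if call.context == c) / n
        for c in CONTEXTS
    }


def find_clusters(
    mirnas: Sequence[MatureMiRNA], max_gap: int = 5000
) -> list[Cluster]:
    """Single-linkage clusters of precursors within *max_gap* nt.

    Per scaffold, precursors sorted by start chain while the gap to the
    running end is ≤ max_gap (inclusive; 5001 nt breaks the chain);
    strand is ignored and only components with ≥2 members are emitted.
    """
    by_scaffold: dict[str, list[MatureMiRNA]] = defaultdict(list)
    for m in mirnas:
        by_scaffold[m.candidate.precursor_interval.scaffold].append(m)
    clusters: list[Cluster] = []
    for scaffold in sorted(by_scaffold):
        group = sorted(
            by_scaffold[scaffold], key=lambda m: m.candidate.precursor_interval.start
        )
        run: list[MatureMiRNA] = []
        run_end = None
        for m in group + [None]:
            iv = m.candidate.precursor_interval if m is not None else None
            if m is not None and (run_end is None or iv.start - run_end <= max_gap):
                run.append(m)
                run_end = iv.end if run_end is None else max(run_end, iv.end)
                continue
            if len(run) >= 2:
                clusters.append(
                    Cluster(
                        scaffold=scaffold,
                        members=[x.name for x in run],
                        span=GenomicInterval(
                            scaffold,
                            min(x.candidate.precursor_interval.start for x in run),
                            max(x.candidate.precursor_interval.end for x in run),
                        ),
                    )
                )
            if m is not None:
                run = [m]
                run_end = iv.end
    return clusters


def per_scaffold_counts(mirnas: Sequence[MatureMiRNA]) -> pd.DataFrame:
    """miRNA counts per scaffold, sorted by descending count."""
    counts = defaultdict(int)
    for m in mirnas:
        counts[m.candidate.precursor_interval.scaffold] += 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["scaffold", "n_mirnas"])
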