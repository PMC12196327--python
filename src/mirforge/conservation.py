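"""Known-vs-novel calls against reference mature catalogs, cross-species
sharing, and comparison with an external prediction set.

Similarity is a deterministic ungapped shift-and-count: a query matches
a catalog mature if, over offsets within ±max_shift, some near-full
overlap has at most max_mm mismatches, or its seed (nt 2–8) is identical
with at most 4 mismatches overall.  Catalogs are stored mature-sense
5′→3′ (miRBase convention); the reverse complement is not searched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import SeqRecord, to_dna


@dataclass(slots=True)
class MatchResult:
    query: str
    subject: str | None
    n_mismatch: int
    offset: int
    seed_identical: bool
    matched: bool


@dataclass
class SharingMatrix:
    membership: dict[str, set[str]]  # miRNA name -> species sharing it

    def per_species_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for species_set in self.membership.values():
            for s in species_set:
                totals[s] = totals.get(s, 0) + 1
        return dict(sorted(totals.items()))

    def upset_counts(self) -> dict[str, int]:
        """Intersection sizes keyed by '+'-joined sorted species names;
        species-specific miRNAs fall under 'none'.  Counts sum to the
        total miRNA count."""
        counts: dict[str, int] = {}
        for species_set in self.membership.values():
            key = "+".join(sorted(species_set)) if species_set else "none"
            counts[key] = counts.get(key, 0) + 1
        return dict(sorted(counts.items()))


def _overlap_mismatches(query: str, subject: str, offset: int) -> tuple[int, int, bool]:
    """Mismatches of the ungapped overlap when query start sits at
    *offset* on the subject.  Returns (overlap_len, mismatches,
    seed_within_overlap_and_identical)."""
    lo_q = max(0, -offset)
    hi_q = min(len(query), len(subject) - offset)
    if hi_q <= lo_q:
        return 0, 0, False
    mm = 0
    for q in range(lo_q, hi_q):
        if query[q] != subject[q + offset]:
            mm += 1
    seed_ok = lo_q <= 1 and hi_q >= 8 and query[1:8] == subject[1 + offset : 8 + offset]
    return hi_q - lo_q, mm, seed_ok


def match_mature(
    query: str,
    catalog: Sequence[SeqRecord],
    max_mm: int = 2,
    max_shift: int = 2,
) -> MatchResult:
    """Best ungapped match of a mature query against a catalog.

    Ties break deterministically: fewest mismatches, then smallest
    |offset|, then first catalog entry.
    """
    query = to_dna(query)
    best: tuple[int, int, int] | None = None  # (mm, |offset|, entry index)
    best_rec: tuple[str, int, int, bool] | None = None
    for idx, rec in enumerate(catalog):
        subject = to_dna(rec.seq)
        for offset in range(-max_shift, max_shift + 1):
            ov, mm, seed_ok = _overlap_mismatches(query, subject, offset)
            if ov < len(query) - max_shift:
                continue
            key = (mm, abs(offset), idx)
            if best is None or key < best:
                best = key
                best_rec = (rec.id, mm, offset, seed_ok)
    if best_rec is None:
        return MatchResult(query, None, -1, 0, False, False)
    subject_id, mm, offset, seed_ok = best_rec
    matched = mm <= max_mm or (seed_ok and mm <= 4)
    return MatchResult(
        query=query,
        subject=subject_id if matched else None,
        n_mismatch=mm,
        offset=offset,
        seed_identical=seed_ok,
        matched=matched,
    )


def call_known_novel(
    mirnas: Sequence[tuple[str, str]],
    combined_catalog: Sequence[SeqRecord],
    max_mm: int = 2,
    max_shift: int = 2,
) -> tuple[list[str], list[str]]:
    """Partition (name, mature_seq) pairs into catalog-similar ("known")
    and species-specific; the two lists always sum to the input size."""
    known: list[str] = []
    specific: list[str] = []
    for name, seq in mirnas:
        res = match_mature(seq, combined_catalog, max_mm=max_mm, max_shift=max_shift)
        (known if res.matched else specific).append(name)
    return known, specific


def sharing_matrix(
    mirnas: Sequence[tuple[str, str]],
    catalogs_by_species: Mapping[str, Sequence[SeqRecord]],
    max_mm: int = 2,
    max_shift: int = 2,
) -> SharingMatrix:
    """Which species share each miRNA (every miRNA appears exactly once,
    possibly with an empty species set)."""
    membership: dict[str, set[str]] = {}
    for name, seq in mirnas:
        shared = {
            species
            for species, catalog in catalogs_by_species.items()
            if match_mature(seq, catalog, max_mm=max_mm, max_shift=max_shift).matched
        }
        membership[name] = shared
    return SharingMatrix(membership=membership)


def _find_all(text: str, pattern: str) -> Iterable[int]:
    i = text.find(pattern)
    while i != -1:
        yield i
        i = text.find(pattern, i + 1)


def substring_match(query: str, subject: str, max_mm: int = 1) -> bool:
    """Does the query occur within the subject with ≤ max_mm mismatches?
    Seeded by the pigeonhole halves of the query."""
    if len(query) > len(subject):
        return False
    half = len(query) // 2
    seen: set[int] = set()
    for q_off, seed in ((0, query[:half]), (half, query[half:])):
        for pos in _find_all(subject, seed):
            start = pos - q_off
            if start < 0 or start + len(query) > len(subject) or start in seen:
                continue
            seen.add(start)
            mm = 0
            for a, b in zip(query, subject[start : start + len(query)]):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
            else:
                return True
    return False


def compare_prediction_sets(
    set_a: Sequence[SeqRecord],
    set_b: Sequence[SeqRecord],
    max_mm: int = 2,
    max_shift: int = 2,
) -> tuple[list[str], list[str], list[str]]:
    """Overlap between two prediction sets.

    An entry of *set_a* is shared if it occurs as a ≤1-mismatch substring
    of some *set_b* entry (which may be a longer precursor) or matches it
    as a mature.  Returns (shared_a_ids, only_a_ids, only_b_ids); the
    first two partition set_a, and only_b lists set_b entries never hit.
    """
    hit_b: set[str] = set()
    shared: list[str] = []
    only_a: list[str] = []
    b_seqs = [(rec.id, to_dna(rec.seq)) for rec in set_b]
    for rec in set_a:
        q = to_dna(rec.seq)
        found = False
        for b_id, b_seq in b_seqs:
            if substring_match(q, b_seq, max_mm=1) or match_mature(
                q, [SeqRecord(id=b_id, seq=b_seq)], max_mm=max_mm, max_shift=max_shift
            ).matched:
                hit_b.add(b_id)
                found = True
        (shared if found else only_a).append(rec.id)
    only_b = [rec.id for rec in set_b if rec.id not in hit_b]
    return shared, only_a, only_b
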