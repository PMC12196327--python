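"""Candidate miRNA discovery: read stacks → excised hairpins → six-way
curation → abundance.

A read stack is a maximal run of overlapping same-strand alignments.
Around each stack's modal read two asymmetric windows are excised (long
flank upstream or downstream), folded by base-pair maximization, and the
better-paired window is kept.  The candidate precursor is then trimmed
to the structure-predicted mature/star duplex span (assuming the
canonical 2 nt 3′ overhang geometry left by Drosha/Dicer) and re-folded.

Curation applies six criteria — hairpin-like structure, 60–80 nt
precursor, 2–3 nt 3′ overhangs with read-supported star, ≥70% 5′
homogeneity, 20–24 nt read-length peak, and no ncRNA/repeat overlap —
keeping candidates that meet at least three.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .folding import HairpinStructure, fold_hairpin
from .io_formats import Feature, GenomicInterval, SeqRecord, revcomp
from .mapping import Alignment

CRITERIA_REQUIRED = 3  # keep iff >= 3 of the 6 criteria hold


def _five_prime(a: Alignment) -> int:
    """Genomic index of the read's 5' base."""
    return a.interval.start if a.interval.strand == "+" else a.interval.end - 1


@dataclass(slots=True)
class ReadStack:
    interval: GenomicInterval
    n_reads: int
    five_prime_counts: dict[int, int]
    length_histogram: dict[int, int]
    modal_seq: str
    modal_start: int  # genomic span of the modal read
    modal_end: int


@dataclass(slots=True)
class HairpinCandidate:
    precursor_interval: GenomicInterval
    precursor_seq: str  # transcript-sense DNA
    structure: HairpinStructure
    mature: tuple[int, int]  # (offset, length) in precursor coordinates
    star: tuple[int, int] | None
    criteria: dict[str, bool] = field(default_factory=dict)
    n_met: int = 0
    verdict: str = "unevaluated"

    @property
    def mature_interval(self) -> GenomicInterval:
        iv = self.precursor_interval
        off, length = self.mature
        if iv.strand == "+":
            return GenomicInterval(iv.scaffold, iv.start + off, iv.start + off + length, "+")
        return GenomicInterval(iv.scaffold, iv.end - off - length, iv.end - off, "-")

    @property
    def mature_seq(self) -> str:
        off, length = self.mature
        return self.precursor_seq[off : off + length]


@dataclass(slots=True)
class MatureMiRNA:
    name: str
    seq: str
    candidate: HairpinCandidate
    read_count: int = 0
    rpm: float = 0.0
    share: float = 0.0


# ---------------------------------------------------------------------------
# read stacks


def call_read_stacks(
    alignments: Iterable[Alignment],
    min_reads: int = 5,
    merge_gap: int = 0,
) -> list[ReadStack]:
    """Maximal runs of overlapping same-strand alignments with at least
    *min_reads* reads.  The modal sequence is the most frequent read
    sequence (ties broken lexicographically)."""
    by_key: dict[tuple[str, str], list[Alignment]] = defaultdict(list)
    for a in alignments:
        by_key[(a.interval.scaffold, a.interval.strand)].append(a)
    stacks: list[ReadStack] = []
    for (scaffold, strand), group in sorted(by_key.items()):
        group.sort(key=lambda a: (a.interval.start, a.interval.end))
        run: list[Alignment] = []
        run_end = -1
        for a in group + [None]:  # sentinel flushes the last run
            if a is not None and (not run or a.interval.start - run_end <= merge_gap):
                run.append(a)
                run_end = max(run_end, a.interval.end)
                continue
            if len(run) >= min_reads:
                stacks.append(_build_stack(run, scaffold, strand))
            if a is not None:
                run = [a]
                run_end = a.interval.end
        # (sentinel handled the final run)
    return stacks


def _build_stack(run: list[Alignment], scaffold: str, strand: str) -> ReadStack:
    five = Counter(_five_prime(a) for a in run)
    lengths = Counter(
        len(a.read_seq) for a in run if 15 <= len(a.read_seq) <= 35
    )
    seqs = Counter(a.read_seq for a in run)
    top = max(seqs.values())
    modal_seq = min(s for s, c in seqs.items() if c == top)
    modal = next(a for a in run if a.read_seq == modal_seq)
    return ReadStack(
        interval=GenomicInterval(
            scaffold,
            min(a.interval.start for a in run),
            max(a.interval.end for a in run),
            strand,
        ),
        n_reads=len(run),
        five_prime_counts=dict(five),
        length_histogram=dict(lengths),
        modal_seq=modal_seq,
        modal_start=modal.interval.start,
        modal_end=modal.interval.end,
    )


# ---------------------------------------------------------------------------
# star prediction from structure


def predict_star(
    pairs: set[tuple[int, int]], mature_off: int, mature_len: int
) -> tuple[int, int] | None:
    """Predicted star span (offset, end) in precursor coordinates,
    assuming the canonical 2 nt 3' overhang duplex geometry.

    The star 3' end lies two nucleotides past the partner of the mature
    5' base; the star 5' end is the partner of the mature base two in
    from its 3' end.  Unpaired anchor positions fall back to the nearest
    paired mature base with the offset carried over."""
    pm: dict[int, int] = {}
    for i, j in pairs:
        pm[i] = j
        pm[j] = i
    a, b = mature_off, mature_off + mature_len
    paired = sorted(i for i in range(a, b) if i in pm)
    if len(paired) < 4:
        return None
    i1 = paired[0]  # nearest to mature 5' end
    anchor3 = b - 3
    below = [i for i in paired if i <= anchor3]
    i2 = below[-1] if below else paired[-1]
    hi = pm[i1] + (i1 - a) + 3
    lo = pm[i2] - (anchor3 - i2)
    if lo >= hi or hi - lo < 10:
        return None
    return lo, hi


def _duplex_overhangs(
    pairs: set[tuple[int, int]],
    mature: tuple[int, int],
    star: tuple[int, int],
) -> tuple[int, int] | None:
    """(mature 3' overhang, star 3' overhang) of the mature/star duplex."""
    pm: dict[int, int] = {}
    for i, j in pairs:
        pm[i] = j
        pm[j] = i
    a, b = mature[0], mature[0] + mature[1]
    c, d = star
    m_paired = [i for i in range(a, b) if i in pm and c <= pm[i] < d]
    s_paired = [j for j in range(c, d) if j in pm and a <= pm[j] < b]
    if not m_paired or not s_paired:
        return None
    return b - (max(m_paired) + 1), d - (max(s_paired) + 1)


# ---------------------------------------------------------------------------
# excision


def _scan_star(seq: str, m_off: int, mlen: int, min_gap: int = 4) -> tuple[int, int] | None:
    """Locate the star arm by direct duplex scan: the near-exact
    reverse-complement image of the mature (minus its 2 nt 3' overhang)
    on the other side of a ≥ min_gap loop.

    This is the Dicer-duplex geometry test: a genuine precursor carries
    the image with at most a few wobble/mismatch positions, while for a
    random stack a ≥85%-identity match of a specific (mlen−2)-mer is
    vanishingly unlikely — so random candidates stay untrimmed (the full
    excision window) and fail the length/structure criteria.  Returns
    the star span with its 2 nt overhang slack, or None."""
    L = mlen - 2
    if L < 10 or m_off < 0 or m_off + mlen > len(seq):
        return None
    pattern = revcomp(seq[m_off : m_off + L])
    max_mm = max(2, (L * 15) // 100)
    best: tuple[int, int, int] | None = None  # (mm, distance, start)
    for s in range(0, len(seq) - L + 1):
        if not (s >= m_off + mlen + min_gap or s + L <= m_off - min_gap):
            continue
        mm = 0
        for a, b in zip(pattern, seq[s : s + L]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            dist = s - (m_off + mlen) if s > m_off else m_off - (s + L)
            key = (mm, dist, s)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    s = best[2]
    return max(0, s - 2), min(len(seq), s + L + 2)


def excise_candidates(
    stack: ReadStack,
    genome: Mapping[str, str] | Sequence[SeqRecord],
    flank_long: int = 70,
    flank_short: int = 20,
) -> list[HairpinCandidate]:
    """Excise, fold and trim a precursor candidate around the stack's
    modal read.  Returns a single unevaluated candidate (empty list if
    the locus is too short to fold)."""
    seqs = (
        dict(genome)
        if isinstance(genome, Mapping)
        else {r.id: r.seq for r in genome}
    )
    scaffold = stack.interval.scaffold
    strand = stack.interval.strand
    text = seqs[scaffold]
    ms, me = stack.modal_start, stack.modal_end
    mlen = me - ms

    if strand == "+":
        windows = [(ms - flank_long, me + flank_short), (ms - flank_short, me + flank_long)]
    else:  # transcript-upstream is genomic-downstream
        windows = [(ms - flank_short, me + flank_long), (ms - flank_long, me + flank_short)]

    folded = []
    for w_lo, w_hi in windows:
        w_lo, w_hi = max(0, w_lo), min(len(text), w_hi)
        if w_hi - w_lo < max(mlen + 10, 20) or w_hi - w_lo > 200:
            continue
        seq = text[w_lo:w_hi]
        if strand == "-":
            seq = revcomp(seq)
        try:
            structure = fold_hairpin(seq)
        except ValueError:
            continue
        off = (ms - w_lo) if strand == "+" else (w_hi - me)
        star = _scan_star(seq, off, mlen)
        folded.append(((w_lo, w_hi), seq, structure, off, star))
    if not folded:
        return []
    # a window exhibiting a genuine mature/star duplex wins outright;
    # otherwise higher paired fraction, then fewer terminal loops, then
    # the upstream (first-listed) window
    best = max(
        range(len(folded)),
        key=lambda i: (
            folded[i][4] is not None,
            folded[i][2].paired_fraction,
            -folded[i][2].n_terminal_loops,
            -i,
        ),
    )
    (w_lo, w_hi), wseq, wstruct, m_off, star = folded[best]

    if star is None:
        trim_lo, trim_hi = 0, len(wseq)
    else:
        lo, hi = star
        trim_lo = min(m_off, lo)
        trim_hi = max(m_off + mlen, hi)
    pseq = wseq[trim_lo:trim_hi]
    try:
        structure = fold_hairpin(pseq)
    except ValueError:
        return []
    m_off2 = m_off - trim_lo
    star2 = predict_star(structure.pairs, m_off2, mlen)
    if star2 is not None:
        star2 = (
            max(0, star2[0]),
            min(len(pseq), star2[1]) - max(0, star2[0]),
        )  # (offset, length)
        if star2[1] < 10:
            star2 = None
    if strand == "+":
        g_lo, g_hi = w_lo + trim_lo, w_lo + trim_hi
    else:
        g_lo, g_hi = w_hi - trim_hi, w_hi - trim_lo
    return [
        HairpinCandidate(
            precursor_interval=GenomicInterval(scaffold, g_lo, g_hi, strand),
            precursor_seq=pseq,
            structure=structure,
            mature=(m_off2, mlen),
            star=star2,
        )
    ]


# ---------------------------------------------------------------------------
# criteria


def evaluate_criteria(
    candidate: HairpinCandidate,
    stack: ReadStack,
    star_alignments: Iterable[Alignment],
    annotation: Sequence[Feature],
    min_hairpin_len: int = 60,
    max_hairpin_len: int = 80,
    min_paired_fraction: float = 0.45,
    min_homogeneity: float = 0.70,
) -> HairpinCandidate:
    """Set the six curation flags and the ≥3-of-6 verdict.

    All thresholds are inclusive at their boundaries.  Criteria that
    cannot be evaluated (e.g. no predicted star) count as unmet.
    """
    st = candidate.structure
    c1 = st.n_terminal_loops == 1 and st.paired_fraction >= min_paired_fraction
    plen = len(candidate.precursor_seq)
    c2 = min_hairpin_len <= plen <= max_hairpin_len

    c3 = False
    if candidate.star is not None:
        s_lo, s_hi = candidate.star[0], candidate.star[0] + candidate.star[1]
        m_lo, m_hi = candidate.mature[0], candidate.mature[0] + candidate.mature[1]
        disjoint = s_hi <= m_lo or s_lo >= m_hi  # star is the *other* arm
        over = _duplex_overhangs(st.pairs, candidate.mature, (s_lo, s_hi))
        if disjoint and over is not None and 2 <= over[0] <= 3 and 2 <= over[1] <= 3:
            # star must be seen in the reads: >=1 read 5' end within ±1 nt
            g5 = _transcript_to_genomic_5p(candidate, candidate.star[0])
            iv = candidate.precursor_interval
            for a in star_alignments:
                if (
                    a.interval.scaffold == iv.scaffold
                    and a.interval.strand == iv.strand
                    and abs(_five_prime(a) - g5) <= 1
                ):
                    c3 = True
                    break

    # integer comparison avoids float edge effects at exactly 70%
    max5 = max(stack.five_prime_counts.values())
    c4 = max5 * 100 >= int(round(min_homogeneity * 100)) * stack.n_reads

    c5 = False
    if stack.length_histogram:
        top = max(stack.length_histogram.values())
        peak = min(L for L, c in stack.length_histogram.items() if c == top)
        c5 = 20 <= peak <= 24

    c6 = not any(
        f.ftype in ("ncRNA", "repeat")
        and f.interval.overlap(candidate.precursor_interval) >= 1
        for f in annotation
    )

    candidate.criteria = {"c1": c1, "c2": c2, "c3": c3, "c4": c4, "c5": c5, "c6": c6}
    candidate.n_met = sum(candidate.criteria.values())
    candidate.verdict = "kept" if candidate.n_met >= CRITERIA_REQUIRED else "discarded"
    return candidate


def _transcript_to_genomic_5p(candidate: HairpinCandidate, offset: int) -> int:
    """Genomic index of the 5' base of a transcript-coordinate offset."""
    iv = candidate.precursor_interval
    if iv.strand == "+":
        return iv.start + offset
    return iv.end - 1 - offset


def verdict_from_flags(flags: Sequence[bool]) -> str:
    """Pure ≥3-of-6 rule (exposed for exhaustive truth-table checks)."""
    return "kept" if sum(flags) >= CRITERIA_REQUIRED else "discarded"


# ---------------------------------------------------------------------------
# quantification


def quantify(
    mirnas: list[MatureMiRNA],
    alignments: Iterable[Alignment],
    total_mapped_reads: int | None = None,
) -> list[MatureMiRNA]:
    """Assign mapped reads to curated mature loci and compute counts,
    RPM and percentage shares.

    A read counts for a mature if an alignment overlaps the mature locus
    by at least (mature length − 2) nt on the same strand; reads
    assignable to two matures go to the larger overlap, exact ties are
    dropped from all shares.
    """
    loci: dict[tuple[str, str], list[tuple[int, int, int]]] = defaultdict(list)
    for idx, m in enumerate(mirnas):
        iv = m.candidate.mature_interval
        loci[(iv.scaffold, iv.strand)].append((iv.start, iv.end, idx))
    for key in loci:
        loci[key].sort()

    best_by_read: dict[str, tuple[int, int]] = {}  # read_id -> (overlap, idx)
    dropped: set[str] = set()
    seen_reads: set[str] = set()
    for a in alignments:
        seen_reads.add(a.read_id)
        key = (a.interval.scaffold, a.interval.strand)
        for lo, hi, idx in loci.get(key, ()):
            if lo >= a.interval.end:
                break
            ov = min(hi, a.interval.end) - max(lo, a.interval.start)
            need = len(mirnas[idx].seq) - 2
            if ov >= need:
                prev = best_by_read.get(a.read_id)
                if prev is None or ov > prev[0]:
                    best_by_read[a.read_id] = (ov, idx)
                    dropped.discard(a.read_id)
                elif ov == prev[0] and idx != prev[1]:
                    dropped.add(a.read_id)

    counts = Counter(
        idx for rid, (_, idx) in best_by_read.items() if rid not in dropped
    )
    total_assigned = sum(counts.values())
    total_mapped = total_mapped_reads if total_mapped_reads is not None else len(seen_reads)
    for idx, m in enumerate(mirnas):
        m.read_count = counts.get(idx, 0)
        m.rpm = m.read_count * 1e6 / total_mapped if total_mapped else 0.0
        m.share = m.read_count * 100.0 / total_assigned if total_assigned else 0.0
    return mirnas


def name_mirnas(
    candidates: Sequence[HairpinCandidate], prefix: str = "mqu-mir"
) -> list[MatureMiRNA]:
    """Wrap kept candidates as named matures, numbered in genomic
    (discovery) order."""
    kept = [c for c in candidates if c.verdict == "kept"]
    kept.sort(
        key=lambda c: (
            c.precursor_interval.scaffold,
            c.precursor_interval.start,
            c.precursor_interval.strand,
        )
    )
    return [
        MatureMiRNA(name=f"{prefix}-{i + 1}", seq=c.mature_seq, candidate=c)
        for i, c in enumerate(kept)
    ]
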