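"""Planted-truth simulator for the whole analysis.

Generates a multi-scaffold genome with gene/exon/ncRNA/repeat/pseudogene
annotation, plants pre-miRNA hairpins whose mature arms dominate a
simulated small-RNA read pool (22 nt mode, 5′-U bias, Zipf abundance),
plants decoy loci that violate the curation criteria, and builds
miRBase-style reference catalogs with configurable cross-species sharing.
Every output is a deterministic function of the seed.

Hairpin design: precursor = mature + loop + star read 5′→3′, with
star = revcomp(mature[:-2]) plus a 2 nt 3′ overhang, so the mature/star
duplex carries the canonical 2 nt 3′ overhang at both ends.  The loop
is drawn from {A, C}, the mature 3′ dinucleotide is fixed to CC and the
star overhang avoids partners of the mature 5′ bases, so no loop or
overhang base can pair and base-pair maximization recovers exactly the
designed single stem-loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    Feature,
    GenomicInterval,
    Read,
    SeqRecord,
    revcomp,
    to_dna,
    write_fasta,
    write_fastq,
    write_gff3,
    write_tsv,
)

#: Illumina TruSeq/NEB small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: per-species probability that a planted mature appears in that species'
#: catalog; proportions mirror the relative sharing observed across bees,
#: model insects, a mite and human in real miRNA repertoires
DEFAULT_SPECIES_PANEL: dict[str, float] = {
    "Bombus_impatiens": 0.197,
    "Bombus_terrestris": 0.171,
    "Apis_mellifera": 0.088,
    "Drosophila_melanogaster": 0.062,
    "Bombyx_mori": 0.057,
    "Varroa_destructor": 0.021,
    "Homo_sapiens": 0.010,
}

GO_VOCABULARY = [
    "cell",
    "protein binding",
    "metabolic process",
    "response to stimulus",
    "negative regulation",
    "positive regulation",
    "morphogenesis",
    "differentiation",
    "transport",
    "signaling",
    "growth",
    "development",
]


class SimConfigError(ValueError):
    pass


def zipf_alpha_for_top_share(top_share: float, n: int) -> float:
    """Zipf exponent at which rank 1 holds *top_share* of the mass over n
    ranks (analytic normalization: share_1 = 1 / H(n, alpha))."""
    ranks = np.arange(1, n + 1, dtype=float)

    def f(a: float) -> float:
        return 1.0 / np.sum(ranks**-a) - top_share

    return float(brentq(f, 0.1, 6.0))


def zipf_shares(alpha: float, n: int) -> np.ndarray:
    p = np.arange(1, n + 1, dtype=float) ** -alpha
    return p / p.sum()


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment."""

    seed: int = 1
    n_scaffolds: int = 3
    scaffold_len: int = 50_000
    gc_content: float = 0.35
    n_true_mirnas: int = 40
    n_decoys: int = 20
    context_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "intronic": 0.50,
            "intergenic": 0.38,
            "exonic": 0.11,
            "pseudogene": 0.01,
        }
    )
    #: None → solved so the expected rank-1 share is `top_share`
    abundance_alpha: float | None = None
    top_share: float = 0.423
    homogeneity_5p: float = 0.9
    frac_5pU: float = 0.8
    read_len_sd: float = 0.8
    n_mirna_reads: int = 190_000
    n_background_reads: int = 5_000
    n_decoy_reads_each: int = 250
    star_fraction: float = 0.1
    machine_read_len: int = 50
    adapter: str = DEFAULT_ADAPTER
    frac_lowq: float = 0.02
    frac_ambiguous: float = 0.01

    def __post_init__(self) -> None:
        total = sum(self.context_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"context proportions sum to {total}, not 1")
        for name in (
            "gc_content",
            "homogeneity_5p",
            "frac_5pU",
            "star_fraction",
            "frac_lowq",
            "frac_ambiguous",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        if self.abundance_alpha is None:
            self.abundance_alpha = zipf_alpha_for_top_share(
                self.top_share, self.n_true_mirnas
            )

    def stage_rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream per pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(8)[stage])


@dataclass(slots=True)
class PlantedMiRNA:
    name: str
    mature_seq: str
    star_seq: str
    precursor_interval: GenomicInterval
    context: str
    rank: int
    mature_offset: int = 0  # offset of mature within precursor (5' arm)
    true_read_count: int = 0

    @property
    def mature_interval(self) -> GenomicInterval:
        iv = self.precursor_interval
        return GenomicInterval(
            iv.scaffold,
            iv.start + self.mature_offset,
            iv.start + self.mature_offset + len(self.mature_seq),
            iv.strand,
        )

    @property
    def star_interval(self) -> GenomicInterval:
        iv = self.precursor_interval
        return GenomicInterval(
            iv.scaffold, iv.end - len(self.star_seq), iv.end, iv.strand
        )


@dataclass(slots=True)
class DecoyLocus:
    """A planted negative: read stack whose candidate must be discarded."""

    name: str
    kind: str  # 'a' non-hairpin | 'b' hairpin-in-repeat | 'c' long hairpin
    read_locus: GenomicInterval  # span the decoy reads pile onto
    precursor_interval: GenomicInterval | None = None


# ---------------------------------------------------------------------------
# genome + annotation


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def simulate_genome(cfg: SimConfig) -> tuple[list[SeqRecord], list[Feature]]:
    """I.i.d.-base scaffolds with non-overlapping ≥2-exon gene models and
    scattered ncRNA/repeat/pseudogene features in intergenic space."""
    if cfg.scaffold_len < 10_000:
        raise SimConfigError("scaffold_len too short to host gene models")
    rng = cfg.stage_rng(0)
    genome: list[SeqRecord] = []
    annotation: list[Feature] = []
    for s in range(cfg.n_scaffolds):
        name = f"scaffold_{s + 1}"
        seq = _random_bases(rng, cfg.scaffold_len, cfg.gc_content)
        genome.append(SeqRecord(id=name, seq=seq))
        pos = int(rng.integers(500, 1500))
        gi = 0
        gene_spans: list[tuple[int, int]] = []
        while True:
            n_exons = int(rng.integers(2, 5))
            exon_lens = rng.integers(150, 401, size=n_exons)
            intron_lens = rng.integers(600, 2501, size=n_exons - 1)
            glen = int(exon_lens.sum() + intron_lens.sum())
            if pos + glen > cfg.scaffold_len - 500:
                break
            gi += 1
            gene_id = f"{name}_g{gi}"
            annotation.append(
                Feature(GenomicInterval(name, pos, pos + glen), "gene", gene_id)
            )
            epos = pos
            for e in range(n_exons):
                annotation.append(
                    Feature(
                        GenomicInterval(name, epos, epos + int(exon_lens[e])),
                        "exon",
                        gene_id,
                    )
                )
                epos += int(exon_lens[e])
                if e < n_exons - 1:
                    epos += int(intron_lens[e])
            gene_spans.append((pos, pos + glen))
            pos += glen + int(rng.integers(1000, 3001))
        # scatter small features in intergenic space
        gaps = _complement_spans(gene_spans, cfg.scaffold_len, margin=100)
        for ftype, flen_lo, flen_hi, count in (
            ("ncRNA", 80, 150, 4),
            ("repeat", 200, 500, 4),
            ("pseudogene", 300, 800, 2),
        ):
            placed = 0
            attempts = 0
            occupied: list[tuple[int, int]] = []
            while placed < count and attempts < 200:
                attempts += 1
                flen = int(rng.integers(flen_lo, flen_hi + 1))
                gap = gaps[int(rng.integers(len(gaps)))]
                if gap[1] - gap[0] < flen + 20:
                    continue
                start = int(rng.integers(gap[0], gap[1] - flen))
                span = (start, start + flen)
                if any(_spans_overlap(span, o) for o in occupied):
                    continue
                taken = [
                    f
                    for f in annotation
                    if f.interval.scaffold == name
                    and f.ftype in ("ncRNA", "repeat", "pseudogene")
                ]
                if any(
                    _spans_overlap(span, (f.interval.start, f.interval.end))
                    for f in taken
                ):
                    continue
                occupied.append(span)
                placed += 1
                annotation.append(
                    Feature(
                        GenomicInterval(name, span[0], span[1]),
                        ftype,
                        f"{name}_{ftype}{placed}",
                    )
                )
            if placed < count:
                raise SimConfigError(
                    f"could not place {count} {ftype} features on {name}"
                )
    return genome, annotation


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _complement_spans(
    spans: Sequence[tuple[int, int]], total: int, margin: int = 0
) -> list[tuple[int, int]]:
    """Gaps of [0, total) not covered by *spans*, shrunk by margin."""
    out = []
    prev = 0
    for s, e in sorted(spans):
        if s - prev > 2 * margin:
            out.append((prev + margin, s - margin))
        prev = max(prev, e)
    if total - prev > 2 * margin:
        out.append((prev + margin, total - margin))
    return out


# ---------------------------------------------------------------------------
# hairpin planting


def _make_mature(rng: np.random.Generator, length: int, frac_5pU: float) -> str:
    first = "T" if rng.random() < frac_5pU else "ACG"[int(rng.integers(3))]
    middle = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=length - 3))
    return first + middle + "CC"  # CC tail: no partners among loop/overhang bases


_PAIR_PARTNERS = {"A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "T": {"A", "G"}}


def _build_star(rng: np.random.Generator, mature: str) -> str:
    """Star arm: exact reverse complement of the mature minus its 2 nt
    3' overhang, plus the star's own 2 nt 3' overhang.

    The overhang is drawn from {A, C} avoiding partners of the mature 5'
    bases so max-pairing folding cannot absorb it into the stem."""
    safe = [
        b
        for b in "AC"
        if mature[0] not in _PAIR_PARTNERS[b] and mature[1] not in _PAIR_PARTNERS[b]
    ] or [b for b in "AC" if mature[0] not in _PAIR_PARTNERS[b]]
    return revcomp(mature[:-2]) + safe[0] * 2


def _make_precursor(rng: np.random.Generator, mature: str) -> tuple[str, str]:
    """Return (precursor, star) with designed 2 nt 3' overhangs."""
    m = len(mature)
    loop_len = int(rng.integers(max(12, 60 - 2 * m), 21))
    loop = "".join("AC"[int(b)] for b in rng.integers(0, 2, size=loop_len))
    star = _build_star(rng, mature)
    return mature + loop + star, star


def _mirror_guard(text: list[str], start: int, end: int, precursor: str, pad: int = 3) -> None:
    """Set the bases immediately 5' of a planted hairpin to the star's
    3'-overhang base.  A 5'-jittered read starting just upstream of the
    arm would otherwise find an exact reverse-complement image running
    from the star core into its overhang whenever the upstream base
    happened to complement it — surfacing as an artificial homogeneous
    minus-strand read stack.  A base never equals its complement, so
    this pins those mirror alignments to ≥1 mismatch, and minimum-
    mismatch mapping then keeps only the true (exact) locus."""
    guard = precursor[-1]  # star overhang base, from {A, C}
    for t in range(pad):
        i = start - 1 - t
        if i >= 0:
            text[i] = guard


def _context_spans(
    annotation: Sequence[Feature], scaffold: str, scaffold_len: int
) -> dict[str, list[tuple[int, int]]]:
    feats = [f for f in annotation if f.interval.scaffold == scaffold]
    genes = [f for f in feats if f.ftype == "gene"]
    exons = [f for f in feats if f.ftype == "exon"]
    blockers = [
        (f.interval.start, f.interval.end)
        for f in feats
        if f.ftype in ("ncRNA", "repeat", "pseudogene")
    ]
    spans: dict[str, list[tuple[int, int]]] = {
        "exonic": [(f.interval.start, f.interval.end) for f in exons],
        "pseudogene": [
            (f.interval.start, f.interval.end) for f in feats if f.ftype == "pseudogene"
        ],
        "intronic": [],
        "intergenic": [],
    }
    for g in genes:
        g_exons = sorted(
            (f.interval.start, f.interval.end)
            for f in exons
            if f.gene_id == g.gene_id
        )
        prev = g.interval.start
        for es, ee in g_exons:
            if es > prev:
                spans["intronic"].append((prev, es))
            prev = max(prev, ee)
        if g.interval.end > prev:
            spans["intronic"].append((prev, g.interval.end))
    covered = [(f.interval.start, f.interval.end) for f in genes] + blockers
    spans["intergenic"] = _complement_spans(covered, scaffold_len, margin=150)
    return spans


def _quota_counts(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n items to the proportions."""
    items = sorted(proportions.items())
    raw = {k: v * n for k, v in items}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k, _ in sorted(items, key=lambda kv: raw[kv[0]] - counts[kv[0]], reverse=True)[
        :short
    ]:
        counts[k] += 1
    return counts


def plant_hairpins(
    genome: list[SeqRecord],
    annotation: list[Feature],
    cfg: SimConfig,
) -> tuple[list[PlantedMiRNA], list[DecoyLocus]]:
    """Overwrite genome sequence with pre-miRNA hairpins honouring the
    configured genomic-context quotas, and plant decoy loci.

    Decoys each violate at least four of the six curation criteria:
    all three kinds get heterogeneous 5′ read ends, no star reads and a
    read-length mode of ~27 nt; kind (a) additionally sits on
    non-hairpin sequence, (b) inside an annotated repeat/ncRNA, and (c)
    folds into a 110 nt over-long hairpin.
    """
    rng = cfg.stage_rng(1)
    seqs = {r.id: list(r.seq) for r in genome}
    lens = {r.id: len(r.seq) for r in genome}
    spans_by_scaffold = {
        r.id: _context_spans(annotation, r.id, lens[r.id]) for r in genome
    }
    used: dict[str, list[tuple[int, int]]] = {r.id: [] for r in genome}
    MIN_SEP = 200

    def place(context: str, length: int) -> GenomicInterval | None:
        """Random non-overlapping site of *length* inside a span of the
        requested context."""
        options = [
            (sc, span)
            for sc in seqs
            for span in spans_by_scaffold[sc][context]
            if span[1] - span[0] >= length + 20
        ]
        order = rng.permutation(len(options))
        for oi in order:
            sc, (lo, hi) = options[int(oi)]
            for _ in range(30):
                start = int(rng.integers(lo + 10, hi - length - 10))
                cand = (start - MIN_SEP, start + length + MIN_SEP)
                if not any(_spans_overlap(cand, u) for u in used[sc]):
                    used[sc].append((start, start + length))
                    return GenomicInterval(sc, start, start + length)
        return None

    # contexts shuffled across abundance ranks
    quota = _quota_counts(cfg.context_proportions, cfg.n_true_mirnas)
    contexts = [c for c, k in sorted(quota.items()) for _ in range(k)]
    contexts = [contexts[int(i)] for i in rng.permutation(len(contexts))]

    planted: list[PlantedMiRNA] = []
    for rank in range(1, cfg.n_true_mirnas + 1):
        # dominant miRNAs fixed at the canonical 22 nt so the read pool
        # mode lands at 22; the rest draw 20-24 centred on 22
        if rank <= 2:
            m_len = 22
        else:
            m_len = int(rng.choice([20, 21, 22, 23, 24], p=[0.1, 0.2, 0.4, 0.2, 0.1]))
        mature = _make_mature(rng, m_len, cfg.frac_5pU)
        precursor, star = _make_precursor(rng, mature)
        context = contexts[rank - 1]
        site = place(context, len(precursor))
        if site is None:
            raise SimConfigError(f"cannot satisfy context quota for {context!r}")
        seqs[site.scaffold][site.start : site.end] = list(precursor)
        _mirror_guard(seqs[site.scaffold], site.start, site.end, precursor)
        planted.append(
            PlantedMiRNA(
                name=f"sim-mir-{rank}",
                mature_seq=mature,
                star_seq=star,
                precursor_interval=site,
                context=context,
                rank=rank,
            )
        )

    decoys: list[DecoyLocus] = []
    kinds = ["a", "b", "c"]
    for d in range(cfg.n_decoys):
        kind = kinds[d % 3]
        name = f"decoy-{kind}-{d + 1}"
        if kind == "a":
            # plain genomic sequence, no hairpin planted
            site = place("intergenic", 27)
            if site is None:
                raise SimConfigError("cannot place decoy of kind 'a'")
            decoys.append(DecoyLocus(name, "a", site))
        elif kind == "b":
            # genuine hairpin inside a repeat feature; 90 nt so the
            # length criterion fails by design as well
            mature = _make_mature(rng, 27, cfg.frac_5pU)
            loop = "".join("AC"[int(b)] for b in rng.integers(0, 2, size=36))
            precursor = mature + loop + _build_star(rng, mature)
            repeats = [
                f
                for f in annotation
                if f.ftype == "repeat" and len(f.interval) >= len(precursor) + 10
            ]
            iv = None
            for ri in rng.permutation(len(repeats)):
                f = repeats[int(ri)]
                start = f.interval.start + 5
                cand = GenomicInterval(f.interval.scaffold, start, start + len(precursor))
                if not any(
                    _spans_overlap((cand.start, cand.end), u) for u in used[cand.scaffold]
                ):
                    iv = cand
                    break
            if iv is None:
                raise SimConfigError("cannot place decoy of kind 'b' in any repeat")
            used[iv.scaffold].append((iv.start, iv.end))
            seqs[iv.scaffold][iv.start : iv.end] = list(precursor)
            _mirror_guard(seqs[iv.scaffold], iv.start, iv.end, precursor)
            decoys.append(
                DecoyLocus(
                    name,
                    "b",
                    GenomicInterval(iv.scaffold, start, start + 27),
                    precursor_interval=iv,
                )
            )
        else:
            # 110 nt over-long hairpin in intergenic space
            arm = (_make_mature(rng, 27, cfg.frac_5pU) + _random_bases(rng, 18, 0.5))[:45]
            loop = "".join("AC"[int(b)] for b in rng.integers(0, 2, size=20))
            precursor = arm + loop + _build_star(rng, arm)
            site = place("intergenic", len(precursor))
            if site is None:
                raise SimConfigError("cannot place decoy of kind 'c'")
            seqs[site.scaffold][site.start : site.end] = list(precursor)
            _mirror_guard(seqs[site.scaffold], site.start, site.end, precursor)
            decoys.append(
                DecoyLocus(
                    name,
                    "c",
                    GenomicInterval(site.scaffold, site.start, site.start + 27),
                    precursor_interval=site,
                )
            )
    for rec in genome:
        rec.seq = "".join(seqs[rec.id])
    return planted, decoys


# ---------------------------------------------------------------------------
# reads


def _jitter_probs(sd: float) -> np.ndarray:
    d = np.arange(-2, 3, dtype=float)
    p = np.exp(-(d**2) / (2 * sd**2))
    return p / p.sum()


def simulate_reads(
    planted: Sequence[PlantedMiRNA],
    decoys: Sequence[DecoyLocus],
    genome: Sequence[SeqRecord],
    cfg: SimConfig,
) -> list[Read]:
    """Simulate the adapter-bearing small-RNA library.

    Per-miRNA totals follow a Zipf law (exponent solved so the expected
    rank-1 share matches the configured top share); a star_fraction of
    each miRNA's reads come from the star arm; 5′ ends are jittered so
    the modal 5′ position has frequency homogeneity_5p and 3′ ends ±2 nt;
    decoy stacks get heterogeneous 5′ ends and a ~27 nt length mode;
    background reads are uniform random genome fragments.  The 3′
    adapter is appended and reads are truncated to the machine length.
    Sets ``true_read_count`` on each planted miRNA.
    """
    if not planted:
        raise SimConfigError("no planted miRNAs to simulate reads from")
    rng = cfg.stage_rng(2)
    seqs = {r.id: r.seq for r in genome}
    p5 = np.array(
        [
            (1 - cfg.homogeneity_5p) / 2,
            cfg.homogeneity_5p,
            (1 - cfg.homogeneity_5p) / 2,
        ]
    )
    p3 = _jitter_probs(cfg.read_len_sd)
    counts = rng.multinomial(cfg.n_mirna_reads, zipf_shares(cfg.abundance_alpha, len(planted)))
    raw: list[str] = []

    def emit(scaffold: str, start: int, end: int) -> None:
        start = max(0, start)
        end = min(len(seqs[scaffold]), end)
        if end - start < 10:
            return
        insert = seqs[scaffold][start:end]
        raw.append((insert + cfg.adapter)[: cfg.machine_read_len])

    for mir, total in zip(planted, counts):
        mir.true_read_count = int(total)
        n_star = rng.binomial(total, cfg.star_fraction)
        iv = mir.precursor_interval
        m = len(mir.mature_seq)
        spans = [
            (iv.start, iv.start + m, int(total) - int(n_star)),
            (iv.end - len(mir.star_seq), iv.end, int(n_star)),
        ]
        for lo, hi, n in spans:
            if n <= 0:
                continue
            j5 = rng.choice([-1, 0, 1], size=n, p=p5)
            j3 = rng.choice([-2, -1, 0, 1, 2], size=n, p=p3)
            for a, b in zip(j5, j3):
                emit(iv.scaffold, lo + int(a), hi + int(b))

    het5 = np.array([0.175, 0.175, 0.30, 0.175, 0.175])
    for dec in decoys:
        iv = dec.read_locus
        n = cfg.n_decoy_reads_each
        j5 = rng.choice([-2, -1, 0, 1, 2], size=n, p=het5)
        dlen = rng.choice([26, 27, 28], size=n, p=[0.25, 0.5, 0.25])
        for a, L in zip(j5, dlen):
            emit(iv.scaffold, iv.start + int(a), iv.start + int(a) + int(L))

    names = sorted(seqs)
    for _ in range(cfg.n_background_reads):
        sc = names[int(rng.integers(len(names)))]
        L = int(rng.integers(15, 36))
        start = int(rng.integers(0, len(seqs[sc]) - L))
        frag = seqs[sc][start : start + L]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        raw.append((frag + cfg.adapter)[: cfg.machine_read_len])

    # quality classes and ambiguous bases, then a global shuffle
    order = rng.permutation(len(raw))
    u = rng.random(len(raw))
    reads: list[Read] = []
    for i, oi in enumerate(order):
        seq = raw[int(oi)]
        if u[i] < cfg.frac_lowq:
            qual = "0" * len(seq)  # Phred 15: fails the mean-quality filter
        else:
            qual = "I" * len(seq)  # Phred 40
            if u[i] < cfg.frac_lowq + cfg.frac_ambiguous:
                pos = int(rng.integers(len(seq)))
                seq = seq[:pos] + "N" + seq[pos + 1 :]
        reads.append(Read(id=f"r{i:07d}", seq=seq, qual=qual))
    return reads


# ---------------------------------------------------------------------------
# reference catalogs


def make_reference_catalogs(
    planted: Sequence[PlantedMiRNA],
    cfg: SimConfig,
    species_panel: Mapping[str, float] | None = None,
    n_subs_max: int = 2,
    n_private: int = 30,
) -> tuple[dict[str, list[SeqRecord]], pd.DataFrame]:
    """miRBase-style mature catalogs per species.

    Each planted mature enters a species' catalog with that species'
    sharing probability, carrying 0–2 substitutions outside the seed
    (positions 2–8); each catalog also holds species-private decoy
    matures.  Catalog sequences are written in RNA alphabet, as in
    miRBase.  Returns the catalogs and the expected-sharing truth table.
    """
    panel = dict(DEFAULT_SPECIES_PANEL if species_panel is None else species_panel)
    rng = cfg.stage_rng(3)
    catalogs: dict[str, list[SeqRecord]] = {}
    truth_rows: list[dict] = []
    for species in sorted(panel):
        prob = panel[species]
        prefix = "".join(w[0] for w in species.lower().split("_"))[:4]
        entries: list[SeqRecord] = []
        for mir in planted:
            if rng.random() >= prob:
                continue
            seq = mir.mature_seq
            n_subs = int(rng.integers(0, n_subs_max + 1))
            # substitutions only outside the seed (query nt 2-8, 1-based)
            allowed = [0] + list(range(8, len(seq) - 1))
            subs = rng.choice(allowed, size=min(n_subs, len(allowed)), replace=False)
            chars = list(seq)
            for p in subs:
                choices = [b for b in "ACGT" if b != chars[p]]
                chars[p] = choices[int(rng.integers(3))]
            rna = "".join(chars).replace("T", "U")
            entries.append(
                SeqRecord(
                    id=f"{prefix}-miR-{mir.rank}",
                    seq=rna,
                    description=f"{prefix}-miR-{mir.rank} {species} mature",
                )
            )
            truth_rows.append(
                {"species": species, "mirna": mir.name, "n_subs": int(len(subs))}
            )
        for k in range(n_private):
            seq = "".join("ACGU"[int(b)] for b in rng.integers(0, 4, size=22))
            entries.append(
                SeqRecord(
                    id=f"{prefix}-miR-p{k + 1}",
                    seq=seq,
                    description=f"{prefix}-miR-p{k + 1} {species} private",
                )
            )
        catalogs[species] = entries
    truth = pd.DataFrame(truth_rows, columns=["species", "mirna", "n_subs"])
    return catalogs, truth


# ---------------------------------------------------------------------------
# target-site fixture + gene2go


def plant_target_utrs(
    mirnas: Sequence[tuple[str, str]],
    seed: int,
    n_decoy_utrs: int = 40,
    utr_len: int = 800,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Synthetic 3'UTR panel with planted consensus-grade target sites.

    For each (name, mature_seq) a UTR embeds the full reverse complement
    of the mature (a perfect 8mer seed site with maximal compensatory
    pairing); decoy UTRs are random sequence.  Returns UTR records and a
    truth table of (mirna, gene_id, site position of the seed-match 3'
    end on the UTR).
    """
    rng = np.random.default_rng(seed)
    records: list[SeqRecord] = []
    rows: list[dict] = []
    for i, (name, mat) in enumerate(mirnas):
        mat = to_dna(mat)
        site = revcomp(mat)
        bg = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=utr_len))
        pos = int(rng.integers(80, utr_len - len(site) - 80))
        seq = bg[:pos] + site + bg[pos + len(site) :]
        gene = f"target_gene_{i + 1}"
        records.append(SeqRecord(id=gene, seq=seq))
        # seed-match 3' end: complement of miRNA nt 2 sits at site 3' end - 1
        rows.append({"mirna": name, "gene_id": gene, "site_end": pos + len(site) - 1})
    for j in range(n_decoy_utrs):
        seq = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=utr_len))
        records.append(SeqRecord(id=f"decoy_gene_{j + 1}", seq=seq))
    return records, pd.DataFrame(rows, columns=["mirna", "gene_id", "site_end"])


def generate_gene2go(
    annotation: Sequence[Feature], cfg: SimConfig
) -> pd.DataFrame:
    """Assign each annotated gene 1-3 GO labels from a small vocabulary."""
    rng = cfg.stage_rng(4)
    rows = []
    for f in annotation:
        if f.ftype != "gene":
            continue
        k = int(rng.integers(1, 4))
        terms = rng.choice(len(GO_VOCABULARY), size=k, replace=False)
        for t in sorted(terms):
            rows.append({"gene_id": f.gene_id, "go_term": GO_VOCABULARY[int(t)]})
    return pd.DataFrame(rows, columns=["gene_id", "go_term"])


# ---------------------------------------------------------------------------
# run-directory writer


def write_run(cfg: SimConfig, outdir: str | Path) -> dict[str, object]:
    """Generate a full synthetic experiment under *outdir*.

    Writes genome.fa, annotation.gff3, reads.fastq, catalogs/<species>.fa,
    gene2go.tsv and the truth manifests (truth_mirnas.tsv,
    truth_decoys.tsv, truth_sharing.tsv).  Returns the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation = simulate_genome(cfg)
    planted, decoys = plant_hairpins(genome, annotation, cfg)
    reads = simulate_reads(planted, decoys, genome, cfg)
    catalogs, sharing_truth = make_reference_catalogs(planted, cfg)
    gene2go = generate_gene2go(annotation, cfg)

    write_fasta(genome, outdir / "genome.fa")
    write_gff3(annotation, outdir / "annotation.gff3")
    write_fastq(reads, outdir / "reads.fastq")
    (outdir / "catalogs").mkdir(exist_ok=True)
    for species, entries in catalogs.items():
        write_fasta(entries, outdir / "catalogs" / f"{species}.fa")
    write_tsv(gene2go, outdir / "gene2go.tsv")

    truth = pd.DataFrame(
        [
            {
                "name": p.name,
                "rank": p.rank,
                "scaffold": p.precursor_interval.scaffold,
                "prec_start": p.precursor_interval.start,
                "prec_end": p.precursor_interval.end,
                "strand": p.precursor_interval.strand,
                "context": p.context,
                "mature_seq": p.mature_seq,
                "star_seq": p.star_seq,
                "true_read_count": p.true_read_count,
            }
            for p in planted
        ]
    )
    write_tsv(truth, outdir / "truth_mirnas.tsv")
    decoy_df = pd.DataFrame(
        [
            {
                "name": d.name,
                "kind": d.kind,
                "scaffold": d.read_locus.scaffold,
                "start": d.read_locus.start,
                "end": d.read_locus.end,
            }
            for d in decoys
        ]
    )
    write_tsv(decoy_df, outdir / "truth_decoys.tsv")
    write_tsv(sharing_truth, outdir / "truth_sharing.tsv")
    return {
        "genome": genome,
        "annotation": annotation,
        "planted": planted,
        "decoys": decoys,
        "reads": reads,
        "catalogs": catalogs,
        "sharing_truth": sharing_truth,
        "gene2go": gene2go,
    }
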