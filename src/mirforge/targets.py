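"""Consensus miRNA target prediction on approximate 3'UTRs.

3'UTRs are approximated as the 1000 nt downstream of each gene's
annotated end (strand-aware, not truncated at neighbouring genes).
Three independent predictors score each candidate site — a canonical
seed-match classifier (6mer/7mer-A1/7mer-m8/8mer), an ungapped duplex
complementarity score, and a site-accessibility score (duplex proxy
penalized by the pairing lost when the site is forced open) — and only
sites called by all three are retained as consensus targets.
All matching happens in DNA space (T ≡ U).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .folding import ENERGY_WEIGHTS, nussinov
from .io_formats import Feature, GenomicInterval, SeqRecord, revcomp, to_dna

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
#: duplex scoring per aligned position
_PAIR_SCORE = {
    ("G", "C"): 3.0,
    ("C", "G"): 3.0,
    ("A", "T"): 2.0,
    ("T", "A"): 2.0,
    ("G", "T"): 1.0,
    ("T", "G"): 1.0,
}
MISMATCH_SCORE = -2.0
P2_MIN_SCORE = 25.0
P3_MAX_DDG = -10.0
MAX_COMPENSATORY = 14  # 3'-pairing beyond the 8 nt seed


@dataclass(slots=True)
class UTRRecord:
    gene_id: str
    seq: str  # 5'->3' in mRNA sense, <= flank nt
    source_interval: GenomicInterval


@dataclass(slots=True)
class TargetSite:
    mirna: str
    gene_id: str
    utr_pos: int  # 0-based position of the seed-match 3' end on the UTR
    site_type: str  # 6mer | 7mer-A1 | 7mer-m8 | 8mer
    p1_hit: bool = False
    p2_score: float = 0.0
    p2_hit: bool = False
    p3_ddg: float = 0.0
    p3_hit: bool = False
    consensus: bool = False


class UTRExtractionError(ValueError):
    pass


def extract_3utrs(
    annotation: Sequence[Feature],
    genome: Sequence[SeqRecord] | Mapping[str, str],
    flank: int = 1000,
) -> list[UTRRecord]:
    """One putative 3'UTR per gene: the *flank* nt downstream of the
    gene end (upstream in plus coordinates, reverse-complemented, for
    minus-strand genes).  Genes at a scaffold edge yield shorter
    records; a gene on an unknown scaffold is an error."""
    seqs = (
        dict(genome) if isinstance(genome, Mapping) else {r.id: r.seq for r in genome}
    )
    utrs: list[UTRRecord] = []
    for f in annotation:
        if f.ftype != "gene":
            continue
        iv = f.interval
        if iv.scaffold not in seqs:
            raise UTRExtractionError(
                f"gene {f.gene_id!r} lies on unknown scaffold {iv.scaffold!r}"
            )
        text = seqs[iv.scaffold]
        if iv.strand == "+":
            lo, hi = iv.end, min(iv.end + flank, len(text))
            seq = text[lo:hi]
        else:
            lo, hi = max(0, iv.start - flank), iv.start
            seq = revcomp(text[lo:hi])
        if hi <= lo:
            continue  # gene flush against the scaffold edge: nothing downstream
        utrs.append(
            UTRRecord(
                gene_id=f.gene_id,
                seq=seq,
                source_interval=GenomicInterval(iv.scaffold, lo, hi, iv.strand),
            )
        )
    return utrs


# ---------------------------------------------------------------------------
# predictor 1: canonical seed-match classes


def predict_p1_seed(mirna_seq: str, utr: UTRRecord | SeqRecord) -> list[TargetSite]:
    """Scan a UTR for seed matches to miRNA nt 2–7 and classify them.

    6mer sites are reported but only 7mer-A1, 7mer-m8 and 8mer count as
    predictor-1 hits.  ``utr_pos`` is the UTR base opposite miRNA nt 1
    (the 3' end of the seed match region).
    """
    m = to_dna(mirna_seq)
    if len(m) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    useq = to_dna(utr.seq)
    gene_id = utr.gene_id if isinstance(utr, UTRRecord) else utr.id
    core = revcomp(m[1:7])  # matches opposite miRNA nt 2-7
    sites: list[TargetSite] = []
    start = useq.find(core)
    while start != -1:
        # UTR runs 5'->3'; the miRNA binds antiparallel, so nt 8 pairs
        # the base 5' of the core and nt 1 faces the base 3' of it
        m8 = start - 1 >= 0 and useq[start - 1] == _WC[m[7]]
        a1 = start + 6 < len(useq) and useq[start + 6] == "A"
        if m8 and a1:
            site_type = "8mer"
        elif m8:
            site_type = "7mer-m8"
        elif a1:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        sites.append(
            TargetSite(
                mirna="",
                gene_id=gene_id,
                utr_pos=start + 6,
                site_type=site_type,
                p1_hit=site_type in ("7mer-A1", "7mer-m8", "8mer"),
            )
        )
        start = useq.find(core, start + 1)
    return sites


# ---------------------------------------------------------------------------
# predictor 2: ungapped duplex complementarity


def predict_p2_duplex(
    mirna_seq: str, utr: UTRRecord | SeqRecord, site: TargetSite
) -> tuple[float, bool]:
    """Score the ungapped duplex anchored at the site: seed pairing plus
    up to 14 nt of 3'-compensatory pairing, GC +3 / AU +2 / GU +1 /
    mismatch −2.  A hit needs score ≥ 25 and at most one non-Watson-Crick
    position within the seed (nt 2–8)."""
    m = to_dna(mirna_seq)
    useq = to_dna(utr.seq)
    n_pos = min(len(m), 8 + MAX_COMPENSATORY)
    score = 0.0
    seed_non_wc = 0
    for i in range(n_pos):  # i = miRNA nt (i+1), paired antiparallel
        q = site.utr_pos - i
        if q < 0:
            break
        if q >= len(useq):  # A1 position can sit past the UTR end
            continue
        pair = (m[i], useq[q])
        score += _PAIR_SCORE.get(pair, MISMATCH_SCORE)
        if 1 <= i <= 7 and _WC.get(m[i]) != useq[q]:
            seed_non_wc += 1
    hit = score >= P2_MIN_SCORE and seed_non_wc <= 1
    return score, hit


# ---------------------------------------------------------------------------
# predictor 3: site accessibility


def predict_p3_access(
    utr: UTRRecord | SeqRecord,
    site: TargetSite,
    window: int = 70,
    seed_span: int = 8,
) -> tuple[float, bool]:
    """Accessibility ΔΔG proxy: ΔG_duplex (−p2 score) plus the pairing
    score lost when the seed site region is forced single-stranded in
    the maximum-weight structure of the surrounding window.

    More negative is more favourable; a hit needs ΔΔG ≤ −10.
    """
    useq = to_dna(utr.seq)
    site_lo = max(0, site.utr_pos - seed_span + 1)
    site_hi = min(len(useq), site.utr_pos + 1)  # A1 may sit past the UTR end
    pad = (window - (site_hi - site_lo)) // 2
    w_lo = max(0, site_lo - pad)
    w_hi = min(len(useq), site_hi + pad)
    wseq = useq[w_lo:w_hi]
    blocked = range(site_lo - w_lo, site_hi - w_lo)
    free_score, _ = nussinov(wseq, weights=ENERGY_WEIGHTS)
    open_score, _ = nussinov(wseq, weights=ENERGY_WEIGHTS, blocked=blocked)
    dg_open = free_score - open_score
    ddg = -site.p2_score + dg_open
    return ddg, ddg <= P3_MAX_DDG


# ---------------------------------------------------------------------------
# consensus


def predict_targets(
    mirnas: Sequence[tuple[str, str]],
    utrs: Sequence[UTRRecord | SeqRecord],
) -> list[TargetSite]:
    """Run all three predictors for every miRNA × UTR combination."""
    sites: list[TargetSite] = []
    for name, seq in mirnas:
        for utr in utrs:
            for site in predict_p1_seed(seq, utr):
                site.mirna = name
                site.p2_score, site.p2_hit = predict_p2_duplex(seq, utr, site)
                site.p3_ddg, site.p3_hit = predict_p3_access(utr, site)
                sites.append(site)
    return consensus_targets(sites)


def consensus_targets(sites: list[TargetSite]) -> list[TargetSite]:
    """A consensus site is one all three predictors call; the consensus
    set is by construction a subset of each predictor's positives."""
    for s in sites:
        s.consensus = s.p1_hit and s.p2_hit and s.p3_hit
    return sites


def target_genes(sites: Iterable[TargetSite]) -> list[str]:
    """Genes with at least one consensus site, sorted."""
    return sorted({s.gene_id for s in sites if s.consensus})


def sites_to_dataframe(sites: Iterable[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": s.mirna,
                "gene_id": s.gene_id,
                "utr_pos": s.utr_pos,
                "site_type": s.site_type,
                "p1_hit": s.p1_hit,
                "p2_score": s.p2_score,
                "p2_hit": s.p2_hit,
                "p3_ddg": s.p3_ddg,
                "p3_hit": s.p3_hit,
                "consensus": s.consensus,
            }
            for s in sites
        ],
        columns=[
            "mirna",
            "gene_id",
            "utr_pos",
            "site_type",
            "p1_hit",
            "p2_score",
            "p2_hit",
            "p3_ddg",
            "p3_hit",
            "consensus",
        ],
    )


# ---------------------------------------------------------------------------
# GO summarization


def summarize_go(
    genes: Iterable[str], gene2go: pd.DataFrame | Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Count GO term labels among target genes (descending); genes with
    no annotation are tallied under 'unannotated'.  Suitable as a word
    frequency table for external word-cloud rendering."""
    if isinstance(gene2go, pd.DataFrame):
        mapping: dict[str, list[str]] = {}
        for gene, term in zip(gene2go["gene_id"], gene2go["go_term"]):
            mapping.setdefault(str(gene), []).append(str(term))
    else:
        mapping = {g: list(ts) for g, ts in gene2go.items()}
    counts: Counter[str] = Counter()
    for g in genes:
        terms = mapping.get(g)
        if not terms:
            counts["unannotated"] += 1
        else:
            counts.update(terms)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["go_term", "count"])
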