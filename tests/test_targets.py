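import numpy as np
import pytest

from mirforge.io_formats import Feature, GenomicInterval, SeqRecord, revcomp
from mirforge.synthetic_data import plant_target_utrs
from mirforge.targets import (
    TargetSite,
    UTRExtractionError,
    UTRRecord,
    _PAIR_SCORE,
    consensus_targets,
    extract_3utrs,
    predict_p1_seed,
    predict_p2_duplex,
    predict_p3_access,
    predict_targets,
    summarize_go,
    target_genes,
)


def _genome(seq, name="s1"):
    return [SeqRecord(id=name, seq=seq)]


class TestExtract3UTRs:
    def test_plus_strand_downstream_slice(self):
        text = "A" * 500 + "C" * 1500
        ann = [Feature(GenomicInterval("s1", 100, 500, "+"), "gene", "g1")]
        utrs = extract_3utrs(ann, _genome(text))
        assert len(utrs) == 1
        assert utrs[0].seq == text[500:1500] and len(utrs[0].seq) == 1000

    def test_clipped_at_scaffold_end(self):
        text = "A" * 700
        ann = [Feature(GenomicInterval("s1", 100, 500, "+"), "gene", "g1")]
        utrs = extract_3utrs(ann, _genome(text))
        assert len(utrs[0].seq) == 200

    def test_minus_strand_revcomp(self):
        text = "".join("ACGT"[i % 4] for i in range(2000))
        ann = [Feature(GenomicInterval("s1", 1200, 1800, "-"), "gene", "g1")]
        utrs = extract_3utrs(ann, _genome(text))
        assert utrs[0].seq == revcomp(text[200:1200])

    def test_unknown_scaffold_names_gene(self):
        ann = [Feature(GenomicInterval("nope", 0, 100, "+"), "gene", "gX")]
        with pytest.raises(UTRExtractionError, match="gX"):
            extract_3utrs(ann, _genome("A" * 200))

    def test_one_record_per_gene_max_1000(self):
        text = "A" * 20_000
        ann = [
            Feature(GenomicInterval("s1", i * 3000 + 100, i * 3000 + 600, "+"), "gene", f"g{i}")
            for i in range(5)
        ]
        utrs = extract_3utrs(ann, _genome(text))
        assert len(utrs) == 5 and all(len(u.seq) <= 1000 for u in utrs)


MIR = "TGAGGTAGTAGGTTGTATAGTT"  # let-7 style 22-mer


def _utr_with_site(mirna, kind="8mer", pad=60):
    """Build a UTR with a single canonical seed site of a given class."""
    seed_core = revcomp(mirna[1:7])
    m8 = revcomp(mirna[7])
    a1 = "A"
    # 'G' filler: never complements miRNA nt 8 ('G'→'C') nor reads as the
    # A of an A1 anchor
    if kind == "8mer":
        site = m8 + seed_core + a1
    elif kind == "7mer-m8":
        site = m8 + seed_core + "G"
    elif kind == "7mer-A1":
        site = "G" + seed_core + a1
    else:  # 6mer
        site = "G" + seed_core + "G"
    bg = "C" * pad  # C background: cannot recreate the AC-rich seed core
    return UTRRecord(
        gene_id="g", seq=bg + site + bg, source_interval=GenomicInterval("s1", 0, 10)
    )


class TestSeedPredictor:
    @pytest.mark.parametrize(
        "kind,hit",
        [("8mer", True), ("7mer-m8", True), ("7mer-A1", True), ("6mer", False)],
    )
    def test_site_classes(self, kind, hit):
        sites = predict_p1_seed(MIR, _utr_with_site(MIR, kind))
        assert len(sites) == 1
        assert sites[0].site_type == kind and sites[0].p1_hit is hit

    def test_enumeration_matches_naive_scan(self):
        rng = np.random.default_rng(13)
        utr_seq = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=600))
        utr = UTRRecord(gene_id="g", seq=utr_seq, source_interval=GenomicInterval("s1", 0, 1))
        sites = predict_p1_seed(MIR, utr)
        core = revcomp(MIR[1:7])
        naive = [i + 6 for i in range(len(utr_seq) - 5) if utr_seq[i : i + 6] == core]
        assert [s.utr_pos for s in sites] == naive

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            predict_p1_seed("ACGTACG", _utr_with_site(MIR))


class TestDuplexPredictor:
    def test_perfect_gc_22mer_scores_66(self):
        m = "G" * 11 + "C" * 11
        utr = UTRRecord(
            gene_id="g",
            seq="A" * 50 + revcomp(m) + "A" * 50,
            source_interval=GenomicInterval("s1", 0, 1),
        )
        site = TargetSite(mirna="m", gene_id="g", utr_pos=50 + 21, site_type="8mer")
        score, hit = predict_p2_duplex(m, utr, site)
        assert score == 66.0 and hit

    def test_two_seed_mismatches_block_hit(self):
        m = MIR
        site_seq = list(revcomp(m))
        # corrupt the UTR bases opposite miRNA nt 3 and 5
        L = len(m)
        for nt in (3, 5):
            q = L - 1 - (nt - 1)
            site_seq[q] = "A" if site_seq[q] != "A" else "C"
        utr = UTRRecord(
            gene_id="g",
            seq="A" * 30 + "".join(site_seq) + "A" * 30,
            source_interval=GenomicInterval("s1", 0, 1),
        )
        site = TargetSite(mirna="m", gene_id="g", utr_pos=30 + L - 1, site_type="8mer")
        score, hit = predict_p2_duplex(m, utr, site)
        assert not hit

    def test_pair_score_table_complement_symmetric(self):
        # Watson-Crick entries are invariant under jointly reverse-
        # complementing both strands; the G:U wobble is intrinsically
        # asymmetric and stays a wobble only in one orientation
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for (a, b), w in _PAIR_SCORE.items():
            if (a, b) not in {("G", "T"), ("T", "G")}:
                assert _PAIR_SCORE[(comp[b], comp[a])] == w
        assert _PAIR_SCORE[("G", "T")] == _PAIR_SCORE[("T", "G")]


class TestAccessibilityPredictor:
    def test_unstructured_window_ddg_is_minus_p2(self):
        utr = UTRRecord(
            gene_id="g", seq="A" * 200, source_interval=GenomicInterval("s1", 0, 1)
        )
        site = TargetSite(
            mirna="m", gene_id="g", utr_pos=100, site_type="8mer", p2_score=40.0
        )
        ddg, hit = predict_p3_access(utr, site)
        assert ddg == -40.0 and hit

    def test_buried_site_less_favourable(self):
        rng = np.random.default_rng(14)
        site_seq = revcomp(MIR)
        # open context
        open_utr = UTRRecord(
            gene_id="g", seq="A" * 60 + site_seq + "A" * 60,
            source_interval=GenomicInterval("s1", 0, 1),
        )
        # buried: flank the site with its own reverse complement → hairpin
        buried_utr = UTRRecord(
            gene_id="g", seq="A" * 30 + revcomp(site_seq) + "AAAA" + site_seq + "A" * 60,
            source_interval=GenomicInterval("s1", 0, 1),
        )
        pos_open = 60 + len(site_seq) - 1
        pos_buried = 30 + len(site_seq) + 4 + len(site_seq) - 1
        s_open = TargetSite("m", "g", pos_open, "8mer", p2_score=40.0)
        s_buried = TargetSite("m", "g", pos_buried, "8mer", p2_score=40.0)
        # window wide enough to cover the burying arm on both fixtures
        ddg_open, _ = predict_p3_access(open_utr, s_open, window=140)
        ddg_buried, _ = predict_p3_access(buried_utr, s_buried, window=140)
        assert ddg_buried > ddg_open

    def test_window_clipped_at_edges(self):
        utr = UTRRecord(
            gene_id="g", seq="A" * 30, source_interval=GenomicInterval("s1", 0, 1)
        )
        site = TargetSite("m", "g", 5, "8mer", p2_score=30.0)
        ddg, _ = predict_p3_access(utr, site)  # must not raise
        assert ddg <= 0


class TestConsensus:
    def test_conjunction(self):
        s = TargetSite("m", "g", 10, "8mer", p1_hit=True, p2_hit=True, p3_hit=False)
        consensus_targets([s])
        assert not s.consensus

    def test_consensus_subset_of_each_predictor(self, small_run):
        truth, report, ev, outdir = small_run
        import pandas as pd

        sites = pd.read_csv(outdir / "run" / "target_sites.tsv", sep="\t")
        if len(sites):
            cons = sites[sites.consensus]
            assert cons.p1_hit.all() and cons.p2_hit.all() and cons.p3_hit.all()

    def test_planted_sites_recovered_decoys_rejected(self):
        rng = np.random.default_rng(15)
        panel = [
            (f"mir{i}", "T" + "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=21)))
            for i in range(6)
        ]
        utrs, site_truth = plant_target_utrs(panel, seed=99, n_decoy_utrs=20)
        sites = predict_targets(panel, utrs)
        cons = [s for s in sites if s.consensus]
        hits = sum(
            any(
                s.mirna == row.mirna and s.gene_id == row.gene_id
                and abs(s.utr_pos - row.site_end) <= 1
                for s in cons
            )
            for row in site_truth.itertuples()
        )
        assert hits / len(site_truth) >= 0.9
        decoy_genes = {u.id for u in utrs if u.id.startswith("decoy_gene_")}
        fp = {s.gene_id for s in cons if s.gene_id in decoy_genes}
        assert len(fp) / len(decoy_genes) <= 0.1

    def test_empty_sites_empty_targets(self):
        assert target_genes([]) == []


class TestGoSummary:
    def test_counts(self):
        import pandas as pd

        gene2go = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g2"],
                "go_term": ["metabolic process", "metabolic process", "cell"],
            }
        )
        out = summarize_go(["g1", "g2"], gene2go)
        assert out.iloc[0].tolist() == ["metabolic process", 2]

    def test_unannotated_bucket(self):
        import pandas as pd

        gene2go = pd.DataFrame({"gene_id": ["g1"], "go_term": ["cell"]})
        out = summarize_go(["gX"], gene2go)
        assert out.iloc[0].tolist() == ["unannotated", 1]

    def test_empty_target_list(self):
        import pandas as pd

        gene2go = pd.DataFrame({"gene_id": [], "go_term": []})
        assert summarize_go([], gene2go).empty
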