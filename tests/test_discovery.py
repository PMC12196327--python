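import itertools

import numpy as np
import pytest

from mirforge.discovery import (
    HairpinCandidate,
    MatureMiRNA,
    ReadStack,
    call_read_stacks,
    evaluate_criteria,
    excise_candidates,
    quantify,
    verdict_from_flags,
)
from mirforge.folding import fold_hairpin
from mirforge.io_formats import Feature, GenomicInterval, revcomp
from mirforge.mapping import Alignment
from mirforge.synthetic_data import SimConfig, plant_hairpins, simulate_genome


def aln(rid, start, end, seq, strand="+", scaffold="s1", mm=0):
    return Alignment(rid, GenomicInterval(scaffold, start, end, strand), mm, seq)


class TestReadStacks:
    def test_identical_reads_one_stack(self):
        alns = [aln(f"r{i}", 100, 122, "A" * 22) for i in range(10)]
        stacks = call_read_stacks(alns)
        assert len(stacks) == 1
        s = stacks[0]
        assert s.n_reads == 10 and s.five_prime_counts == {100: 10}

    def test_distant_loci_two_stacks(self):
        alns = [aln(f"a{i}", 100, 122, "A" * 22) for i in range(5)] + [
            aln(f"b{i}", 222, 244, "C" * 22) for i in range(5)
        ]
        assert len(call_read_stacks(alns, merge_gap=0)) == 2

    def test_min_reads_threshold(self):
        alns = [aln(f"r{i}", 100, 122, "A" * 22) for i in range(4)]
        assert call_read_stacks(alns, min_reads=5) == []

    def test_modal_seq_tie_lexicographic(self):
        alns = [
            aln("r1", 100, 122, "C" * 22),
            aln("r2", 100, 122, "A" * 22),
            aln("r3", 100, 122, "C" * 22),
            aln("r4", 100, 122, "A" * 22),
            aln("r5", 101, 122, "G" * 21),
        ]
        assert call_read_stacks(alns)[0].modal_seq == "A" * 22

    def test_boundaries_match_interval_union_oracle(self):
        rng = np.random.default_rng(11)
        alns = []
        for i in range(200):
            start = int(rng.integers(0, 1000))
            L = int(rng.integers(15, 36))
            alns.append(aln(f"r{i}", start, start + L, "A" * L))
        stacks = call_read_stacks(alns, min_reads=1)
        # oracle: union of intervals via boolean coverage mask
        mask = np.zeros(1100, dtype=bool)
        for a in alns:
            mask[a.interval.start : a.interval.end] = True
        runs = []
        pos = 0
        while pos < len(mask):
            if mask[pos]:
                end = pos
                while end < len(mask) and mask[end]:
                    end += 1
                runs.append((pos, end))
                pos = end
            else:
                pos += 1
        assert sorted((s.interval.start, s.interval.end) for s in stacks) == runs

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        alns = [
            aln(f"r{i}", int(s), int(s) + 22, "A" * 22)
            for i, s in enumerate(rng.integers(0, 500, size=60))
        ]
        a = call_read_stacks(alns)
        b = call_read_stacks(list(reversed(alns)))
        assert [(s.interval.start, s.interval.end, s.n_reads) for s in a] == [
            (s.interval.start, s.interval.end, s.n_reads) for s in b
        ]


@pytest.fixture(scope="module")
def planted_world():
    cfg = SimConfig(seed=9, n_scaffolds=2, scaffold_len=30_000, n_true_mirnas=8, n_decoys=0)
    genome, ann = simulate_genome(cfg)
    planted, _ = plant_hairpins(genome, ann, cfg)
    return cfg, genome, ann, planted


class TestExcision:
    def test_planted_window_contains_mature_and_star(self, planted_world):
        _, genome, _, planted = planted_world
        gm = {r.id: r.seq for r in genome}
        for p in planted:
            iv = p.mature_interval
            stack = _stack_for(p)
            cands = excise_candidates(stack, gm)
            assert len(cands) == 1
            c = cands[0]
            pi = c.precursor_interval
            assert pi.start <= p.precursor_interval.start
            assert pi.end >= p.precursor_interval.end - 0
            # candidate sequence equals the genome slice
            assert c.precursor_seq == gm[pi.scaffold][pi.start : pi.end]

    def test_scaffold_edge_clipped(self):
        text = "ACGT" * 60
        stack = ReadStack(
            interval=GenomicInterval("s1", 0, 22),
            n_reads=5,
            five_prime_counts={0: 5},
            length_histogram={22: 5},
            modal_seq=text[0:22],
            modal_start=0,
            modal_end=22,
        )
        cands = excise_candidates(stack, {"s1": text})
        assert cands and cands[0].precursor_interval.start >= 0

    def test_minus_strand_candidate_is_revcomp_slice(self, planted_world):
        _, genome, _, planted = planted_world
        gm = {r.id: r.seq for r in genome}
        p = planted[0]
        # pretend the stack was seen on the minus strand at the star arm
        si = p.star_interval
        stack = ReadStack(
            interval=GenomicInterval(si.scaffold, si.start, si.end, "-"),
            n_reads=6,
            five_prime_counts={si.end - 1: 6},
            length_histogram={len(si): 6},
            modal_seq=revcomp(gm[si.scaffold][si.start : si.end]),
            modal_start=si.start,
            modal_end=si.end,
        )
        cands = excise_candidates(stack, gm)
        assert cands
        c = cands[0]
        pi = c.precursor_interval
        assert c.precursor_seq == revcomp(gm[pi.scaffold][pi.start : pi.end])


def _stack_for(p, homogeneity=0.9, n=100):
    iv = p.mature_interval
    m = len(p.mature_seq)
    main = int(n * homogeneity)
    side = (n - main) // 2
    five = {iv.start: main, iv.start - 1: side, iv.start + 1: n - main - side}
    return ReadStack(
        interval=GenomicInterval(iv.scaffold, iv.start - 1, iv.end + 2, iv.strand),
        n_reads=n,
        five_prime_counts=five,
        length_histogram={m: main, m - 1: side, m + 1: n - main - side},
        modal_seq=p.mature_seq,
        modal_start=iv.start,
        modal_end=iv.end,
    )


class TestCriteria:
    def test_planted_candidate_meets_all_six(self, planted_world):
        _, genome, ann, planted = planted_world
        gm = {r.id: r.seq for r in genome}
        p = planted[0]
        stack = _stack_for(p)
        cand = excise_candidates(stack, gm)[0]
        star_read = aln(
            "star1",
            p.star_interval.start,
            p.star_interval.end,
            p.star_seq,
            scaffold=p.star_interval.scaffold,
        )
        evaluate_criteria(cand, stack, [star_read], ann)
        assert cand.criteria == {f"c{i}": True for i in range(1, 7)}
        assert cand.verdict == "kept"

    def test_no_star_reads_fails_c3_only(self, planted_world):
        _, genome, ann, planted = planted_world
        gm = {r.id: r.seq for r in genome}
        p = planted[1]
        stack = _stack_for(p)
        cand = excise_candidates(stack, gm)[0]
        evaluate_criteria(cand, stack, [], ann)
        assert not cand.criteria["c3"]
        assert cand.n_met == 5 and cand.verdict == "kept"

    def test_homogeneity_boundary_inclusive(self, planted_world):
        _, genome, ann, planted = planted_world
        gm = {r.id: r.seq for r in genome}
        p = planted[2]
        stack = _stack_for(p, n=10)
        stack.five_prime_counts = {p.mature_interval.start: 7, 0: 2, 1: 1}
        cand = excise_candidates(stack, gm)[0]
        evaluate_criteria(cand, stack, [], ann)
        assert cand.criteria["c4"] is True  # 7/10 == 70%, inclusive
        stack.five_prime_counts = {p.mature_interval.start: 6, 0: 2, 1: 1, 2: 1}
        cand2 = excise_candidates(stack, gm)[0]
        evaluate_criteria(cand2, stack, [], ann)
        assert cand2.criteria["c4"] is False

    def test_heterogeneous_decoy_discarded(self, planted_world):
        _, genome, ann, planted = planted_world
        gm = {r.id: r.seq for r in genome}
        # a decoy-like stack over plain sequence: heterogeneous 5' ends,
        # 27 nt reads, no star support
        scaffold = genome[0].id
        start = 25_000
        five = {start - 2: 18, start - 1: 17, start: 30, start + 1: 17, start + 2: 18}
        stack = ReadStack(
            interval=GenomicInterval(scaffold, start - 2, start + 29),
            n_reads=100,
            five_prime_counts=five,
            length_histogram={26: 25, 27: 50, 28: 25},
            modal_seq=gm[scaffold][start : start + 27],
            modal_start=start,
            modal_end=start + 27,
        )
        cands = excise_candidates(stack, gm)
        assert cands
        evaluate_criteria(cands[0], stack, [], ann)
        assert cands[0].n_met <= 2 and cands[0].verdict == "discarded"

    def test_length_boundaries_inclusive(self):
        for plen, expected in ((59, False), (60, True), (80, True), (81, False)):
            seq = "G" * ((plen - 4) // 2) + "AAAA" + "C" * (plen - 4 - (plen - 4) // 2)
            cand = HairpinCandidate(
                precursor_interval=GenomicInterval("s1", 0, plen),
                precursor_seq=seq,
                structure=fold_hairpin(seq),
                mature=(0, 22),
                star=None,
            )
            stack = ReadStack(
                interval=GenomicInterval("s1", 0, 22),
                n_reads=10,
                five_prime_counts={0: 10},
                length_histogram={22: 10},
                modal_seq=seq[:22],
                modal_start=0,
                modal_end=22,
            )
            evaluate_criteria(cand, stack, [], [])
            assert cand.criteria["c2"] is expected

    def test_ncrna_overlap_fails_c6(self, planted_world):
        _, genome, ann, planted = planted_world
        gm = {r.id: r.seq for r in genome}
        p = planted[3]
        stack = _stack_for(p)
        cand = excise_candidates(stack, gm)[0]
        pi = cand.precursor_interval
        fake = [Feature(GenomicInterval(pi.scaffold, pi.end - 1, pi.end + 10), "repeat", "")]
        evaluate_criteria(cand, stack, [], fake)
        assert cand.criteria["c6"] is False


class TestVerdictRule:
    @pytest.mark.parametrize("flags", list(itertools.product([False, True], repeat=6)))
    def test_all_64_truth_assignments(self, flags):
        expected = "kept" if sum(flags) >= 3 else "discarded"
        assert verdict_from_flags(flags) == expected

    def test_monotone_in_flags(self):
        for flags in itertools.product([False, True], repeat=6):
            if verdict_from_flags(flags) == "kept":
                for i in range(6):
                    stronger = list(flags)
                    stronger[i] = True
                    assert verdict_from_flags(stronger) == "kept"


class TestQuantify:
    def _mir(self, name, scaffold, start, length=22):
        seq = "A" * length
        cand = HairpinCandidate(
            precursor_interval=GenomicInterval(scaffold, start, start + 60),
            precursor_seq="A" * 60,
            structure=fold_hairpin("GGGAAACCC"),
            mature=(0, length),
            star=None,
        )
        return MatureMiRNA(name=name, seq=seq, candidate=cand)

    def test_single_mirna_full_share(self):
        m = self._mir("m1", "s1", 100)
        alns = [aln(f"r{i}", 100, 122, "A" * 22) for i in range(10)]
        quantify([m], alns)
        assert m.read_count == 10 and m.share == 100.0

    def test_shares_sum_to_100(self):
        m1, m2 = self._mir("m1", "s1", 100), self._mir("m2", "s1", 500)
        alns = [aln(f"r{i}", 100, 122, "A" * 22) for i in range(7)] + [
            aln(f"q{i}", 500, 522, "A" * 22) for i in range(3)
        ]
        quantify([m1, m2], alns)
        assert abs(m1.share + m2.share - 100.0) < 1e-6
        assert (m1.share, m2.share) == (70.0, 30.0)

    def test_partial_overlap_threshold(self):
        m = self._mir("m1", "s1", 100)
        # overlap 19 < 22-2: not assigned
        alns = [aln("r1", 97, 119, "A" * 22)]
        quantify([m], alns)
        assert m.read_count == 0

    def test_rpm(self):
        m = self._mir("m1", "s1", 100)
        alns = [aln(f"r{i}", 100, 122, "A" * 22) for i in range(5)]
        quantify([m], alns, total_mapped_reads=1000)
        assert m.rpm == 5 * 1e6 / 1000
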