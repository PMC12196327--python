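# Methods

This note documents the models and procedures implemented in mirforge,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Read preprocessing

Adapter trimming finds the leftmost read position where a prefix of the
3′ adapter aligns with mismatch fraction ≤ `max_err_rate` (default 0.1)
and overlap ≥ `min_overlap` (default 3 nt), and truncates the read
there. An adapter match at position 0 leaves a 1 nt stub so the read
object stays valid; the length filter removes it immediately.

"Low Phred score (< 20)" is interpreted as *mean* read quality < 20:
the phrase is read-level in common usage, and a per-base rule would
conflate quality with the ambiguity filter. Reads violating several
filters are tallied once, with fixed precedence quality → ambiguous →
short, so reports are deterministic.

## Mapping

The mapper is exact seed-and-verify: plus-strand k-mers are indexed and
each read (and its reverse complement) is anchored by two *disjoint*
seeds, then verified by full-length Hamming comparison. With `k = 7`
the two seeds are disjoint for the shortest read considered (15 nt), so
by pigeonhole every alignment with ≤ 1 mismatch is found — the property
the brute-force oracle test checks. A larger seed (e.g. 10 nt) would be
faster but loses this guarantee for reads shorter than 20 nt.

All loci with the minimum mismatch count are reported (ties are never
sampled); reads with more than `max_hits = 5` equally-best loci are
discarded as multi-mappers, following the miRDeep2 community default.
Alignments live in plus-strand coordinates; for minus-strand hits the
read equals the reverse complement of the reference slice.

## Folding

Secondary structure is computed by base-pair maximization (Nussinov
dynamic programming) over {AU, GC, GU} with a minimum hairpin loop of
3 nt, vectorized per diagonal in numpy. Maximization rather than free
energy keeps the component self-contained and exactly verifiable
against exhaustive enumeration; an energy backend could be swapped in
behind the same `HairpinStructure` contract.

The traceback is deterministic and pairs the 5′-most base of each
subproblem with the **largest** admissible partner that preserves
optimality. Maximum-pairing landscapes over near-complementary arms are
massively degenerate; outermost-first readout collapses those ties onto
the clean stem-loop whenever one attains the maximum, which is what the
curation criteria need to see. `n_terminal_loops` counts pairs
enclosing no other paired base (hairpin loops); `paired_fraction` is
2·|pairs|/length.

The accessibility predictor reuses the same dynamic program with
weighted pairs (GC 3, AU 2, GU 1) as a coarse stability proxy.

## Discovery and curation

Read stacks are maximal runs of overlapping same-strand alignments with
≥ 5 reads. Around each stack's modal read two asymmetric windows
(70 nt/20 nt flanks) are excised and folded, mirroring the two-window
excision of stack-based miRNA finders.

**Star inference and precursor trimming.** Taking the raw ~110 nt
window as the precursor would make the structure and length criteria
unsatisfiable for every locus, genuine or not, so the candidate is
trimmed to the mature/star duplex before curation. The duplex is
located by a direct scan for the near-exact reverse-complement image of
the mature (minus its 2 nt 3′ overhang) across a ≥ 4 nt loop, allowing
~15% wobble/mismatch positions. This is the Dicer-duplex geometry test:
a genuine precursor always carries the image, while a ≥ 85%-identity
match of a specific ~20-mer in random sequence is vanishingly rare.
Window-level global folds are *not* used to locate the star — at 110 nt
base-pair maximization routinely buries the biological stem inside
noise pairs. A window exhibiting a genuine duplex is preferred
outright; otherwise the higher paired fraction (then fewer terminal
loops, then the upstream window) decides. Candidates without a credible
duplex stay untrimmed and consequently fail the structure/length
criteria — they can still be kept on the read-pattern criteria alone if
three of them hold.

**Criteria.** All thresholds are inclusive at their boundaries; the 70%
5′-homogeneity test is computed in integer arithmetic to avoid float
edge effects. The star criterion (c3) additionally requires the
predicted star to be a distinct arm (disjoint from the mature) and at
least one observed same-strand read whose 5′ end falls within ±1 nt of
the predicted star 5′ end: structure-only star evidence does not count.
Criteria that cannot be evaluated (no predicted star) count as unmet;
the verdict is `kept` iff ≥ 3 of 6 hold. The rule is deliberately
permissive — it tolerates a missing star or an annotation overlap — and
therefore admits the occasional random locus whose stack happens to
peak at 20–24 nt inside a hairpin-like stretch (typically 0–3 per 200k
reads in the synthetic runs). This mirrors the need for manual curation
in real analyses; the planted decoys, which violate ≥ 4 criteria by
design, are rejected reliably.

**Quantification.** A read counts toward a mature locus when an
alignment overlaps it by ≥ (mature length − 2) nt on the same strand;
ties between two matures drop the read from all shares. Shares are
percentages of miRNA-assigned reads and therefore sum to 100; RPM
normalizes by total mapped reads.

## Genomic context, overlaps, clusters

Overlapping precursors (≥ 1 nt, any strand) are resolved greedily by
descending read count — the best-supported locus in each overlap chain
survives. This also collapses the duplicate candidate that every
genuine hairpin produces from its star-arm read stack. Context uses
most-specific-first precedence (pseudogene > exonic > intronic >
intergenic) with strand-agnostic ≥ 1 nt overlap; a precursor inside a
gene but touching no exon is intronic. Clusters are single-linkage
chains of precursors with end-to-start gaps ≤ 5000 nt (inclusive),
strand-ignored, reported at ≥ 2 members.

## Conservation

Similarity to catalog matures is an ungapped shift-and-count over
offsets within ±2 nt covering ≥ (query length − 2) nt: matched if ≤ 2
mismatches, or if the seed (nt 2–8) is identical with ≤ 4 mismatches —
a deterministic stand-in for the "complete or seed-region similarity"
notion used with BLASTn in catalog comparisons, with ties broken by
mismatch count, |offset|, then catalog order. Catalogs are assumed
mature-sense 5′→3′ (miRBase convention); reverse complements are not
searched. Comparison against an external prediction set additionally
accepts a ≤ 1-mismatch substring hit, since such sets may contain
precursors.

## Target prediction

3′UTRs are approximated by the 1000 nt downstream of each annotated
gene end, strand-aware, clipped at scaffold edges and *not* truncated
at neighbouring genes (matching the plain downstream-window
extraction). The three predictors are deliberately independent signals:

* **Seed classes** — exact matches to miRNA nt 2–7 classified as
  6mer / 7mer-A1 / 7mer-m8 / 8mer; only the 7mer+/8mer classes count.
* **Duplex score** — ungapped pairing over the seed plus up to 14 nt of
  3′-compensatory pairing, GC +3 / AU +2 / GU +1 / mismatch −2; hit at
  ≥ 25 with ≤ 1 non-Watson-Crick seed position. A perfect 22-mer
  duplex scores 44–66 depending on GC content.
* **Accessibility** — ΔΔG = −(duplex score) + (pairing score lost when
  the 8 nt seed region is forced single-stranded in the max-weight
  structure of a 70 nt window); hit at ≤ −10.

The retained contribution is the strict three-way intersection:
consensus sites are by construction a subset of each predictor's
positives. The two numeric thresholds are calibration choices validated
in the tests — planted perfect-complement sites in random UTRs pass at
~100% while shuffled UTRs yield ≤ 10% false-positive genes. GO
summarization is plain label counting (suitable for word-cloud input);
enrichment statistics are intentionally out of scope.

## The synthetic experiment

Defaults (the study conditions of every full-scale test):
3 scaffolds × 50 kb at GC 0.35; 40 true miRNAs; 20 decoys; 190k miRNA
reads + 5k background reads + 250 reads per decoy (≈ 200k total);
5′-homogeneity 0.9; 5′-U fraction 0.8; star-read fraction 0.1; read
machine length 50 with the standard small-RNA 3′ adapter; 2% low-quality
and 1% N-containing reads.

* **Hairpins** are mature + loop (12–20 nt from {A, C}) + star, with
  star = revcomp(mature minus its 3′ dinucleotide) plus its own 2 nt
  overhang — a perfect duplex with canonical 2 nt 3′ overhangs. The
  mature 3′ dinucleotide is fixed to CC and overhang/loop alphabets are
  chosen so no loop or overhang base has a pairing partner: the
  designed stem is then the unique maximum-pairing structure, which the
  planted-structure tests assert exactly. Three "mirror-guard" bases
  upstream of each hairpin prevent jittered reads from finding exact
  reverse-complement images around the star arm (an artifact that would
  otherwise fabricate homogeneous minus-strand stacks at decoys).
* **Abundance** follows a Zipf law whose exponent is solved
  analytically so the expected rank-1 share is 42.3% — the share
  reported for the dominant miRNA in bee small-RNA repertoires; the
  two top-ranked miRNAs are fixed at 22 nt so the library's length mode
  is the canonical 22.
* **Context quotas** 50/38/11/1% (intronic/intergenic/exonic/
  pseudogene) are apportioned by largest remainder; at 40 miRNAs the
  pseudogene quota rounds to 0–1.
* **Decoys** each violate ≥ 4 of the six criteria: all get
  heterogeneous 5′ ends (modal share 0.3), no star reads and a ~27 nt
  read-length mode; kind (a) sits on plain sequence, (b) is a genuine
  hairpin inside an annotated repeat, lengthened to 90 nt so the length
  criterion fails by design, and (c) is an over-long ~110 nt hairpin.
* **Catalogs** include each planted mature with a per-species sharing
  probability and 0–2 substitutions outside the seed, plus
  species-private decoy matures, written in RNA alphabet.
* All miRNAs are planted on the plus strand; minus-strand mapping and
  excision logic is exercised by constructed fixtures instead.

What passing tests show: the pipeline recovers essentially all planted
loci, rejects the designed negatives, and reproduces planted context,
abundance and sharing structure. What they do not show: performance on
real libraries with isomiR heterogeneity, RNA editing, sequencing-error
profiles, repeat-rich genomes, or hairpins with bulged, partially
paired stems — the generator's hairpins are cleaner than biological
ones, and the duplex-scan star locator's ~15% mismatch allowance is the
only concession to imperfect stems.

## Numerical and degenerate-input choices

* All internal coordinates are 0-based half-open; conversion happens
  only at file boundaries (GFF3 1-based inclusive, BED half-open).
* Matching is done in DNA space throughout (U ≡ T); catalogs and
  folding accept RNA input.
* Criterion thresholds compare in integer arithmetic where float
  boundaries could bite (the 70% homogeneity rule).
* Ties: modal stack sequences break lexicographically; equal-mismatch
  alignments are all reported; equal-overlap read assignments are
  dropped from shares; cluster membership is order-invariant.
* Scaffold-edge windows are clipped, genes flush against a scaffold
  end yield shorter (or no) UTR records, and empty inputs produce
  empty outputs rather than errors wherever a stage can meaningfully
  continue.
* Pipeline reports are JSON with sorted keys and no timestamps, so a
  rerun with identical inputs is byte-identical.

## Known limitations

* Base-pair maximization over-pairs long random sequence; all
  structure-sensitive decisions therefore operate on duplex-scan-
  trimmed precursors, and window-scale folds are used only as a
  tie-break.
* The ≥ 3-of-6 rule admits rare random loci (see above); consumers
  should treat the curated list as high-recall rather than
  high-precision, as in the original stack-based protocols.
* The conservation matcher is ungapped; indel-divergent homologs are
  missed by design.
* Target prediction operates on approximate downstream-window UTRs and
  simplified scoring; it ranks and intersects sites consistently but
  does not model thermodynamics quantitatively.
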