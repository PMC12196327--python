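"""End-to-end orchestration: preprocess → map → profile → discover →
context/clusters → conservation → targets → report.

Every stage writes its tables under the run directory and the final
report is a deterministic JSON document: identical inputs and
configuration produce byte-identical reports.
"""

from __future__ import annotations

import bisect
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import conservation as cons
from . import discovery as disc
from . import genome_context as gctx
from . import mapping as mp
from . import preprocess as pp
from . import targets as tg
from .io_formats import (
    SeqRecord,
    read_fasta,
    read_fastq,
    read_gff3,
    write_bed,
    write_fasta,
    write_fastq,
    write_tsv,
)
from .synthetic_data import DEFAULT_ADAPTER, SimConfig, plant_target_utrs, write_run

log = logging.getLogger("mirforge")


@dataclass
class PipelineConfig:
    fastq: str
    genome: str
    gff3: str
    outdir: str
    catalogs_dir: str | None = None
    gene2go: str | None = None
    seed: int = 1
    # preprocess
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 3
    max_err_rate: float = 0.1
    min_len: int = 15
    min_mean_q: float = 20.0
    # mapping
    index_k: int = 7
    max_mm: int = 1
    max_hits: int = 5
    # discovery
    min_reads: int = 5
    merge_gap: int = 0
    flank_long: int = 70
    flank_short: int = 20
    # context
    max_cluster_gap: int = 5000
    # conservation
    cons_max_mm: int = 2
    cons_max_shift: int = 2
    # targets
    utr_flank: int = 1000
    n_target_mirnas: int = 1  # predict targets for the top-N abundant miRNAs

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    preprocess: dict[str, int]
    mapping: dict[str, int]
    size_profile: dict[str, Any]
    n_candidates: int
    n_kept: int
    n_discarded: int
    n_after_overlap_drop: int
    context_fractions: dict[str, float]
    clusters: list[dict[str, Any]]
    scaffold_counts: list[dict[str, Any]]
    top10_shares: list[dict[str, Any]]
    known_specific: dict[str, int] | None
    sharing_totals: dict[str, int] | None
    targets: dict[str, int] | None
    go_top_terms: list[dict[str, Any]] | None

    def __post_init__(self) -> None:
        if self.n_kept + self.n_discarded != self.n_candidates:
            raise ValueError("kept + discarded != candidates")
        total = sum(self.context_fractions.values())
        if self.context_fractions and abs(total - 100.0) > 1e-6 and total != 0.0:
            raise ValueError(f"context fractions sum to {total}, not 100")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


class StageError(RuntimeError):
    pass


def run_all(config: PipelineConfig) -> RunReport:
    """Execute the whole analysis and write all artifacts to outdir."""
    report, _ = run_all_with_state(config)
    return report


def run_all_with_state(config: PipelineConfig) -> tuple[RunReport, dict[str, Any]]:
    """As :func:`run_all`, but also return the in-memory stage objects
    (alignments, candidates, curated miRNAs …) for downstream joins."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- preprocess ---------------------------------------------------
    reads = read_fastq(config.fastq)
    kept_reads, report_pp = pp.preprocess_reads(
        reads,
        adapter=config.adapter,
        min_overlap=config.min_overlap,
        max_err_rate=config.max_err_rate,
        min_len=config.min_len,
        min_mean_q=config.min_mean_q,
    )
    write_fastq(kept_reads, outdir / "kept.fastq")
    write_tsv(pd.DataFrame([report_pp.as_dict()]), outdir / "preprocess_report.tsv")
    log.info("preprocess: %d in, %d kept", report_pp.n_input, report_pp.n_kept)

    # --- map + profile ------------------------------------------------
    genome = read_fasta(config.genome)
    index = mp.build_index(genome, k=config.index_k)
    alignments, map_stats = mp.map_reads(
        kept_reads, index, max_mm=config.max_mm, max_hits=config.max_hits
    )
    write_tsv(mp.alignments_to_tsv(alignments), outdir / "alignments.tsv")
    profile = mp.profile_mapped(alignments)
    profile.to_dataframe().to_csv(outdir / "size_profile.tsv", sep="\t")
    log.info("mapping: %d reads, %d mapped", map_stats["n_reads"], map_stats["n_mapped"])

    # --- discovery ----------------------------------------------------
    annotation = read_gff3(config.gff3)
    stacks = disc.call_read_stacks(
        alignments, min_reads=config.min_reads, merge_gap=config.merge_gap
    )
    genome_map = {r.id: r.seq for r in genome}
    by_scaffold: dict[str, tuple[list[int], list[mp.Alignment]]] = {}
    for a in sorted(alignments, key=lambda a: (a.interval.scaffold, a.interval.start)):
        starts, items = by_scaffold.setdefault(a.interval.scaffold, ([], []))
        starts.append(a.interval.start)
        items.append(a)

    def nearby(iv, pad=50):
        starts, items = by_scaffold.get(iv.scaffold, ([], []))
        lo = bisect.bisect_left(starts, iv.start - pad - 60)
        hi = bisect.bisect_right(starts, iv.end + pad)
        return items[lo:hi]

    candidates: list[disc.HairpinCandidate] = []
    for stack in stacks:
        for cand in disc.excise_candidates(
            stack, genome_map, flank_long=config.flank_long, flank_short=config.flank_short
        ):
            disc.evaluate_criteria(cand, stack, nearby(cand.precursor_interval), annotation)
            candidates.append(cand)
    n_kept = sum(1 for c in candidates if c.verdict == "kept")
    cand_df = pd.DataFrame(
        [
            {
                "scaffold": c.precursor_interval.scaffold,
                "start": c.precursor_interval.start,
                "end": c.precursor_interval.end,
                "strand": c.precursor_interval.strand,
                "precursor_len": len(c.precursor_seq),
                **{k: int(v) for k, v in c.criteria.items()},
                "n_met": c.n_met,
                "verdict": c.verdict,
            }
            for c in candidates
        ]
    )
    write_tsv(cand_df, outdir / "candidates.tsv")
    log.info("discovery: %d candidates, %d kept", len(candidates), n_kept)

    mirnas = disc.name_mirnas(candidates)
    disc.quantify(mirnas, alignments, total_mapped_reads=map_stats["n_mapped"])
    write_fasta(
        [SeqRecord(id=m.name, seq=m.seq) for m in mirnas], outdir / "mirnas.fa"
    )
    write_fasta(
        [SeqRecord(id=m.name, seq=m.candidate.precursor_seq) for m in mirnas],
        outdir / "precursors.fa",
    )

    # --- genomic context ---------------------------------------------
    kept_mirnas, dropped_mirnas = gctx.drop_overlapping(mirnas)
    # shares are relative to the surviving miRNA set
    disc.quantify(kept_mirnas, alignments, total_mapped_reads=map_stats["n_mapped"])
    quant_df = pd.DataFrame(
        [
            {
                "name": m.name,
                "seq": m.seq,
                "read_count": m.read_count,
                "rpm": round(m.rpm, 3),
                "share_pct": round(m.share, 4),
            }
            for m in sorted(kept_mirnas, key=lambda m: -m.read_count)
        ]
    )
    write_tsv(quant_df, outdir / "quantification.tsv")

    calls = [gctx.classify_context(m, annotation) for m in kept_mirnas]
    fractions = gctx.context_fractions(calls)
    write_tsv(
        pd.DataFrame([{"mirna": c.mirna, "context": c.context} for c in calls]),
        outdir / "context.tsv",
    )
    clusters = gctx.find_clusters(kept_mirnas, max_gap=config.max_cluster_gap)
    write_tsv(
        pd.DataFrame(
            [
                {
                    "scaffold": c.scaffold,
                    "n_members": len(c.members),
                    "members": ",".join(c.members),
                    "start": c.span.start,
                    "end": c.span.end,
                }
                for c in clusters
            ],
            columns=["scaffold", "n_members", "members", "start", "end"],
        ),
        outdir / "clusters.tsv",
    )
    write_bed(
        [c.span for c in clusters],
        outdir / "clusters.bed",
        names=[f"cluster_{i + 1}" for i in range(len(clusters))],
    )
    scaffold_counts = gctx.per_scaffold_counts(kept_mirnas)
    write_tsv(scaffold_counts, outdir / "scaffold_counts.tsv")
    log.info(
        "context: %d mirnas after overlap drop, %d clusters", len(kept_mirnas), len(clusters)
    )

    # --- conservation -------------------------------------------------
    known_specific = None
    sharing_totals = None
    cat_dir = Path(config.catalogs_dir) if config.catalogs_dir else None
    if cat_dir is not None and cat_dir.is_dir():
        catalogs = {
            p.stem: read_fasta(p, alphabet=frozenset("ACGUTN"))
            for p in sorted(cat_dir.glob("*.fa"))
        }
        pairs = [(m.name, m.seq) for m in kept_mirnas]
        combined = [rec for recs in catalogs.values() for rec in recs]
        known, specific = cons.call_known_novel(
            pairs, combined, max_mm=config.cons_max_mm, max_shift=config.cons_max_shift
        )
        matrix = cons.sharing_matrix(
            pairs, catalogs, max_mm=config.cons_max_mm, max_shift=config.cons_max_shift
        )
        known_specific = {"n_known": len(known), "n_specific": len(specific)}
        sharing_totals = matrix.per_species_totals()
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "mirna": name,
                        "status": "known" if name in set(known) else "specific",
                        "species": ",".join(sorted(matrix.membership[name])),
                    }
                    for name, _ in pairs
                ],
                columns=["mirna", "status", "species"],
            ),
            outdir / "known_novel.tsv",
        )
        write_tsv(
            pd.DataFrame(
                [{"intersection": k, "count": v} for k, v in matrix.upset_counts().items()],
                columns=["intersection", "count"],
            ),
            outdir / "upset_counts.tsv",
        )
    else:
        log.warning("conservation: catalog directory missing, stage skipped")

    # --- targets ------------------------------------------------------
    targets_summary = None
    go_top = None
    if kept_mirnas:
        utrs = tg.extract_3utrs(annotation, genome, flank=config.utr_flank)
        write_fasta(
            [SeqRecord(id=u.gene_id, seq=u.seq) for u in utrs], outdir / "utrs.fa"
        )
        top = sorted(kept_mirnas, key=lambda m: -m.read_count)[: config.n_target_mirnas]
        sites = tg.predict_targets([(m.name, m.seq) for m in top], utrs)
        genes = tg.target_genes(sites)
        write_tsv(tg.sites_to_dataframe(sites), outdir / "target_sites.tsv")
        write_tsv(pd.DataFrame({"gene_id": genes}), outdir / "target_genes.tsv")
        targets_summary = {
            "n_sites": len(sites),
            "n_consensus_sites": sum(1 for s in sites if s.consensus),
            "n_target_genes": len(genes),
        }
        if config.gene2go and Path(config.gene2go).exists():
            gene2go = pd.read_csv(config.gene2go, sep="\t")
            go = tg.summarize_go(genes, gene2go)
            write_tsv(go, outdir / "go_counts.tsv")
            go_top = [
                {"go_term": str(t), "count": int(c)}
                for t, c in zip(go["go_term"].head(10), go["count"].head(10))
            ]
        log.info("targets: %s", targets_summary)

    top10 = sorted(kept_mirnas, key=lambda m: (-m.read_count, m.name))[:10]
    report = RunReport(
        preprocess=report_pp.as_dict(),
        mapping=map_stats,
        size_profile={
            "modal_length": profile.modal_length(),
            "top_5p_base_at_mode": profile.top_5p_base(profile.modal_length()),
            "n_profiled": int(profile.counts.sum()),
        },
        n_candidates=len(candidates),
        n_kept=n_kept,
        n_discarded=len(candidates) - n_kept,
        n_after_overlap_drop=len(kept_mirnas),
        context_fractions=dict(fractions),
        clusters=[
            {"scaffold": c.scaffold, "n_members": len(c.members), "members": c.members}
            for c in clusters
        ],
        scaffold_counts=[
            {"scaffold": str(r.scaffold), "n_mirnas": int(r.n_mirnas)}
            for r in scaffold_counts.itertuples()
        ],
        top10_shares=[
            {"name": m.name, "read_count": m.read_count, "share_pct": round(m.share, 4)}
            for m in top10
        ],
        known_specific=known_specific,
        sharing_totals=sharing_totals,
        targets=targets_summary,
        go_top_terms=go_top,
    )
    (outdir / "report.json").write_text(report.to_json())
    state = {
        "alignments": alignments,
        "profile": profile,
        "stacks": stacks,
        "candidates": candidates,
        "mirnas": mirnas,
        "kept_mirnas": kept_mirnas,
        "dropped_mirnas": dropped_mirnas,
        "context_calls": calls,
        "clusters": clusters,
    }
    return report, state


# ---------------------------------------------------------------------------
# simulate + evaluate


def _match_to_planted(kept_mirnas, planted, min_overlap_nt: int = 16):
    """Map each kept miRNA to the planted mature locus it recovers."""
    assignment: dict[str, str] = {}
    for m in kept_mirnas:
        iv = m.candidate.mature_interval
        for p in planted:
            if iv.overlap(p.mature_interval) >= min_overlap_nt:
                assignment[m.name] = p.name
                break
    return assignment


def simulate_and_run(
    sim_config: SimConfig,
    outdir: str | Path,
    pipeline_overrides: dict[str, Any] | None = None,
) -> tuple[dict[str, Any], RunReport, dict[str, Any]]:
    """Generate a synthetic experiment, run the pipeline on it, and join
    predictions to the planted truth.

    Returns (truth objects, run report, evaluation metrics); the metrics
    cover discovery recall, decoy acceptance, context accuracy, the
    recovered rank-1 abundance share, per-species sharing and
    target-site recall/false-positive rates on a planted UTR panel.
    """
    outdir = Path(outdir)
    sim_dir = outdir / "sim"
    truth = write_run(sim_config, sim_dir)
    cfg = PipelineConfig(
        fastq=str(sim_dir / "reads.fastq"),
        genome=str(sim_dir / "genome.fa"),
        gff3=str(sim_dir / "annotation.gff3"),
        catalogs_dir=str(sim_dir / "catalogs"),
        gene2go=str(sim_dir / "gene2go.tsv"),
        outdir=str(outdir / "run"),
        seed=sim_config.seed,
    )
    for k, v in (pipeline_overrides or {}).items():
        setattr(cfg, k, v)
    report, state = run_all_with_state(cfg)

    planted = truth["planted"]
    decoys = truth["decoys"]
    kept = state["kept_mirnas"]

    def recovered(target_iv) -> bool:
        return any(
            m.candidate.precursor_interval.overlap(target_iv) >= 1 for m in kept
        )

    n_rec = sum(recovered(p.mature_interval) for p in planted)
    n_dec = sum(recovered(d.read_locus) for d in decoys)
    recall = n_rec / len(planted) if planted else 0.0
    decoy_rate = n_dec / len(decoys) if decoys else 0.0

    # context accuracy over kept miRNAs that recover a planted locus
    ctx_by_name = {c.mirna: c.context for c in state["context_calls"]}
    correct = total_ctx = 0
    for m in kept:
        hits = [
            p
            for p in planted
            if m.candidate.precursor_interval.overlap(p.precursor_interval) >= 1
        ]
        if hits:
            total_ctx += 1
            correct += hits[0].context == ctx_by_name.get(m.name)
    context_accuracy = correct / total_ctx if total_ctx else 0.0

    rank1_share = max((m.share for m in kept), default=0.0)

    # planted-site target panel on the most abundant recovered miRNAs
    panel = [
        (m.name, m.seq)
        for m in sorted(kept, key=lambda m: -m.read_count)[:10]
    ]
    utr_records, site_truth = plant_target_utrs(panel, seed=sim_config.seed + 101)
    sites = tg.predict_targets(panel, utr_records)
    consensus = [s for s in sites if s.consensus]
    hit = 0
    for row in site_truth.itertuples():
        if any(
            s.mirna == row.mirna
            and s.gene_id == row.gene_id
            and abs(s.utr_pos - row.site_end) <= 1
            for s in consensus
        ):
            hit += 1
    site_recall = hit / len(site_truth) if len(site_truth) else 0.0
    decoy_genes = {r.id for r in utr_records if r.id.startswith("decoy_gene_")}
    fp_genes = {s.gene_id for s in consensus if s.gene_id in decoy_genes}
    fp_rate = len(fp_genes) / len(decoy_genes) if decoy_genes else 0.0

    evaluation = {
        "n_planted": len(planted),
        "n_recovered": int(n_rec),
        "discovery_recall": round(recall, 4),
        "n_decoys": len(decoys),
        "decoy_acceptance": round(decoy_rate, 4),
        "context_accuracy": round(context_accuracy, 4),
        "context_fractions": report.context_fractions,
        "rank1_share_pct": round(rank1_share, 4),
        "target_site_recall": round(site_recall, 4),
        "target_fp_gene_rate": round(fp_rate, 4),
    }
    (outdir / "evaluation.json").write_text(
        json.dumps(evaluation, indent=2, sort_keys=True) + "\n"
    )
    return truth, report, evaluation
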