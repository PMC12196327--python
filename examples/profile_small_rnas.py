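"""Size × 5'-nucleotide profile of a simulated small-RNA library.

The hallmark of a genuine miRNA population is a sharp read-length mode
at 22 nt dominated by reads starting with U — this script shows both
signatures emerging from the simulator + preprocessing + mapping.
"""

from mirforge import preprocess as pp
from mirforge.mapping import build_index, map_reads, profile_mapped
from mirforge.synthetic_data import SimConfig, plant_hairpins, simulate_genome, simulate_reads

cfg = SimConfig(
    seed=3, n_scaffolds=2, scaffold_len=30_000,
    n_true_mirnas=10, n_decoys=0,
    n_mirna_reads=30_000, n_background_reads=2_000,
)
genome, annotation = simulate_genome(cfg)
planted, decoys = plant_hairpins(genome, annotation, cfg)
reads = simulate_reads(planted, decoys, genome, cfg)

kept, rep = pp.preprocess_reads(reads, cfg.adapter)
print(f"preprocessing: {rep.n_input} reads in, {rep.n_kept} kept "
      f"({rep.n_removed_quality} low-quality, {rep.n_removed_ambiguous} with N, "
      f"{rep.n_removed_short} short)")

index = build_index(genome)
alignments, stats = map_reads(kept, index)
print(f"mapping: {stats['n_mapped']} of {stats['n_reads']} reads aligned "
      f"with <=1 mismatch")

profile = profile_mapped(alignments)
df = profile.to_dataframe()
df["total"] = df.sum(axis=1)
print(df[df.total > 0])
mode = profile.modal_length()
print(f"\nread-length mode: {mode} nt; most frequent 5' base there: "
      f"{profile.top_5p_base(mode)} (T = U in DNA space)")
# Rows are read lengths 15-35, columns the 5' nucleotide; miRNA-derived
# reads concentrate at 20-24 nt with a U-start excess, background reads
# spread uniformly.
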