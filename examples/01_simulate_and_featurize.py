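"""Generate a small synthetic ChIA-PET-like dataset and inspect its features.

Builds a 2-chromosome fixture (peaks, ChIP-Seq reads, CTCF motifs,
NB-distributed loop strengths) and assembles the 10-column design matrix.
"""

from chipr import FeatureSchema, SimConfig, build_feature_matrix, simulate_dataset

config = SimConfig(
    n_chromosomes=2,
    chrom_length_bp=400_000,
    n_peaks_per_chrom=40,
    reads_per_chrom=20_000,
    n_interactions=1_000,
    seed=7,
)
ds = simulate_dataset(config)
print(f"{len(ds.peaks)} anchor peaks, {len(ds.interactions)} interactions, "
      f"{len(ds.motifs)} CTCF motif hits")

x, y = build_feature_matrix(ds.interactions, ds.tracks, ds.genome, ds.motifs,
                            FeatureSchema("full"))
print("\nFeature matrix (one row per anchor pair):")
print(x.head().round(2).to_string())
print(f"\nPET-count targets: mean {y.mean():.1f}, max {y.max():.0f}")
print("Distance is in kb between peak centers; signal columns are RPKM with a")
print("per-chromosome scaling factor; ctcf_flag = 1 only for convergent motifs.")
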