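"""Bin peak-level interactions into 25-kbp contact maps and compare with SCC.

The stratum-adjusted correlation coefficient smooths both maps (window
half-size h = 2), splits them into constant-distance strata, and averages
the per-stratum Pearson correlations with rank-variance weights, removing
the distance-decay confound that inflates a plain Pearson correlation.
"""

import numpy as np

from chipr import (
    FeatureSchema,
    InteractionRecord,
    bin_interactions,
    build_feature_matrix,
    predict,
    scc,
    simulate_dataset,
    train,
)

ds = simulate_dataset(seed=3)
x, y = build_feature_matrix(ds.interactions, ds.tracks, ds.genome, ds.motifs,
                            FeatureSchema("full"))
model = train("gb", x, y, FeatureSchema("full"), seed=3)
predicted = [
    InteractionRecord(r.anchor1, r.anchor2, float(p))
    for r, p in zip(ds.interactions, predict(model, x))
]

for chrom in ds.config.chrom_names[:2]:
    truth = [r for r in ds.interactions if r.chrom == chrom]
    preds = [r for r in predicted if r.chrom == chrom]
    m_true = bin_interactions(truth, 25_000, ds.config.chrom_length_bp)
    m_pred = bin_interactions(preds, 25_000, ds.config.chrom_length_bp)
    result = scc(m_true, m_pred, h=2, max_distance_bp=25_000_000)
    print(f"{chrom}: SCC = {result.scc:.3f} over {len(result.strata_used)} strata; "
          f"total map mass = {m_true.total_mass():.0f} PETs")
print("\nSCC near 1 means the predicted map reproduces the observed contact")
print("structure within every genomic-distance stratum, not just its decay.")
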