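"""Capture of strong loops vs shuffled-anchor control loops.

A reference loop counts as captured when a predicted interaction with
strength >= 3 PETs overlaps both of its anchors. Shuffling the first anchors
within each chromosome produces control loops with realistic anchors but a
scrambled pairing; these should rarely be captured.
"""

import numpy as np

from chipr import (
    FeatureSchema,
    InteractionRecord,
    build_feature_matrix,
    capture_rate,
    predict,
    shuffle_first_anchor,
    simulate_dataset,
    train,
)

ds = simulate_dataset(seed=5)
x, y = build_feature_matrix(ds.interactions, ds.tracks, ds.genome, ds.motifs,
                            FeatureSchema("full"))
model = train("gb", x, y, FeatureSchema("full"), seed=5)
predicted = [
    InteractionRecord(r.anchor1, r.anchor2, float(p))
    for r, p in zip(ds.interactions, predict(model, x))
]

strong = [r for r in ds.interactions if r.strength >= 3]
rng = np.random.default_rng(5)
loops = [strong[i] for i in rng.choice(len(strong), size=400, replace=False)]

true_rate = capture_rate(predicted, loops)
null_rate = capture_rate(predicted, shuffle_first_anchor(loops, seed=5))
print(f"capture of true strong loops:     {true_rate:5.1f}%")
print(f"capture of shuffled-anchor loops: {null_rate:5.1f}%")
print("\nThe gap shows predictions respond to the actual anchor pairing,")
print("not merely to anchor composition or distance marginals.")
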