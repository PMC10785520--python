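# Methods

## Problem and model

`chipr` treats chromatin-interaction strength prediction as tabular
regression. A training example is one intra-chromosomal ChIA-PET interaction:
the features of its two anchor peaks and the integer PET count as target.
Inter-chromosomal records are dropped at parse time and anchors are stored in
coordinate order, so "first anchor" always means the leftmost; this
convention is load-bearing for the CTCF convergence flag and for the
shuffled-first-anchor null.

All coordinates are 0-based half-open (BED convention) throughout. A shared
boundary (one interval's end equal to another's start) is never an overlap.

### Features

| feature | definition | units / range |
|---|---|---|
| distance | \|center(p1) − center(p2)\| / 1000, center = floor((start+end)/2) | kb, ≥ 0 |
| RAD21, H3K27ac, H3K27me3 | reads with midpoint in [start, end), RPKM-normalized | RPKM, ≥ 0 |
| GC | 100 · (#G + #C) / length; ambiguous bases count in the denominator only | %, [0, 100] |
| ctcf_flag | 1 iff left anchor's best motif is '+' and right anchor's is '−' | {0, 1} |

RPKM uses a **per-chromosome** per-million factor: count / (chromosome total
/ 1e6) / (peak length / 1000). Zero reads on a chromosome make RPKM
undefined and raise an error rather than silently producing zeros.

Reads are assigned to peaks by their midpoint — symmetric and robust to
fragment length; 5′-end assignment would be an equally defensible choice and
differs only at peak borders. Reads are not deduplicated. Motif-to-peak
assignment keeps the highest-scoring hit whose midpoint lies in the peak,
ties broken toward the leftmost start so the choice is deterministic.

### Regressors

The tree ensembles are scikit-learn's `RandomForestRegressor` and
`GradientBoostingRegressor` with their canonical defaults pinned numerically
(100 trees / unlimited depth / bootstrap; 100 stages / shrinkage 0.1 /
depth 3 / squared error) so behavior cannot drift across library versions.
Their predictions are clipped at zero.

The DNN is a compact numpy multilayer perceptron: three hidden layers of 128
rectified units, a rectified output unit (predictions are non-negative by
construction), inverted dropout 0.2 after each hidden layer, He
initialization, Adam (lr 1e-5, β₁ 0.9, β₂ 0.999), minibatches of 32, MSE
loss, at most 750 epochs with early stopping when the validation MSE fails
to improve for 50 epochs, restoring the best weights. The validation slice
is the last 10% of the shuffled training rows — the monitored quantity is
fixed but the slice size was an open choice; 10% is the smallest slice that
still gives a stable early-stopping signal at the fixture sizes used here.

Input standardization for the DNN is off by default (tree models are
scale-invariant and the feature definitions above are meaningful raw
numbers) but available as `DnnConfig(standardize=True)`: a z-scale fitted on
the training rows only. With raw kb distances and RPKM values in the
thousands, a learning rate of 1e-5 makes unstandardized training
impractically slow, so the synthetic-data profile and the examples enable
it. This changes only optimization conditioning, not the model class.

Splits: `split_random` draws a 75/25 partition (round(0.75 N) training
rows); `split_by_chromosome_parity` implements the train-odd/test-even
protocol, excluding non-numeric chromosome names (chrX/chrY/chrM) since
parity is undefined for them.

## Contact maps and SCC

An anchor maps to bin floor(center / bin_size); a peak straddling a bin
boundary therefore belongs unambiguously to the bin holding its center. Map
values sum the strengths of all interactions hitting a bin pair; storage is
sparse and symmetric with the diagonal stored once, so total mass (upper
triangle + diagonal) equals total input strength exactly.

Smoothing replaces each cell by the truncated mean of its (2h+1)×(2h+1)
window (in-bounds cells only; a constant map is a fixed point). It is
computed from an integral image with a single division per cell: for
count-valued maps every windowed sum is exact in double precision, so
exactly tied values remain exactly tied after smoothing — this matters
because the SCC weights rank-transform the strata and float noise would
otherwise break ties arbitrarily.

SCC between two maps: smooth both with h, split into constant-distance
strata k = 0 … floor(max_distance/bin_size), compute the per-stratum Pearson
correlation ρₖ, and combine with weights wₖ = Nₖ·√(var(rank Xₖ)·var(rank
Yₖ)) (rank-based variance stabilization). Strata with fewer than two cells
or zero variance in either map are excluded; if nothing remains the SCC is
undefined and an error is raised. Defaults h = 2 and max distance 25 Mbp.

## Evaluation procedures

**NB controls.** Method-of-moments fit p = m/v, r = m²/(v−m) to the observed
strengths, then one independent draw per interaction. Counts with v ≤ m
cannot be negative-binomial; the fit falls back to Poisson(m) with a logged
flag. The controls share the marginal count distribution with the data and
nothing else, so their correlation with the observations centers on zero —
the floor any useful model must clear.

**Loop capture.** A reference loop is captured when some predicted record
with strength ≥ 3 PETs overlaps both of its anchors respectively (≥ 1 bp,
after coordinate ordering). The ≥ 3 threshold is the conventional boundary
between strong and weak interactions; the overlap rule is the simplest
reproducible definition of "the same loop". Null loops permute first-anchor
coordinates within each chromosome (derangements preferred, up to 100
attempts; a single-loop chromosome is left unshuffled with a warning),
preserving anchor composition and count while scrambling the pairing.

**Importance.** Permutation importance is the mean (default 10 repeats) rise
in MAE after shuffling one held-out feature column; permuting a constant
column is the identity, so its importance is exactly zero. Ablation
importance retrains the model without a feature (or the H3K27ac+H3K27me3
pair jointly) and reports the MAE difference on the held-out chromosomes.

**Overlap significance.** For a target subset and a comparison class within
a universe of interactions: 10,000 simulations (configurable) each sample
|target| records without replacement and count the intersection with the
class; the counter increments only on *strictly greater* intersections, so
ties favor the null and the p-value is conservative; expected overlap is the
simulation mean (hypergeometric mean in the random case).

**Shuffled-input controls.** Whole feature rows are permuted jointly and
predictions on the shuffled matrix are compared against the targets in the
original order — a control that preserves every marginal feature
distribution, notably the distance profile.

## Synthetic data

The generator emulates the structure of a cohesin ChIA-PET study:

* genome: i.i.d. bases with block-wise GC targets uniform in [30, 70]% over
  100-kb blocks (isochore-like variation for the GC feature);
* peaks: 2-kb anchors placed one per slot on a regular grid with random
  offsets (guaranteed non-overlapping);
* reads: 36-bp reads, uniform background plus intensity-weighted extra reads
  inside peaks; the peak-read fraction solves mean in-peak density =
  enrichment_fold × background (default 10×, typical of good ChIP-Seq).
  RAD21 intensities are lognormal(0, 0.5) per peak; H3K27ac and H3K27me3
  intensities are u and 1−u plus noise, so the marks are anti-correlated as
  active and repressive marks should be;
* motifs: one 19-bp stranded CTCF motif per peak with probability 0.7,
  strands balanced; CTCF ChIP peaks cover 80% of motif-bearing anchors;
* interactions: distinct within-chromosome peak pairs with generative mean
  μ = μ₀·exp(−d/λ)·(1 + β·mean anchor RAD21 RPKM)·(1 + γ·ctcf_flag) and
  strength ~ NB(mean μ, dispersion k), variance μ + μ²/k.

Defaults: 4 chromosomes × 1 Mbp, 80 peaks each, 50,000 reads per chromosome
per track, 5,000 interactions, μ₀ = 30, λ = 300 kb, β = 2×10⁻⁴ (scaled to
per-chromosome RPKM values in the thousands, giving a ~1.2–1.8× signal
factor), γ = 1 (convergent motifs double the mean), k = 6 (strong
overdispersion, variance ≈ μ + μ²/6). Exponential distance decay was chosen
for its closed-form scale parameter; any monotone decay would serve. All
randomness flows from one master seed through independent named substreams,
so components can be regenerated in isolation.

What the generator does **not** emulate: fragment-length and read-quality
structure, mappability and blacklist artifacts, replicate variation,
trans-chromosomal contacts, TAD/compartment structure beyond distance decay,
and any dependence of strength on histone marks or GC (those features are
present but carry no independent signal). Passing tests therefore show the
pipeline recovers the planted dependence structure at realistic noise
levels — not that the trained models transfer to real chromatin.

## Numerical choices and degenerate inputs

* Correlations on a constant vector are undefined and returned as NaN,
  never silently zero.
* nb_moment_match requires m > 0; v ≤ m triggers the Poisson fallback.
* Bin assignment errors on anchors at or beyond the stated chromosome
  length; feature extraction errors on anchors beyond the sequence.
* The empirical p-value lies on the grid {0, 1/n_sim, …, 1}.
* Tree-model training is bit-reproducible under a fixed seed; the numpy DNN
  is deterministic too since all of its randomness comes from one Generator.
* Problem sizes in the tests and the acceptance script (5,000 interactions,
  4 × 1 Mbp chromosomes, 500-loop capture sets, 200 × 200 resampling for the
  p-value uniformity check) are the package's default desk-scale study
  conditions, chosen so the full suite runs in about a minute while keeping
  binomial/NB sampling tolerances comfortably tight.

## Known limitations

* The DNN is a minimal MLP: no learning-rate schedules, no weight decay, no
  GPU path. It matches the fixed architecture above and nothing more.
* SCC is implemented for single-chromosome maps; genome-wide summaries
  average per-chromosome values.
* `capture_rate` is O(|reference| × |strong predictions per chromosome|);
  fine for peak-level lists, not for dense bin-level sets.
* The BEDPE strength column index is configurable because upstream
  pipelines disagree on layout; defaults assume column 7.
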