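"""Evaluation procedures for predicted interaction strengths.

Covers: negative-binomial control strengths matched to the observed mean and
variance, Pearson/Spearman correlations, the stratum-adjusted correlation
coefficient (SCC) between contact maps, loop capture against shuffled-anchor
null loops, permutation and drop-one-feature (ablation) importance, CTCF
occupancy classes, the resampling-based overlap significance test, and
shuffled-input control predictions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contact_maps import ContactMap, smooth_map, stratify
from .io_formats import InteractionRecord, Peak
from .models import STRONG_THRESHOLD, TrainedModel, predict, train

logger = logging.getLogger(__name__)

__all__ = [
    "NbParams",
    "SccResult",
    "nb_moment_match",
    "sample_nb_control",
    "correlate",
    "scc",
    "shuffle_first_anchor",
    "capture_rate",
    "permutation_importance",
    "ablation_importance",
    "classify_ctcf_occupancy",
    "empirical_overlap_test",
    "shuffled_input_control",
]


@dataclass(frozen=True)
class NbParams:
    """Negative-binomial parameters (size r, success probability p).

    Moment-matched so that the implied mean r(1-p)/p and variance r(1-p)/p^2
    reproduce a target mean and variance. When the data are not overdispersed
    (variance <= mean) the distribution degenerates and a Poisson fallback is
    flagged instead.
    """

    r: float
    p: float
    poisson_fallback: bool = False
    poisson_mean: float = float("nan")

    @property
    def mean(self) -> float:
        if self.poisson_fallback:
            return self.poisson_mean
        return self.r * (1 - self.p) / self.p

    @property
    def variance(self) -> float:
        if self.poisson_fallback:
            return self.poisson_mean
        return self.r * (1 - self.p) / self.p**2


def nb_moment_match(mean: float, variance: float) -> NbParams:
    """Fit NB(r, p) by the method of moments: p = m/v, r = m^2/(v - m).

    Requires overdispersion; at variance <= mean a Poisson(mean) fallback is
    returned with a logged warning (flagged on the result).
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if variance <= mean:
        logger.warning(
            "variance (%.4g) <= mean (%.4g): falling back to Poisson", variance, mean
        )
        return NbParams(r=float("nan"), p=1.0, poisson_fallback=True,
                        poisson_mean=mean)
    p = mean / variance
    r = mean * mean / (variance - mean)
    return NbParams(r=r, p=p)


def sample_nb_control(interactions, seed: int = 0) -> np.ndarray:
    """Control strengths: one NB draw per interaction, distribution matched
    to the sample mean/variance of the observed strengths.

    These controls share the marginal count distribution with the data but
    carry no information about which anchor pair they belong to, so their
    correlation with the observed strengths centers on zero.
    """
    if len(interactions) and isinstance(interactions[0], InteractionRecord):
        strengths = np.asarray([r.strength for r in interactions], dtype=float)
    else:
        strengths = np.asarray(interactions, dtype=float)
    if len(strengths) < 2:
        raise ValueError("need at least 2 interactions to fit a control")
    m = float(strengths.mean())
    v = float(strengths.var(ddof=1))
    params = nb_moment_match(m, v)
    rng = np.random.default_rng(seed)
    if params.poisson_fallback:
        return rng.poisson(params.poisson_mean, size=len(strengths)).astype(float)
    return rng.negative_binomial(params.r, params.p, size=len(strengths)).astype(float)


def correlate(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class SccResult:
    """Stratum-adjusted correlation between two contact maps."""

    scc: float
    stratum_correlations: list[float] = field(default_factory=list)
    stratum_weights: list[float] = field(default_factory=list)
    strata_used: list[int] = field(default_factory=list)


def scc(
    map_a: ContactMap,
    map_b: ContactMap,
    h: int = 2,
    max_distance_bp: int = 25_000_000,
) -> SccResult:
    """Stratum-adjusted correlation coefficient between two contact maps.

    Both maps are smoothed with window half-size ``h``, split into
    constant-distance strata up to ``max_distance_bp``, and the per-stratum
    Pearson correlations are combined with weights
    ``w_k = N_k * sqrt(var(rank(X_k)) * var(rank(Y_k)))`` (rank-based
    variance stabilization). Strata with zero variance in either map are
    excluded.
    """
    if map_a.chrom != map_b.chrom:
        raise ValueError("maps must describe the same chromosome")
    if map_a.bin_size_bp != map_b.bin_size_bp or map_a.n_bins != map_b.n_bins:
        raise ValueError("maps must share bin size and bin count")
    sa = stratify(smooth_map(map_a, h), max_distance_bp)
    sb = stratify(smooth_map(map_b, h), max_distance_bp)

    rhos, weights, used = [], [], []
    for k, (xk, yk) in enumerate(zip(sa, sb)):
        if len(xk) < 2 or xk.std() == 0 or yk.std() == 0:
            continue
        rho = float(np.corrcoef(xk, yk)[0, 1])
        rank_x = stats.rankdata(xk)
        rank_y = stats.rankdata(yk)
        w = len(xk) * math.sqrt(rank_x.var() * rank_y.var())
        rhos.append(rho)
        weights.append(w)
        used.append(k)
    if not weights or sum(weights) == 0:
        raise ValueError("no stratum with variance in both maps: SCC undefined")
    value = float(np.dot(weights, rhos) / np.sum(weights))
    return SccResult(scc=value, stratum_correlations=rhos,
                     stratum_weights=weights, strata_used=used)


def shuffle_first_anchor(
    loops: list[InteractionRecord], seed: int = 0
) -> list[InteractionRecord]:
    """Random control loops: permute first anchors within each chromosome.

    The multiset of first-anchor coordinates per chromosome is preserved;
    second anchors stay put. A derangement (no loop keeping its own first
    anchor) is preferred; a chromosome with a single loop is left unshuffled
    with a warning.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[int]] = {}
    for i, rec in enumerate(loops):
        by_chrom.setdefault(rec.chrom, []).append(i)

    out: list[InteractionRecord | None] = [None] * len(loops)
    for chrom, idxs in by_chrom.items():
        n = len(idxs)
        if n < 2:
            warnings.warn(
                f"single loop on {chrom}: left unshuffled", stacklevel=2
            )
            out[idxs[0]] = loops[idxs[0]]
            continue
        perm = None
        for _ in range(100):  # derangement-preferred
            cand = rng.permutation(n)
            if not np.any(cand == np.arange(n)):
                perm = cand
                break
        if perm is None:
            perm = rng.permutation(n)
        for pos, src in enumerate(perm):
            orig = loops[idxs[pos]]
            donor = loops[idxs[src]]
            out[idxs[pos]] = InteractionRecord(
                donor.anchor1, orig.anchor2, orig.strength
            )
    return out  # type: ignore[return-value]


def _anchors_match(pred: InteractionRecord, ref: InteractionRecord) -> bool:
    """Respective-anchor match: >= 1 bp overlap of both ordered anchors."""
    return pred.anchor1.overlaps(ref.anchor1) and pred.anchor2.overlaps(ref.anchor2)


def capture_rate(
    predicted: list[InteractionRecord],
    reference_loops: list[InteractionRecord],
    threshold: float = STRONG_THRESHOLD,
) -> float:
    """Percentage of reference loops matched by a strong predicted interaction.

    A reference loop counts as captured when some predicted record with
    strength >= threshold overlaps both of its anchors (respectively, after
    coordinate ordering).
    """
    if not reference_loops:
        raise ValueError("reference loop list is empty")
    strong = [p for p in predicted if p.strength >= threshold]
    strong_by_chrom: dict[str, list[InteractionRecord]] = {}
    for p in strong:
        strong_by_chrom.setdefault(p.chrom, []).append(p)
    captured = 0
    for ref in reference_loops:
        cands = strong_by_chrom.get(ref.chrom, [])
        if any(_anchors_match(p, ref) for p in cands):
            captured += 1
    return 100.0 * captured / len(reference_loops)


def _metric(name: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if name == "mae":
        return float(np.mean(np.abs(y_true - y_pred)))
    if name == "mse":
        return float(np.mean((y_true - y_pred) ** 2))
    raise ValueError(f"unknown metric {name!r}")


def permutation_importance(
    model: TrainedModel,
    features: pd.DataFrame,
    targets,
    column: str,
    metric: str = "mae",
    seed: int = 0,
    repeats: int = 10,
) -> float:
    """Permutation importance of one feature column on held-out data.

    The column is shuffled, the error metric recomputed, and the importance
    is the mean (over repeats) increase of the metric over its baseline:
    larger means the model leans on that feature more.
    """
    if column not in features.columns:
        raise ValueError(f"unknown feature column {column!r}")
    if len(features) < 10:
        raise ValueError("need at least 10 test rows")
    y = np.asarray(targets, dtype=float)
    baseline = _metric(metric, y, predict(model, features))
    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(repeats):
        shuffled = features.copy()
        shuffled[column] = rng.permutation(shuffled[column].to_numpy())
        deltas.append(_metric(metric, y, predict(model, shuffled)) - baseline)
    return float(np.mean(deltas))


def ablation_importance(
    variant: str,
    train_features: pd.DataFrame,
    train_targets,
    test_features: pd.DataFrame,
    test_targets,
    drop: str | tuple[str, ...],
    config=None,
    seed: int = 0,
) -> float:
    """Drop-one-feature retraining importance on a held-out chromosome set.

    Retrains the given variant without the named feature column (or the
    histone pair, passed as a tuple such as ("h3k27ac_p1", "h3k27ac_p2",
    "h3k27me3_p1", "h3k27me3_p2") or the shorthand "histones") and reports
    MAE(reduced model) - MAE(full model) on the test rows. Positive values
    mean the feature was helping.
    """
    if drop == "histones":
        drop_cols = [c for c in train_features.columns if c.startswith("h3k27")]
    elif isinstance(drop, str):
        drop_cols = [drop]
    else:
        drop_cols = list(drop)
    missing = [c for c in drop_cols if c not in train_features.columns]
    if missing:
        raise ValueError(f"features not in schema: {missing}")
    if len(drop_cols) >= len(train_features.columns):
        raise ValueError("cannot drop every feature")

    y_tr = np.asarray(train_targets, dtype=float)
    y_te = np.asarray(test_targets, dtype=float)
    # arrays bypass the DataFrame/schema column check: ablation uses ad-hoc schemas
    full = train(variant, train_features.to_numpy(dtype=float), y_tr,
                 config=config, seed=seed)
    mae_full = _metric("mae", y_te, predict(full, test_features.to_numpy(dtype=float)))
    reduced_train = train_features.drop(columns=drop_cols)
    reduced_test = test_features.drop(columns=drop_cols)
    reduced = train(variant, reduced_train.to_numpy(dtype=float), y_tr,
                    config=config, seed=seed)
    mae_reduced = _metric("mae", y_te, predict(reduced, reduced_test.to_numpy(dtype=float)))
    return mae_reduced - mae_full


def classify_ctcf_occupancy(
    interactions: list[InteractionRecord], ctcf_peaks: list[Peak]
) -> list[str]:
    """Label each interaction by CTCF ChIP-Seq peak overlap of its anchors.

    An anchor is occupied when it overlaps any CTCF peak by >= 1 bp
    (half-open intervals, so a shared boundary is not an overlap). Classes
    are "both", "one" or "none".
    """
    peaks_by_chrom: dict[str, list[Peak]] = {}
    for p in ctcf_peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    for ps in peaks_by_chrom.values():
        ps.sort()

    def occupied(anchor: Peak) -> bool:
        return any(anchor.overlaps(p) for p in peaks_by_chrom.get(anchor.chrom, []))

    classes = []
    for rec in interactions:
        n = int(occupied(rec.anchor1)) + int(occupied(rec.anchor2))
        classes.append({2: "both", 1: "one", 0: "none"}[n])
    return classes


def empirical_overlap_test(
    target_set: list[InteractionRecord],
    comparison_class: list[InteractionRecord],
    universe: list[InteractionRecord],
    n_sim: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Resampling significance of the overlap between two interaction subsets.

    observed = |target ∩ class|. Each simulation samples |target| records
    from the universe without replacement and counts the intersection with
    the class; the counter increments only when the simulated intersection
    strictly exceeds the observed one. Returns (p_value, expected_overlap,
    observed_overlap) with p = counter / n_sim and expected = mean simulated
    intersection.
    """
    if len(target_set) > len(universe):
        raise ValueError("target set larger than universe")
    class_set = set(comparison_class)
    observed = sum(1 for r in target_set if r in class_set)
    in_class = np.fromiter((r in class_set for r in universe), dtype=bool,
                           count=len(universe))
    rng = np.random.default_rng(seed)
    n_target = len(target_set)
    counter = 0
    total = 0.0
    for _ in range(n_sim):
        idx = rng.choice(len(universe), size=n_target, replace=False)
        inter = int(in_class[idx].sum())
        total += inter
        if inter > observed:
            counter += 1
    return counter / n_sim, total / n_sim, observed


def shuffled_input_control(
    model: TrainedModel, features: pd.DataFrame, seed: int = 0
) -> np.ndarray:
    """Control predictions from whole-row-shuffled inputs.

    Feature rows are permuted jointly and the model applied to the shuffled
    matrix; comparing the result (in shuffled-row order) against the targets
    in their original order gives a control correlation that preserves the
    marginal feature distributions, notably the genomic-distance profile.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(features))
    shuffled = features.iloc[perm].reset_index(drop=True) if isinstance(
        features, pd.DataFrame
    ) else np.asarray(features)[perm]
    return predict(model, shuffled)
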