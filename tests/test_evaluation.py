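"""Negative-binomial controls, correlations, SCC, loop capture, importance,
occupancy classes and the overlap significance test."""

import numpy as np
import pandas as pd
import pytest
from scipy.sparse import csr_matrix
from scipy.stats import hypergeom

from chipr.contact_maps import ContactMap
from chipr.evaluation import (
    capture_rate,
    classify_ctcf_occupancy,
    correlate,
    empirical_overlap_test,
    nb_moment_match,
    permutation_importance,
    sample_nb_control,
    scc,
    shuffle_first_anchor,
    shuffled_input_control,
)
from chipr.features import FeatureSchema
from chipr.io_formats import InteractionRecord, Peak
from chipr.models import predict, train

from scc_oracle import brute_force_scc


def _rec(s1, s2, strength, chrom="chr1", length=2000):
    return InteractionRecord(
        Peak(chrom, s1, s1 + length), Peak(chrom, s2, s2 + length), strength
    )


class TestNbMomentMatch:
    def test_worked_example(self):
        params = nb_moment_match(5.0, 20.0)
        assert params.p == pytest.approx(0.25)
        assert params.r == pytest.approx(5 / 3)

    def test_round_trip_moments(self):
        params = nb_moment_match(5.0, 20.0)
        assert params.mean == pytest.approx(5.0)
        assert params.variance == pytest.approx(20.0)

    def test_poisson_fallback_at_equal_moments(self):
        params = nb_moment_match(4.0, 4.0)
        assert params.poisson_fallback and params.mean == 4.0

    def test_nonpositive_mean_errors(self):
        with pytest.raises(ValueError):
            nb_moment_match(0.0, 5.0)


class TestSampleNbControl:
    def test_output_length_and_seed_determinism(self):
        strengths = [1.0, 4.0, 9.0, 2.0, 7.0, 3.0]
        a = sample_nb_control(strengths, seed=5)
        b = sample_nb_control(strengths, seed=5)
        assert len(a) == 6 and np.array_equal(a, b)

    def test_identical_strengths_use_poisson_path(self):
        draws = sample_nb_control([5.0] * 100, seed=1)
        assert len(draws) == 100 and (draws >= 0).all()

    def test_accepts_interaction_records(self):
        recs = [_rec(i * 5000, i * 5000 + 20_000, i) for i in range(1, 6)]
        assert len(sample_nb_control(recs, seed=0)) == 5


class TestCorrelate:
    def test_linear_map_pearson_one(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1) == pytest.approx(1.0)

    def test_monotone_transform_spearman_one(self):
        x = np.arange(1.0, 11.0)
        assert correlate(x, np.exp(x / 3), method="spearman") == pytest.approx(1.0)

    def test_constant_vector_is_nan(self):
        assert np.isnan(correlate(np.ones(5), np.arange(5.0)))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [1, 2])


def _random_symmetric(n, rng):
    mat = rng.poisson(4, size=(n, n)).astype(float)
    return (mat + mat.T) / 2


class TestScc:
    @staticmethod
    def _map(arr):
        return ContactMap("chr1", 25_000, csr_matrix(arr))

    def test_self_correlation_is_one(self, rng):
        m = self._map(_random_symmetric(30, rng))
        assert scc(m, m, h=1, max_distance_bp=250_000).scc == pytest.approx(1.0)

    def test_permuted_stratum_lowers_scc(self, rng):
        arr = _random_symmetric(30, rng)
        other = arr.copy()
        k = 3  # permute one off-diagonal in both triangles
        diag = np.diagonal(other, offset=k).copy()
        perm = rng.permutation(len(diag))
        for i, p in enumerate(perm):
            other[i, i + k] = diag[p]
            other[i + k, i] = diag[p]
        val = scc(self._map(arr), self._map(other), h=0,
                  max_distance_bp=250_000).scc
        assert val < 1.0

    def test_symmetric_in_arguments(self, rng):
        a = self._map(_random_symmetric(25, rng))
        b = self._map(_random_symmetric(25, rng))
        assert scc(a, b, h=2, max_distance_bp=250_000).scc == pytest.approx(
            scc(b, a, h=2, max_distance_bp=250_000).scc, abs=1e-12
        )

    def test_matches_brute_force_oracle(self, rng):
        a = _random_symmetric(20, rng)
        b = _random_symmetric(20, rng)
        got = scc(self._map(a), self._map(b), h=1, max_distance_bp=150_000).scc
        want = brute_force_scc(a, b, h=1, max_k=6)
        assert got == pytest.approx(want, abs=1e-10)

    def test_mismatched_maps_error(self, rng):
        a = self._map(_random_symmetric(10, rng))
        b = ContactMap("chr2", 25_000, csr_matrix(_random_symmetric(10, rng)))
        with pytest.raises(ValueError):
            scc(a, b)


class TestShuffleFirstAnchor:
    def test_two_loops_swap(self):
        loops = [_rec(0, 50_000, 3), _rec(10_000, 80_000, 5)]
        out = shuffle_first_anchor(loops, seed=0)
        assert out[0].anchor1.start == 10_000 and out[1].anchor1.start == 0
        # second anchors and strengths stay put
        assert out[0].anchor2 == loops[0].anchor2
        assert [r.strength for r in out] == [3, 5]

    def test_multiset_of_first_anchors_preserved(self):
        # first anchors in [0, 50 kb), second anchors in [120 kb, ...): any
        # permutation of first anchors keeps coordinate order intact
        rng = np.random.default_rng(3)
        loops = [
            _rec(int(s), 120_000 + int(d), int(v))
            for s, d, v in zip(
                rng.integers(0, 50_000, 20),
                rng.integers(0, 60_000, 20),
                rng.integers(0, 9, 20),
            )
        ]
        out = shuffle_first_anchor(loops, seed=1)
        assert len(out) == len(loops)
        assert sorted(r.anchor1 for r in out) == sorted(r.anchor1 for r in loops)

    def test_single_loop_chromosome_warns(self):
        loops = [_rec(0, 50_000, 3, chrom="chr7")]
        with pytest.warns(UserWarning, match="single loop"):
            out = shuffle_first_anchor(loops, seed=0)
        assert out == loops


class TestCaptureRate:
    def test_reference_equals_predicted_is_100(self):
        recs = [_rec(i * 10_000, i * 10_000 + 50_000, 5) for i in range(10)]
        assert capture_rate(recs, recs) == 100.0

    def test_all_weak_predictions_capture_nothing(self):
        ref = [_rec(0, 50_000, 5)]
        pred = [_rec(0, 50_000, 2.9)]
        assert capture_rate(pred, ref) == 0.0

    def test_half_matched_constructed_fixture(self):
        """10 reference loops, strong predictions overlap exactly 5 of them
        (verified by brute-force overlap enumeration)."""
        ref = [_rec(i * 20_000, i * 20_000 + 100_000, 4) for i in range(10)]
        pred = [
            _rec(i * 20_000 + 500, i * 20_000 + 100_500, 6) for i in range(5)
        ] + [_rec(500_000 + i * 5_000, 700_000 + i * 5_000, 6) for i in range(5)]

        def overlaps(a, b):
            return a.chrom == b.chrom and a.start < b.end and b.start < a.end

        brute = sum(
            any(
                p.strength >= 3
                and overlaps(p.anchor1, r.anchor1)
                and overlaps(p.anchor2, r.anchor2)
                for p in pred
            )
            for r in ref
        )
        assert brute == 5
        assert capture_rate(pred, ref) == 50.0

    def test_boundary_touch_is_not_overlap(self):
        ref = [_rec(0, 50_000, 5)]  # anchor1 = [0, 2000)
        pred = [
            InteractionRecord(Peak("chr1", 2_000, 4_000), Peak("chr1", 50_000, 52_000), 9)
        ]
        assert capture_rate(pred, ref) == 0.0

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            capture_rate([_rec(0, 50_000, 5)], [])


class TestImportance:
    def test_permuting_constant_column_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(
            {
                "distance_kb": rng.uniform(0, 500, 200),
                "rad21_p1": rng.uniform(0, 5, 200),
                "rad21_p2": rng.uniform(0, 5, 200),
                "gc_p1": np.full(200, 50.0),
                "gc_p2": rng.uniform(30, 70, 200),
                "ctcf_flag": np.zeros(200),
            }
        )
        y = 10 * np.exp(-x["distance_kb"].to_numpy() / 100)
        model = train("gb", x, y, FeatureSchema("minimal"), seed=0)
        imp = permutation_importance(model, x, y, "gc_p1", seed=1, repeats=3)
        assert imp == 0.0

    def test_single_repeat_reproducible(self, trained_models, full_features,
                                        split_75_25):
        x_full, _, y = full_features
        _, te = split_75_25
        xt = x_full.iloc[te].reset_index(drop=True)
        a = permutation_importance(trained_models["gb"], xt, y[te],
                                   "distance_kb", seed=9, repeats=1)
        b = permutation_importance(trained_models["gb"], xt, y[te],
                                   "distance_kb", seed=9, repeats=1)
        assert a == b

    def test_unknown_column_errors(self, trained_models, full_features):
        x_full, _, y = full_features
        with pytest.raises(ValueError, match="unknown feature"):
            permutation_importance(trained_models["gb"], x_full, y, "nope")


class TestClassifyOccupancy:
    def test_three_classes(self):
        interactions = [
            _rec(0, 50_000, 1),  # anchors [0,2000) and [50000,52000)
            _rec(100_000, 150_000, 1),
            _rec(200_000, 250_000, 1),
        ]
        ctcf = [
            Peak("chr1", 1_000, 1_500),
            Peak("chr1", 50_500, 51_000),
            Peak("chr1", 100_100, 100_300),
        ]
        assert classify_ctcf_occupancy(interactions, ctcf) == ["both", "one", "none"]

    def test_shared_boundary_not_occupied(self):
        interactions = [_rec(0, 50_000, 1)]
        ctcf = [Peak("chr1", 2_000, 3_000)]  # starts exactly at anchor end
        assert classify_ctcf_occupancy(interactions, ctcf) == ["none"]


class TestEmpiricalOverlap:
    @staticmethod
    def _universe(n=60):
        return [_rec(i * 10_000, i * 10_000 + 60_000, i % 7) for i in range(n)]

    def test_target_equals_class_equals_universe(self):
        u = self._universe()
        p, expected, observed = empirical_overlap_test(u, u, u, n_sim=50, seed=0)
        assert observed == len(u)
        assert p == 0.0  # no simulation can strictly exceed a full overlap
        assert expected == len(u)

    def test_expected_matches_hypergeometric_mean(self):
        u = self._universe(200)
        target, cls = u[:50], u[100:180]
        _, expected, observed = empirical_overlap_test(target, cls, u,
                                                       n_sim=3000, seed=2)
        hyper_mean = hypergeom(200, 80, 50).mean()
        assert observed == 0
        assert expected == pytest.approx(hyper_mean, rel=0.05)

    def test_p_value_grid_and_expected_bounds(self):
        u = self._universe(100)
        p, expected, _ = empirical_overlap_test(u[:20], u[10:40], u, n_sim=40, seed=1)
        assert p in {i / 40 for i in range(41)}
        assert 0 <= expected <= 20

    def test_target_bigger_than_universe_errors(self):
        u = self._universe(10)
        with pytest.raises(ValueError):
            empirical_overlap_test(u + u + u, u, u)


class TestShuffledInputControl:
    def test_multiset_of_predictions_preserved(self, trained_models, full_features):
        x_full, _, _ = full_features
        x = x_full.head(500)
        normal = predict(trained_models["gb"], x)
        control = shuffled_input_control(trained_models["gb"], x, seed=4)
        assert np.allclose(np.sort(normal), np.sort(control))

    def test_control_correlation_below_real(self, trained_models, full_features,
                                            split_75_25):
        x_full, _, y = full_features
        _, te = split_75_25
        xt = x_full.iloc[te].reset_index(drop=True)
        real_r = correlate(predict(trained_models["gb"], xt), y[te])
        control_r = correlate(shuffled_input_control(trained_models["gb"], xt, seed=5),
                              y[te])
        assert control_r < real_r
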