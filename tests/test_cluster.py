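"""Spectral clustering contracts: affinity, Laplacian spectrum, eigengap
model selection, region assignment, accuracy and grid resampling."""

import numpy as np
import pytest
from itertools import product
from sklearn.base import clone

from sulcimap.cluster import (
    SpectralChannelClusterer,
    affinity_matrix,
    assign_regions,
    choose_k_eigengap,
    clustering_accuracy,
    resample_grids,
    rw_laplacian,
    spectral_cluster,
)
from sulcimap.preprocess import SSEPTrace, preprocess_recording
from sulcimap.simulate import SimulationParams, simulate_session


def make_trace(values, **kw):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    t = 10.0 + np.arange(values.shape[1]) / 2400.0 * 1000.0
    return SSEPTrace(values=values, time_axis_ms=t, flavor="zscored", **kw)


def two_group_waveforms(n_per_group=4, T=24, gap=4.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base = np.sin(np.linspace(0, 3, T))
    a = base + noise * rng.normal(size=(n_per_group, T))
    b = base + gap + noise * rng.normal(size=(n_per_group, T))
    return np.vstack([a, b])


class TestAffinity:
    def test_identical_waveforms_have_unit_affinity(self):
        X = np.tile(np.arange(5.0), (3, 1))
        W = affinity_matrix(X)
        np.testing.assert_allclose(W, 1.0)

    def test_closed_form_at_known_distance(self):
        # squared distance 8 with sigma=2 -> exp(-1)
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        W = affinity_matrix(X, sigma=2.0)
        assert W[0, 1] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_symmetry_and_diagonal(self, rng):
        X = rng.normal(size=(6, 10))
        W = affinity_matrix(X)
        np.testing.assert_allclose(W, W.T)
        np.testing.assert_allclose(np.diag(W), 1.0)
        assert np.all(W > 0) and np.all(W <= 1.0)

    def test_excluded_channels_rejected(self):
        trace = make_trace(np.zeros((4, 8)),
                           excluded_channels=np.array([1]))
        with pytest.raises(ValueError, match="excluded"):
            affinity_matrix(trace)


class TestLaplacian:
    def test_all_ones_matrix_spectrum(self):
        graph = rw_laplacian(np.ones((3, 3)))
        np.testing.assert_allclose(graph.eigenvalues, [0.0, 1.0, 1.0],
                                   atol=1e-12)
        np.testing.assert_allclose(graph.D, 3.0)
        np.testing.assert_allclose(graph.L, np.eye(3) - np.ones((3, 3)) / 3)

    def test_two_blocks_give_two_zero_eigenvalues(self):
        W = np.zeros((6, 6))
        W[:3, :3] = 0.9
        W[3:, 3:] = 0.9
        np.fill_diagonal(W, 1.0)
        graph = rw_laplacian(W)
        assert np.sum(graph.eigenvalues < 1e-10) == 2

    def test_smallest_eigenvalue_is_zero_for_random_affinity(self, rng):
        for _ in range(20):
            n = rng.integers(3, 10)
            W = rng.uniform(0.05, 1.0, size=(n, n))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 1.0)
            graph = rw_laplacian(W)
            assert abs(graph.eigenvalues[0]) < 1e-8

    def test_zero_row_sum_raises(self):
        W = np.zeros((3, 3))
        with pytest.raises(ValueError, match="row sum"):
            rw_laplacian(W)


class TestEigengap:
    def test_clear_second_gap_gives_two(self):
        assert choose_k_eigengap(np.array([0.0, 0.01, 0.9, 0.95, 0.99])) == 2

    def test_dominant_first_gap_gives_one(self):
        assert choose_k_eigengap(np.array([0.0, 0.8, 0.85, 0.9, 0.95])) == 1

    def test_near_tie_prefers_fewer_clusters(self):
        # gaps 0.4, 0.42: within the floor -> smaller k wins
        assert choose_k_eigengap(np.array([0.0, 0.4, 0.82, 0.84, 0.86])) == 1

    def test_too_few_eigenvalues_raise(self):
        with pytest.raises(ValueError):
            choose_k_eigengap(np.array([0.0]))


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        est = SpectralChannelClusterer(sigma=3.0, random_state=5)
        assert est.get_params()["sigma"] == 3.0
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_well_separated_groups_split_for_any_seed(self):
        X = two_group_waveforms()
        for seed in (0, 1, 2, 99):
            labels = SpectralChannelClusterer(random_state=seed).fit_predict(X)
            assert len(set(labels[:4])) == 1
            assert len(set(labels[4:])) == 1
            assert labels[0] != labels[-1]

    def test_fit_is_deterministic_given_seed(self):
        X = two_group_waveforms(noise=0.3, seed=3)
        a = SpectralChannelClusterer(random_state=0).fit(X)
        b = SpectralChannelClusterer(random_state=0).fit(X)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        np.testing.assert_allclose(a.eigenvalues_, b.eigenvalues_)

    def test_fitted_attributes_present(self):
        est = SpectralChannelClusterer(random_state=0).fit(two_group_waveforms())
        for attr in ("affinity_", "eigenvalues_", "eigengaps_", "k_",
                     "embedding_", "labels_"):
            assert hasattr(est, attr)
        assert est.k_ == 2

    def test_kmeans_matches_exhaustive_partition_search(self):
        # on <=8 channels the k-means split of the 1-D embedding must reach
        # the global minimum within-cluster sum of squares
        X = two_group_waveforms(n_per_group=4, gap=1.0, noise=0.6, seed=5)
        est = SpectralChannelClusterer(random_state=0).fit(X)
        if est.k_ != 2:
            pytest.skip("model selection chose k != 2 on this instance")
        emb = est.embedding_
        best_sse, best_part = np.inf, None
        for assign in product([0, 1], repeat=len(emb)):
            assign = np.asarray(assign)
            if assign.min() == assign.max():
                continue
            sse = sum(
                np.sum((emb[assign == c] - emb[assign == c].mean()) ** 2)
                for c in (0, 1)
            )
            if sse < best_sse - 1e-15:
                best_sse, best_part = sse, assign
        got = est.labels_
        same = np.array_equal(got, best_part) or np.array_equal(1 - got, best_part)
        assert same

    def test_spectrum_invariant_under_channel_permutation(self, rng):
        X = two_group_waveforms(noise=0.4, seed=8)
        perm = rng.permutation(len(X))
        a = SpectralChannelClusterer(random_state=0).fit(X)
        b = SpectralChannelClusterer(random_state=0).fit(X[perm])
        np.testing.assert_allclose(a.eigenvalues_, b.eigenvalues_, atol=1e-9)
        # partitions equal up to the same permutation (cluster ids may swap
        # because the eigenvector sign is arbitrary)
        expected = a.labels_[perm]
        same = np.array_equal(b.labels_, expected) or np.array_equal(
            b.labels_, 1 - expected
        )
        assert same


class TestRegionAssignment:
    def _clustered(self, traces, truth, flavor="zscored", seed=0):
        res = spectral_cluster(traces[flavor], seed=seed)
        return assign_regions(res, traces[flavor], truth)

    def test_accuracy_at_least_half_over_permutations(self, traces, session):
        _, _, truth = session
        res = self._clustered(traces, truth)
        assert res.accuracy_pct is not None and res.accuracy_pct >= 50.0

    def test_polarity_rule_matches_ground_truth_mapping(self, traces, session):
        _, _, truth = session
        with_gt = self._clustered(traces, truth)
        res = spectral_cluster(traces["zscored"], seed=0)
        unsup = assign_regions(res, traces["zscored"], None)
        assert unsup.region_map == with_gt.region_map

    def test_single_cluster_has_no_accuracy(self, traces):
        res = spectral_cluster(traces["zscored"], seed=0)
        res.k = 1
        res = assign_regions(res, traces["zscored"], None)
        assert set(res.region_map.values()) == {"single"}
        assert res.accuracy_pct is None

    def test_all_anterior_truth_gives_larger_cluster_fraction(self):
        from sulcimap.simulate import GroundTruth

        X = two_group_waveforms(n_per_group=4)
        trace = make_trace(X)
        res = spectral_cluster(trace, seed=0)
        assert res.k == 2
        truth = GroundTruth(
            region_labels=np.asarray(["anterior"] * 8, dtype=object),
            cs_line=np.zeros((2, 2)), corrupted_channels=np.array([], int),
            true_latencies_ms={},
        )
        res = assign_regions(res, trace, truth)
        sizes = np.bincount(res.labels)
        assert res.accuracy_pct == pytest.approx(100.0 * sizes.max() / 8)

    def test_complement_identity(self, traces, session):
        _, _, truth = session
        res = spectral_cluster(traces["zscored"], seed=0)
        kept = res.channel_indices
        true = np.asarray(truth.region_labels, dtype=object)[kept]
        accs = []
        for mapping in ({0: "anterior", 1: "posterior"},
                        {0: "posterior", 1: "anterior"}):
            pred = np.asarray([mapping[int(l)] for l in res.labels], object)
            accs.append(clustering_accuracy(pred, true))
        assert accs[0] + accs[1] == pytest.approx(100.0)


class TestAccuracy:
    def test_perfect_agreement(self):
        labels = np.asarray(["anterior"] * 16 + ["posterior"] * 16, object)
        assert clustering_accuracy(labels, labels) == 100.0

    def test_partial_agreement(self):
        true = np.asarray(["anterior"] * 15 + ["posterior"] * 15, object)
        pred = true.copy()
        pred[:3] = "posterior"
        assert clustering_accuracy(pred, true) == pytest.approx(90.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            clustering_accuracy(np.array([], object), np.array([], object))


class TestPipelineClustering:
    def test_clean_phase_reversal_recovered_on_both_flavors(self, traces,
                                                            session):
        _, _, truth = session
        for flavor in ("zscored", "zscored_derivative"):
            res = spectral_cluster(traces[flavor], seed=0)
            res = assign_regions(res, traces[flavor], truth)
            assert res.k == 2
            assert res.accuracy_pct == 100.0

    def test_no_crossing_grid_yields_single_cluster(self):
        p = SimulationParams(seed=2, n_trials=30, cs_offset_mm=-5.0,
                             cs_angle_deg=0.0)
        recording, _, _ = simulate_session(p)
        out = preprocess_recording(recording)
        res = spectral_cluster(out["zscored_derivative"], seed=0)
        assert res.k == 1

    def test_repeated_runs_identical(self, traces):
        a = spectral_cluster(traces["zscored"], seed=4)
        b = spectral_cluster(traces["zscored"], seed=4)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_derivative_beats_raw_under_farfield_overlap(self):
        # a large spatially-uniform slow far-field swamps the raw traces
        # (raw clustering degenerates) but barely touches the derivative
        from sulcimap.cluster import _score_subset

        wins = 0
        for seed in range(3):
            p = SimulationParams(seed=seed, n_trials=30, shared_amp_uV=25.0)
            recording, _, truth = simulate_session(p)
            out = preprocess_recording(recording)
            accs = {}
            for flavor in ("zscored", "zscored_derivative"):
                res = spectral_cluster(out[flavor], seed=0)
                accs[flavor] = _score_subset(
                    res, truth.region_labels[res.channel_indices]
                )
            if accs["zscored_derivative"] >= accs["zscored"]:
                wins += 1
        assert wins == 3


class TestResampling:
    def test_subset_counts_on_8x4_grid(self, traces, session):
        _, geometry, truth = session
        per_subset, summary, skipped = resample_grids(
            geometry, traces["zscored_derivative"], truth, seed=0
        )
        counts = per_subset.groupby("grid_type").size()
        assert counts["1xN"] == 4 and counts["2xN"] == 3 and counts["large"] == 1
        assert not skipped
        assert set(summary.columns) == {"grid_type", "n_subsets", "mean_acc",
                                        "sd_acc"}

    def test_degenerate_small_grid_skips_short_strips(self):
        p = SimulationParams(seed=0, n_trials=2, grid_rows=2, grid_cols=2,
                             cs_offset_mm=2.5, noise_sd_uV=0.0,
                             latency_jitter_ms=0.0)
        recording, geometry, truth = simulate_session(p)
        out = preprocess_recording(recording, flag_corrupted=False)
        per_subset, _, skipped = resample_grids(
            geometry, out["zscored"], truth, seed=0
        )
        assert len(skipped) == 2      # both 1x2 strips too short
        assert set(per_subset.grid_type) == {"2xN", "large"}

    def test_one_row_grid_raises(self, traces):
        from sulcimap.geometry import make_grid_geometry
        from sulcimap.simulate import GroundTruth

        geom = make_grid_geometry(1, 8, 5.0, 16.5)
        truth = GroundTruth(region_labels=geom.region_labels,
                            cs_line=geom.cs_line,
                            corrupted_channels=np.array([], int),
                            true_latencies_ms={})
        with pytest.raises(ValueError):
            resample_grids(geom, traces["zscored"], truth)
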