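"""LEiDA stage: filtering, phases, coherence frames, leading eigenvectors,
pooling, validity indices against brute force, clustering and labeling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import adjusted_rand_score

import brainstates.leida as leida
from brainstates.synth import BoldTimeSeries
from oracles import brute_calinski_harabasz, brute_dunn, brute_silhouette

TR = 1.97


def _sine_ts(freq, t=261, dt=TR, n_regions=1):
    tt = np.arange(t) * dt
    data = np.tile(np.sin(2 * np.pi * freq * tt), (n_regions, 1))
    return BoldTimeSeries("s", data, dt)


class TestBandpass:
    def test_dc_removed(self):
        ts = BoldTimeSeries("s", np.ones((3, 261)), TR)
        out = leida.bandpass_filter(ts, 0.01, 0.1)
        assert np.abs(out.data).max() < 1e-6

    def test_passband_gain_near_unity(self):
        out = leida.bandpass_filter(_sine_ts(0.05), 0.01, 0.1)
        central = out.data[0, 65:196]
        assert np.abs(central).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated(self):
        out = leida.bandpass_filter(_sine_ts(0.2), 0.01, 0.1)
        assert np.abs(out.data[0, 65:196]).max() < 0.5

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            leida.bandpass_filter(_sine_ts(0.05), 0.01, 0.3)

    def test_short_series_rejected(self):
        ts = BoldTimeSeries("s", np.random.default_rng(0).normal(size=(2, 10)), TR)
        with pytest.raises(ValueError, match="too short"):
            leida.bandpass_filter(ts, 0.01, 0.1)


class TestInstantaneousPhase:
    def test_cosine_phase_slope(self):
        tt = np.arange(261) * TR
        data = np.cos(2 * np.pi * 0.05 * tt)[None, :]
        phases = np.unwrap(leida.instantaneous_phase(data))
        slope = np.polyfit(tt[65:196], phases[0, 65:196], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 0.05, rel=0.01)

    def test_identical_channels_zero_phase_difference(self):
        tt = np.arange(200) * TR
        row = np.cos(2 * np.pi * 0.04 * tt)
        phases = leida.instantaneous_phase(np.vstack([row, row]))
        assert np.abs(phases[0] - phases[1]).max() < 1e-12

    def test_quarter_period_delay_is_half_pi(self):
        f = 0.05
        tt = np.arange(261) * TR
        delay = 1.0 / (4 * f)
        data = np.vstack([np.cos(2 * np.pi * f * tt),
                          np.cos(2 * np.pi * f * (tt - delay))])
        phases = np.unwrap(leida.instantaneous_phase(data), axis=1)
        diff = (phases[0] - phases[1])[65:196]
        assert np.abs(diff - np.pi / 2).max() < 0.05

    def test_zero_channel_rejected(self):
        data = np.zeros((2, 50))
        data[0] = np.sin(np.arange(50))
        with pytest.raises(ValueError, match="all-zero"):
            leida.instantaneous_phase(data)


class TestPhaseCoherence:
    @pytest.mark.parametrize("theta, expected", [
        ((0.0, 0.0, 0.0), np.ones((3, 3))),
        ((0.0, np.pi), np.array([[1.0, -1.0], [-1.0, 1.0]])),
    ])
    def test_exact_frames(self, theta, expected):
        assert np.allclose(leida.phase_coherence_matrix(theta), expected, atol=1e-12)

    def test_mixed_angles(self):
        m = leida.phase_coherence_matrix((0.0, np.pi / 3, np.pi / 2))
        assert m[0, 1] == pytest.approx(0.5)
        assert m[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert m[1, 2] == pytest.approx(np.cos(np.pi / 6))

    @given(arrays(float, st.integers(2, 8),
                  elements=st.floats(-np.pi, np.pi)))
    @settings(max_examples=50, deadline=None)
    def test_frame_invariants(self, theta):
        m = leida.phase_coherence_matrix(theta)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert (np.abs(m) <= 1 + 1e-12).all()


class TestLeadingEigenvector:
    def test_all_ones_matrix(self):
        v = leida.leading_eigenvector(np.ones((4, 4)))
        assert np.allclose(v, [-0.5, -0.5, -0.5, -0.5])

    def test_zero_mean_tie_break(self):
        frame = leida.phase_coherence_matrix((0.0, 0.0, np.pi, np.pi))
        v = leida.leading_eigenvector(frame)
        assert np.allclose(v, [-0.5, -0.5, 0.5, 0.5])

    @given(arrays(float, (6, 6), elements=st.floats(-1, 1)))
    @settings(max_examples=50, deadline=None)
    def test_unit_norm_and_sign_convention(self, a):
        frame = (a + a.T) / 2
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = leida.leading_eigenvector(frame)
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-10)
        assert v.mean() <= 1e-12

    def test_degenerate_top_eigenvalue_warns(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            leida.leading_eigenvector(np.eye(3))


class TestPooling:
    def test_study_scale_count_with_edges_kept(self):
        # 197 subjects x 261 timepoints pooled without edge discard
        cohort = {f"s{i}": np.zeros((261, 4)) for i in range(197)}
        pooled, _ = leida.pool_eigenvectors(cohort, keep_edges=True)
        assert pooled.shape[0] == 51_417

    def test_single_subject_counts(self):
        pooled, _ = leida.pool_eigenvectors({"a": np.zeros((10, 3))}, keep_edges=True)
        assert pooled.shape[0] == 10
        pooled, _ = leida.pool_eigenvectors({"a": np.zeros((10, 3))})
        assert pooled.shape[0] == 8  # first/last frame discarded

    def test_label_round_trip(self, rng):
        cohort = {f"s{i}": rng.normal(size=(20 + i, 3)) for i in range(4)}
        pooled, index = leida.pool_eigenvectors(cohort)
        labels = rng.integers(1, 4, size=pooled.shape[0])
        per_subject = leida.unpool_labels(labels, index)
        assert [len(v) for v in per_subject.values()] == [18 + i for i in range(4)]
        assert np.concatenate(list(per_subject.values())).tolist() == labels.tolist()

    def test_inconsistent_regions_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            leida.pool_eigenvectors({"a": np.zeros((5, 3)), "b": np.zeros((5, 4))})


class TestClusterValidity:
    def test_dunn_hand_computed(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        assert leida.dunn_index(pts, labels) == pytest.approx(99.0)

    def test_silhouette_hand_computed(self):
        from sklearn.metrics import silhouette_samples
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        # point 0: a = 0.1, b = (10 + 10.1)/2 = 10.05 -> (b - a)/b
        s0 = silhouette_samples(pts, labels)[0]
        assert s0 == pytest.approx((10.05 - 0.1) / 10.05, abs=1e-10)

    def test_wrong_split_scores_lower(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        good = leida.cluster_validity(pts, np.array([0, 0, 1, 1]))[1]
        bad = leida.cluster_validity(pts, np.array([0, 1, 0, 1]))[1]
        assert bad < good

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 50))
            k = int(rng.integers(2, 5))
            pts = rng.normal(size=(n, 3))
            labels = rng.integers(0, k, size=n)
            if np.unique(labels).size < 2:
                continue
            dunn, sil, ch = leida.cluster_validity(pts, labels)
            assert dunn == pytest.approx(brute_dunn(pts, labels), rel=1e-12)
            assert ch == pytest.approx(brute_calinski_harabasz(pts, labels), rel=1e-10)
            assert sil == pytest.approx(brute_silhouette(pts, labels), abs=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            leida.cluster_validity(np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_zero_diameter_clusters_finite_dunn(self):
        pts = np.array([[0.0], [0.0], [1.0], [1.0]])
        d = leida.dunn_index(pts, np.array([0, 0, 1, 1]))
        assert np.isfinite(d) and d > 0


class TestLeidaStates:
    def test_orthogonal_patterns_exact_recovery(self, rng):
        centers = np.eye(3)
        labels_true = rng.integers(0, 3, size=90)
        x = centers[labels_true]
        model = leida.LeidaStates(k_range=(3, 3), n_restarts=5, random_state=0).fit(x)
        assert adjusted_rand_score(labels_true, model.labels_) == 1.0

    def test_chosen_k_on_three_separated_clusters(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10]], dtype=float)
        x = np.vstack([c + 0.2 * rng.normal(size=(30, 2)) for c in centers])
        model = leida.LeidaStates(k_range=(2, 6), n_restarts=10, random_state=0).fit(x)
        assert model.chosen_k_ == 3

    def test_same_seed_identical_model(self, rng):
        x = rng.normal(size=(80, 5))
        a = leida.LeidaStates(k_range=(2, 4), n_restarts=5, random_state=1).fit(x)
        b = leida.LeidaStates(k_range=(2, 4), n_restarts=5, random_state=1).fit(x)
        assert a.chosen_k_ == b.chosen_k_
        assert (a.labels_ == b.labels_).all()
        assert np.array_equal(a.centroids_raw_, b.centroids_raw_)

    def test_states_ordered_by_occupancy(self, rng):
        x = np.vstack([np.tile([0.0, 0.0], (60, 1)), np.tile([5.0, 5.0], (20, 1))])
        x += 0.01 * rng.normal(size=x.shape)
        model = leida.LeidaStates(k_range=(2, 2), n_restarts=3, random_state=0).fit(x)
        counts = np.bincount(model.labels_)[1:]
        assert (np.diff(counts) <= 0).all()

    def test_sklearn_get_set_params_round_trip(self):
        model = leida.LeidaStates(k_range=(2, 5), n_restarts=7)
        params = model.get_params()
        clone = leida.LeidaStates(**params)
        assert clone.get_params() == params


class TestLabelAndAssign:
    def test_positive_community_names_state(self):
        networks = ["FPN"] * 3 + ["DMN"] * 3
        centroid = np.array([0.4, 0.4, 0.4, -0.3, -0.3, -0.3])
        assert leida.label_states(centroid, networks) == ["FPN"]

    def test_all_negative_is_global_coherence(self):
        assert leida.label_states(-np.ones(4), ["A"] * 4) == ["Global Coherence"]

    def test_overlap_count_wins(self):
        networks = ["Visual"] * 3 + ["DMN"] * 3
        centroid = np.array([0.3, 0.3, 0.3, 0.3, -0.5, -0.5])
        assert leida.label_states(centroid, networks) == ["Visual"]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            leida.label_states(np.ones(0), [])

    def test_assign_exact_centroid(self):
        centroids = np.eye(4)
        assert leida.assign_states(centroids[2], centroids)[0] == 3

    def test_assign_tie_goes_to_lowest_index(self):
        centroids = np.array([[0.0, 1.0], [0.0, -1.0]])
        assert leida.assign_states(np.array([0.0, 0.0]), centroids)[0] == 1

    def test_noiseless_planted_sequence_recovered(self):
        import brainstates as bs
        patterns = bs.generate_state_patterns(24, 3, seed=8)
        seq = bs.generate_state_sequence(bs.default_markov(3, 0.95), 80, seed=2)
        ts = bs.generate_bold(seq, patterns, noise_sd=0.0, seed=0)
        vecs = leida.leading_eigenvectors(leida.instantaneous_phase(ts))
        recovered = leida.assign_states(vecs, patterns)
        switch = np.flatnonzero(np.diff(seq) != 0) + 1
        safe = [t for t in range(3, 77)
                if not (switch.size and np.abs(switch - t).min() < 3)]
        assert (recovered[safe] == seq[safe]).all()


class TestFullRecovery:
    def test_planted_cohort_recovered(self, small_cohort, recovered_model):
        pooled, index, model = recovered_model
        assert model.chosen_k_ == 3
        per_subject = leida.unpool_labels(model.labels_, index)
        rec = np.concatenate(list(per_subject.values()))
        planted = np.concatenate([small_cohort.state_sequences[sid][1:-1]
                                  for sid in per_subject])
        assert adjusted_rand_score(planted, rec) >= 0.9
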