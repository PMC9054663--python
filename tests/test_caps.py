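import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trinet import caps, synthetic
from trinet.core_io import MotionTrace, TimeSeriesVolume
from trinet.errors import CapacityError, UndefinedEffectError, ValidationError


def _run_from_series(series_by_voxel, n_extra_voxels=0):
    """Build a tiny 1-voxel-per-seed run from explicit time series."""
    series = np.asarray(series_by_voxel, dtype=float)
    n_vox, t = series.shape
    frames = np.zeros((n_vox + n_extra_voxels, 1, 1, t))
    frames[:n_vox, 0, 0, :] = series
    return TimeSeriesVolume(frames, tr_seconds=1.0)


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        trace = MotionTrace(np.zeros((5, 3)), np.zeros((5, 3)))
        np.testing.assert_allclose(caps.framewise_displacement(trace, 50.0), 0.0)

    def test_single_translation_step(self):
        tr = np.zeros((4, 3))
        tr[2:, 0] = 0.1
        fd = caps.framewise_displacement(MotionTrace(tr, np.zeros((4, 3))), 50.0)
        np.testing.assert_allclose(fd, [0.0, 0.0, 0.1, 0.0])

    def test_rotation_arc_length(self):
        # 0.01 rad step on each axis with a 5 mm lever arm: 3 * 5 * 0.01 = 0.15
        rot = np.zeros((3, 3))
        rot[1:, :] = 0.01
        fd = caps.framewise_displacement(MotionTrace(np.zeros((3, 3)), rot), 5.0)
        np.testing.assert_allclose(fd, [0.0, 0.15, 0.0])

    def test_first_frame_defined_zero_and_nonnegative(self, rng):
        trace = MotionTrace(rng.standard_normal((20, 3)), rng.standard_normal((20, 3)) * 0.01)
        fd = caps.framewise_displacement(trace, 25.0)
        assert fd[0] == 0.0 and (fd >= 0).all()

    def test_too_short_trace(self):
        with pytest.raises(ValidationError):
            caps.framewise_displacement(MotionTrace(np.zeros((1, 3)), np.zeros((1, 3))), 5.0)


class TestSelectFrames:
    def test_positive_z_frames_retained(self):
        ts = _run_from_series([[1.2, -0.3, 0.8]])
        mask = np.zeros((1, 1, 1), dtype=bool)
        mask[0] = True
        sel = caps.select_frames(ts, [mask], seed_threshold_z=0.0)
        # z-scoring preserves the sign pattern around the series mean
        assert list(sel.retained_indices) == [0, 2]
        assert sel.reason_codes == {1: "seed-fail"}

    def test_all_motion_rejected(self):
        # two anti-phase seeds guarantee the seed criterion passes every frame
        ts = _run_from_series([[1, -1, 1, -1], [-1, 1, -1, 1]])
        masks = [np.array([[[True]], [[False]]]), np.array([[[False]], [[True]]])]
        sel = caps.select_frames(ts, masks, 0.0, fd_mm=np.full(4, 9.0),
                                 fd_threshold_mm=0.2)
        assert sel.retained.sum() == 0
        assert set(sel.reason_codes.values()) == {"fd-fail"}

    def test_reasons_partition_rejections(self, rng):
        ts = _run_from_series(rng.standard_normal((2, 50)))
        masks = [np.array([[[True]], [[False]]]), np.array([[[False]], [[True]]])]
        fd = rng.uniform(0, 0.4, 50)
        sel = caps.select_frames(ts, masks, 0.0, fd_mm=fd, fd_threshold_mm=0.2)
        assert set(sel.reason_codes) == set(np.flatnonzero(~sel.retained))

    def test_retention_matches_union_probability(self):
        # three independent noise seeds at theta=0: P(retain) = 1 - 0.5^3
        rng = np.random.default_rng(5)
        ts = _run_from_series(rng.standard_normal((3, 10_000)))
        masks = []
        for i in range(3):
            m = np.zeros((3, 1, 1), dtype=bool)
            m[i] = True
            masks.append(m)
        sel = caps.select_frames(ts, masks, 0.0)
        assert sel.retention_fraction == pytest.approx(0.875, abs=0.02)

    def test_empty_seed_mask_rejected(self):
        ts = _run_from_series([[1.0, 2.0, 3.0]])
        with pytest.raises(ValidationError):
            caps.select_frames(ts, [np.zeros((1, 1, 1), dtype=bool)], 0.0)

    def test_selection_matches_brute_force(self, rng):
        for _ in range(10):
            series = rng.standard_normal((2, 40))
            fd = rng.uniform(0, 0.4, 40)
            theta = rng.uniform(-0.5, 0.5)
            ts = _run_from_series(series)
            masks = [np.array([[[True]], [[False]]]), np.array([[[False]], [[True]]])]
            sel = caps.select_frames(ts, masks, theta, fd_mm=fd, fd_threshold_mm=0.2)
            z = (series - series.mean(axis=1, keepdims=True)) / series.std(axis=1, keepdims=True)
            expected = [t for t in range(40) if z[:, t].max() > theta and fd[t] < 0.2]
            assert list(sel.retained_indices) == expected


class TestFitCaps:
    def test_recovers_exact_orthogonal_patterns(self):
        patterns = np.eye(6)
        frames = np.repeat(patterns, 30, axis=0)
        model = caps.fit_caps(frames, K=6, seed=0)
        perm, corrs = caps.match_states(model.centroids, patterns)
        assert sorted(perm) == list(range(6))
        np.testing.assert_allclose(corrs, 1.0, atol=1e-12)

    def test_k1_centroid_is_grand_mean(self, rng):
        frames = rng.standard_normal((40, 10))
        model = caps.fit_caps(frames, K=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], frames.mean(axis=0), atol=1e-12)

    def test_fewer_frames_than_clusters(self, rng):
        with pytest.raises(CapacityError):
            caps.fit_caps(rng.standard_normal((3, 5)), K=4)

    def test_centroid_membership_consistency(self, rng):
        frames = rng.standard_normal((100, 8))
        model = caps.fit_caps(frames, K=4, seed=1)
        for k in range(4):
            members = frames[model.assignments == k]
            np.testing.assert_allclose(model.centroids[k], members.mean(axis=0), atol=1e-6)

    def test_deterministic_given_seed(self, rng):
        frames = rng.standard_normal((60, 6))
        a = caps.fit_caps(frames, K=3, seed=5)
        b = caps.fit_caps(frames, K=3, seed=5)
        np.testing.assert_array_equal(a.assignments, b.assignments)


class TestPacSelection:
    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_identical_frames_have_zero_pac(self):
        frames = np.ones((60, 5))
        curve = caps.pac_model_selection(frames, [2, 3], n_subsamples=5, seed=0)
        assert curve.pac[2] == 0.0 and curve.pac[3] == 0.0

    def test_two_blobs_prefer_k2(self, rng):
        blob_a = rng.standard_normal((80, 6)) * 0.05 + 5
        blob_b = rng.standard_normal((80, 6)) * 0.05 - 5
        frames = np.vstack([blob_a, blob_b])
        curve = caps.pac_model_selection(frames, [2, 4], n_subsamples=10, seed=0)
        assert curve.pac[2] < 0.01
        assert curve.pac[2] < curve.pac[4]
        assert curve.best_k == 2

    def test_pac_invariant_to_frame_order(self, rng):
        blob_a = rng.standard_normal((40, 4)) * 0.05 + 3
        blob_b = rng.standard_normal((40, 4)) * 0.05 - 3
        frames = np.vstack([blob_a, blob_b])
        shuffled = frames[rng.permutation(80)]
        a = caps.pac_model_selection(frames, [2], n_subsamples=8, seed=1)
        b = caps.pac_model_selection(shuffled, [2], n_subsamples=8, seed=1)
        assert a.pac[2] == pytest.approx(b.pac[2], abs=1e-12)

    def test_pac_values_in_unit_interval(self, rng):
        frames = rng.standard_normal((50, 4))
        curve = caps.pac_model_selection(frames, [2, 3, 4], n_subsamples=4, seed=2)
        assert all(0.0 <= v <= 1.0 for v in curve.pac.values())

    def test_too_few_subsamples(self, rng):
        with pytest.raises(ValidationError):
            caps.pac_model_selection(rng.standard_normal((20, 3)), [2], n_subsamples=1)


def _info(times, run=0):
    return pd.DataFrame({"run": run, "time": np.asarray(times)})


class TestTransitionStats:
    def test_hand_enumeration(self):
        labels = np.array([0, 0, 1, 1, 0])  # states 1,1,2,2,1
        tm = caps.transition_stats(labels, _info(range(5)), K=2)
        np.testing.assert_array_equal(tm.counts, [[1, 1], [1, 1]])
        np.testing.assert_allclose(tm.probabilities, [[0.5, 0.5], [0.5, 0.5]])
        np.testing.assert_array_equal(tm.entries, [2, 1])

    def test_constant_labels_one_entry(self):
        labels = np.zeros(8, dtype=int)
        tm = caps.transition_stats(labels, _info(range(8)), K=2)
        np.testing.assert_allclose(tm.probabilities[0], [1.0, 0.0])
        assert tm.counts[0, 0] == 7
        np.testing.assert_array_equal(tm.entries, [1, 0])

    def test_scrubbed_gaps_not_counted(self):
        labels = np.array([0, 1, 1, 0])
        tm = caps.transition_stats(labels, _info([1, 2, 5, 6]), K=2)
        # only the adjacent pairs (1,2) and (5,6) count
        assert tm.counts.sum() == 2
        np.testing.assert_array_equal(tm.counts, [[0, 1], [1, 0]])
        np.testing.assert_array_equal(tm.entries, [2, 2])

    def test_across_gaps_flag_restores_pooled_counting(self):
        labels = np.array([0, 1, 1, 0])
        tm = caps.transition_stats(labels, _info([1, 2, 5, 6]), K=2,
                                   count_across_gaps=True)
        assert tm.counts.sum() == 3

    def test_matches_brute_force_pair_scan(self, rng):
        labels = rng.integers(0, 3, 60)
        times = np.sort(rng.choice(120, size=60, replace=False))
        tm = caps.transition_stats(labels, _info(times), K=3)
        expected = np.zeros((3, 3), dtype=int)
        for i in range(59):
            if times[i + 1] == times[i] + 1:
                expected[labels[i], labels[i + 1]] += 1
        np.testing.assert_array_equal(tm.counts, expected)

    def test_runs_are_independent(self):
        labels = np.array([0, 0, 1, 1])
        info = pd.DataFrame({"run": [0, 0, 1, 1], "time": [0, 1, 0, 1]})
        tm = caps.transition_stats(labels, info, K=2)
        # no cross-run pair: only (0,0) and (1,1) transitions
        np.testing.assert_array_equal(tm.counts, [[1, 0], [0, 1]])
        np.testing.assert_array_equal(tm.entries, [1, 1])

    def test_rows_with_counts_are_stochastic_and_entries_bounded(self, rng):
        labels = rng.integers(0, 4, 200)
        tm = caps.transition_stats(labels, _info(range(200)), K=4)
        sums = tm.probabilities.sum(axis=1)
        np.testing.assert_allclose(sums[tm.counts.sum(axis=1) > 0], 1.0, atol=1e-12)
        member_counts = np.bincount(labels, minlength=4)
        assert (tm.entries <= member_counts).all()


class TestMatchStates:
    def test_recovers_shuffle_exactly(self, rng):
        maps_a = rng.standard_normal((5, 30))
        shuffle = rng.permutation(5)
        maps_b = maps_a[shuffle]
        perm, corrs = caps.match_states(maps_a, maps_b)
        # maps_b[perm[i]] must be state i again
        np.testing.assert_array_equal(shuffle[perm], np.arange(5))
        np.testing.assert_allclose(corrs, 1.0, atol=1e-12)

    def test_single_state_identity(self, rng):
        maps = rng.standard_normal((1, 10))
        perm, corrs = caps.match_states(maps, maps)
        assert list(perm) == [0] and corrs[0] == pytest.approx(1.0)

    def test_noise_preserves_the_permutation(self, rng):
        maps_a = rng.standard_normal((6, 50))
        shuffle = rng.permutation(6)
        noisy_b = maps_a[shuffle] + rng.normal(scale=0.1, size=(6, 50))
        perm_clean, _ = caps.match_states(maps_a, maps_a[shuffle])
        perm_noisy, _ = caps.match_states(maps_a, noisy_b)
        np.testing.assert_array_equal(perm_clean, perm_noisy)

    def test_unequal_k_rejected(self, rng):
        with pytest.raises(ValidationError):
            caps.match_states(rng.standard_normal((3, 10)), rng.standard_normal((4, 10)))


class TestCompareTransitions:
    def _tm(self, probs):
        probs = np.asarray(probs, dtype=float)
        counts = np.rint(probs * 100).astype(int)
        return caps.TransitionMatrix(counts=counts, probabilities=probs,
                                     entries=np.zeros(len(probs), dtype=int))

    def test_identical_matrices_coefficient_one(self):
        probs = synthetic.random_transition_matrix(4, seed=3)
        est = caps.compare_transitions(self._tm(probs), self._tm(probs))
        assert est.estimate == pytest.approx(1.0, abs=1e-10)

    def test_independent_matrices_coefficient_near_zero(self):
        coefs = []
        for seed in range(40):
            a = synthetic.random_transition_matrix(5, seed=2 * seed, persistence=0.0)
            b = synthetic.random_transition_matrix(5, seed=2 * seed + 1, persistence=0.0)
            coefs.append(caps.compare_transitions(self._tm(a), self._tm(b)).estimate)
        assert abs(np.mean(coefs)) < 0.1

    def test_degenerate_vector_rejected(self):
        flat = np.full((3, 3), 1 / 3)
        probs = synthetic.random_transition_matrix(3, seed=1)
        with pytest.raises(UndefinedEffectError):
            caps.compare_transitions(self._tm(flat), self._tm(probs))


class TestStackRetainedFrames:
    def test_bookkeeping_tracks_run_and_time(self, mini_dataset):
        atlas, gt, runs = mini_dataset
        masks = [atlas.labels == r for r in (1, 2, 3)]
        sels = [caps.select_frames(r, masks, 0.0,
                                   fd_mm=caps.framewise_displacement(r.motion, 5.0),
                                   fd_threshold_mm=0.2) for r in runs]
        x, info = caps.stack_retained_frames(runs, sels)
        assert x.shape[0] == len(info) == sum(s.retained.sum() for s in sels)
        assert x.shape[1] == int(runs[0].mask.sum())
        first = info[info.run == 0]
        np.testing.assert_array_equal(first["time"], sels[0].retained_indices)
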