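import numpy as np
import pytest

from serialdep import decoding as dec
from serialdep import synthetic as syn
from serialdep.circular import relative_orientation
from serialdep.io_core import AnalysisConfig, ConfigError, EpochsSet

from conftest import make_epochs


def _epochs_from_array(data, sfreq=10.0, t0=0.0, lock="probe"):
    n_trials, n_sensors, n_times = data.shape
    return EpochsSet(
        data=data,
        times=t0 + np.arange(n_times) / sfreq,
        sfreq=sfreq,
        sensor_ids=[f"S{i}" for i in range(n_sensors)],
        sensor_pos=np.column_stack([np.arange(n_sensors), np.zeros(n_sensors)]),
        lock_event=lock,
        trial_ids=np.arange(n_trials),
    )


class TestPreprocess:
    def test_remove_cross_trial_mean(self, rng):
        ep = _epochs_from_array(rng.standard_normal((7, 3, 12)))
        out = dec.preprocess_epochs(ep, ["remove_cross_trial_mean"])
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-6)

    def test_unit_variance(self, rng):
        ep = _epochs_from_array(rng.standard_normal((9, 3, 12)))
        out = dec.preprocess_epochs(ep, ["unit_variance"])
        np.testing.assert_allclose(out.data.std(axis=0), 1.0, atol=1e-5)

    def test_gaussian_smooth_preserves_constant(self, rng):
        ep = _epochs_from_array(np.full((4, 2, 30), 2.5, dtype=np.float32), sfreq=250.0)
        out = dec.preprocess_epochs(ep, [("gaussian_smooth", 8.0)])
        np.testing.assert_allclose(out.data, 2.5, atol=1e-5)

    def test_baseline_regress_closed_form(self, rng):
        # each trial is a per-trial constant offset of a common template:
        # regressing the baseline mean out across trials removes the offsets
        template = rng.standard_normal((1, 4, 20))
        offsets = rng.standard_normal((12, 1, 1)) * 3.0
        ep = _epochs_from_array((template + offsets).astype(np.float32), sfreq=10.0)
        out = dec.preprocess_epochs(ep, [("baseline_regress", (0.0, 0.5))])
        base = out.data[:, :, :5].mean(axis=2)
        np.testing.assert_allclose(base, 0.0, atol=1e-4)
        # and the residuals no longer depend on the offset (trial-invariant)
        np.testing.assert_allclose(
            out.data - out.data.mean(axis=0, keepdims=True), 0.0, atol=1e-4
        )

    def test_baseline_window_outside_epoch(self, rng):
        ep = _epochs_from_array(rng.standard_normal((5, 2, 10)))
        with pytest.raises(ConfigError):
            dec.preprocess_epochs(ep, [("baseline_regress", (-2.0, -1.0))])


class TestFeatures:
    def test_published_dimensionality(self):
        # 306 sensors x 37-sample window -> 11,322 features
        ep = _epochs_from_array(np.zeros((3, 306, 40), dtype=np.float32), sfreq=250.0)
        F = dec.build_features(ep, t_index=39, window_samples=37)
        assert F.shape == (3, 11322)

    def test_small_arithmetic_and_identity(self, rng):
        ep = _epochs_from_array(rng.standard_normal((5, 4, 10)))
        assert dec.build_features(ep, 5, 3).shape == (5, 12)
        F1 = dec.build_features(ep, 6, 1)
        np.testing.assert_array_equal(F1, ep.data[:, :, 6].astype(float))

    def test_truncated_window_rejected(self, rng):
        ep = _epochs_from_array(rng.standard_normal((5, 4, 10)))
        with pytest.raises(ConfigError):
            dec.build_features(ep, 1, 3)


class TestPCA:
    def test_rank_one_keeps_one_component(self, rng):
        v = rng.standard_normal(20)
        X = np.outer(rng.standard_normal(30), v)
        Z, red = dec.reduce_dimensionality(X, 0.9)
        assert red.k == 1
        assert Z.shape == (30, 1)

    def test_white_noise_keeps_about_90_percent(self, rng):
        X = rng.standard_normal((3000, 50))
        _, red = dec.reduce_dimensionality(X, 0.9)
        assert 0.8 * 50 <= red.k <= 50  # within 10% of 0.9 * n_features

    def test_variance_one_keeps_full_rank(self, rng):
        X = rng.standard_normal((40, 10))
        _, red = dec.reduce_dimensionality(X, 1.0)
        assert red.k == 10

    def test_transform_reusable_on_heldout_rows(self, rng):
        X = rng.standard_normal((30, 8))
        Z, red = dec.reduce_dimensionality(X, 0.9)
        np.testing.assert_allclose(red.transform(X[:5]), Z[:5], atol=1e-10)


class TestMahalanobis:
    def test_euclidean_reduction(self):
        assert dec.mahalanobis_distance([0, 0], [3, 4], np.eye(2)) == pytest.approx(5.0)

    def test_diagonal_closed_form(self):
        assert dec.mahalanobis_distance([2, 0], [0, 0], np.diag([4.0, 1.0])) == pytest.approx(1.0)

    def test_matches_independent_quadratic_form(self, rng):
        from scipy.spatial.distance import mahalanobis as scipy_maha

        for _ in range(50):
            p = rng.integers(2, 6)
            A = rng.standard_normal((p + 3, p))
            cov = A.T @ A / (p + 3)
            x, y = rng.standard_normal(p), rng.standard_normal(p)
            expected = scipy_maha(x, y, np.linalg.inv(cov))
            assert dec.mahalanobis_distance(x, y, cov) == pytest.approx(expected, abs=1e-10)


class TestShrinkageCovariance:
    def test_matches_sklearn_ledoit_wolf(self, rng):
        from sklearn.covariance import ledoit_wolf

        R = rng.standard_normal((80, 6))
        R -= R.mean(axis=0)  # centered residuals
        ours = dec.shrinkage_covariance(R)
        theirs, _ = ledoit_wolf(R, assume_centered=True)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestTuningCurves:
    def test_curve_sums_to_zero(self, rng):
        X = rng.standard_normal((40, 6))
        ori = rng.uniform(0, 180, 40)
        curves = dec.tuning_curves_loo_all(X, ori, "shrinkage")
        sums = np.nansum(curves, axis=1)[~np.isnan(curves[:, 0])]
        np.testing.assert_allclose(sums, 0.0, atol=1e-10)

    def test_nearest_bin_wins_with_identity_cov(self):
        # test pattern equals one bin's mean and is far from all others
        rng = np.random.default_rng(3)
        ori = np.arange(20) * 9.0  # evenly spaced: every bin populated
        X = rng.standard_normal((20, 5)) * 10
        i = 0
        curve = dec.tuning_curve_loo(X.copy(), ori, i, cov_estimator="identity")
        rel = relative_orientation(ori, ori[i])
        bins = dec._bin_index(np.asarray(rel))
        # place the test pattern exactly on the mean of bin 7's training trials
        members = [j for j in range(20) if j != i and bins[j] == 7]
        X[i] = X[members].mean(axis=0)
        curve = dec.tuning_curve_loo(X, ori, i, cov_estimator="identity")
        assert np.argmax(curve.similarities) == 7

    def test_identity_cov_equals_euclidean_oracle(self):
        # hand-rolled nearest-bin-mean oracle, 20-trial toy set
        rng = np.random.default_rng(17)
        ori = (np.arange(20) * 9.0 + 4.0) % 180.0
        X = rng.standard_normal((20, 4))
        curves = dec.tuning_curves_loo_all(X, ori, "identity")
        for i in range(20):
            d = np.zeros(10)
            for b in range(10):
                members = [
                    j
                    for j in range(20)
                    if j != i
                    and dec._bin_index(
                        np.asarray([relative_orientation(ori[j], ori[i])])
                    )[0]
                    == b
                ]
                mean_pattern = X[members].mean(axis=0)
                d[b] = np.sqrt(np.sum((X[i] - mean_pattern) ** 2))
            oracle = -(d - d.mean())
            np.testing.assert_allclose(curves[i], oracle, atol=1e-8)

    def test_fast_path_matches_reference(self, rng):
        X = rng.standard_normal((50, 8))
        ori = rng.uniform(0, 180, 50)
        for cov in ("shrinkage", "identity"):
            fast = dec.tuning_curves_loo_all(X, ori, cov, use_fast=True)
            ref = dec.tuning_curves_loo_all(X, ori, cov, use_fast=False)
            np.testing.assert_allclose(fast, ref, atol=1e-10, equal_nan=True)

    def test_empty_bin_marks_curve_missing(self, rng):
        ori = np.array([5.0] * 10 + [100.0])  # only two distinct orientations
        X = rng.standard_normal((11, 3))
        curves = dec.tuning_curves_loo_all(X, ori, "identity")
        assert np.isnan(curves).all()


class TestDecodingEvidence:
    def test_flat_curve_gives_zero(self):
        assert dec.decoding_evidence(np.full(10, 3.7)) == pytest.approx(0.0, abs=1e-12)

    def test_cosine_tuned_curve(self):
        centers = np.linspace(-90, 90, 11)[:-1] + 9.0
        sims = np.cos(2 * np.deg2rad(centers))
        # direct summation over the 10 bin centers: mean(cos^2) = 0.5
        assert dec.decoding_evidence(sims) == pytest.approx(0.5, abs=1e-12)
        anti = np.cos(2 * np.deg2rad(centers - 90.0))
        assert dec.decoding_evidence(anti) == pytest.approx(-0.5, abs=1e-12)

    def test_invariant_to_constant_offset(self, rng):
        sims = rng.standard_normal(10)
        a = dec.decoding_evidence(sims)
        b = dec.decoding_evidence(sims + 11.3)
        assert a == pytest.approx(b, abs=1e-10)


class TestDecodeTimecourse:
    def test_signal_window_recovered(self, meg_trials, fast_config):
        sub = meg_trials[meg_trials.participant_id == "sub00"]
        ep = make_epochs(sub, seed=70)
        res = dec.decode_timecourse(ep, sub, "target", fast_config)
        inside = (res.times > -1.0) & (res.times < 0.0)
        outside = res.times < -1.25  # before the signal window
        assert res.values[inside].mean() > 0.3
        assert abs(res.values[outside].mean()) < 0.15

    def test_shuffled_labels_destroy_evidence(self, meg_trials, fast_config, rng):
        sub = meg_trials[meg_trials.participant_id == "sub00"].copy()
        ep = make_epochs(sub, seed=71)
        sub["target_orientation"] = rng.permutation(
            sub["target_orientation"].to_numpy()
        )
        sub["signed_error"] = np.nan
        sub["report_orientation"] = np.nan
        res = dec.decode_timecourse(ep, sub, "target", fast_config)
        assert abs(np.nanmean(res.values)) < 0.15

    def test_previous_target_not_decodable_without_carryover(
        self, meg_trials, fast_config
    ):
        # epochs tuned to the current target only: previous-target evidence ~ 0
        sub = meg_trials[meg_trials.participant_id == "sub01"]
        ep = make_epochs(sub, seed=72)
        res = dec.decode_timecourse(ep, sub, "previous_target", fast_config)
        assert abs(np.nanmean(res.values)) < 0.15
        # first-in-block trials were excluded
        assert len(res.trial_ids) == (~sub.first_in_block).sum()


class TestResponseLock:
    def _probe_epochs(self, trials, n_times=60, sfreq=10.0):
        rngl = np.random.default_rng(0)
        return _epochs_from_array(
            rngl.standard_normal((len(trials), 2, n_times)), sfreq=sfreq, t0=0.0
        )

    def test_rt_bounds_filtering(self, meg_trials):
        sub = meg_trials[meg_trials.participant_id == "sub00"].iloc[:10].copy()
        sub["rt"] = [2.0, 2.5, 0.5, 3.0, 12.0, 2.2, 2.9, 3.3, 2.1, 2.7]
        sub["trial_id"] = np.arange(10)
        ep = self._probe_epochs(sub)
        out = dec.response_lock(ep, sub, rt_bounds=(0.65, 11.85), span=(-2.0, 0.0))
        assert out.n_trials == 8  # rt=0.5 (too short) and rt=12 (too long) removed
        assert 2 not in out.trial_ids and 4 not in out.trial_ids
        assert out.lock_event == "response"

    def test_window_maps_to_original_samples(self, meg_trials):
        sub = meg_trials[meg_trials.participant_id == "sub00"].iloc[:1].copy()
        sub["rt"] = 2.0
        sub["trial_id"] = [0]
        ep = self._probe_epochs(sub)
        out = dec.response_lock(ep, sub, span=(-2.0, 0.0))
        # rt=2 s, span (-2, 0): covers 0..2 s of the probe-locked epoch
        np.testing.assert_array_equal(out.data[0], ep.data[0, :, 0:20])
        np.testing.assert_allclose(out.times[0], -2.0)

    def test_missing_rt_excluded(self, meg_trials):
        sub = meg_trials[meg_trials.participant_id == "sub00"].iloc[:3].copy()
        sub["rt"] = [2.0, np.nan, 2.5]
        sub["trial_id"] = np.arange(3)
        ep = self._probe_epochs(sub)
        out = dec.response_lock(ep, sub, span=(-1.0, 0.0))
        assert out.n_trials == 2


class TestSearchlight:
    def test_neighborhoods_and_limits(self, rng):
        pos = np.array([[0, 0], [1, 0], [2, 0], [5, 0]], dtype=float)
        nb = dec.sensor_neighborhoods(pos, 2)
        np.testing.assert_array_equal(nb[0], [0, 1])
        np.testing.assert_array_equal(nb[3], [3, 2])
        np.testing.assert_array_equal(dec.sensor_neighborhoods(pos, 1)[:, 0], np.arange(4))
        with pytest.raises(ConfigError):
            dec.sensor_neighborhoods(pos, 5)

    def test_k_equals_n_matches_whole_array(self, meg_trials, fast_config):
        sub = meg_trials[meg_trials.participant_id == "sub00"].iloc[:80]
        ep = make_epochs(sub, seed=73, n_sensors=6)
        t_idx = [20, 30]
        full = dec.decode_timecourse(ep, sub, "target", fast_config, t_indices=t_idx)
        maps = dec.searchlight_map(
            ep, sub, {"kind": "evidence", "label": "target"},
            k=6, config=fast_config, t_indices=t_idx,
        )
        np.testing.assert_allclose(maps, np.nanmean(full.values), atol=1e-9)

    def test_signal_cluster_localized(self, meg_trials, fast_config):
        # orientation signal carried by sensors 0-3 only: searchlight with
        # small k peaks over that cluster
        sub = meg_trials[meg_trials.participant_id == "sub00"].iloc[:100]
        ep = make_epochs(sub, seed=74, n_sensors=9, noise="diagonal")
        data = ep.data.copy()
        data[:, 4:, :] = np.random.default_rng(5).standard_normal(
            data[:, 4:, :].shape
        ).astype(np.float32)
        ep.data = data
        maps = dec.searchlight_map(
            ep, sub, {"kind": "evidence", "label": "target"},
            k=3, config=fast_config, t_indices=[20, 28],
        )
        assert maps[:4].mean() > maps[4:].mean() + 0.05


class TestTopographyCorrelation:
    def test_self_and_negation(self, rng):
        m = rng.standard_normal(64)
        rho, _ = dec.topography_correlation(m, m)
        assert rho == pytest.approx(1.0)
        rho, _ = dec.topography_correlation(m, -m)
        assert rho == pytest.approx(-1.0)

    def test_independent_maps_uncorrelated(self, rng):
        rhos = [
            dec.topography_correlation(
                rng.standard_normal(64), rng.standard_normal(64)
            )[0]
            for _ in range(50)
        ]
        assert abs(np.mean(rhos)) < 0.1
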