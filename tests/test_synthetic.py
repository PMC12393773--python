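import numpy as np
import pandas as pd
import pytest

from serialdep import synthetic as syn
from serialdep.circular import relative_orientation
from serialdep.io_core import ConfigError


class TestTaskSequence:
    def test_meg_design_counts(self):
        trials = syn.generate_task_sequence("meg", 3, seed=0)
        for _, sub in trials.groupby("participant_id"):
            assert len(sub) == 400
            counts = sub.groupby(["condition", "cued_item"]).size().to_dict()
            assert counts[("both_shown", "sample1")] == 100
            assert counts[("both_shown", "sample2")] == 100
            assert counts[("first_only", "sample1")] == 100
            assert counts[("second_only", "sample2")] == 100
            # single-item conditions lack the other sample
            assert sub.loc[sub.condition == "first_only", "sample2_orientation"].isna().all()
            assert sub.loc[sub.condition == "second_only", "sample1_orientation"].isna().all()

    def test_eeg_design_counts(self):
        trials = syn.generate_task_sequence("eeg", 2, seed=0)
        for _, sub in trials.groupby("participant_id"):
            assert len(sub) == 1008  # 2 sessions x 6 cued-recall blocks x 84
            assert sub["block_id"].nunique() == 12
            assert (sub.groupby("block_id").size() == 84).all()
            assert (sub["condition"] == "cued_recall").all()

    def test_previous_target_links_respect_blocks(self):
        trials = syn.generate_task_sequence("meg", 1, seed=3)
        sub = trials.reset_index(drop=True)
        firsts = sub[sub.first_in_block]
        assert firsts["previous_target_orientation"].isna().all()
        rest = sub[~sub.first_in_block]
        np.testing.assert_allclose(
            rest["previous_target_orientation"].to_numpy(),
            sub["target_orientation"].shift(1)[~sub.first_in_block].to_numpy(),
        )

    def test_target_equals_cued_item(self):
        trials = syn.generate_task_sequence("meg", 1, seed=4)
        cued1 = trials[trials.cued_item == "sample1"]
        np.testing.assert_allclose(
            cued1["target_orientation"], cued1["sample1_orientation"]
        )

    def test_orientations_uniform(self):
        from scipy import stats

        trials = syn.generate_task_sequence("meg", 5, seed=9)
        theta = trials["target_orientation"].to_numpy()
        assert ((theta >= 0) & (theta < 180)).all()
        p = stats.kstest(theta / 180.0, "uniform").pvalue
        assert p > 0.001

    def test_pure_function_of_seed(self):
        a = syn.generate_task_sequence("meg", 1, seed=7)
        b = syn.generate_task_sequence("meg", 1, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestDogKernel:
    def test_odd_and_zero_at_origin(self):
        d = np.linspace(-90, 90, 181)
        vals = syn.dog_kernel(d, 2.0, 20.0)
        assert syn.dog_kernel(0.0, 3.0, 25.0) == 0.0
        np.testing.assert_allclose(vals, -syn.dog_kernel(-d, 2.0, 20.0), atol=1e-12)

    @pytest.mark.parametrize("width", [10.0, 20.0, 35.0])
    def test_peak_location_and_amplitude(self, width):
        # brute force over a 0.01 degree grid: |kernel| peaks at delta=width
        grid = np.arange(0.01, 90.0, 0.01)
        vals = syn.dog_kernel(grid, 2.5, width)
        assert grid[np.argmax(np.abs(vals))] == pytest.approx(width, abs=0.01)
        assert np.max(vals) == pytest.approx(2.5, rel=1e-6)


class TestBehavior:
    def test_noiseless_unbiased_reports_equal_target(self, meg_trials):
        params = syn.BehaviorParams(
            dog_amp_prev=0, dog_amp_s1=0, cardinal_amp=0, report_noise_sd=1e-9
        )
        trials = syn.generate_task_sequence("meg", 1, seed=21)
        out = syn.generate_behavior(trials, params, seed=22)
        np.testing.assert_allclose(
            out["report_orientation"], out["target_orientation"], atol=1e-6
        )
        np.testing.assert_allclose(out["signed_error"], 0.0, atol=1e-6)

    def test_unbiased_mean_error_near_zero(self):
        params = syn.BehaviorParams(dog_amp_prev=0, dog_amp_s1=0, cardinal_amp=0)
        trials = syn.generate_task_sequence("meg", 10, seed=31)
        out = syn.generate_behavior(trials, params, seed=32)
        err = out["signed_error"].to_numpy()
        assert abs(err.mean()) < 3 * err.std() / np.sqrt(len(err))

    def test_rt_and_rotation_start_ordering(self, meg_trials):
        assert (meg_trials["rt"] > 0).all()
        assert (meg_trials["rotation_start"] > 0).all()
        assert (meg_trials["rotation_start"] < meg_trials["rt"]).all()

    def test_swaps_create_apparent_attraction_to_sample2(self):
        # mixture-model logic: swapping to the uncued sample 2 on
        # sample-1-cued trials pulls reports toward sample 2
        from serialdep import behavior as beh

        trials = syn.generate_task_sequence("meg", 8, seed=41)
        params = syn.BehaviorParams(
            dog_amp_prev=0, dog_amp_s1=0, cardinal_amp=0, swap_rate=0.2
        )
        out = syn.generate_behavior(trials, params, seed=42)
        idx = []
        for _, sub in out.groupby("participant_id"):
            est = beh.participant_bias(sub, "sample2_on_sample1")
            idx.append(est.index)
        assert np.mean(idx) > 1.0  # strongly positive apparent attraction


class TestEpochs:
    def test_determinism_and_shapes(self, meg_trials):
        sub = meg_trials[meg_trials.participant_id == "sub00"]
        p = syn.NeuralParams(n_sensors=9)
        a = syn.generate_epochs(sub, p, "probe", (0, 1.0), 20.0, seed=5)
        b = syn.generate_epochs(sub, p, "probe", (0, 1.0), 20.0, seed=5)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.data.shape == (len(sub), 9, 20)

    def test_bias_window_outside_epoch_rejected(self, meg_trials):
        sub = meg_trials[meg_trials.participant_id == "sub00"]
        p = syn.NeuralParams(bias_schedule=[((-5.0, -4.0), "previous_target", 8.0)])
        with pytest.raises(ConfigError, match="outside the epoch"):
            syn.generate_epochs(sub, p, "response", (-1.0, 0.0), 20.0, seed=5)

    def test_shift_magnitude_validated(self):
        with pytest.raises(ConfigError):
            syn.NeuralParams(bias_schedule=[((-1, 0), "previous_target", 95.0)])

    def test_signal_is_cosine_tuned(self, meg_trials):
        # noiseless limit: inside the signal window each sensor follows
        # gain*cos(2(theta - phi_s))
        sub = meg_trials[meg_trials.participant_id == "sub00"].iloc[:10]
        p = syn.NeuralParams(
            n_sensors=8, tuning_gain=2.0, noise_sd=1e-6, noise_cov_spec="diagonal",
            signal_window=(0.2, 0.8), ramp_ms=0.0,
        )
        ep = syn.generate_epochs(sub, p, "probe", (0, 1.0), 20.0, seed=6)
        t_mid = np.argmin(np.abs(ep.times - 0.5))
        theta = sub["target_orientation"].to_numpy()
        phi = 180.0 * np.arange(8) / 8
        expected = 2.0 * np.cos(2 * np.deg2rad(theta[:, None] - phi[None, :]))
        np.testing.assert_allclose(ep.data[:, :, t_mid], expected, atol=1e-4)
        # outside the signal window: pure (tiny) noise
        assert np.abs(ep.data[:, :, 0]).max() < 1e-4

    def test_spatial_noise_correlation_decays(self, meg_trials):
        sub = meg_trials[meg_trials.participant_id == "sub00"]
        p = syn.NeuralParams(
            n_sensors=16, tuning_gain=0.0, noise_cov_spec=("spatially_correlated", 0.6)
        )
        ep = syn.generate_epochs(sub, p, "probe", (0, 1.0), 25.0, seed=8)
        x = ep.data.reshape(-1, 16).astype(float)
        x = x.reshape(ep.n_trials * 1, 16, -1).transpose(0, 2, 1).reshape(-1, 16)
        c = np.corrcoef(x.T)
        d = np.linalg.norm(
            ep.sensor_pos[:, None, :] - ep.sensor_pos[None, :, :], axis=-1
        )
        near = c[(d > 0) & (d < 1.5)].mean()
        far = c[d > 3.0].mean()
        assert near > far + 0.1
        np.testing.assert_allclose(np.diag(c), 1.0, atol=0.05)
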