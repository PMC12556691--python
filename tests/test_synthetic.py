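"""Synthetic generators: determinism, contracts, and ground-truth fidelity."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

from dyadsync.behaviour import estimation_error
from dyadsync.kinematics import synchrony_score
from dyadsync.synthetic import (
    REST_POSE,
    DyadSimConfig,
    FnirsSimConfig,
    ObserverSimConfig,
    generate_fnirs_recording,
    generate_follower,
    generate_leader,
    generate_observer_data,
    generate_schedule,
    generate_traits,
    make_montage,
)


class TestLeader:
    def test_deterministic_per_seed(self):
        cfg = DyadSimConfig(n_frames=100, seed=5)
        a = generate_leader(cfg)
        b = generate_leader(cfg)
        np.testing.assert_array_equal(a.coords, b.coords)
        c = generate_leader(DyadSimConfig(n_frames=100, seed=6))
        assert not np.array_equal(a.coords, c.coords)

    def test_shape_and_duration(self):
        seq = generate_leader(DyadSimConfig(n_frames=250, fps=25, seed=1))
        assert seq.coords.shape == (250, 7, 2)
        assert seq.duration == pytest.approx(10.0)

    def test_band_limited_spectrum(self):
        # trajectories are sums of sinusoids below 1 Hz; beyond spectral
        # leakage there should be essentially no power above 2 Hz
        seq = generate_leader(DyadSimConfig(n_frames=2000, fps=25, seed=2))
        x = seq.joint("r_hand")[:, 0] - seq.joint("r_hand")[:, 0].mean()
        f, p = periodogram(x, fs=25)
        assert p[f > 2.0].sum() / p.sum() < 1e-3

    def test_trunk_joints_near_stationary(self):
        seq = generate_leader(DyadSimConfig(n_frames=500, seed=3))
        neck_sd = seq.joint("neck").std(axis=0).max()
        hand_sd = seq.joint("r_hand").std(axis=0).max()
        assert neck_sd < hand_sd / 5

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            DyadSimConfig(n_frames=0)
        with pytest.raises(ValueError):
            DyadSimConfig(n_frames=10, lag_frames=10)
        with pytest.raises(ValueError):
            DyadSimConfig(follower_noise_sd=-1)


class TestFollower:
    def test_identity_case(self, leader):
        cfg = DyadSimConfig(n_frames=300, seed=7, lag_frames=0, follower_noise_sd=0.0)
        f = generate_follower(leader, cfg)
        np.testing.assert_allclose(f.coords, leader.coords)

    def test_lag_shifts_frames(self, leader):
        cfg = DyadSimConfig(n_frames=300, seed=7, lag_frames=5, follower_noise_sd=0.0)
        f = generate_follower(leader, cfg)
        np.testing.assert_allclose(f.coords[5:], leader.coords[:-5])
        np.testing.assert_allclose(f.coords[:5], np.broadcast_to(REST_POSE, (5, 7, 2)))

    def test_synchrony_decreases_with_noise(self):
        # Monte-Carlo monotonicity: mean score strictly decreasing in noise
        levels = [0.0, 1.0, 5.0, 20.0]
        means = []
        for sd in levels:
            scores = []
            for seed in range(50):
                cfg = DyadSimConfig(n_frames=100, seed=seed, lag_frames=0, follower_noise_sd=sd)
                lead = generate_leader(cfg)
                scores.append(synchrony_score(lead, generate_follower(lead, cfg)))
            means.append(np.mean(scores))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestSchedule:
    def test_even_split(self):
        sched = generate_schedule(40, seed=1)
        counts = sched.video_conditions["condition"].value_counts()
        assert counts["performed"] == 20
        assert counts["unknown"] == 20

    def test_block_structure(self):
        sched = generate_schedule(40, seed=1)
        assert sched.trials["block"].nunique() == 20
        assert len(sched.trials) == 60
        for _, block in sched.trials.groupby("block"):
            assert list(block["trial_type"]) == ["mirror", "observe", "observe"]
            mirror_video = block[block["trial_type"] == "mirror"]["video_id"].iloc[0]
            observed = block[block["trial_type"] == "observe"]
            assert mirror_video in set(observed["video_id"])
            assert set(observed["condition"]) == {"performed", "unknown"}

    def test_seeds_give_different_permutations_same_counts(self):
        a = generate_schedule(40, seed=1)
        b = generate_schedule(40, seed=2)
        assert not a.trials["video_id"].equals(b.trials["video_id"])
        for sched in (a, b):
            counts = sched.video_conditions["condition"].value_counts()
            assert counts.tolist() == [20, 20]

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError):
            generate_schedule(39, seed=0)


class TestObserverData:
    def test_null_model_reproduces_measured(self, observer_dataset):
        cfg = ObserverSimConfig(
            n_participants=12,
            intercept_performed=0.0,
            intercept_unknown=0.0,
            trait_coefficients={},
            random_intercept_sd=0.0,
            residual_sd=0.0,
            seed=0,
        )
        trials, _ = generate_observer_data(
            observer_dataset["measured"], observer_dataset["traits"], cfg
        )
        np.testing.assert_allclose(
            trials["estimated_synchrony"], 100 * trials["measured_synchrony"], atol=1e-12
        )

    def test_clamping_at_zero(self):
        measured = pd.DataFrame({"video_id": [0], "condition": ["performed"], "synchrony": [0.02]})
        traits = generate_traits(2, seed=0)
        cfg = ObserverSimConfig(
            n_participants=2,
            intercept_performed=50.0,
            trait_coefficients={},
            random_intercept_sd=0.0,
            residual_sd=0.0,
            seed=0,
        )
        trials, _ = generate_observer_data(measured, traits, cfg)
        assert (trials["estimated_synchrony"] == 0.0).all()

    def test_intercepts_recovered_by_sample_means(self):
        """Simulated error means converge to the generating intercepts."""
        rng = np.random.default_rng(0)
        sched = generate_schedule(40, seed=0)
        measured = sched.video_conditions.assign(synchrony=rng.uniform(0.4, 0.9, 40))
        traits = generate_traits(43, seed=0)
        cfg = ObserverSimConfig(n_participants=43, trait_coefficients={}, seed=1)
        trials, _ = generate_observer_data(measured, traits, cfg)
        d = estimation_error(trials["measured_synchrony"], trials["estimated_synchrony"])
        trials = trials.assign(d=d)
        for cond, target in (("performed", 14.4), ("unknown", 19.1)):
            sub = trials[trials["condition"] == cond]["d"]
            sem = 3 * np.sqrt(cfg.residual_sd**2 / len(sub) + cfg.random_intercept_sd**2 / 43)
            assert abs(sub.mean() - target) < sem

    def test_error_moments_converge(self):
        """Mean/SD of simulated D match the configured values at n=10,000."""
        rng = np.random.default_rng(1)
        measured = pd.DataFrame(
            {"video_id": np.arange(100), "condition": "performed", "synchrony": rng.uniform(0.3, 0.9, 100)}
        )
        traits = generate_traits(100, seed=2)
        cfg = ObserverSimConfig(
            n_participants=100, trait_coefficients={}, random_intercept_sd=0.0, seed=2
        )
        trials, _ = generate_observer_data(measured, traits, cfg)
        d = trials["true_error"]
        assert len(d) == 10000
        assert abs(d.mean() - 14.4) < 3 * cfg.residual_sd / np.sqrt(10000)
        assert abs(d.std() - cfg.residual_sd) < 0.05 * cfg.residual_sd

    def test_participant_mismatch_errors(self, observer_dataset):
        cfg = ObserverSimConfig(n_participants=5, seed=0)
        with pytest.raises(ValueError, match="participants"):
            generate_observer_data(observer_dataset["measured"], observer_dataset["traits"], cfg)


class TestFnirsSimulation:
    def test_zero_amplitude_zero_noise_constant_intensity(self):
        sched = generate_schedule(4, seed=0)
        cfg = FnirsSimConfig(
            n_long_channels=4,
            n_short_channels=2,
            true_amplitude={(roi, cond): 0.0 for roi in set(make_montage(4, 2).channels["roi"]) for cond in ("performed", "unknown")},
            superficial_sd=0.0,
            white_noise_sd=0.0,
            drift_slope=0.0,
            seed=0,
        )
        rec, _ = generate_fnirs_recording(sched, cfg, montage=make_montage(4, 2))
        assert np.ptp(rec.intensities, axis=-1).max() == pytest.approx(0.0, abs=1e-15)

    def test_determinism(self):
        sched = generate_schedule(4, seed=1)
        cfg = FnirsSimConfig(n_long_channels=4, n_short_channels=2, seed=9)
        rec1, _ = generate_fnirs_recording(sched, cfg)
        rec2, _ = generate_fnirs_recording(sched, cfg)
        np.testing.assert_array_equal(rec1.intensities, rec2.intensities)

    def test_unknown_roi_rejected(self):
        sched = generate_schedule(4, seed=1)
        cfg = FnirsSimConfig(
            n_long_channels=4, n_short_channels=2, true_amplitude={("NOWHERE", "performed"): 1e-6}, seed=0
        )
        with pytest.raises(KeyError):
            generate_fnirs_recording(sched, cfg)

    def test_truth_table_covers_long_channels(self):
        sched = generate_schedule(4, seed=1)
        cfg = FnirsSimConfig(n_long_channels=6, n_short_channels=2, seed=0)
        rec, truth = generate_fnirs_recording(sched, cfg)
        assert set(truth.channel_amplitudes["channel"]) == set(
            rec.montage.channels.loc[~rec.montage.channels["is_short"], "channel"]
        )
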