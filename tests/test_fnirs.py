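"""fNIRS chain: OD, SCI, TDDR, Beer-Lambert, design matrix, AR(1) GLM."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist

from dyadsync.fnirs import (
    ChannelRecording,
    FnirsPipeline,
    MontageSpec,
    PPFParams,
    aggregate_roi,
    build_design_matrix,
    canonical_hrf,
    condition_regressor,
    cosine_drift_basis,
    extinction_coefficients,
    fit_glm_ar1,
    forward_mbll,
    hbdiff,
    intensity_to_od,
    od_to_haemo,
    partial_pathlength_factor,
    scalp_coupling_index,
    tddr_correct,
)
from dyadsync.synthetic import (
    FnirsSimConfig,
    generate_fnirs_recording,
    generate_schedule,
    make_montage,
)


def _tiny_recording(signals_760, signals_850, fs=2.6):
    """Wrap raw per-channel signals into a ChannelRecording (2 long, 1 short)."""
    n_ch = signals_760.shape[0]
    montage = make_montage(n_long=n_ch - 1, n_short=1)
    intensities = np.stack([signals_760, signals_850], axis=1)
    events = pd.DataFrame({"onset": [10.0], "condition": ["performed"], "duration": [16.0]})
    return ChannelRecording(intensities=intensities, sampling_rate=fs, events=events, montage=montage)


class TestOpticalDensity:
    def test_constant_intensity_gives_zero(self):
        od = intensity_to_od(np.full((2, 2, 50), 3.7))
        np.testing.assert_allclose(od, 0.0, atol=1e-14)

    def test_halved_intensity_raises_od_by_ln2(self):
        x = np.full(100, 2.0)
        x[50] = 1.0
        od = intensity_to_od(x[None, None, :])[0, 0]
        assert od[50] - od[0] == pytest.approx(np.log(2.0))

    def test_nonpositive_sample_names_channel(self):
        x = np.ones((3, 2, 10))
        x[2, 0, 5] = -1.0
        with pytest.raises(ValueError, match="2"):
            intensity_to_od(x)


class TestBeerLambert:
    def test_zero_od_zero_concentration(self):
        haemo = od_to_haemo(np.zeros((2, 20)), distance_mm=30.0)
        np.testing.assert_allclose(haemo, 0.0)

    def test_hand_built_inversion(self):
        """OD built from known concentrations via a hand-written forward
        relation is inverted exactly."""
        eps = extinction_coefficients()
        c_hbo, c_hbr = 2.3e-6, -0.8e-6
        d_cm, ppf = 3.0, 0.1
        ln10 = np.log(10.0)
        od = np.empty((2, 5))
        for wi, wl in enumerate((760, 850)):
            od[wi] = ln10 * (eps.loc[wl, "hbo"] * c_hbo + eps.loc[wl, "hbr"] * c_hbr) * d_cm * ppf
        haemo = od_to_haemo(od, distance_mm=30.0, ppf=PPFParams())
        np.testing.assert_allclose(haemo[0], c_hbo, rtol=1e-12)
        np.testing.assert_allclose(haemo[1], c_hbr, rtol=1e-12)

    def test_roundtrip_with_simulator_forward_model(self):
        rng = np.random.default_rng(0)
        hbo = rng.normal(0, 1e-6, 200)
        hbr = rng.normal(0, 0.3e-6, 200)
        od10 = forward_mbll(hbo, hbr, distance_mm=31.0)
        # intensity domain and back: I = 10^-OD, then natural-log OD
        od_natural = -np.log(10.0 ** (-od10))
        rec = od_to_haemo(od_natural, distance_mm=31.0)
        assert np.abs(rec[0] - hbo).max() < 1e-8
        assert np.abs(rec[1] - hbr).max() < 1e-8

    def test_ppf_values(self):
        assert partial_pathlength_factor(6, 60) == pytest.approx(0.1)
        assert partial_pathlength_factor(7.25, 1) == pytest.approx(7.25)
        assert partial_pathlength_factor(0, 60) == 0.0
        with pytest.raises(ValueError):
            partial_pathlength_factor(6, 0)
        assert PPFParams().ppf == pytest.approx(0.1)


class TestScalpCouplingIndex:
    def _cardiac(self, n, fs=2.6, f=1.1, seed=0):
        t = np.arange(n) / fs
        return np.sin(2 * np.pi * f * t)

    def test_shared_cardiac_gives_high_sci(self):
        n = 500
        card = self._cardiac(n)
        base = 1.0 + 0.05 * card
        sig = np.tile(base, (3, 1))
        rec = _tiny_recording(sig, sig)
        sci = scalp_coupling_index(rec)
        assert np.all(sci > 0.95)

    def test_antiphase_cardiac_gives_negative_sci(self):
        n = 500
        card = self._cardiac(n)
        rec = _tiny_recording(np.tile(1 + 0.05 * card, (3, 1)), np.tile(1 - 0.05 * card, (3, 1)))
        sci = scalp_coupling_index(rec)
        assert np.all(sci < -0.95)

    def test_independent_noise_gives_low_sci(self):
        rng = np.random.default_rng(1)
        a = 1.0 + 0.01 * rng.normal(size=(3, 1000))
        b = 1.0 + 0.01 * rng.normal(size=(3, 1000))
        sci = scalp_coupling_index(_tiny_recording(a, b))
        assert np.all(np.abs(sci) < 0.3)

    def test_short_recording_rejected(self):
        sig = np.ones((3, 20))
        with pytest.raises(ValueError, match="30 s"):
            scalp_coupling_index(_tiny_recording(sig, sig))


class TestTDDR:
    def test_constant_signal_unchanged(self):
        x = np.full(200, 0.3)
        np.testing.assert_allclose(tddr_correct(x, 2.6), x, atol=1e-12)

    def test_matches_reference_implementation(self):
        """Bitwise-near agreement with the published reference algorithm
        as shipped in MNE (independent implementation)."""
        from mne.preprocessing.nirs._tddr import _TDDR

        rng = np.random.default_rng(0)
        x = 1e-3 * condition_regressor(np.array([20.0, 80.0]), 400, 2.6) + 1e-4 * rng.normal(size=400)
        x[200:] += 5e-3  # baseline shift artifact
        np.testing.assert_allclose(tddr_correct(x, 2.6), _TDDR(x.copy(), 2.6), atol=1e-9)

    def test_clean_haemodynamic_signal_preserved(self):
        # realistic background noise: the robust SD of the derivative must
        # reflect ongoing fluctuations, otherwise response ramps look like
        # outliers to the biweight. Mild low-band re-integration distortion
        # is inherent to the algorithm at 2.6 Hz, so the bar is 0.95.
        rng = np.random.default_rng(1)
        reg = condition_regressor(np.array([20.0, 80.0]), 400, 2.6)
        x = 1e-3 * reg + 1e-4 * rng.normal(size=400)
        out = tddr_correct(x, 2.6)
        assert np.corrcoef(out, x)[0, 1] > 0.95

    def test_spike_suppressed(self):
        """A 20-SD spike is strongly attenuated (its sub-0.5-Hz content is
        removed; the high-band residue passes, so suppression is partial)."""
        rng = np.random.default_rng(2)
        x = 1e-3 * condition_regressor(np.array([30.0]), 400, 2.6) + 1e-4 * rng.normal(size=400)
        spiked = x.copy()
        spiked[200] += 20 * x.std()
        out = tddr_correct(spiked, 2.6)
        peak_pre = np.abs(spiked - np.median(spiked)).max()
        peak_post = np.abs(out - np.median(out)).max()
        assert peak_post < 0.75 * peak_pre

    def test_baseline_shift_removed(self):
        """A step artifact's deviation from the clean signal shrinks several-fold."""
        rng = np.random.default_rng(3)
        clean = 1e-3 * condition_regressor(np.array([20.0, 80.0]), 400, 2.6) + 1e-4 * rng.normal(size=400)
        shifted = clean.copy()
        shifted[200:] += 20 * clean.std()
        out = tddr_correct(shifted, 2.6)
        err_pre = np.sqrt(np.mean((shifted - shifted.mean() - (clean - clean.mean())) ** 2))
        err_post = np.sqrt(np.mean((out - out.mean() - (clean - clean.mean())) ** 2))
        assert err_post < err_pre / 4

    def test_nonfinite_rejected(self):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(ValueError):
            tddr_correct(x, 2.6)


class TestDesignMatrix:
    events = pd.DataFrame(
        {"onset": [20.0, 120.0, 220.0], "condition": ["performed", "unknown", "performed"], "duration": 16.0}
    )

    def test_causality(self):
        X = build_design_matrix(self.events, n_times=800, sampling_rate=2.6)
        before = X["cond_performed"].to_numpy()[: int(20.0 * 2.6) - 1]
        np.testing.assert_allclose(before, 0.0, atol=1e-12)

    def test_single_event_integral_matches_quadrature(self):
        """Time-integral of one unit-peak event regressor equals the
        quadrature of the boxcar-HRF convolution computed independently."""
        reg = condition_regressor(np.array([5.0]), n_times=2000, sampling_rate=2.6, duration_s=16.0)
        got = reg.sum() / 2.6
        # independent dense-grid computation
        dt = 0.005
        t = np.arange(0, 40, dt)
        hrf = gamma_dist.pdf(t, a=6.0) - gamma_dist.pdf(t, a=16.0) / 6.0
        box = np.ones(int(16.0 / dt))
        resp = np.convolve(box, hrf) * dt
        want = resp.sum() * dt / resp.max()
        assert got == pytest.approx(want, rel=0.01)

    def test_drift_columns_orthogonal(self):
        drift = cosine_drift_basis(1000, 2.6, cutoff_hz=0.01)
        assert drift.shape[1] >= 2
        gram = drift.T @ drift
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-9 * np.abs(np.diag(gram)).max()

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_design_matrix(pd.DataFrame(columns=["onset", "condition"]), 100, 2.6)

    def test_hrf_shape(self):
        t = np.linspace(0, 32, 500)
        h = canonical_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=1.5)  # peak near 5-6 s
        assert h.min() < 0  # undershoot present


class TestGlmAr1:
    def test_noise_free_exact_recovery(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            {
                "a": condition_regressor(np.array([10.0, 60.0]), 400, 2.6),
                "b": rng.normal(size=400),
                "constant": np.ones(400),
            }
        )
        beta = np.array([2.0, -1.0, 0.5])
        fit = fit_glm_ar1(X.to_numpy() @ beta, X)
        np.testing.assert_allclose(fit["beta"], beta, atol=1e-10)
        assert (fit["se"] < 1e-8).all()

    def test_rho_recovered(self):
        rng = np.random.default_rng(4)
        n, rho = 1000, 0.6
        noise = np.empty(n)
        noise[0] = rng.normal()
        for i in range(1, n):
            noise[i] = rho * noise[i - 1] + rng.normal()
        X = pd.DataFrame({"x": rng.normal(size=n), "constant": np.ones(n)})
        fit = fit_glm_ar1(X.to_numpy() @ np.array([1.0, 0.0]) + noise, X)
        assert fit["rho"].iloc[0] == pytest.approx(rho, abs=0.1)

    def test_ar1_cis_calibrated_vs_naive_ols(self):
        """With AR(1) noise, prewhitened 95% CIs should cover near-nominally
        while naive OLS under-covers."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n, rho, beta_true = 300, 0.6, 1.0
        # smooth regressor so autocorrelated noise actually hurts OLS
        x = np.convolve(rng.normal(size=n + 50), np.ones(20) / 20, mode="same")[:n]
        cover_ar1 = cover_ols = 0
        n_sims = 100
        for _ in range(n_sims):
            e = np.empty(n)
            e[0] = rng.normal()
            for i in range(1, n):
                e[i] = rho * e[i - 1] + rng.normal()
            y = beta_true * x + e
            X = pd.DataFrame({"x": x, "constant": np.ones(n)})
            fit = fit_glm_ar1(y, X)
            b, se = fit["beta"].iloc[0], fit["se"].iloc[0]
            cover_ar1 += abs(b - beta_true) < 1.96 * se
            ols = sm.OLS(y, X.to_numpy()).fit()
            cover_ols += abs(ols.params[0] - beta_true) < 1.96 * ols.bse[0]
        assert cover_ar1 / n_sims > 0.85
        assert cover_ols / n_sims < cover_ar1 / n_sims

    def test_rank_deficient_rejected(self):
        X = pd.DataFrame({"a": np.ones(50), "b": np.ones(50)})
        with pytest.raises(ValueError):
            fit_glm_ar1(np.zeros(50), X)


class TestRoiAggregation:
    def test_equal_ses_give_simple_mean(self):
        est = pd.DataFrame({"roi": ["A"] * 3, "beta": [1.0, 2.0, 6.0], "se": [0.5] * 3})
        out = aggregate_roi(est)
        assert out["beta"].iloc[0] == pytest.approx(3.0)

    def test_single_channel_passthrough(self):
        est = pd.DataFrame({"roi": ["A"], "beta": [4.2], "se": [0.3]})
        out = aggregate_roi(est)
        assert out["beta"].iloc[0] == pytest.approx(4.2)
        assert out["se"].iloc[0] == pytest.approx(0.3)

    def test_hand_computed_weighted_mean(self):
        betas = np.array([1.0, 2.0, 4.0])
        ses = np.array([0.1, 0.2, 0.4])
        w = 1 / ses**2
        est = pd.DataFrame({"roi": ["A"] * 3, "beta": betas, "se": ses})
        out = aggregate_roi(est)
        assert out["beta"].iloc[0] == pytest.approx(float((w * betas).sum() / w.sum()))
        assert out["se"].iloc[0] == pytest.approx(float(np.sqrt(1 / w.sum())))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            k = int(rng.integers(1, 8))
            betas = rng.normal(size=k)
            ses = rng.uniform(0.05, 1.0, k)
            est = pd.DataFrame({"roi": ["r"] * k, "beta": betas, "se": ses})
            expected = sum(b / s**2 for b, s in zip(betas, ses)) / sum(1 / s**2 for s in ses)
            assert aggregate_roi(est)["beta"].iloc[0] == pytest.approx(expected)

    def test_inverse_se_weighting_option(self):
        est = pd.DataFrame({"roi": ["A"] * 2, "beta": [0.0, 1.0], "se": [1.0, 4.0]})
        out = aggregate_roi(est, weighting="inverse_se")
        assert out["beta"].iloc[0] == pytest.approx((0.0 * 1.0 + 1.0 * 0.25) / 1.25)


class TestHbDiff:
    @pytest.mark.parametrize(
        "hbo,hbr,diff,cat",
        [
            (0.3, -0.1, 0.4, "canonical"),
            (-0.2, 0.1, -0.3, "inverted"),
            (0.2, 0.1, 0.1, "same_sign"),
            (-0.2, -0.3, 0.1, "same_sign"),
        ],
    )
    def test_sign_rule(self, hbo, hbr, diff, cat):
        got_diff, got_cat = hbdiff(hbo, hbr)
        assert got_diff == pytest.approx(diff)
        assert got_cat == cat

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            hbdiff(np.nan, 0.1)


class TestMontage:
    def test_distance_constraints_enforced(self):
        bad = make_montage(4, 2).channels.copy()
        bad.loc[0, "distance_mm"] = 45.0
        with pytest.raises(ValueError, match="long channels"):
            MontageSpec(channels=bad)

    def test_short_channels_not_in_roi_mapping(self):
        m = make_montage(24, 4)
        assert len(m.long_index) == 24
        assert len(m.short_index) == 4


class TestEndToEnd:
    def test_noise_free_roi_recovery_within_one_percent(self):
        sched = generate_schedule(8, seed=2)
        cfg = FnirsSimConfig(
            n_long_channels=12, n_short_channels=2, superficial_sd=0.0,
            white_noise_sd=0.0, drift_slope=0.0, seed=3,
        )
        rec, truth = generate_fnirs_recording(sched, cfg)
        est = FnirsPipeline(apply_tddr=False, use_short_channels=False).roi_estimates(rec)
        m = est.merge(truth.roi_amplitudes, on=["roi", "condition"])
        assert (np.abs(m["hbo_beta"] - m["hbo_amp"]) / np.abs(m["hbo_amp"])).max() < 0.01
        assert (np.abs(m["hbr_beta"] - m["hbr_amp"]) / np.abs(m["hbr_amp"])).max() < 0.01
        assert (m["category"] == "canonical").all()

    def test_short_channel_regression_rejects_superficial_signal(self):
        """A large shared scalp component should corrupt condition betas
        far less when short-channel regressors are enabled."""
        sched = generate_schedule(8, seed=4)
        cfg = FnirsSimConfig(
            n_long_channels=12, n_short_channels=4, superficial_sd=2e-2,
            white_noise_sd=0.0, drift_slope=0.0, seed=5,
        )
        rec, truth = generate_fnirs_recording(sched, cfg)

        def max_rel_error(use_short):
            est = FnirsPipeline(apply_tddr=False, use_short_channels=use_short).roi_estimates(rec)
            m = est.merge(truth.roi_amplitudes, on=["roi", "condition"])
            return (np.abs(m["hbo_beta"] - m["hbo_amp"]) / np.abs(m["hbo_amp"])).max()

        err_with = max_rel_error(True)
        err_without = max_rel_error(False)
        assert err_without >= 2 * err_with

    def test_short_channels_carry_no_event_locked_signal(self):
        """GLM condition betas fitted on short channels are ~0 by design."""
        sched = generate_schedule(8, seed=6)
        cfg = FnirsSimConfig(
            n_long_channels=4, n_short_channels=2, superficial_sd=0.0,
            white_noise_sd=0.0, drift_slope=0.0, seed=7,
        )
        rec, _ = generate_fnirs_recording(sched, cfg)
        od = intensity_to_od(rec.intensities)
        X = build_design_matrix(rec.events, rec.n_times, rec.sampling_rate)
        for ci in rec.montage.short_index:
            haemo = od_to_haemo(od[ci], rec.montage.channels["distance_mm"].iloc[ci])
            fit = fit_glm_ar1(haemo[0], X).set_index("regressor")
            for cond in ("cond_performed", "cond_unknown"):
                assert abs(fit.loc[cond, "beta"]) < 1e-12
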