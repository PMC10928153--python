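"""The tau estimator battery and the pulse pressure method."""

import numpy as np
import pytest

from wktau.errors import DataError, FitError
from wktau.features import average_beats, extract_features
from wktau.population import NoiseConfig, add_measurement_noise
from wktau.tau import (
    DecayFitConfig,
    fit_diastolic_decay,
    peripheral_resistance,
    ppm_compliance,
    tau_formula,
    tau_reference,
)
from wktau.windkessel import PressureWave, WindkesselParams, solve_wk2_periodic


def _exp_wave(p0=90.0, tau=1.3, T=1.0, fs=1000.0):
    t = np.arange(round(fs * T)) / fs
    return PressureWave(fs=fs, T=T, samples=p0 * np.exp(-t / tau))


class TestDiastolicDecayFit:
    def test_exact_exponential(self):
        tau = fit_diastolic_decay(_exp_wave(), ts=0.1)
        assert tau == pytest.approx(1.3, abs=1e-10)

    def test_wk2_diastole_recovers_rc(self, default_params, wk_wave):
        _, wave = wk_wave
        tau = fit_diastolic_decay(wave, default_params.ts)
        assert tau == pytest.approx(default_params.tau, rel=1e-3)

    def test_nonlinear_matches_loglinear_on_clean_data(self, default_params, wk_wave):
        _, wave = wk_wave
        a = fit_diastolic_decay(wave, default_params.ts)
        b = fit_diastolic_decay(
            wave, default_params.ts, DecayFitConfig(method="nonlinear_ls")
        )
        assert b == pytest.approx(a, rel=1e-6)

    def test_noise_monte_carlo_unbiased(self, default_params, wk_wave, rng):
        """1000 noisy replicates: the mean decay fit stays within 2% of RC."""
        _, wave = wk_wave
        taus = []
        for _ in range(1000):
            noisy = PressureWave(
                wave.fs, wave.T, wave.samples + rng.normal(0.0, 1.0, wave.samples.size)
            )
            taus.append(fit_diastolic_decay(noisy, default_params.ts))
        assert abs(np.mean(taus) - default_params.tau) / default_params.tau < 0.02

    def test_nonpositive_window_requires_nonlinear(self):
        wave = _exp_wave(p0=5.0, tau=0.2)  # decays through ~0 late in diastole
        wave.samples[-200:] -= 1.0
        with pytest.raises(FitError, match="nonlinear"):
            fit_diastolic_decay(wave, ts=0.1)

    def test_rising_window_rejected(self):
        t = np.arange(1000) / 1000.0
        wave = PressureWave(1000.0, 1.0, 50.0 * np.exp(t))
        with pytest.raises(FitError, match="not decaying"):
            fit_diastolic_decay(wave, ts=0.1)

    def test_short_window_rejected(self, wk_wave, default_params):
        _, wave = wk_wave
        with pytest.raises(DataError, match="window"):
            fit_diastolic_decay(wave, default_params.ts, DecayFitConfig(0.98, 1.0))


class TestPulsePressureMethod:
    def test_recovers_generator_compliance(self, default_params, wk_wave):
        fl, wave = wk_wave
        c = ppm_compliance(wave, fl, default_params.R)
        assert c == pytest.approx(default_params.C, rel=1e-6)

    def test_larger_measured_pp_means_smaller_compliance(self, default_params, wk_wave):
        fl, wave = wk_wave
        doubled = PressureWave(wave.fs, wave.T, wave.samples * 2.0)
        c1 = ppm_compliance(wave, fl, default_params.R)
        c2 = ppm_compliance(doubled, fl, default_params.R)
        assert c2 < c1

    def test_predicted_pp_strictly_decreasing_in_c(self, wk_wave, default_params):
        fl, _ = wk_wave
        pps = []
        for c in np.linspace(0.1, 5.0, 25):
            prm = WindkesselParams(default_params.R, c, fl.T, fl.ts, fl.SV)
            pps.append(np.ptp(solve_wk2_periodic(prm, fl).samples))
        assert all(b < a for a, b in zip(pps, pps[1:]))

    def test_noisy_pressure_within_five_percent(self, default_params, wk_wave):
        fl, wave = wk_wave
        rec = add_measurement_noise(wave, NoiseConfig(white_sd=1.0), seed=8)
        cycle = average_beats(rec, smoothing=True)
        c = ppm_compliance(cycle, fl, default_params.R)
        assert c == pytest.approx(default_params.C, rel=0.05)

    def test_harmonic_truncation_variant(self, default_params, wk_wave):
        fl, wave = wk_wave
        c = ppm_compliance(wave, fl, default_params.R, n_harmonics=5)
        assert c == pytest.approx(default_params.C, rel=0.05)

    def test_unattainable_pp_raises_bracketing_error(self, default_params, wk_wave):
        fl, wave = wk_wave
        huge = PressureWave(wave.fs, wave.T, wave.samples * 100.0)
        with pytest.raises(FitError, match="attainable"):
            ppm_compliance(huge, fl, default_params.R)


class TestScalarEstimators:
    def test_peripheral_resistance(self):
        assert peripheral_resistance(100.0, 100.0) == 1.0
        assert peripheral_resistance(100.0, 4.9e3 / 60.0) == pytest.approx(1.2245, abs=1e-4)
        assert peripheral_resistance(0.0, 50.0) == 0.0
        with pytest.raises(ValueError):
            peripheral_resistance(100.0, 0.0)

    def test_tau_formula(self):
        assert tau_formula(1.0, 100.0, 54.0, 0.7) == pytest.approx(1.2963, abs=1e-4)
        assert tau_formula(1.0, 50.0, 50.0, 1.0) == 1.0
        with pytest.raises(ValueError):
            tau_formula(1.0, 100.0, 54.0, 0.0)  # degenerate coefficient
        with pytest.raises(ValueError):
            tau_formula(1.0, 100.0, 0.0, 0.7)

    def test_tau_reference(self):
        assert tau_reference(1.0, 1.1) == pytest.approx(1.1)
        assert tau_reference(2.0, 0.5) == 1.0
        with pytest.raises(ValueError):
            tau_reference(-1.0, 1.0)


class TestEstimatorAgreement:
    def test_all_estimators_close_on_clean_subjects(self, small_cohort):
        """Decay fit and PPM-derived R*C both recover tau = R*C on clean data."""
        table, subjects = small_cohort
        for s in subjects[:25]:
            f = extract_features(s.pressure)
            tau_exp = fit_diastolic_decay(s.pressure, s.params.ts)
            assert tau_exp == pytest.approx(s.params.tau, rel=1e-3)
            r_est = f.MBP / (s.params.SV / s.params.T)
            c_ppm = ppm_compliance(s.pressure, s.flow, r_est)
            assert r_est * c_ppm == pytest.approx(s.params.tau, rel=1e-5)

    def test_exact_coefficient_recovers_reference(self, small_cohort):
        """tau_formula with k = C*cPP/SV and MBP = R*SV/T is the RC identity."""
        table, _ = small_cohort
        k = table["C"] * table["cPP"] / table["SV_ml"]
        mbp_exact = table["R"] * table["SV_ml"] / table["T_s"]
        tau_hat = tau_formula(
            table["T_s"].to_numpy(), mbp_exact.to_numpy(),
            table["cPP"].to_numpy(), k.to_numpy(),
        )
        assert np.max(np.abs(tau_hat / table["tau_true"].to_numpy() - 1.0)) < 1e-12
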