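"""Feature extraction, MBP formulas, beat averaging and calibration."""

import numpy as np
import pytest

from wktau.errors import DataError
from wktau.features import (
    MBP_FORMULAS,
    average_beats,
    calibrate_wave,
    estimate_mbp,
    extract_features,
)
from wktau.population import NoiseConfig, add_measurement_noise
from wktau.windkessel import PressureWave, WindkesselParams, half_sine_flow, solve_wk2_periodic


def _wave(samples, fs=1000.0):
    samples = np.asarray(samples, dtype=float)
    return PressureWave(fs=fs, T=samples.size / fs, samples=samples)


class TestExtractFeatures:
    def test_constant_wave(self):
        f = extract_features(_wave(np.full(700, 100.0)))
        assert (f.SBP, f.DBP, f.MBP, f.cPP) == (100.0, 100.0, 100.0, 0.0)
        assert f.HR == pytest.approx(60.0 / f.T)

    def test_mbp_matches_conservation_oracle(self):
        """Waveform-mean MBP equals R*SV/T from the Windkessel balance."""
        prm = WindkesselParams(R=1.2, C=1.3, T=1.0, ts=0.35, SV=81.7)
        wave = solve_wk2_periodic(prm, half_sine_flow(1.0, 0.35, 81.7, 1000.0))
        f = extract_features(wave)
        assert f.MBP == pytest.approx(1.2 * 81.7 / 1.0, rel=1e-6)

    def test_pulse_pressure_is_sbp_minus_dbp(self):
        t = np.linspace(0.0, 2 * np.pi, 800, endpoint=False)
        f = extract_features(_wave(104.0 + 27.0 * np.sin(t)))
        assert f.SBP == pytest.approx(131.0, abs=1e-3)
        assert f.DBP == pytest.approx(77.0, abs=1e-3)
        assert f.cPP == pytest.approx(f.SBP - f.DBP, abs=1e-12)

    def test_sampling_rate_invariance(self):
        """Features shift < 0.2 mmHg between 250 Hz and 2 kHz sampling."""
        prm = WindkesselParams(R=1.0, C=1.1, T=0.7, ts=0.245, SV=70.0)
        feats = []
        for fs in (250.0, 500.0, 1000.0, 2000.0):
            wave = solve_wk2_periodic(prm, half_sine_flow(0.7, 0.245, 70.0, fs))
            feats.append(extract_features(wave))
        for attr in ("SBP", "DBP", "MBP", "cPP"):
            vals = [getattr(f, attr) for f in feats]
            assert max(vals) - min(vals) < 0.2

    def test_bad_samples_rejected(self):
        with pytest.raises(DataError):
            extract_features(_wave(np.array([])))
        with pytest.raises(DataError):
            extract_features(_wave(np.array([1.0, np.nan, 2.0])))


class TestEstimateMbp:
    @pytest.mark.parametrize("formula", [f for f in MBP_FORMULAS if f != "dbp_plus_pp3_plus5"])
    def test_formulas_coincide_without_pulse_pressure(self, formula):
        assert estimate_mbp(100.0, 100.0, formula, HR=70.0) == pytest.approx(100.0)

    def test_additive_constant_formula_offset_at_zero_pp(self):
        # the DBP + 0.33*PP + 5 variant keeps its +5 mmHg offset when PP = 0
        assert estimate_mbp(100.0, 100.0, "dbp_plus_pp3_plus5") == pytest.approx(105.0)

    @pytest.mark.parametrize(
        "sbp, dbp, hr, formula, expected",
        [
            (131.0, 77.0, None, "dbp_plus_pp3", 77.0 + 0.33 * 54.0),
            (120.0, 80.0, None, "weighted_42_58", 96.8),
            (131.0, 77.0, None, "dbp_plus_pp3_plus5", 77.0 + 0.33 * 54.0 + 5.0),
            (120.0, 80.0, None, "geometric_mean", np.sqrt(120.0 * 80.0)),
            (131.0, 77.0, 60.0, "hr_adjusted", 77.0 + (0.33 + 0.072) * 54.0),
        ],
    )
    def test_formula_arithmetic(self, sbp, dbp, hr, formula, expected):
        assert estimate_mbp(sbp, dbp, formula, HR=hr) == pytest.approx(expected)

    def test_random_degenerate_draws_coincide(self, rng):
        no_offset = [f for f in MBP_FORMULAS if f != "dbp_plus_pp3_plus5"]
        for _ in range(20):
            v = rng.uniform(60.0, 140.0)
            vals = [estimate_mbp(v, v, f, HR=rng.uniform(50, 100)) for f in no_offset]
            assert np.allclose(vals, v)

    def test_unknown_formula_rejected(self):
        with pytest.raises(ValueError, match="unknown MBP formula"):
            estimate_mbp(120.0, 80.0, "nonsense")

    def test_requires_wave_for_integral_mean(self):
        with pytest.raises(ValueError, match="wave"):
            estimate_mbp(120.0, 80.0, "waveform_mean")

    def test_inverted_pressures_rejected(self):
        with pytest.raises(ValueError):
            estimate_mbp(80.0, 120.0, "dbp_plus_pp3")


class TestCalibrateWave:
    def test_contract_hits_anchors(self, wk_wave):
        _, wave = wk_wave
        cal = calibrate_wave(wave, 77.0, 100.0)
        assert cal.samples.min() == pytest.approx(77.0, abs=1e-9)
        assert cal.samples.mean() == pytest.approx(100.0, abs=1e-9)
        f = extract_features(cal)
        assert (f.DBP, f.MBP) == (pytest.approx(77.0, abs=1e-9), pytest.approx(100.0, abs=1e-9))

    def test_identity_when_anchors_already_met(self, wk_wave):
        _, wave = wk_wave
        cal = calibrate_wave(wave, float(wave.samples.min()), float(wave.samples.mean()))
        assert np.allclose(cal.samples, wave.samples, atol=1e-10)

    def test_affine_gain_propagates_into_pulse_pressure(self, wk_wave):
        """cPP scales by a = (MBP_ref - DBP_ref)/(mean - min) exactly."""
        _, wave = wk_wave
        dbp_ref, mbp_ref = 80.0, 97.0
        a = (mbp_ref - dbp_ref) / (wave.samples.mean() - wave.samples.min())
        cal = calibrate_wave(wave, dbp_ref, mbp_ref)
        assert np.ptp(cal.samples) == pytest.approx(a * np.ptp(wave.samples), rel=1e-9)

    def test_flat_wave_rejected(self):
        with pytest.raises(DataError, match="flat"):
            calibrate_wave(_wave(np.full(100, 90.0)), 77.0, 100.0)

    def test_bad_anchor_order_rejected(self, wk_wave):
        with pytest.raises(ValueError):
            calibrate_wave(wk_wave[1], 100.0, 90.0)


class TestAverageBeats:
    def test_clean_tiling_recovered_exactly(self, wk_wave, roll_to_foot):
        _, wave = wk_wave
        rec = add_measurement_noise(wave, NoiseConfig(), seed=0, duration=8.0)
        cycle = average_beats(rec)
        assert cycle.samples.size == wave.samples.size
        assert np.max(np.abs(cycle.samples - roll_to_foot(wave.samples))) < 1e-9

    def test_white_noise_suppressed(self, wk_wave, roll_to_foot):
        _, wave = wk_wave
        rec = add_measurement_noise(wave, NoiseConfig(white_sd=1.0), seed=21)
        cycle = average_beats(rec, smoothing=True)
        clean = roll_to_foot(wave.samples)
        n = min(cycle.samples.size, clean.size)
        rmse = np.sqrt(np.mean((cycle.samples[:n] - clean[:n]) ** 2))
        assert rmse < 0.5

    def test_jittered_noisy_recording_recovered(self, wk_wave, roll_to_foot):
        _, wave = wk_wave
        noise = NoiseConfig(white_sd=1.0, drift_amplitude=3.0, cycle_jitter_sd=0.02)
        rec = add_measurement_noise(wave, noise, seed=4)
        cycle = average_beats(rec, smoothing=True)
        clean = roll_to_foot(wave.samples)
        n = min(cycle.samples.size, clean.size)
        rmse = np.sqrt(np.mean((cycle.samples[:n] - clean[:n]) ** 2))
        assert rmse < 1.0

    def test_too_few_cycles_rejected(self, wk_wave):
        _, wave = wk_wave
        rec = add_measurement_noise(wave, NoiseConfig(), seed=0, duration=1.5)
        with pytest.raises(DataError, match="cycles"):
            average_beats(rec)

    def test_extract_features_rejects_multibeat(self, wk_wave):
        _, wave = wk_wave
        rec = add_measurement_noise(wave, NoiseConfig(), seed=0, duration=5.0)
        with pytest.raises(DataError, match="single-cycle"):
            extract_features(rec)
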