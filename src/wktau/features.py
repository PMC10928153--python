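"""Scalar features of pressure waves and the tonometry processing chain.

``extract_features`` reduces a single calibrated cycle to the quantities the
time-constant formula consumes (SBP, DBP, MBP, cPP, T, HR).  The multi-beat
path mirrors how carotid tonometry recordings are turned into one
representative cycle: optional Savitzky-Golay smoothing, detection of cycle
feet at the pressure minima, per-cycle linear detrending so each beat starts
and ends at the same value, resampling to a common length and pointwise
averaging, then affine calibration to cuff diastolic and mean pressure.

Mean blood pressure can also be estimated from SBP/DBP alone through the
standard clinical formulas (fixed 0.42/0.58 weighting, DBP + PP/3 variants,
heart-rate-adjusted form factor, geometric mean), used for the sensitivity
analysis of the fitted coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DataError
from .windkessel import PressureWave

__all__ = [
    "FeatureRow",
    "MBP_FORMULAS",
    "extract_features",
    "estimate_mbp",
    "average_beats",
    "calibrate_wave",
]


@dataclass(frozen=True)
class FeatureRow:
    """Per-subject scalar pressure features (mmHg, s, beats/min, mL, mL/s)."""

    SBP: float
    DBP: float
    MBP: float
    cPP: float
    T: float
    HR: float
    bPP: float | None = None
    SV: float | None = None
    CO: float | None = None


def extract_features(wave: PressureWave) -> FeatureRow:
    """SBP = max, DBP = min, MBP = time average over the cycle, cPP = SBP - DBP.

    For a uniformly sampled periodic cycle the trapezoidal time average (with
    the wrap point ``P(T) = P(0)``) equals the arithmetic sample mean, which
    is what is computed here.
    """
    if wave.n_beats != 1:
        raise DataError("extract_features expects a single-cycle wave; average beats first")
    p = np.asarray(wave.samples, dtype=float)
    if p.size == 0 or not np.all(np.isfinite(p)):
        raise DataError("pressure samples are empty or contain non-finite values")
    sbp = float(p.max())
    dbp = float(p.min())
    mbp = float(p.mean())
    return FeatureRow(
        SBP=sbp, DBP=dbp, MBP=mbp, cPP=sbp - dbp, T=wave.T, HR=60.0 / wave.T
    )


def _needs_hr(sbp, dbp, hr):
    if hr is None:
        raise ValueError("this MBP formula requires the heart rate")
    return dbp + (0.33 + 0.0012 * hr) * (sbp - dbp)


#: Clinical MBP estimation formulas, keyed by identifier.
MBP_FORMULAS = {
    "weighted_42_58": lambda sbp, dbp, hr=None: 0.42 * sbp + 0.58 * dbp,
    "dbp_plus_pp3": lambda sbp, dbp, hr=None: dbp + 0.33 * (sbp - dbp),
    "dbp_plus_pp3_plus5": lambda sbp, dbp, hr=None: dbp + 0.33 * (sbp - dbp) + 5.0,
    "hr_adjusted": lambda sbp, dbp, hr=None: _needs_hr(sbp, dbp, hr),
    "geometric_mean": lambda sbp, dbp, hr=None: np.sqrt(sbp * dbp),
}

#: Identifier for the waveform integral mean (the baseline definition).
WAVEFORM_MEAN = "waveform_mean"

MBP_FORMULA_IDS = (WAVEFORM_MEAN, *MBP_FORMULAS)


def estimate_mbp(SBP, DBP, formula: str, HR=None, wave: PressureWave | None = None):
    """Mean blood pressure by the chosen formula (vectorised over arrays).

    ``formula="waveform_mean"`` returns the integral mean and requires the
    wave; the remaining formulas use SBP/DBP (and HR where noted).
    """
    if formula == WAVEFORM_MEAN:
        if wave is None:
            raise ValueError("waveform_mean requires the pressure wave")
        return extract_features(wave).MBP
    try:
        fn = MBP_FORMULAS[formula]
    except KeyError:
        raise ValueError(
            f"unknown MBP formula {formula!r}; choose from {MBP_FORMULA_IDS}"
        ) from None
    SBP = np.asarray(SBP, dtype=float)
    DBP = np.asarray(DBP, dtype=float)
    if np.any(DBP <= 0) or np.any(SBP < DBP):
        raise ValueError("require SBP >= DBP > 0")
    out = fn(SBP, DBP, None if HR is None else np.asarray(HR, dtype=float))
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def _estimate_period(p: np.ndarray, fs: float) -> int:
    """Dominant period in samples via the autocorrelation of the detrended signal."""
    x = signal.detrend(p)
    ac = signal.correlate(x, x, mode="full")[x.size - 1 :]
    lo, hi = int(0.3 * fs), min(int(2.0 * fs), ac.size - 1)
    if hi <= lo:
        raise DataError("recording too short to detect periodicity")
    lag = lo + int(np.argmax(ac[lo : hi + 1]))
    if ac[lag] <= 0:
        raise DataError("no periodicity detected in the recording")
    return lag


def average_beats(
    recording: PressureWave,
    smoothing: bool = False,
    sg_window: int = 51,
    sg_order: int = 3,
) -> PressureWave:
    """Collapse a multi-beat recording into one representative cycle.

    Cycle feet (pressure minima at ejection onset) are detected on the
    linearly detrended signal with a minimum spacing of 70% of the dominant
    period; each cycle is linearly detrended so its start and end values
    coincide, resampled to the median cycle length, and averaged pointwise.
    """
    p = np.asarray(recording.samples, dtype=float)
    fs = recording.fs
    if p.size == 0 or not np.all(np.isfinite(p)):
        raise DataError("pressure samples are empty or contain non-finite values")
    if smoothing:
        win = min(sg_window if sg_window % 2 else sg_window + 1, p.size - (p.size + 1) % 2)
        if win > sg_order + 1:
            p = signal.savgol_filter(p, win, sg_order)

    period = _estimate_period(p, fs)
    base = signal.detrend(p)  # drift-robust detection signal
    feet, _ = signal.find_peaks(-base, distance=max(int(0.7 * period), 1))
    if feet.size < 4:
        raise DataError(
            f"found only {max(feet.size - 1, 0)} full cycles; need at least 3"
        )

    cycles = []
    for a, b in zip(feet[:-1], feet[1:]):
        seg = p[a : b + 1].copy()  # include the next foot for detrending
        L = seg.size - 1
        seg -= (seg[-1] - seg[0]) * np.arange(L + 1) / L
        cycles.append(seg)

    n_out = int(round(np.median([c.size - 1 for c in cycles])))
    phases = np.arange(n_out) / n_out
    resampled = np.vstack(
        [np.interp(phases * (c.size - 1), np.arange(c.size), c) for c in cycles]
    )
    return PressureWave(fs, n_out / fs, resampled.mean(axis=0))


def calibrate_wave(wave: PressureWave, DBP_ref: float, MBP_ref: float) -> PressureWave:
    """Affine recalibration so that min = DBP_ref and mean = MBP_ref.

    The transform ``p' = a*p + b`` with ``a = (MBP_ref - DBP_ref)/(mean - min)``
    preserves the normalised waveform shape.
    """
    if not MBP_ref > DBP_ref:
        raise ValueError("require MBP_ref > DBP_ref")
    p = np.asarray(wave.samples, dtype=float)
    mn, mu = p.min(), p.mean()
    if mu - mn <= 1e-12 * max(abs(mu), 1.0):
        raise DataError("flat wave cannot be calibrated (mean equals min)")
    a = (MBP_ref - DBP_ref) / (mu - mn)
    b = DBP_ref - a * mn
    return PressureWave(wave.fs, wave.T, a * p + b, n_beats=wave.n_beats)
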