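"""Estimators of the diastolic decay time constant.

Three routes to tau per subject, plus the pulse-pressure-method compliance
estimator:

- ``tau_reference``: the ground-truth product R*C.
- ``fit_diastolic_decay``: mono-exponential fit to the diastolic limb of the
  pressure wave (log-linear least squares by default).
- ``tau_formula``: the closed-form estimate k' * T * MBP / cPP from routine
  pressure features.  In consistent seconds units the dimensionless k' equals
  the per-subject ratio C*cPP/SV, so plugging that exact ratio back in
  recovers R*C identically.
- ``ppm_compliance``: total arterial compliance by matching the measured
  pulse pressure with the pulse pressure of a two-element Windkessel driven
  by the measured flow; predicted PP decreases strictly with C, so the match
  is a bracketed root find.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import DataError, FitError
from .windkessel import (
    FlowWave,
    PressureWave,
    WindkesselParams,
    solve_wk2_fourier,
    solve_wk2_periodic,
)

__all__ = [
    "TauEstimates",
    "DecayFitConfig",
    "fit_diastolic_decay",
    "ppm_compliance",
    "peripheral_resistance",
    "tau_formula",
    "tau_reference",
]


@dataclass(frozen=True)
class TauEstimates:
    """The per-subject tau battery (s) plus the PPM compliance inputs."""

    tau_ref: float
    tau_exp: float | None = None
    tau_formula: float | None = None
    C_ppm: float | None = None
    R_est: float | None = None


@dataclass(frozen=True)
class DecayFitConfig:
    """Diastolic fit window as fractions of the period, and the fit method.

    The window starts ``window_start * T`` after ejection end to skip the
    incisura region, and ``method`` is ``"log_linear"`` (default,
    deterministic) or ``"nonlinear_ls"``.
    """

    window_start: float = 0.05
    window_end: float = 1.0
    method: str = "log_linear"

    def __post_init__(self) -> None:
        if not 0 <= self.window_start < self.window_end <= 1:
            raise ValueError("require 0 <= window_start < window_end <= 1")
        if self.method not in ("log_linear", "nonlinear_ls"):
            raise ValueError(f"unknown decay fit method {self.method!r}")


def fit_diastolic_decay(
    wave: PressureWave, ts: float, cfg: DecayFitConfig = DecayFitConfig()
) -> float:
    """Fit ``P(t) = P0 * exp(-t/tau)`` over the diastolic window; return tau (s)."""
    t = wave.times
    sel = (t >= ts + cfg.window_start * wave.T) & (t <= cfg.window_end * wave.T)
    if sel.sum() < 10:
        raise DataError(
            f"diastolic window holds {int(sel.sum())} samples; need >= 10"
        )
    td, pd_ = t[sel], np.asarray(wave.samples)[sel]

    if cfg.method == "log_linear":
        if np.any(pd_ <= 0):
            raise FitError(
                "non-positive pressures in the diastolic window; "
                "use method='nonlinear_ls'"
            )
        slope, _ = np.polyfit(td, np.log(pd_), 1)
        if slope >= 0:
            raise FitError("diastolic window is not decaying (fitted tau <= 0)")
        return -1.0 / slope

    # nonlinear least squares, seeded from a crude two-point estimate
    p0 = max(pd_[0], 1e-6)
    tau0 = (td[-1] - td[0]) / max(np.log(max(pd_[0], 1e-9) / max(pd_[-1], 1e-9)), 1e-6)
    try:
        (p0_hat, tau_hat), _ = optimize.curve_fit(
            lambda t_, a, tau: a * np.exp(-(t_ - td[0]) / tau),
            td, pd_, p0=(p0, abs(tau0)), maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitError(f"nonlinear decay fit did not converge: {exc}") from exc
    if tau_hat <= 0:
        raise FitError("diastolic window is not decaying (fitted tau <= 0)")
    return float(tau_hat)


def ppm_compliance(
    pressure: PressureWave,
    flow: FlowWave,
    R: float,
    n_harmonics: int | None = None,
    c_bounds: tuple[float, float] = (1e-3, 50.0),
    pp_tol: float = 1e-8,
) -> float:
    """Pulse pressure method: the compliance whose Windkessel PP matches.

    With ``n_harmonics`` set, the flow is truncated to that many harmonics
    (classically 5) and the Windkessel is solved spectrally; otherwise the
    analytic full-waveform solution is used.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if abs(pressure.T - flow.T) > 1e-9 * flow.T:
        raise ValueError("pressure and flow must share the heart period")
    p = np.asarray(pressure.samples, dtype=float)
    pp_meas = float(p.max() - p.min())
    if pp_meas <= 0:
        raise DataError("measured pulse pressure must be positive")

    use_fourier = n_harmonics is not None or flow.shape not in ("half_sine", "triangular")

    def predicted_pp(c: float) -> float:
        if use_fourier:
            w = solve_wk2_fourier(R, c, flow, n_harmonics)
        else:
            params = WindkesselParams(R, c, flow.T, flow.ts, flow.SV)
            w = solve_wk2_periodic(params, flow)
        return float(np.ptp(w.samples))

    lo, hi = c_bounds
    f_lo, f_hi = predicted_pp(lo) - pp_meas, predicted_pp(hi) - pp_meas
    if f_lo < 0 or f_hi > 0:
        raise FitError(
            "measured pulse pressure outside the attainable Windkessel range: "
            f"PP={pp_meas:.3f} mmHg vs predicted [{f_hi + pp_meas:.3f}, "
            f"{f_lo + pp_meas:.3f}] for C in [{lo}, {hi}] mL/mmHg"
        )
    c_hat = optimize.brentq(
        lambda c: predicted_pp(c) - pp_meas, lo, hi, xtol=1e-12, rtol=1e-14
    )
    if abs(predicted_pp(c_hat) - pp_meas) > max(pp_tol, 1e-12 * pp_meas):
        raise FitError("pulse pressure match did not reach tolerance")
    return float(c_hat)


def peripheral_resistance(MBP, CO):
    """Total peripheral resistance R = MBP / CO (mmHg*s/mL; CO in mL/s)."""
    MBP = np.asarray(MBP, dtype=float)
    CO = np.asarray(CO, dtype=float)
    if np.any(CO <= 0):
        raise ValueError("cardiac output must be positive")
    out = MBP / CO
    return float(out) if out.ndim == 0 else out


def tau_formula(T, MBP, cPP, kprime):
    """Closed-form time constant tau = k' * T * MBP / cPP (seconds).

    ``k'`` is the dimensionless compliance coefficient; with heart rate in
    beats/min the equivalent coefficient is 60 times larger.
    """
    T = np.asarray(T, dtype=float)
    MBP = np.asarray(MBP, dtype=float)
    cPP = np.asarray(cPP, dtype=float)
    kprime = np.asarray(kprime, dtype=float)
    if np.any(cPP <= 0):
        raise ValueError("central pulse pressure must be positive")
    if np.any(T <= 0) or np.any(MBP <= 0) or np.any(kprime <= 0):
        raise ValueError("T, MBP and kprime must be positive")
    out = kprime * T * MBP / cPP
    return float(out) if out.ndim == 0 else out


def tau_reference(R, C):
    """Ground-truth time constant tau = R*C (s)."""
    R = np.asarray(R, dtype=float)
    C = np.asarray(C, dtype=float)
    if np.any(R <= 0) or np.any(C <= 0):
        raise ValueError("R and C must be positive")
    out = R * C
    return float(out) if out.ndim == 0 else out
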