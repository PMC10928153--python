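"""Two-element Windkessel engine.

The arterial tree is lumped into a total compliance ``C`` in parallel with a
peripheral resistance ``R``, driven by the ventricular ejection flow ``Q``:

    C dP/dt = Q(t) - P/R

Diastole (``Q = 0``) therefore decays mono-exponentially with time constant
``tau = R*C``, which makes this model the natural ground-truth generator for
studies of the diastolic pressure decay: the reference time constant is exact
by construction.

The periodic steady-state solution is computed in closed form.  Because the
ODE is linear, the response from a zero initial state, ``p_zero(t)``, fully
determines the periodic solution:

    P(t) = p_zero(t) + P0 * exp(-t/tau),   P0 = p_zero(T) / (1 - exp(-T/tau))

so no time stepping is involved and the diastolic limb is exactly exponential
down to machine precision.  Two parametric ejection profiles are provided
(half-sine and triangular); both admit analytic ``p_zero``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = [
    "WindkesselParams",
    "FlowWave",
    "PressureWave",
    "half_sine_flow",
    "triangular_flow",
    "solve_wk2_periodic",
    "solve_wk2_fourier",
]

DEFAULT_FS = 1000.0  # Hz; resolves systole with >= 200 samples at rest


@dataclass(frozen=True)
class WindkesselParams:
    """Ground-truth hemodynamics of one subject.

    Attributes
    ----------
    R : float
        Total peripheral resistance, mmHg*s/mL.
    C : float
        Total arterial compliance, mL/mmHg.
    T : float
        Heart period, s.
    ts : float
        Ejection (systolic outflow) duration, s; ``0 < ts < T``.
    SV : float
        Stroke volume, mL.
    """

    R: float
    C: float
    T: float
    ts: float
    SV: float

    def __post_init__(self) -> None:
        if not (self.R > 0 and self.C > 0 and self.T > 0):
            raise ValueError("R, C and T must be positive")
        if self.SV < 0:
            raise ValueError("SV must be non-negative")
        if not (0 < self.ts < self.T):
            raise ValueError(
                f"ejection duration ts={self.ts} must lie strictly inside (0, T={self.T})"
            )

    @property
    def tau(self) -> float:
        """Decay time constant tau = R*C (s); derived, never stored."""
        return self.R * self.C


@dataclass
class FlowWave:
    """One period of ejection flow, uniformly sampled.

    ``samples`` holds flow in mL/s at times ``k/fs`` for ``k = 0..N-1`` with
    ``N = round(fs*T)``; flow is zero on ``(ts, T]`` and non-negative
    everywhere, and its integral over the period equals ``SV``.
    """

    shape: str  # "half_sine" | "triangular" | "custom"
    T: float
    ts: float
    SV: float
    fs: float
    samples: np.ndarray = field(repr=False)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class PressureWave:
    """Pressure signal in mmHg sampled at ``fs``.

    A clean single-cycle wave starts at ejection onset (t = 0), hence the
    pressure minimum sits at/near the first sample.  Multi-beat recordings
    (``n_beats > 1``) may carry jittered cycle lengths, so ``T`` is then the
    nominal period only.
    """

    fs: float
    T: float
    samples: np.ndarray = field(repr=False)
    n_beats: int = 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


def _flow_grid(T: float, ts: float, SV: float, fs: float) -> np.ndarray:
    if not (0 < ts < T):
        raise ValueError(f"invalid ejection: need 0 < ts < T, got ts={ts}, T={T}")
    if SV < 0:
        raise ValueError("SV must be non-negative")
    if fs * ts < 10:
        raise DataError(
            f"sampling rate {fs} Hz resolves systole with only {fs * ts:.1f} "
            "samples (< 10); increase fs"
        )
    # snap the spacing so the grid tiles the period exactly (n*dt == T);
    # the effective rate n/T differs from the requested fs by < 0.1%
    n = round(fs * T)
    return np.arange(n) * (T / n)


def half_sine_flow(T: float, ts: float, SV: float, fs: float = DEFAULT_FS) -> FlowWave:
    """Half-sine ejection: Q(t) = (pi*SV / (2*ts)) * sin(pi*t/ts) on [0, ts].

    The amplitude normalises the integral to exactly ``SV``.
    """
    t = _flow_grid(T, ts, SV, fs)
    q = np.zeros_like(t)
    sys = t <= ts
    q[sys] = (np.pi * SV / (2.0 * ts)) * np.sin(np.pi * t[sys] / ts)
    np.clip(q, 0.0, None, out=q)  # guard the t == ts round-off
    return FlowWave("half_sine", T, ts, SV, t.size / T, q)


def triangular_flow(T: float, ts: float, SV: float, fs: float = DEFAULT_FS) -> FlowWave:
    """Symmetric triangular ejection peaking at ts/2 with height 2*SV/ts."""
    t = _flow_grid(T, ts, SV, fs)
    q = np.zeros_like(t)
    m = 4.0 * SV / ts**2  # rising/falling slope magnitude
    up = t <= ts / 2.0
    down = (t > ts / 2.0) & (t <= ts)
    q[up] = m * t[up]
    q[down] = m * (ts - t[down])
    return FlowWave("triangular", T, ts, SV, t.size / T, q)


def _pzero_half_sine(t, R, C, T, ts, SV):
    """Zero-initial-state response to half-sine ejection, and its value at T."""
    tau = R * C
    w = np.pi / ts
    amp = np.pi * SV / (2.0 * ts)
    d = R * amp / (1.0 + (w * tau) ** 2)
    b = d * w * tau
    p = np.empty_like(t)
    sys = t <= ts
    td = t[sys]
    p[sys] = d * (np.sin(w * td) - w * tau * np.cos(w * td)) + b * np.exp(-td / tau)
    pz_ts = b * (1.0 + np.exp(-ts / tau))
    p[~sys] = pz_ts * np.exp(-(t[~sys] - ts) / tau)
    return p, pz_ts * np.exp(-(T - ts) / tau)


def _pzero_triangular(t, R, C, T, ts, SV):
    """Zero-initial-state response to the triangular ejection profile.

    Each affine forcing segment Q = a + b*t has particular solution
    ``R*(a + b*t) - R*tau*b``; segment constants follow from continuity.
    """
    tau = R * C
    m = 4.0 * SV / ts**2
    h = ts / 2.0
    p = np.empty_like(t)

    s1 = t <= h
    t1 = t[s1]
    # segment 1: Q = m*t, P(0) = 0
    p[s1] = R * tau * m * np.exp(-t1 / tau) + R * m * (t1 - tau)
    v1 = R * tau * m * np.exp(-h / tau) + R * m * (h - tau)

    s2 = (t > h) & (t <= ts)
    t2 = t[s2]
    # segment 2: Q = m*(ts - t)
    pp2 = lambda u: R * m * (ts - u) + R * tau * m  # noqa: E731
    p[s2] = (v1 - pp2(h)) * np.exp(-(t2 - h) / tau) + pp2(t2)
    v2 = (v1 - pp2(h)) * np.exp(-(ts - h) / tau) + pp2(ts)

    s3 = t > ts
    p[s3] = v2 * np.exp(-(t[s3] - ts) / tau)
    return p, v2 * np.exp(-(T - ts) / tau)


_PZERO = {"half_sine": _pzero_half_sine, "triangular": _pzero_triangular}


def solve_wk2_periodic(
    params: WindkesselParams, flow: FlowWave, fs: float | None = None
) -> PressureWave:
    """Closed-form periodic solution of ``C dP/dt = Q(t) - P/R``.

    The periodic boundary condition ``P(0) = P(T)`` is solved linearly for the
    initial pressure, so periodicity holds to round-off and the diastolic
    segment equals ``P(ts) * exp(-(t - ts)/tau)`` exactly.
    """
    if abs(flow.T - params.T) > 1e-9 * params.T or abs(flow.ts - params.ts) > 1e-9 * params.T:
        raise ValueError("flow wave and Windkessel parameters disagree on T or ts")
    if flow.shape not in _PZERO:
        raise ValueError(f"no analytic solution for flow shape {flow.shape!r}; "
                         "use solve_wk2_fourier for sampled flows")
    fs = flow.fs if fs is None else fs
    n = round(fs * params.T)
    t = np.arange(n) * (params.T / n)
    fs_eff = n / params.T
    if params.SV == 0:
        return PressureWave(fs_eff, params.T, np.zeros_like(t))
    pz, pz_T = _PZERO[flow.shape](t, params.R, params.C, params.T, params.ts, params.SV)
    tau = params.tau
    p0 = pz_T / -np.expm1(-params.T / tau)
    return PressureWave(fs_eff, params.T, pz + p0 * np.exp(-t / tau))


def solve_wk2_fourier(
    R: float, C: float, flow: FlowWave, n_harmonics: int | None = None
) -> PressureWave:
    """Periodic solution for an arbitrary sampled flow, in the frequency domain.

    The transfer function of the two-element Windkessel at harmonic ``k`` is
    ``R / (1 + i*2*pi*k/T * R*C)``.  With ``n_harmonics`` given, flow content
    above that harmonic is discarded (the classical low-frequency variant of
    the pulse pressure method keeps harmonics 0-5).
    """
    if R <= 0 or C <= 0:
        raise ValueError("R and C must be positive")
    q = np.asarray(flow.samples, dtype=float)
    qh = np.fft.rfft(q)
    k = np.arange(qh.size)
    if n_harmonics is not None:
        qh = qh.copy()
        qh[k > n_harmonics] = 0.0
    w = 2.0 * np.pi * k / flow.T
    ph = qh * R / (1.0 + 1j * w * R * C)
    p = np.fft.irfft(ph, n=q.size)
    return PressureWave(flow.fs, flow.T, p)
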