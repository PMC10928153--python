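"""Seeded virtual cohorts for the time-constant analysis.

Each virtual subject is a two-element Windkessel whose parameters are drawn
independently from distributions matched to the moments of a healthy adult
population: total peripheral resistance R ~ 1 +/- 0.2 mmHg*s/mL, total
arterial compliance C ~ 1.1 +/- 0.5 mL/mmHg, heart period T ~ 0.7 +/- 0.1 s,
stroke volume SV ~ 70 +/- 14 mL (all truncated normals).  The ground-truth
decay time constant is tau = R*C by construction.

Ejection duration follows by default a Weissler-type systolic-time-interval
relation, LVET = 0.413 - 0.0017*HR seconds plus subject jitter: absolute
ejection time varies far less than the heart period, so the ejected fraction
of the cycle rises with heart rate.  This coupling is what imprints the weak
heart-rate dependence of the compliance coefficient k = C*cPP/SV on the
cohort; an independent uniform ts/T draw is available as an alternative mode.

Optional layers emulate non-ideal acquisition: multi-beat tiling with cycle
jitter, white sensor noise and slow baseline drift (tonometry), cuff
calibration error, and a scalar brachial pulse-pressure amplification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .windkessel import (
    DEFAULT_FS,
    FlowWave,
    PressureWave,
    WindkesselParams,
    half_sine_flow,
    solve_wk2_periodic,
    triangular_flow,
)

__all__ = [
    "Distribution",
    "EjectionModel",
    "NoiseConfig",
    "PopulationConfig",
    "VirtualSubject",
    "default_distributions",
    "generate_population",
    "add_measurement_noise",
    "brachial_surrogate",
]

#: Columns of the cohort ground-truth table, in order.
COHORT_COLUMNS = ["id", "age", "gender", "R", "C", "tau_true", "T_s", "ts_s", "SV_ml", "bpp_factor"]


@dataclass(frozen=True)
class Distribution:
    """One marginal parameter distribution.

    family: ``"normal_truncated"`` (location/scale = untruncated mean/SD,
    hard bounds ``lower``/``upper``) or ``"uniform"`` (on [lower, upper]).
    """

    family: str
    location: float = 0.0
    scale: float = 1.0
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.family not in ("normal_truncated", "uniform"):
            raise ConfigError(f"unknown distribution family {self.family!r}")
        if not self.lower < self.upper:
            raise ConfigError("distribution requires lower < upper")
        if self.family == "normal_truncated" and self.scale <= 0:
            raise ConfigError("truncated normal requires scale > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "uniform":
            return rng.uniform(self.lower, self.upper, n)
        a = (self.lower - self.location) / self.scale
        b = (self.upper - self.location) / self.scale
        return stats.truncnorm.rvs(
            a, b, loc=self.location, scale=self.scale, size=n, random_state=rng
        )


def default_distributions() -> dict[str, Distribution]:
    """Marginals matched to healthy-adult moments; bounds keep physiology positive."""
    return {
        "R": Distribution("normal_truncated", 1.0, 0.2, 0.4, 1.8),
        "C": Distribution("normal_truncated", 1.1, 0.5, 0.3, 3.0),
        "T": Distribution("normal_truncated", 0.7, 0.1, 0.45, 1.1),
        "SV": Distribution("normal_truncated", 70.0, 14.0, 35.0, 120.0),
        "ts_fraction": Distribution("uniform", lower=0.30, upper=0.40),
    }


@dataclass(frozen=True)
class EjectionModel:
    """How ejection duration is assigned.

    mode="lvet" (default): ts = intercept + slope*HR + N(0, jitter_sd),
    clipped to [min_fraction, max_fraction] of T (Weissler-type relation,
    seconds and beats/min).  mode="fraction": ts = ts_fraction * T with
    ts_fraction drawn from the configured distribution, independent of T.
    """

    mode: str = "lvet"
    intercept: float = 0.413
    slope: float = -0.0017
    jitter_sd: float = 0.01
    min_fraction: float = 0.20
    max_fraction: float = 0.45

    def __post_init__(self) -> None:
        if self.mode not in ("lvet", "fraction"):
            raise ConfigError(f"unknown ejection mode {self.mode!r}")
        if not 0 < self.min_fraction < self.max_fraction < 1:
            raise ConfigError("ejection fractions must satisfy 0 < min < max < 1")
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-imperfection magnitudes (all >= 0; zero disables a term)."""

    white_sd: float = 0.0  # mmHg, additive white noise
    drift_amplitude: float = 0.0  # mmHg, baseline excursion across the recording
    cycle_jitter_sd: float = 0.0  # fraction of T, beat-length variability
    calibration_dbp_sd: float = 0.0  # mmHg, cuff DBP anchor error
    calibration_mbp_sd: float = 0.0  # mmHg, cuff MBP anchor error

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigError(f"noise parameter {f.name} must be >= 0")


@dataclass(frozen=True)
class PopulationConfig:
    n: int = 3818
    seed: int = 1
    distributions: dict[str, Distribution] = field(default_factory=default_distributions)
    ejection: EjectionModel = field(default_factory=EjectionModel)
    noise: NoiseConfig | None = None
    brachial_amplification: tuple[float, float] = (57.0 / 45.0, 0.05)  # (mean, sd)
    age_range: tuple[float, float] = (35.0, 55.0)
    male_fraction: float = 0.5
    age_c_slope: float = 0.0  # fractional change in C per year of age offset
    flow_shape: str = "half_sine"
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError("population size must be >= 2")
        missing = {"R", "C", "T", "SV", "ts_fraction"} - set(self.distributions)
        if missing:
            raise ConfigError(f"distributions missing for parameters: {sorted(missing)}")
        if not 0 <= self.male_fraction <= 1:
            raise ConfigError("male_fraction must lie in [0, 1]")
        if self.brachial_amplification[0] <= 0:
            raise ConfigError("brachial amplification mean must be > 0")
        if self.flow_shape not in ("half_sine", "triangular"):
            raise ConfigError(f"unknown flow shape {self.flow_shape!r}")
        for name in ("R", "C", "T", "SV"):
            if self.distributions[name].lower <= 0:
                raise ConfigError(f"distribution for {name} must be bounded away from 0")
        tf = self.distributions["ts_fraction"]
        if not (0 < tf.lower < tf.upper < 1):
            raise ConfigError("ts_fraction bounds must lie in (0, 1)")


@dataclass
class VirtualSubject:
    """One simulated subject: ground truth plus its waveforms."""

    id: int
    age: float
    gender: str
    params: WindkesselParams
    pressure: PressureWave
    flow: FlowWave
    bpp_factor: float

    @property
    def tau_true(self) -> float:
        return self.params.tau


_FLOW_MAKERS = {"half_sine": half_sine_flow, "triangular": triangular_flow}


def generate_population(
    config: PopulationConfig,
) -> tuple[pd.DataFrame, list[VirtualSubject]]:
    """Draw a seeded cohort and solve each subject's periodic pressure.

    Returns the ground-truth table (one row per subject, columns
    ``COHORT_COLUMNS``) and the list of subjects carrying the waveforms.
    Regeneration with the same config is bit-identical: all draws come from a
    single ``numpy`` Generator seeded with ``config.seed`` in a fixed order.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    d = config.distributions
    R = d["R"].sample(rng, n)
    C = d["C"].sample(rng, n)
    T = d["T"].sample(rng, n)

    ej = config.ejection
    if ej.mode == "lvet":
        hr = 60.0 / T
        ts = ej.intercept + ej.slope * hr + rng.normal(0.0, ej.jitter_sd, n)
        ts = np.clip(ts, ej.min_fraction * T, ej.max_fraction * T)
    else:
        ts = d["ts_fraction"].sample(rng, n) * T

    SV = d["SV"].sample(rng, n)
    age = rng.uniform(config.age_range[0], config.age_range[1], n)
    gender = np.where(rng.random(n) < config.male_fraction, "M", "F")
    amp_mean, amp_sd = config.brachial_amplification
    bpp_factor = np.clip(rng.normal(amp_mean, amp_sd, n), 0.5, None)

    if config.age_c_slope != 0.0:
        mid = 0.5 * (config.age_range[0] + config.age_range[1])
        C = np.clip(C * (1.0 + config.age_c_slope * (age - mid)), d["C"].lower, None)

    make_flow = _FLOW_MAKERS[config.flow_shape]
    subjects: list[VirtualSubject] = []
    for i in range(n):
        params = WindkesselParams(R[i], C[i], T[i], ts[i], SV[i])
        flow = make_flow(T[i], ts[i], SV[i], config.fs)
        pressure = solve_wk2_periodic(params, flow)
        subjects.append(
            VirtualSubject(i, float(age[i]), str(gender[i]), params, pressure, flow,
                           float(bpp_factor[i]))
        )

    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": age,
            "gender": gender,
            "R": R,
            "C": C,
            "tau_true": R * C,
            "T_s": T,
            "ts_s": ts,
            "SV_ml": SV,
            "bpp_factor": bpp_factor,
        }
    )
    return table, subjects


def add_measurement_noise(
    wave: PressureWave,
    noise: NoiseConfig,
    seed: int,
    duration: float = 20.0,
) -> PressureWave:
    """Tile a clean cycle into a ~``duration``-second noisy recording.

    Beat lengths are jittered multiplicatively (``cycle_jitter_sd``), each
    beat being the clean cycle resampled to the jittered length; white noise
    is added per sample and a linear baseline drift spans ``drift_amplitude``
    mmHg across the recording.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    fs, T = wave.fs, wave.T
    cycle = np.asarray(wave.samples, dtype=float)
    m = cycle.size
    beats: list[np.ndarray] = []
    total = 0
    n_target = round(duration * fs)
    while total < n_target:
        factor = 1.0 + (rng.normal(0.0, noise.cycle_jitter_sd) if noise.cycle_jitter_sd else 0.0)
        li = max(4, round(m * factor))
        if li == m:
            beat = cycle
        else:
            # resample by phase so the beat keeps its morphology
            phase = np.arange(li) * m / li
            beat = np.interp(phase, np.arange(m + 1), np.append(cycle, cycle[0]))
        beats.append(beat)
        total += li
    rec = np.concatenate(beats)
    n_beats = len(beats)
    if noise.white_sd:
        rec = rec + rng.normal(0.0, noise.white_sd, rec.size)
    if noise.drift_amplitude:
        u = np.arange(rec.size) / max(rec.size - 1, 1)
        rec = rec + noise.drift_amplitude * (u - 0.5)
    return PressureWave(fs, T, rec, n_beats=n_beats)


def brachial_surrogate(cPP, amplification):
    """Brachial pulse pressure as a scalar amplification of central PP.

    Both arguments may be scalars or arrays; all values must be positive.
    """
    cPP = np.asarray(cPP, dtype=float)
    amplification = np.asarray(amplification, dtype=float)
    if np.any(cPP <= 0) or np.any(amplification <= 0):
        raise ValueError("central PP and amplification must be positive")
    out = cPP * amplification
    return float(out) if out.ndim == 0 else out
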