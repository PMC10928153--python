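"""CSV and YAML interfaces.

All tables travel as headed CSV written with 9 significant digits so that a
write/read round trip is lossless at that precision; readers validate the
header and name every missing column.  Waveforms use the two/three-column
schema ``time_s, pressure_mmHg[, flow_ml_s]``.  Experiment configuration is
plain YAML mirroring the config dataclasses field for field.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .population import (
    Distribution,
    EjectionModel,
    NoiseConfig,
    PopulationConfig,
)
from .windkessel import FlowWave, PressureWave

__all__ = [
    "COHORT_SCHEMA",
    "FEATURE_SCHEMA",
    "TAU_SCHEMA",
    "write_table",
    "read_table",
    "write_waveform",
    "read_waveform",
    "population_config_from_dict",
    "population_config_to_dict",
    "load_yaml",
    "dump_yaml",
]

FLOAT_FORMAT = "%.9g"

COHORT_SCHEMA = ["id", "age", "gender", "R", "C", "tau_true", "T_s", "ts_s", "SV_ml"]
FEATURE_SCHEMA = ["id", "SBP", "DBP", "MBP", "cPP", "bPP", "T_s", "HR_bpm"]
TAU_SCHEMA = ["id", "tau_ref", "tau_exp", "tau_formula", "C_ppm", "R_est"]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_table(path, schema: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ConfigError(
                f"{Path(path).name}: missing required columns {missing}; "
                f"found {list(df.columns)}"
            )
    return df


def write_waveform(path, pressure: PressureWave, flow: FlowWave | None = None) -> Path:
    cols = {"time_s": pressure.times, "pressure_mmHg": pressure.samples}
    if flow is not None:
        if flow.samples.size != pressure.samples.size:
            raise ValueError("pressure and flow waveforms differ in length")
        cols["flow_ml_s"] = flow.samples
    return write_table(pd.DataFrame(cols), path)


def read_waveform(path) -> PressureWave:
    df = read_table(path, ["time_s", "pressure_mmHg"])
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ConfigError(f"{Path(path).name}: waveform needs >= 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ConfigError(f"{Path(path).name}: waveform must be uniformly sampled")
    fs = 1.0 / dt[0]
    return PressureWave(fs=fs, T=t.size / fs, samples=df["pressure_mmHg"].to_numpy())


# --- configuration ---------------------------------------------------------


def _dist_to_dict(d: Distribution) -> dict:
    return dataclasses.asdict(d)


def population_config_to_dict(cfg: PopulationConfig) -> dict:
    out = {
        "n": cfg.n,
        "seed": cfg.seed,
        "distributions": {k: _dist_to_dict(v) for k, v in cfg.distributions.items()},
        "ejection": dataclasses.asdict(cfg.ejection),
        "noise": None if cfg.noise is None else dataclasses.asdict(cfg.noise),
        "brachial_amplification": list(cfg.brachial_amplification),
        "age_range": list(cfg.age_range),
        "male_fraction": cfg.male_fraction,
        "age_c_slope": cfg.age_c_slope,
        "flow_shape": cfg.flow_shape,
        "fs": cfg.fs,
    }
    return out


def population_config_from_dict(data: dict) -> PopulationConfig:
    data = dict(data)
    problems: list[str] = []
    kwargs: dict = {}
    try:
        if "distributions" in data:
            base = PopulationConfig().distributions
            for k, v in data.pop("distributions").items():
                try:
                    base[k] = Distribution(**v)
                except (TypeError, ConfigError) as exc:
                    problems.append(f"distributions.{k}: {exc}")
            kwargs["distributions"] = base
        if "ejection" in data:
            kwargs["ejection"] = EjectionModel(**data.pop("ejection"))
        if (noise := data.pop("noise", None)) is not None:
            kwargs["noise"] = NoiseConfig(**noise)
        for key in ("brachial_amplification", "age_range"):
            if key in data:
                kwargs[key] = tuple(data.pop(key))
        kwargs.update(data)
        if problems:
            raise ConfigError("invalid population config: " + "; ".join(problems))
        return PopulationConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid population config: {exc}") from exc


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{Path(path).name}: expected a YAML mapping")
    return data


def dump_yaml(data: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
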