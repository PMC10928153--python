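"""End-to-end experiment orchestration.

The workflow mirrors the two-stage design of the underlying study: derive
the compliance coefficient k' by origin-constrained fitting on a clean
virtual population, then evaluate the fixed-coefficient formula on a
held-out cohort processed through the full measurement chain (multi-beat
noisy recording -> beat averaging -> cuff calibration -> feature
extraction), scoring the estimates with the agreement battery.

Every stage is a plain function over dataframes so the analysis scripts,
the CLI and the tests all drive the same code; ``run_experiment`` wires the
stages together, writes the table analogues and figures, and records a
manifest with every seed so a rerun is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import evaluate_by_group
from .errors import ConfigError
from .features import average_beats, calibrate_wave, extract_features
from .fitting import fit_kprime, mbp_sensitivity, predictor, subgroup_fits
from .io import population_config_from_dict, population_config_to_dict, write_table
from .population import (
    NoiseConfig,
    PopulationConfig,
    VirtualSubject,
    add_measurement_noise,
    generate_population,
)
from .tau import DecayFitConfig, fit_diastolic_decay, ppm_compliance, tau_formula

__all__ = [
    "ExperimentConfig",
    "cohort_with_features",
    "tau_table",
    "fit_tables",
    "evaluate_fixed_kprime",
    "run_experiment",
]

logger = logging.getLogger(__name__)

DEFAULT_EVAL_NOISE = NoiseConfig(
    white_sd=1.0,
    drift_amplitude=3.0,
    cycle_jitter_sd=0.02,
    calibration_dbp_sd=2.0,
    calibration_mbp_sd=2.0,
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Derivation and evaluation cohorts plus fitting/evaluation options."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    evaluation: PopulationConfig = field(
        default_factory=lambda: PopulationConfig(n=2263, seed=2, noise=DEFAULT_EVAL_NOISE)
    )
    kprime_fixed: float = 0.7
    compute_decay: bool = True
    compute_ppm: bool = True
    decay: DecayFitConfig = field(default_factory=DecayFitConfig)

    def __post_init__(self) -> None:
        if self.population.seed == self.evaluation.seed:
            raise ConfigError(
                "derivation and evaluation cohorts must use distinct seeds"
            )
        if not self.kprime_fixed > 0:
            raise ConfigError("kprime_fixed must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        kwargs: dict = {}
        if "population" in data:
            kwargs["population"] = population_config_from_dict(data.pop("population"))
        if "evaluation" in data:
            kwargs["evaluation"] = population_config_from_dict(data.pop("evaluation"))
        if "decay" in data:
            kwargs["decay"] = DecayFitConfig(**data.pop("decay"))
        unknown = set(data) - {"kprime_fixed", "compute_decay", "compute_ppm"}
        if unknown:
            raise ConfigError(f"unknown experiment config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "population": population_config_to_dict(self.population),
            "evaluation": population_config_to_dict(self.evaluation),
            "kprime_fixed": self.kprime_fixed,
            "compute_decay": self.compute_decay,
            "compute_ppm": self.compute_ppm,
            "decay": dataclasses.asdict(self.decay),
        }


def cohort_with_features(
    config: PopulationConfig,
) -> tuple[pd.DataFrame, list[VirtualSubject]]:
    """Generate a cohort and append noiseless waveform features to its table.

    Adds SBP, DBP, MBP (waveform mean), cPP, bPP (= cPP x per-subject
    amplification) and HR_bpm to the ground-truth table.
    """
    table, subjects = generate_population(config)
    feats = [extract_features(s.pressure) for s in subjects]
    table = table.assign(
        SBP=[f.SBP for f in feats],
        DBP=[f.DBP for f in feats],
        MBP=[f.MBP for f in feats],
        cPP=[f.cPP for f in feats],
        HR_bpm=[f.HR for f in feats],
    )
    table["bPP"] = table["cPP"] * table["bpp_factor"]
    return table, subjects


def tau_table(
    cohort: pd.DataFrame,
    subjects: list[VirtualSubject],
    kprime: float,
    compute_decay: bool = True,
    compute_ppm: bool = True,
    decay: DecayFitConfig = DecayFitConfig(),
) -> pd.DataFrame:
    """Per-subject tau battery: reference, decay fit, formula, PPM compliance."""
    out = {
        "id": cohort["id"].to_numpy(),
        "tau_ref": cohort["tau_true"].to_numpy(),
        "tau_formula": tau_formula(
            cohort["T_s"].to_numpy(),
            cohort["MBP"].to_numpy(),
            cohort["cPP"].to_numpy(),
            kprime,
        ),
    }
    co = cohort["SV_ml"].to_numpy() / cohort["T_s"].to_numpy()  # mL/s
    out["R_est"] = cohort["MBP"].to_numpy() / co
    if compute_decay:
        out["tau_exp"] = [
            fit_diastolic_decay(s.pressure, s.params.ts, decay) for s in subjects
        ]
    if compute_ppm:
        out["C_ppm"] = [
            ppm_compliance(s.pressure, s.flow, r)
            for s, r in zip(subjects, out["R_est"])
        ]
    cols = ["id", "tau_ref"] + [c for c in ("tau_exp",) if c in out] + ["tau_formula"]
    cols += [c for c in ("C_ppm",) if c in out] + ["R_est"]
    return pd.DataFrame({c: out[c] for c in cols})


def fit_tables(
    cohort: pd.DataFrame, tau_col: str = "tau_true"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The three fitting analyses on one cohort.

    Returns (overall/gender/age fits, HR & MBP tertile fits, MBP-formula
    sensitivity) as dataframes mirroring the layouts of the coefficient
    tables.
    """
    rows = []
    fit = fit_kprime(cohort[tau_col].to_numpy(), predictor(cohort).to_numpy())
    rows.append(("all", "all", fit.n, fit.kprime, fit.R2))
    for _, r in subgroup_fits(cohort, "gender", tau_col=tau_col).iterrows():
        rows.append(("gender", r["group"], r["n"], r["kprime"], r["R2"]))
    for _, r in subgroup_fits(cohort, "age", tau_col=tau_col).iterrows():
        rows.append(("age", r["group"], r["n"], r["kprime"], r["R2"]))
    table_fits = pd.DataFrame(rows, columns=["variable", "group", "n", "kprime", "R2"])

    table_tertiles = pd.concat(
        [subgroup_fits(cohort, "HR", tau_col=tau_col),
         subgroup_fits(cohort, "MBP", tau_col=tau_col)],
        ignore_index=True,
    )
    table_mbp = mbp_sensitivity(cohort, tau_col=tau_col)
    return table_fits, table_tertiles, table_mbp


def _measured_features(subject: VirtualSubject, config: PopulationConfig, rng):
    """Run one subject through the measurement chain; return a feature dict."""
    noise = config.noise
    clean = extract_features(subject.pressure)
    if noise is None:
        return {
            "SBP": clean.SBP, "DBP": clean.DBP, "MBP": clean.MBP,
            "cPP": clean.cPP, "T_s": clean.T, "HR_bpm": clean.HR,
        }
    rec = add_measurement_noise(
        subject.pressure, noise, seed=int(rng.integers(2**31))
    )
    cycle = average_beats(rec, smoothing=noise.white_sd > 0)
    dbp_ref = clean.DBP + rng.normal(0.0, noise.calibration_dbp_sd)
    mbp_ref = clean.MBP + rng.normal(0.0, noise.calibration_mbp_sd)
    if mbp_ref <= dbp_ref:  # cuff anchors must stay ordered
        mbp_ref = dbp_ref + max(clean.MBP - clean.DBP, 1.0)
    cycle = calibrate_wave(cycle, dbp_ref, mbp_ref)
    f = extract_features(cycle)
    return {
        "SBP": f.SBP, "DBP": f.DBP, "MBP": f.MBP,
        "cPP": f.cPP, "T_s": f.T, "HR_bpm": f.HR,
    }


def evaluate_fixed_kprime(
    config: PopulationConfig, kprime: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the fixed-coefficient formula to a held-out cohort.

    Each subject's wave passes through the configured measurement chain; the
    formula estimate ``kprime * T * MBP / cPP`` is compared with the
    ground-truth tau per demographic stratum.  Returns (agreement table,
    per-subject estimates).
    """
    table, subjects = generate_population(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5EED]).generate_state(1)[0]
    )
    feats = pd.DataFrame([_measured_features(s, config, rng) for s in subjects])
    est = table[["id", "age", "gender", "tau_true"]].copy()
    est = pd.concat([est, feats], axis=1)
    est["tau_est"] = tau_formula(
        est["T_s"].to_numpy(), est["MBP"].to_numpy(), est["cPP"].to_numpy(), kprime
    )
    report = evaluate_by_group(est, "tau_est", "tau_true")
    return report, est


def _figures(est: pd.DataFrame, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref, hat = est["tau_true"].to_numpy(), est["tau_est"].to_numpy()
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.2))
    lim = [0, max(ref.max(), hat.max()) * 1.05]
    axes[0].scatter(ref, hat, s=6, alpha=0.4)
    axes[0].plot(lim, lim, "k--", lw=1)
    axes[0].set(xlabel="reference tau = RC (s)", ylabel="estimated tau (s)",
                title="Formula vs reference", xlim=lim, ylim=lim)
    d = hat - ref
    m = (hat + ref) / 2
    bias, sd = d.mean(), d.std(ddof=1)
    axes[1].scatter(m, d, s=6, alpha=0.4)
    for y, style in ((bias, "-"), (bias + 1.96 * sd, "--"), (bias - 1.96 * sd, "--")):
        axes[1].axhline(y, color="k", ls=style, lw=1)
    axes[1].set(xlabel="mean of methods (s)", ylabel="difference (s)",
                title="Bland-Altman")
    fig.tight_layout()
    path = out_dir / "fig_agreement.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return [path]


def run_experiment(
    config: ExperimentConfig, output_dir, make_figures: bool = True
) -> dict:
    """Derive k', run the sensitivity analyses, evaluate on held-out data.

    Writes cohort/feature/tau CSVs, the three fit tables, the agreement
    table, optional figures and a manifest; returns the in-memory results.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("generating derivation cohort (n=%d, seed=%d)",
                config.population.n, config.population.seed)
    cohort, subjects = cohort_with_features(config.population)
    write_table(cohort, out / "cohort_derivation.csv")

    taus = tau_table(
        cohort, subjects, kprime=config.kprime_fixed,
        compute_decay=config.compute_decay, compute_ppm=config.compute_ppm,
        decay=config.decay,
    )
    write_table(taus, out / "tau_derivation.csv")

    fits, tertiles, mbp_sens = fit_tables(cohort)
    write_table(fits, out / "fit_overall.csv")
    write_table(tertiles, out / "fit_subgroups.csv")
    write_table(mbp_sens, out / "fit_mbp_formulas.csv")
    kprime_derived = float(fits.loc[0, "kprime"])

    logger.info("evaluating fixed k'=%.3f on held-out cohort (n=%d, seed=%d)",
                config.kprime_fixed, config.evaluation.n, config.evaluation.seed)
    report, est = evaluate_fixed_kprime(config.evaluation, config.kprime_fixed)
    write_table(report, out / "evaluation_agreement.csv")
    write_table(est, out / "evaluation_subjects.csv")

    figures = _figures(est, out) if make_figures else []

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "kprime_derived": kprime_derived,
        "kprime_fixed": config.kprime_fixed,
        "seeds": {
            "derivation": config.population.seed,
            "evaluation": config.evaluation.seed,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "cohort": cohort,
        "tau": taus,
        "fits": fits,
        "tertiles": tertiles,
        "mbp_sensitivity": mbp_sens,
        "kprime_derived": kprime_derived,
        "evaluation": report,
        "evaluation_subjects": est,
        "figures": figures,
        "output_dir": out,
    }
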