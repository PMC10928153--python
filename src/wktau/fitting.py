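"""Recovery of the compliance coefficient k' and its sensitivity analyses.

The time-constant formula tau = k' * T * MBP / cPP has no intercept, so k'
is recovered by least squares through the origin, k' = sum(x*tau)/sum(x^2)
with x = T*MBP/cPP.  Goodness of fit is reported as R^2 with the centred
total sum of squares so that values are comparable with ordinary regression
(an uncentred variant is available).

Subgroup fits split the cohort into heart-rate or mean-pressure tertiles
(equal thirds by sorted value, outer groups taking the remainder), age bins
(<40, 40-50, >50 years) or gender, and refit k' per group.  The MBP
sensitivity analysis refits k' once per clinical MBP estimation formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError
from .features import MBP_FORMULA_IDS, WAVEFORM_MEAN, estimate_mbp

__all__ = [
    "OriginFit",
    "fit_kprime",
    "predictor",
    "subgroup_fits",
    "mbp_sensitivity",
    "tertile_sizes",
    "age_bin",
]

AGE_BIN_LABELS = ("<40", "40-50", ">50")
TERTILE_LABELS = ("<Q1", "[Q1,Q3]", ">Q3")


@dataclass(frozen=True)
class OriginFit:
    """A fitted multiplicative coefficient with its goodness of fit."""

    kprime: float
    R2: float
    n: int
    predictor_label: str = "T*MBP/cPP"
    intercept: float = 0.0


def fit_kprime(
    tau,
    x,
    intercept: bool = False,
    uncentered_r2: bool = False,
    predictor_label: str = "T*MBP/cPP",
) -> OriginFit:
    """Least-squares slope of tau on x, through the origin by default.

    With ``intercept=True`` an ordinary least-squares line is fitted instead
    and its slope reported as the coefficient.  R^2 = 1 - SSres/SStot with
    SStot centred unless ``uncentered_r2``.
    """
    tau = np.asarray(tau, dtype=float)
    x = np.asarray(x, dtype=float)
    if tau.shape != x.shape or tau.ndim != 1:
        raise ValueError("tau and x must be 1-D arrays of equal length")
    n = tau.size
    if n < 2:
        raise FitError("need at least 2 observations to fit k'")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise FitError("degenerate predictor: all x are zero")

    if intercept:
        if np.ptp(x) == 0.0:
            raise FitError("degenerate predictor: x is constant")
        res = stats.linregress(x, tau)
        k, b = float(res.slope), float(res.intercept)
    else:
        k, b = float(x @ tau / sxx), 0.0

    ss_res = float(np.sum((tau - (k * x + b)) ** 2))
    ss_tot = float(np.sum(tau**2) if uncentered_r2 else np.sum((tau - tau.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return OriginFit(kprime=k, R2=r2, n=n, predictor_label=predictor_label, intercept=b)


def predictor(cohort: pd.DataFrame, mbp_col: str = "MBP", pp_col: str = "cPP") -> pd.Series:
    """The formula predictor x = T * MBP / cPP from a cohort feature table."""
    return cohort["T_s"] * cohort[mbp_col] / cohort[pp_col]


def tertile_sizes(n: int) -> tuple[int, int, int]:
    """Equal thirds with the remainder assigned to the outer groups.

    (3818 -> 1273/1272/1273.)
    """
    outer = (n + 2) // 3
    return outer, n - 2 * outer, outer


def age_bin(age) -> pd.Series:
    """Age groups <40, 40-50 (inclusive), >50 years."""
    age = pd.Series(np.asarray(age, dtype=float))
    return pd.Series(
        np.where(age < 40, AGE_BIN_LABELS[0], np.where(age <= 50, AGE_BIN_LABELS[1], AGE_BIN_LABELS[2])),
        index=age.index,
    )


def _fit_group(g: pd.DataFrame, tau_col: str, **kw) -> OriginFit:
    if len(g) < 2:
        raise FitError(f"subgroup of size {len(g)} is too small to fit")
    return fit_kprime(g[tau_col].to_numpy(), predictor(g).to_numpy(), **kw)


def subgroup_fits(
    cohort: pd.DataFrame,
    variable: str,
    tau_col: str = "tau_true",
    **fit_kwargs,
) -> pd.DataFrame:
    """Per-group origin fits of k' for one grouping variable.

    ``variable``: "HR" or "MBP" (sorted tertiles labelled <Q1 / [Q1,Q3] / >Q3),
    "age" (<40 / 40-50 / >50) or "gender" (M / F).  Returns one row per group
    with columns ``variable, group, n, kprime, R2``.
    """
    rows = []
    if variable in ("HR", "MBP"):
        key = cohort["HR_bpm"] if variable == "HR" else cohort["MBP"]
        order = np.argsort(key.to_numpy(), kind="stable")
        n1, n2, n3 = tertile_sizes(len(cohort))
        splits = np.split(order, [n1, n1 + n2])
        for label, idx in zip(TERTILE_LABELS, splits):
            fit = _fit_group(cohort.iloc[idx], tau_col, **fit_kwargs)
            rows.append((variable, label, fit.n, fit.kprime, fit.R2))
    elif variable == "age":
        groups = age_bin(cohort["age"].to_numpy())
        for label in AGE_BIN_LABELS:
            g = cohort.loc[(groups == label).to_numpy()]
            fit = _fit_group(g, tau_col, **fit_kwargs)
            rows.append((variable, label, fit.n, fit.kprime, fit.R2))
    elif variable == "gender":
        for label in ("M", "F"):
            g = cohort[cohort["gender"] == label]
            fit = _fit_group(g, tau_col, **fit_kwargs)
            rows.append((variable, label, fit.n, fit.kprime, fit.R2))
    else:
        raise ValueError(f"unknown grouping variable {variable!r}")
    return pd.DataFrame(rows, columns=["variable", "group", "n", "kprime", "R2"])


def mbp_sensitivity(
    cohort: pd.DataFrame,
    formula_ids=MBP_FORMULA_IDS,
    tau_col: str = "tau_true",
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit k' once per MBP estimation formula.

    ``waveform_mean`` uses the cohort's MBP column (the integral mean
    computed at feature extraction); the other formulas recompute MBP from
    SBP, DBP and HR.  Returns columns
    ``formula, mbp_mean, mbp_sd, n, kprime, R2``.
    """
    tau = cohort[tau_col].to_numpy()
    rows = []
    for fid in formula_ids:
        if fid == WAVEFORM_MEAN:
            mbp = cohort["MBP"].to_numpy()
        else:
            mbp = estimate_mbp(
                cohort["SBP"].to_numpy(),
                cohort["DBP"].to_numpy(),
                fid,
                HR=cohort["HR_bpm"].to_numpy(),
            )
        x = cohort["T_s"].to_numpy() * mbp / cohort["cPP"].to_numpy()
        fit = fit_kprime(tau, x, predictor_label=f"T*MBP[{fid}]/cPP", **fit_kwargs)
        rows.append((fid, float(np.mean(mbp)), float(np.std(mbp, ddof=1)), fit.n,
                     fit.kprime, fit.R2))
    return pd.DataFrame(
        rows, columns=["formula", "mbp_mean", "mbp_sd", "n", "kprime", "R2"]
    )
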