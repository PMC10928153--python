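"""Method-agreement statistics between estimated and reference time constants.

One call produces the full battery used to judge a tau estimator against its
reference: Pearson correlation, intraclass correlation (two-way random,
absolute agreement, single measures — ICC(2,1)), ordinary least-squares
regression of the estimate on the reference with a two-sided Wald t-test of
the slope, RMSE normalised by the reference range, and Bland-Altman bias
with 1.96-SD limits of agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .fitting import age_bin

__all__ = ["AgreementReport", "evaluate_agreement", "evaluate_by_group", "icc_agreement"]

logger = logging.getLogger(__name__)

LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class AgreementReport:
    r: float
    icc: float
    slope: float
    intercept: float
    p_slope: float
    nrmse_pct: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


def icc_agreement(est, ref) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares of the n x 2 rating table
    (targets x methods):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    data = np.column_stack([np.asarray(ref, float), np.asarray(est, float)])
    n, k = data.shape
    row_m = data.mean(axis=1)
    col_m = data.mean(axis=0)
    grand = data.mean()
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_m[:, None] - col_m[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise DataError("ICC undefined: no variance in the rating table")
    return float((msr - mse) / denom)


def evaluate_agreement(est, ref) -> AgreementReport:
    """Full agreement battery for paired estimates and references (seconds)."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("est and ref must be 1-D arrays of equal length")
    n = est.size
    if n < 3:
        raise DataError(f"need at least 3 pairs, got {n}")
    ref_range = float(np.ptp(ref))
    if ref_range == 0:
        raise DataError("reference values are constant; r and nRMSE undefined")

    r = float(stats.pearsonr(est, ref).statistic)
    reg = stats.linregress(ref, est)  # estimate regressed on reference
    d = est - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    rmse = float(np.sqrt(np.mean(d**2)))
    return AgreementReport(
        r=r,
        icc=icc_agreement(est, ref),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        p_slope=float(reg.pvalue),
        nrmse_pct=100.0 * rmse / ref_range,
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n=n,
    )


def _report_row(label: str, est, ref) -> dict:
    rep = evaluate_agreement(est, ref)
    row = {"group": label}
    row.update({f.name: getattr(rep, f.name) for f in fields(AgreementReport)})
    return row


def evaluate_by_group(
    cohort: pd.DataFrame,
    est_col: str,
    ref_col: str,
    by_age: bool = True,
    by_gender: bool = True,
) -> pd.DataFrame:
    """One agreement report per demographic stratum, plus the pooled row.

    Strata: all subjects; each gender; each age bin; each age bin x gender.
    Groups with fewer than 3 members are skipped with a logged warning.
    """
    est = cohort[est_col].to_numpy()
    ref = cohort[ref_col].to_numpy()
    rows = [_report_row("all", est, ref)]

    def _try(label: str, mask: np.ndarray) -> None:
        if mask.sum() < 3:
            logger.warning("skipping group %s with n=%d < 3", label, int(mask.sum()))
            return
        rows.append(_report_row(label, est[mask], ref[mask]))

    genders = ("M", "F") if by_gender and "gender" in cohort else ()
    for g in genders:
        _try(f"all|{g}", (cohort["gender"] == g).to_numpy())
    if by_age and "age" in cohort:
        bins = age_bin(cohort["age"].to_numpy()).to_numpy()
        for b in ("<40", "40-50", ">50"):
            mask = bins == b
            _try(b, mask)
            for g in genders:
                _try(f"{b}|{g}", mask & (cohort["gender"] == g).to_numpy())
    return pd.DataFrame(rows)
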