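"""Naive-formula re-implementations used as independent oracles in tests.

Everything here is written from the defining sums, deliberately avoiding the
library calls used by the package.
"""

import math

import numpy as np
from scipy.stats import t as t_dist


def pearson_r(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / math.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def ols_with_wald(x, y):
    """Slope, intercept and two-sided Wald-t p-value for H0: slope = 0."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    slope = float(np.sum(xm * ym) / np.sum(xm**2))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    se = math.sqrt(np.sum(resid**2) / (n - 2) / np.sum(xm**2))
    if se == 0.0:
        return slope, intercept, 0.0
    p = 2.0 * float(t_dist.sf(abs(slope / se), n - 2))
    return slope, intercept, p


def icc_two_way_absolute(x, y):
    """ICC(2,1) from the explicit two-way ANOVA variance components."""
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
    resid = data - data.mean(axis=1)[:, None] - data.mean(axis=0)[None, :] + grand
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(
        (ms_rows - ms_err)
        / (ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)
    )


def bland_altman(est, ref):
    d = np.asarray(est, float) - np.asarray(ref, float)
    n = d.size
    bias = float(d.sum() / n)
    sd = math.sqrt(np.sum((d - bias) ** 2) / (n - 1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def nrmse_pct(est, ref):
    est, ref = np.asarray(est, float), np.asarray(ref, float)
    rmse = math.sqrt(np.mean((est - ref) ** 2))
    return 100.0 * rmse / (ref.max() - ref.min())
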