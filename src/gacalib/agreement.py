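"""Validity and agreement of a GA measure against the ultrasound reference.

Bland-Altman bias and limits of agreement (mean difference +/- k * SD, k=2
by default), a one-sample t-test of zero bias, Pearson correlation, and
preterm classification rates.  Differences are oriented method-under-test
minus reference, so a positive mean difference means overestimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AgreementStats", "bland_altman", "pearson_correlation", "preterm_rate"]


@dataclass
class AgreementStats:
    n_pairs: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    p_bias: float
    pearson_rho: float
    k: float = 2.0
    #: per-pair (mean, difference) table for the difference-vs-mean plot
    plot_data: pd.DataFrame | None = field(default=None, repr=False, compare=False)


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation over complete pairs."""
    x, y = _complete_pairs(x, y)
    if x.size < 3:
        raise ValueError(f"pearson_correlation: need >= 3 complete pairs, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_correlation: zero variance in input")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(x, y, k: float = 2.0) -> AgreementStats:
    """Bland-Altman agreement of ``x`` (method under test) against ``y``.

    ``d = x - y``; limits of agreement are ``mean(d) +/- k * sd(d)`` with the
    sample (n-1) SD.  ``p_bias`` is a two-sided one-sample t-test of the
    differences against zero.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < 2:
        raise ValueError(f"bland_altman: need >= 2 complete pairs, got {n}")
    d = x - y
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    if sd_diff == 0.0:
        if mean_diff == 0.0:
            p_bias = 1.0
        else:
            warnings.warn("bland_altman: zero variance with nonzero mean difference", RuntimeWarning)
            p_bias = 0.0
    else:
        p_bias = float(stats.ttest_1samp(d, 0.0).pvalue)
    try:
        rho = pearson_correlation(x, y)
    except ValueError:
        rho = float("nan")
    plot = pd.DataFrame({"pair_mean": (x + y) / 2.0, "difference": d})
    return AgreementStats(
        n_pairs=int(n),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - k * sd_diff,
        loa_high=mean_diff + k * sd_diff,
        p_bias=p_bias,
        pearson_rho=rho,
        k=k,
        plot_data=plot,
    )


def preterm_rate(ga, cutoff: float = 37.0) -> tuple[float, np.ndarray]:
    """Proportion of records with GA strictly below ``cutoff`` weeks.

    Returns ``(rate, flags)`` where ``flags`` is a float array aligned to the
    input (1.0 preterm, 0.0 term, NaN missing); the rate is computed over
    non-missing records.
    """
    arr = np.asarray(ga, dtype=float)
    ok = ~np.isnan(arr)
    if not ok.any():
        raise ValueError("preterm_rate: all values missing")
    flags = np.where(ok, (arr < cutoff).astype(float), np.nan)
    rate = float(np.nansum(flags) / ok.sum())
    return rate, flags
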