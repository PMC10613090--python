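"""GA-outcome association with and without measurement-error correction.

The outcome model is a univariable logistic regression of a binary outcome
on gestational age, either continuous (per week) or dichotomized at the
preterm cutoff.  Calibrated analyses replace the error-prone exposure with
the calibration-model prediction; their standard errors come from a
two-stage bootstrap that refits the calibration model in every replicate,
so calibration uncertainty propagates into the reported SE and CI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .calibration import PredictorSpec, fit_calibration, predict_calibrated

__all__ = [
    "AssociationEstimate",
    "BootstrapSpec",
    "fit_logistic_univariable",
    "or_from_log_or",
    "percent_change_log_or",
    "or_reduction_points",
    "bootstrap_statistic",
    "bootstrap_association",
]

Z975 = 1.959963984540054


class SeparationError(ValueError):
    """Raised when the logistic MLE does not exist (separation/degeneracy)."""


@dataclass
class AssociationEstimate:
    outcome: str
    exposure_form: str  # "continuous" | "preterm"
    calibration_status: str  # "uncalibrated" | "calibrated"
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    n_used: int
    ci_method: str = "wald"
    n_replicates: int | None = None
    n_failed: int | None = None


@dataclass
class BootstrapSpec:
    n_replicates: int = 1000
    sample_size: int = 1500
    with_replacement: bool = True
    seed: int = 0
    ci_method: str = "percentile"  # "percentile" | "normal"

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates: must be >= 2")
        if self.sample_size < 1:
            raise ValueError("sample_size: must be >= 1")
        if self.ci_method not in ("percentile", "normal"):
            raise ValueError(f"ci_method: unknown method {self.ci_method!r}")


def fit_logistic_univariable(outcome, exposure, *, outcome_name: str = "outcome",
                             exposure_form: str = "continuous",
                             calibration_status: str = "uncalibrated") -> AssociationEstimate:
    """ML logistic fit of a binary outcome on a single exposure.

    Returns the slope as log OR with the model-based (observed-information)
    SE and a Wald 95% CI on the OR scale.  Separation and degenerate layouts
    raise :class:`SeparationError` rather than returning a huge coefficient.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcome and exposure must have equal length")
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome: must be binary 0/1")
    n_events = int(y.sum())
    if n_events == 0 or n_events == y.size:
        raise SeparationError(
            f"fit_logistic_univariable: degenerate outcome ({n_events} events of {y.size})"
        )
    if np.std(x) == 0:
        raise SeparationError("fit_logistic_univariable: exposure has zero variance")

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=200, tol=1e-10)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
            raise SeparationError(f"fit_logistic_univariable: separation detected ({exc})") from exc
    if not res.mle_retvals.get("converged", True) or abs(res.params[1]) > 30:
        raise SeparationError("fit_logistic_univariable: fit did not converge (separation suspected)")

    log_or = float(res.params[1])
    se = float(res.bse[1])
    return AssociationEstimate(
        outcome=outcome_name,
        exposure_form=exposure_form,
        calibration_status=calibration_status,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        n_used=int(y.size),
        ci_method="wald",
    )


def or_from_log_or(log_or: float) -> float:
    """Odds ratio exp(log OR)."""
    if not math.isfinite(log_or):
        raise ValueError("or_from_log_or: input must be finite")
    return math.exp(log_or)


def percent_change_log_or(log_or_uncal: float, log_or_cal: float) -> float:
    """Percent change in |log OR| from calibration: 100*(|cal|-|uncal|)/|uncal|."""
    if log_or_uncal == 0:
        raise ValueError("percent_change_log_or: uncalibrated log OR must be nonzero")
    return 100.0 * (abs(log_or_cal) - abs(log_or_uncal)) / abs(log_or_uncal)


def or_reduction_points(or_uncal: float, or_cal: float) -> float:
    """Reduction of the odds ratio in percentage points: 100*(uncal - cal)."""
    if or_uncal <= 0 or or_cal <= 0:
        raise ValueError("or_reduction_points: odds ratios must be positive")
    return 100.0 * (or_uncal - or_cal)


def bootstrap_statistic(cohort: pd.DataFrame, stat_fn: Callable[[pd.DataFrame], float],
                        boot: BootstrapSpec) -> tuple[np.ndarray, int]:
    """Resample the cohort per ``boot`` and evaluate ``stat_fn`` per replicate.

    Replicates where ``stat_fn`` raises are dropped and counted.  Returns the
    array of successful replicate statistics and the failure count; errors
    out if more than 10% of replicates fail.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("bootstrap_statistic: empty cohort")
    if not boot.with_replacement and boot.sample_size > n:
        raise ValueError("bootstrap_statistic: sample_size > n without replacement")
    rng = np.random.default_rng(boot.seed)
    values: list[float] = []
    n_failed = 0
    for _ in range(boot.n_replicates):
        idx = rng.choice(n, size=boot.sample_size, replace=boot.with_replacement)
        replicate = cohort.iloc[idx]
        try:
            values.append(float(stat_fn(replicate)))
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > 0.1 * boot.n_replicates:
        raise RuntimeError(
            f"bootstrap_statistic: {n_failed}/{boot.n_replicates} replicates failed"
        )
    return np.asarray(values), n_failed


def _calibrated_log_or(cohort: pd.DataFrame, spec: PredictorSpec, outcome_col: str,
                       exposure_form: str, trim: bool, preterm_cutoff: float,
                       on_aliased: str = "raise") -> float:
    model = fit_calibration(cohort, spec, trim=trim, on_aliased=on_aliased)
    ga_cal = predict_calibrated(model, cohort)
    if exposure_form == "preterm":
        exposure = np.where(np.isnan(ga_cal), np.nan, (ga_cal < preterm_cutoff).astype(float))
    else:
        exposure = ga_cal.to_numpy()
    est = fit_logistic_univariable(cohort[outcome_col].to_numpy(), exposure)
    return est.log_or


def bootstrap_association(cohort: pd.DataFrame, spec: PredictorSpec, outcome_col: str,
                          exposure_form: str, boot: BootstrapSpec, *, trim: bool = True,
                          preterm_cutoff: float = 37.0) -> AssociationEstimate:
    """Calibrated association estimate with two-stage bootstrap uncertainty.

    The point estimate is the plug-in fit on the full cohort (calibrate,
    predict, logistic fit).  Each replicate redraws ``sample_size`` records,
    refits the calibration model on the replicate's ultrasound subset,
    recalibrates, and refits the outcome model; the SE is the SD of the
    replicate log ORs and the CI follows ``boot.ci_method``.
    """
    if exposure_form not in ("continuous", "preterm"):
        raise ValueError(f"exposure_form: unknown form {exposure_form!r}")

    point = _calibrated_log_or(cohort, spec, outcome_col, exposure_form, trim, preterm_cutoff)
    model = fit_calibration(cohort, spec, trim=trim)
    ga_cal = predict_calibrated(model, cohort)
    n_used = int((~(np.isnan(ga_cal.to_numpy()) | cohort[outcome_col].isna().to_numpy())).sum())

    values, n_failed = bootstrap_statistic(
        cohort,
        lambda rep: _calibrated_log_or(rep, spec, outcome_col, exposure_form, trim,
                                       preterm_cutoff, on_aliased="drop"),
        boot,
    )
    se = float(np.std(values, ddof=1))
    if boot.ci_method == "percentile":
        lo, hi = np.quantile(values, [0.025, 0.975])
    else:
        lo, hi = point - Z975 * se, point + Z975 * se
    return AssociationEstimate(
        outcome=outcome_col,
        exposure_form=exposure_form,
        calibration_status="calibrated",
        log_or=point,
        se=se,
        or_=math.exp(point),
        ci_low=math.exp(float(lo)),
        ci_high=math.exp(float(hi)),
        n_used=n_used,
        ci_method=boot.ci_method,
        n_replicates=int(values.size),
        n_failed=n_failed,
    )
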