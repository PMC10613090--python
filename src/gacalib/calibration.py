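"""Regression calibration of error-prone gestational-age measurements.

The calibration model is an ordinary least-squares fit of ultrasound GA (the
gold standard, assumed unbiased with independent error) on one or both
error-prone measures plus error-free covariates, over complete cases in the
ultrasound validation sub-cohort.  Predictions from the fitted model are the
calibrated GA — the estimated conditional mean of true GA given the
error-prone measure(s) and covariates — and are produced for records with
and without ultrasound alike.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredictorSpec",
    "CalibrationModel",
    "trim_extreme_reference",
    "fit_calibration",
    "predict_calibrated",
    "Q_COLUMN",
    "CATEGORICAL_LEVELS",
    "DEFAULT_Z_VARIABLES",
]

#: mapping from measure keyword to cohort column
Q_COLUMN = {"fh": "ga_fh", "lmp": "ga_lmp"}

#: fixed level sets for categorical covariates; first level is the reference
CATEGORICAL_LEVELS: dict[str, list] = {
    "education": ["none", "primary", "secondary", "tertiary"],
    "trimester_enrol": [1, 2, 3],
}

#: the full error-free predictor set (drop birth_weight for the LBW analysis)
DEFAULT_Z_VARIABLES = (
    "birth_weight",
    "baby_sex",
    "maternal_age",
    "hiv",
    "muac",
    "malaria",
    "syphilis",
    "first_pregnancy",
    "education",
    "trimester_enrol",
    "hb_enrol",
    "hb_delivery",
)

_VALID_Z = set(DEFAULT_Z_VARIABLES)


@dataclass(frozen=True)
class PredictorSpec:
    """Which error-prone measure(s) and covariates enter the calibration fit."""

    q_measures: tuple[str, ...]
    z_variables: tuple[str, ...] = ()
    exclude_birth_weight: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "q_measures", tuple(self.q_measures))
        object.__setattr__(self, "z_variables", tuple(self.z_variables))
        if not self.q_measures:
            raise ValueError("q_measures: must be non-empty")
        bad = [q for q in self.q_measures if q not in Q_COLUMN]
        if bad:
            raise ValueError(f"q_measures: unknown measure(s) {bad}; expected subset of {sorted(Q_COLUMN)}")
        if len(set(self.q_measures)) != len(self.q_measures):
            raise ValueError("q_measures: duplicates not allowed")
        badz = [z for z in self.z_variables if z not in _VALID_Z]
        if badz:
            raise ValueError(f"z_variables: unknown covariate(s) {badz}")
        if self.exclude_birth_weight and "birth_weight" in self.z_variables:
            raise ValueError("z_variables: birth_weight present but exclude_birth_weight is set")

    @property
    def q_columns(self) -> tuple[str, ...]:
        return tuple(Q_COLUMN[q] for q in self.q_measures)

    @property
    def required_columns(self) -> tuple[str, ...]:
        return self.q_columns + self.z_variables


@dataclass
class CalibrationModel:
    """A fitted calibration regression E(true GA | Q, Z)."""

    predictor_spec: PredictorSpec
    intercept: float
    coefficients: dict[str, float]
    residual_sd: float
    n_fit: int
    trim_window: tuple[float, float] | None = None
    n_trimmed: int = 0
    #: predictors dropped from the fit (constant or aliased); coefficient fixed at 0
    dropped_predictors: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "q_measures": list(self.predictor_spec.q_measures),
            "z_variables": list(self.predictor_spec.z_variables),
            "exclude_birth_weight": self.predictor_spec.exclude_birth_weight,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "residual_sd": self.residual_sd,
            "n_fit": self.n_fit,
            "trim_window": list(self.trim_window) if self.trim_window else None,
            "n_trimmed": self.n_trimmed,
            "dropped_predictors": list(self.dropped_predictors),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _nearest_rank_percentile(sorted_values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: value at rank ceil(pct/100 * n), 1-based."""
    n = sorted_values.size
    rank = math.ceil(pct / 100.0 * n)
    rank = min(max(rank, 1), n)
    return float(sorted_values[rank - 1])


def trim_extreme_reference(values: Iterable[float], lower_pct: float = 0.5,
                           upper_pct: float = 99.5) -> tuple[np.ndarray, tuple[float, float]]:
    """Mask off extreme reference (ultrasound) values by percentile.

    Values ``<=`` the ``lower_pct``-th or ``>=`` the ``upper_pct``-th
    nearest-rank percentile are dropped (mask False).  Returns the keep mask
    over the *non-missing* input order and the realized thresholds.
    """
    if not (0.0 <= lower_pct < upper_pct <= 100.0):
        raise ValueError("percentiles: need 0 <= lower_pct < upper_pct <= 100")
    arr = np.asarray(list(values), dtype=float)
    finite = arr[~np.isnan(arr)]
    if np.unique(finite).size < 3:
        raise ValueError("trim_extreme_reference: need at least 3 distinct values")
    srt = np.sort(finite)
    lo = _nearest_rank_percentile(srt, lower_pct)
    hi = _nearest_rank_percentile(srt, upper_pct)
    mask = (arr > lo) & (arr < hi)  # NaN compares False -> dropped
    return mask, (lo, hi)


def _design_matrix(cohort: pd.DataFrame, spec: PredictorSpec) -> pd.DataFrame:
    """Expand predictors into numeric design columns (no intercept).

    Categorical covariates become reference-category indicator contrasts
    with the first listed level as reference.
    """
    missing = [c for c in spec.required_columns if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing required column(s): {missing}")
    cols: dict[str, pd.Series] = {}
    for qcol in spec.q_columns:
        cols[qcol] = pd.to_numeric(cohort[qcol], errors="coerce")
    for z in spec.z_variables:
        if z in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[z]
            raw = cohort[z]
            known = raw.isin(levels) | raw.isna()
            if not known.all():
                bad = sorted(set(raw[~known].tolist()))
                raise ValueError(f"{z}: unknown level(s) {bad}; expected one of {levels}")
            for level in levels[1:]:
                ind = (raw == level).astype(float)
                ind[raw.isna()] = np.nan
                cols[f"{z}[{level}]"] = ind
        else:
            cols[z] = pd.to_numeric(cohort[z], errors="coerce")
    return pd.DataFrame(cols, index=cohort.index)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns responsible for rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return [names[i] for i in sorted(piv[rank:])]


def fit_calibration(cohort: pd.DataFrame, spec: PredictorSpec, trim: bool = True,
                    lower_pct: float = 0.5, upper_pct: float = 99.5,
                    on_aliased: str = "raise") -> CalibrationModel:
    """OLS fit of ultrasound GA on the specified predictors over complete cases.

    Trimming (on by default) drops records whose ultrasound value ties or
    exceeds the extreme percentiles of the ultrasound distribution *before*
    the complete-case restriction; trimmed records can still receive
    predictions later.

    Constant predictors (e.g. a rare indicator absent from the validation
    subset) are always dropped with a zero coefficient.  Remaining collinear
    predictors raise by default; ``on_aliased="drop"`` zeroes them instead,
    which bootstrap replicate refits rely on.
    """
    if on_aliased not in ("raise", "drop"):
        raise ValueError(f"on_aliased: unknown mode {on_aliased!r}")
    if "ga_us" not in cohort.columns:
        raise ValueError("cohort is missing required column(s): ['ga_us']")
    design = _design_matrix(cohort, spec)

    us = pd.to_numeric(cohort["ga_us"], errors="coerce")
    trim_window = None
    n_trimmed = 0
    keep = pd.Series(True, index=cohort.index)
    if trim:
        mask, trim_window = trim_extreme_reference(us.to_numpy())
        keep = pd.Series(mask, index=cohort.index)
        n_trimmed = int((~mask & us.notna().to_numpy()).sum())

    complete = us.notna() & design.notna().all(axis=1) & keep
    y = us[complete].to_numpy()
    Xd = design.loc[complete]
    all_names = list(Xd.columns)
    # constant columns (e.g. a rare indicator absent from the validation
    # subset) are collinear with the intercept; fit without them, keep a
    # zero coefficient so predictions stay defined
    arr = Xd.to_numpy(dtype=float)
    variable = [i for i in range(arr.shape[1]) if np.ptp(arr[:, i]) > 0] if len(y) else []
    dropped = [all_names[i] for i in range(len(all_names)) if i not in variable]
    names = [all_names[i] for i in variable]
    p = len(names)
    n = len(y)
    if n < p + 2:
        raise ValueError(
            f"fit_calibration: insufficient complete cases (n={n}, need >= {p + 2} "
            f"for {p} predictors)"
        )
    X = np.column_stack([np.ones(n), arr[:, variable]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        if on_aliased == "raise":
            bad = _collinear_columns(X, ["intercept"] + names)
            raise ValueError(
                f"fit_calibration: rank-deficient design; collinear predictor(s): {bad}")
        # greedy forward selection keeps the intercept and the earliest
        # full-rank subset; aliased columns get coefficient 0
        kept = [0]
        rank = 1
        for j in range(1, X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) > rank:
                kept.append(j)
                rank += 1
            else:
                dropped.append(names[j - 1])
        names = [names[j - 1] for j in kept[1:]]
        X = X[:, kept]
        p = len(names)
        if n < p + 2:
            raise ValueError(
                f"fit_calibration: insufficient complete cases (n={n}, need >= {p + 2} "
                f"for {p} predictors)")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    dof = n - X.shape[1]
    residual_sd = math.sqrt(rss / dof) if dof > 0 else 0.0

    coefficients = {name: 0.0 for name in all_names}
    coefficients.update({name: float(b) for name, b in zip(names, beta[1:])})
    return CalibrationModel(
        predictor_spec=spec,
        intercept=float(beta[0]),
        coefficients=coefficients,
        residual_sd=residual_sd,
        n_fit=n,
        trim_window=trim_window,
        n_trimmed=n_trimmed,
        dropped_predictors=tuple(dropped),
    )


def predict_calibrated(model: CalibrationModel, cohort: pd.DataFrame) -> pd.Series:
    """Calibrated GA for every record with all required predictors present.

    Records missing any required predictor get NaN.  Applies to records with
    and without ultrasound alike.
    """
    design = _design_matrix(cohort, model.predictor_spec)
    expected = list(model.coefficients)
    if list(design.columns) != expected:
        raise ValueError(
            f"predict_calibrated: design mismatch; model expects {expected}, "
            f"cohort provides {list(design.columns)}"
        )
    coefs = np.array([model.coefficients[c] for c in expected])
    pred = model.intercept + design.to_numpy(dtype=float) @ coefs
    out = pd.Series(pred, index=cohort.index, name="ga_calibrated")
    out[design.isna().any(axis=1)] = np.nan
    return out
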