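"""End-to-end study orchestration.

Runs trim -> calibration (FH-only, LMP-only, joint) -> agreement reporting
-> association analysis for both outcomes and both exposure forms, with
bootstrap SEs for calibrated rows, plus the ultrasound-availability
sensitivity analysis.  Every table row carries its n; the provenance block
records enough (config hash, seeds, version, stage counts) to regenerate a
report bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import bland_altman, preterm_rate
from .association import (
    AssociationEstimate,
    BootstrapSpec,
    SeparationError,
    bootstrap_association,
    fit_logistic_univariable,
)
from .calibration import (
    DEFAULT_Z_VARIABLES,
    PredictorSpec,
    fit_calibration,
    predict_calibrated,
)
from .synthetic import COHORT_COLUMNS, GA_COLUMNS

__all__ = [
    "AnalysisConfig",
    "StudyReport",
    "run_full_analysis",
    "sensitivity_ultrasound_availability",
    "load_cohort",
    "write_report",
]

logger = logging.getLogger("gacalib")

MEASURE_SPECS = {
    "fh": ("fh",),
    "lmp": ("lmp",),
    "joint": ("fh", "lmp"),
}

OUTCOMES = ("neonatal_death", "low_birth_weight")


@dataclass
class AnalysisConfig:
    """Knobs for the full-study run."""

    trim: bool = True
    loa_k: float = 2.0
    preterm_cutoff: float = 37.0
    z_variables: tuple[str, ...] = DEFAULT_Z_VARIABLES
    measures: tuple[str, ...] = ("fh", "lmp", "joint")
    bootstrap_calibrated: bool = True
    n_replicates: int = 1000
    sample_size: int = 1500
    ci_method: str = "percentile"
    seed: int = 0

    def z_for_outcome(self, outcome: str) -> tuple[str, ...]:
        # birth weight cannot adjust its own dichotomization
        if outcome == "low_birth_weight":
            return tuple(z for z in self.z_variables if z != "birth_weight")
        return self.z_variables

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["z_variables"] = list(self.z_variables)
        d["measures"] = list(self.measures)
        return d


@dataclass
class StudyReport:
    agreement_table: pd.DataFrame
    association_table: pd.DataFrame
    preterm_rates: pd.DataFrame
    provenance: dict
    sensitivity_table: pd.DataFrame | None = None


def _predictor_spec(measure: str, z_variables: tuple[str, ...], outcome: str | None) -> PredictorSpec:
    z = tuple(z_variables)
    exclude_bw = outcome == "low_birth_weight"
    if exclude_bw:
        z = tuple(v for v in z if v != "birth_weight")
    return PredictorSpec(q_measures=MEASURE_SPECS[measure], z_variables=z,
                         exclude_birth_weight=exclude_bw)


def _estimate_row(est: AssociationEstimate, measure: str) -> dict:
    return {
        "outcome": est.outcome,
        "exposure_form": est.exposure_form,
        "measure": measure,
        "calibration_status": est.calibration_status,
        "log_or": est.log_or,
        "se": est.se,
        "or": est.or_,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "n_used": est.n_used,
        "ci_method": est.ci_method,
        "n_replicates": est.n_replicates,
        "n_failed": est.n_failed,
    }


def run_full_analysis(cohort: pd.DataFrame, config: AnalysisConfig) -> StudyReport:
    """Execute the whole study on a cohort and return the report tables."""
    _validate_cohort(cohort)
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * len(config.measures) * 4 + 8)
    seed_iter = iter(int(s) for s in seeds)

    counts = {"n_records": int(len(cohort))}
    for col in GA_COLUMNS:
        counts[f"n_{col}"] = int(cohort[col].notna().sum())

    # --- calibration (mortality-variant Z, includes birth weight) ---
    calibrated: dict[str, pd.Series] = {}
    for measure in config.measures:
        spec = _predictor_spec(measure, config.z_variables, outcome=None)
        model = fit_calibration(cohort, spec, trim=config.trim)
        calibrated[measure] = predict_calibrated(model, cohort)
        counts[f"n_fit_{measure}"] = model.n_fit
        counts[f"n_trimmed_{measure}"] = model.n_trimmed
        logger.info("calibration[%s]: n_fit=%d trimmed=%d", measure, model.n_fit, model.n_trimmed)

    # --- agreement vs ultrasound ---
    agreement_rows = []
    comparisons = [("fh", "uncalibrated", cohort["ga_fh"]), ("lmp", "uncalibrated", cohort["ga_lmp"])]
    comparisons += [(m, "calibrated", calibrated[m]) for m in config.measures]
    for measure, status, values in comparisons:
        ba = bland_altman(values.to_numpy(dtype=float), cohort["ga_us"].to_numpy(dtype=float),
                          k=config.loa_k)
        agreement_rows.append(
            {
                "measure": measure,
                "calibration_status": status,
                "n_pairs": ba.n_pairs,
                "mean": float(np.nanmean(values.to_numpy(dtype=float))),
                "sd": float(np.nanstd(values.to_numpy(dtype=float), ddof=1)),
                "mean_diff": ba.mean_diff,
                "sd_diff": ba.sd_diff,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "p_bias": ba.p_bias,
                "pearson_rho": ba.pearson_rho,
            }
        )
    agreement_table = pd.DataFrame(agreement_rows)

    # --- preterm classification rates ---
    preterm_rows = []
    for measure, status, values in comparisons:
        rate, _ = preterm_rate(values.to_numpy(dtype=float), cutoff=config.preterm_cutoff)
        n = int(values.notna().sum())
        preterm_rows.append({"measure": measure, "calibration_status": status,
                             "preterm_rate": rate, "n_used": n})
    preterm_table = pd.DataFrame(preterm_rows)

    # --- association ---
    association_rows = []
    for outcome in OUTCOMES:
        for form in ("continuous", "preterm"):
            for measure in ("fh", "lmp"):
                raw = cohort[f"ga_{measure}"].to_numpy(dtype=float)
                if form == "preterm":
                    exposure = np.where(np.isnan(raw), np.nan,
                                        (raw < config.preterm_cutoff).astype(float))
                else:
                    exposure = raw
                try:
                    est = fit_logistic_univariable(
                        cohort[outcome].to_numpy(dtype=float), exposure,
                        outcome_name=outcome, exposure_form=form,
                        calibration_status="uncalibrated")
                    association_rows.append(_estimate_row(est, measure))
                except SeparationError as exc:
                    raise RuntimeError(
                        f"association stage failed for uncalibrated {measure}/{outcome}/{form}: {exc}"
                    ) from exc
            for measure in config.measures:
                spec = _predictor_spec(measure, config.z_variables, outcome=outcome)
                try:
                    if config.bootstrap_calibrated:
                        boot = BootstrapSpec(
                            n_replicates=config.n_replicates,
                            sample_size=min(config.sample_size, len(cohort)),
                            seed=next(seed_iter),
                            ci_method=config.ci_method,
                        )
                        est = bootstrap_association(
                            cohort, spec, outcome, form, boot,
                            trim=config.trim, preterm_cutoff=config.preterm_cutoff)
                    else:
                        model = fit_calibration(cohort, spec, trim=config.trim)
                        ga_cal = predict_calibrated(model, cohort)
                        if form == "preterm":
                            exposure = np.where(np.isnan(ga_cal),
                                                np.nan,
                                                (ga_cal < config.preterm_cutoff).astype(float))
                        else:
                            exposure = ga_cal.to_numpy()
                        est = fit_logistic_univariable(
                            cohort[outcome].to_numpy(dtype=float), exposure,
                            outcome_name=outcome, exposure_form=form,
                            calibration_status="calibrated")
                    est.outcome = outcome
                    est.exposure_form = form
                    association_rows.append(_estimate_row(est, measure))
                except (SeparationError, RuntimeError, ValueError) as exc:
                    raise RuntimeError(
                        f"association stage failed for calibrated {measure}/{outcome}/{form}: {exc}"
                    ) from exc
    association_table = pd.DataFrame(association_rows)

    provenance = {
        "software_version": __version__,
        "analysis_config": AnalysisConfig.to_dict(config),
        "seed": config.seed,
        "record_counts": counts,
        "config_hash": _hash_dict(AnalysisConfig.to_dict(config)),
    }
    return StudyReport(
        agreement_table=agreement_table,
        association_table=association_table,
        preterm_rates=preterm_table,
        provenance=provenance,
    )


def sensitivity_ultrasound_availability(cohort: pd.DataFrame,
                                        fractions=(0.25, 0.50, 1.00),
                                        seed: int = 0,
                                        config: AnalysisConfig | None = None,
                                        outcome: str = "neonatal_death",
                                        exposure_form: str = "continuous") -> pd.DataFrame:
    """Effect of partial ultrasound availability on the calibrated estimate.

    Restricts to records with all three GA measurements, masks ultrasound by
    an independent Bernoulli indicator at each fraction (drawn once per
    fraction), and reruns calibration + association + bootstrap.
    """
    config = config or AnalysisConfig()
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fractions: {f} outside (0, 1]")
    triple = cohort[cohort[list(GA_COLUMNS)].notna().all(axis=1)].reset_index(drop=True)
    if triple.empty:
        raise ValueError("sensitivity: no records with all three GA measurements")
    ss = np.random.SeedSequence(seed)
    mask_seeds = ss.generate_state(len(fractions))
    boot_root = ss.spawn(1)[0].generate_state(len(fractions) * len(config.measures))
    boot_iter = iter(int(s) for s in boot_root)

    rows = []
    for frac, mseed in zip(fractions, mask_seeds):
        rng = np.random.default_rng(int(mseed))
        r = rng.random(len(triple)) < frac
        masked = triple.copy()
        masked["ga_us"] = masked["ga_us"].where(r, other=np.nan)
        n_us = int(masked["ga_us"].notna().sum())
        for measure in config.measures:
            spec = _predictor_spec(measure, config.z_variables, outcome=outcome)
            boot = BootstrapSpec(
                n_replicates=config.n_replicates,
                sample_size=min(config.sample_size, len(masked)),
                seed=next(boot_iter),
                ci_method=config.ci_method,
            )
            est = bootstrap_association(masked, spec, outcome, exposure_form, boot,
                                        trim=config.trim, preterm_cutoff=config.preterm_cutoff)
            rows.append(
                {
                    "fraction": frac,
                    "measure": measure,
                    "outcome": outcome,
                    "exposure_form": exposure_form,
                    "n_triple_complete": int(len(triple)),
                    "n_us_available": n_us,
                    "log_or": est.log_or,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n_replicates": est.n_replicates,
                    "n_failed": est.n_failed,
                }
            )
            logger.info("sensitivity fraction=%.2f measure=%s n_us=%d log_or=%.4f se=%.4f",
                        frac, measure, n_us, est.log_or, est.se)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort I/O

_RANGES = {
    "ga_us": (0.0, 60.0),
    "ga_fh": (0.0, 60.0),
    "ga_lmp": (0.0, 60.0),
    "T_true": (0.0, 60.0),
    "birth_weight": (200.0, 7000.0),
}
_BINARY = ("first_pregnancy", "malaria", "syphilis", "hiv", "baby_sex",
           "neonatal_death", "low_birth_weight")
_REQUIRED = tuple(c for c in COHORT_COLUMNS if c != "T_true")


class CohortSchemaError(ValueError):
    """Cohort file violates the schema; message lists offending columns/rows."""


def _validate_cohort(cohort: pd.DataFrame) -> None:
    problems: list[str] = []
    missing = [c for c in _REQUIRED if c not in cohort.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")
    for col, (lo, hi) in _RANGES.items():
        if col not in cohort.columns:
            continue
        vals = pd.to_numeric(cohort[col], errors="coerce")
        bad = cohort.index[(vals.notna()) & ((vals <= lo) | (vals >= hi))]
        if len(bad):
            problems.append(
                f"{col}: {len(bad)} value(s) outside ({lo}, {hi}); first offending rows {list(bad[:5])}"
            )
    for col in _BINARY:
        vals = cohort[col]
        bad = cohort.index[vals.notna() & ~vals.isin([0, 1, 0.0, 1.0])]
        if len(bad):
            problems.append(f"{col}: non-binary value(s); first offending rows {list(bad[:5])}")
    if problems:
        raise CohortSchemaError("; ".join(problems))


def load_cohort(path) -> pd.DataFrame:
    """Load and validate a cohort CSV; unknown columns preserved but ignored."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortSchemaError(f"{path}: empty file") from exc
    if frame.empty and not len(frame.columns):
        raise CohortSchemaError(f"{path}: no columns")
    if "trimester_enrol" in frame.columns:
        frame["trimester_enrol"] = pd.to_numeric(frame["trimester_enrol"], errors="ignore")
    _validate_cohort(frame)
    return frame


def write_report(report: StudyReport, outdir) -> dict[str, Path]:
    """Write the report as one CSV per table plus a provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "agreement": report.agreement_table,
        "association": report.association_table,
        "preterm": report.preterm_rates,
    }
    if report.sensitivity_table is not None:
        tables["sensitivity"] = report.sensitivity_table
    for name, table in tables.items():
        p = outdir / f"{name}.csv"
        table.to_csv(p, index=False)
        paths[name] = p
    p = outdir / "provenance.json"
    with open(p, "w") as fh:
        json.dump(report.provenance, fh, indent=2, default=str)
    paths["provenance"] = p
    return paths


def _hash_dict(d: dict) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()
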