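"""Synthetic-cohort generator.

Produces cohorts with the statistical structure the calibration analysis
assumes: a latent true gestational age ``T`` and three classically
mismeasured versions of it (ultrasound, fundal height, last menstrual
period), error-free covariates, and rare binary outcomes.  Classical error
means ``Q = T + bias + delta`` with ``delta`` zero-mean normal, independent
of ``T`` and of the other methods' errors — which makes attenuation factors
and between-method correlations analytically checkable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "COHORT_COLUMNS",
    "GA_COLUMNS",
    "generate_cohort",
    "apply_availability",
    "simulate_cohort",
    "theoretical_attenuation",
]

GA_COLUMNS = ("ga_us", "ga_fh", "ga_lmp")

COHORT_COLUMNS = (
    "record_id",
    "T_true",
    "ga_us",
    "ga_fh",
    "ga_lmp",
    "maternal_age",
    "education",
    "first_pregnancy",
    "trimester_enrol",
    "malaria",
    "syphilis",
    "hiv",
    "hb_enrol",
    "hb_delivery",
    "muac",
    "baby_sex",
    "birth_weight",
    "neonatal_death",
    "low_birth_weight",
)


def theoretical_attenuation(sigma_T: float, sigma_delta: float) -> float:
    """Reliability ratio of a classically mismeasured exposure.

    Returns ``sigma_T**2 / (sigma_T**2 + sigma_delta**2)``, the factor by
    which classical error shrinks a regression slope toward zero.
    """
    if sigma_T <= 0:
        raise ValueError("sigma_T: must be > 0")
    if sigma_delta < 0:
        raise ValueError("sigma_delta: must be >= 0")
    return sigma_T**2 / (sigma_T**2 + sigma_delta**2)


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float,
                      bounds: tuple[float, float], n: int) -> np.ndarray:
    """Rejection-sample a truncated normal. Deterministic given ``rng``."""
    lo, hi = bounds
    if sigma == 0:
        if not (lo < mu < hi):
            raise ValueError("T_bounds: degenerate distribution outside bounds")
        return np.full(n, mu)
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(mu, sigma, size=max(n, 1000))
        out = np.concatenate([out, draw[(draw > lo) & (draw < hi)]])
    return out[:n]


def _draw_covariates(rng: np.random.Generator, marginals: dict, n: int) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    # iterate in fixed key order so identical seeds give identical cohorts
    for var in sorted(marginals):
        spec = marginals[var]
        dist = spec["dist"]
        if dist == "normal":
            x = rng.normal(spec["mean"], spec["sd"], size=n)
            if "min" in spec or "max" in spec:
                x = np.clip(x, spec.get("min", -np.inf), spec.get("max", np.inf))
            cols[var] = x
        elif dist == "bernoulli":
            cols[var] = (rng.random(n) < spec["p"]).astype(np.int64)
        elif dist == "categorical":
            probs = np.asarray(spec["probs"], dtype=float)
            probs = probs / probs.sum()
            idx = rng.choice(len(probs), size=n, p=probs)
            cols[var] = np.asarray(spec["levels"], dtype=object)[idx]
        else:  # pragma: no cover - blocked by config validation
            raise ValueError(f"unknown dist {dist!r}")
    return cols


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a fully observed cohort (no missingness applied).

    One row per mother-infant pair with the latent ``T_true``, the three GA
    measurements, covariates, birth weight and binary outcomes.  Identical
    config (including seed) gives a byte-identical frame.  Use
    :func:`apply_availability` (or :func:`simulate_cohort`) to impose the
    partial-availability pattern of the three methods.
    """
    config.validate()
    n = config.n_records
    rng = np.random.default_rng(config.seed)

    T = _truncated_normal(rng, config.mu_T, config.sigma_T, config.T_bounds, n)
    ga_us = T + rng.normal(0.0, config.sigma_US, size=n) if config.sigma_US > 0 else T.copy()
    ga_fh = T + config.bias_FH + (rng.normal(0.0, config.sigma_FH, size=n) if config.sigma_FH > 0 else 0.0)
    ga_lmp = T + config.bias_LMP + (rng.normal(0.0, config.sigma_LMP, size=n) if config.sigma_LMP > 0 else 0.0)

    cov = _draw_covariates(rng, config.covariate_marginals, n)

    bw_noise = rng.normal(0.0, config.bw_sigma, size=n) if config.bw_sigma > 0 else np.zeros(n)
    birth_weight = config.bw_intercept + config.bw_slope * (T - config.mu_T) + bw_noise
    birth_weight = np.clip(birth_weight, 300.0, 6800.0)

    logit_p = config.intercept_death + config.lambda_T_death * (T - config.mu_T)
    p_death = 1.0 / (1.0 + np.exp(-logit_p))
    neonatal_death = (rng.random(n) < p_death).astype(np.int64)
    low_birth_weight = (birth_weight < config.lbw_cutoff).astype(np.int64)

    frame = pd.DataFrame(
        {
            "record_id": np.arange(1, n + 1, dtype=np.int64),
            "T_true": T,
            "ga_us": ga_us,
            "ga_fh": ga_fh,
            "ga_lmp": ga_lmp,
            **cov,
            "birth_weight": birth_weight,
            "neonatal_death": neonatal_death,
            "low_birth_weight": low_birth_weight,
        }
    )
    return frame[list(COHORT_COLUMNS)]


def apply_availability(cohort: pd.DataFrame, p_us: float, p_fh: float, p_lmp: float,
                       seed: int | np.random.Generator | None = 0) -> pd.DataFrame:
    """Independently retain each GA measurement with its probability.

    Masked values become NaN; ``T_true`` is never masked.  Returns a copy.
    """
    for name, p in (("p_us", p_us), ("p_fh", p_fh), ("p_lmp", p_lmp)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}: probability must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    for col, p in zip(GA_COLUMNS, (p_us, p_fh, p_lmp)):
        keep = rng.random(n) < p
        out[col] = out[col].where(keep, other=np.nan)
    return out


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a cohort and apply the configured availability pattern."""
    full = generate_cohort(config)
    # separate stream so masking does not perturb the measurement draws
    mask_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    return apply_availability(full, config.p_avail_US, config.p_avail_FH,
                              config.p_avail_LMP, seed=mask_rng)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV with one header row; missing values as empty fields."""
    cohort.to_csv(path, index=False, na_rep="")
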