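"""Simulation configuration for synthetic pregnancy cohorts.

All generator knobs live in :class:`SimulationConfig`.  Defaults are tuned so
that a large simulated cohort reproduces the marginal structure the analysis
modules expect: true gestational age (GA) around 38.7 weeks (SD 2.15),
ultrasound the most precise measure, fundal height (FH) intermediate and last
menstrual period (LMP) the least precise, partial availability of each
method, and rare binary outcomes.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimulationConfig", "load_simulation_config", "DEFAULT_COVARIATE_MARGINALS"]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


#: Default marginal distributions for the error-free covariates Z.
#: ``normal`` entries are optionally clipped to [min, max]; ``categorical``
#: entries carry explicit level labels; ``bernoulli`` entries give P(1).
DEFAULT_COVARIATE_MARGINALS: dict[str, dict[str, Any]] = {
    "maternal_age": {"dist": "normal", "mean": 25.4, "sd": 5.5, "min": 13.0, "max": 50.0},
    "education": {
        "dist": "categorical",
        "levels": ["none", "primary", "secondary", "tertiary"],
        "probs": [0.0098, 0.5590, 0.3090, 0.1222],
    },
    "first_pregnancy": {"dist": "bernoulli", "p": 0.258},
    "trimester_enrol": {"dist": "categorical", "levels": [1, 2, 3], "probs": [0.272, 0.723, 0.005]},
    "malaria": {"dist": "bernoulli", "p": 0.160},
    "syphilis": {"dist": "bernoulli", "p": 0.0087},
    "hiv": {"dist": "bernoulli", "p": 0.187},
    "hb_enrol": {"dist": "normal", "mean": 11.3, "sd": 1.7, "min": 4.0, "max": 20.0},
    "hb_delivery": {"dist": "normal", "mean": 10.2, "sd": 2.3, "min": 4.0, "max": 20.0},
    "muac": {"dist": "normal", "mean": 27.3, "sd": 3.0, "min": 8.0, "max": 45.0},
    "baby_sex": {"dist": "bernoulli", "p": 0.512},
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-cohort generator.

    The latent true GA ``T`` is a truncated normal; each measurement method
    adds an independent zero-mean normal error (plus a fixed bias for FH and
    LMP); birth weight is linear in ``T`` with Gaussian noise; neonatal death
    follows a logistic model in ``T`` centred at ``mu_T``.
    """

    n_records: int = 2750
    mu_T: float = 38.7
    sigma_T: float = 2.15
    T_bounds: tuple[float, float] = (30.0, 44.0)
    sigma_US: float = 0.8
    bias_FH: float = 0.25
    sigma_FH: float = 1.2
    bias_LMP: float = 0.0
    sigma_LMP: float = 3.0
    p_avail_US: float = 0.428
    p_avail_FH: float = 0.917
    p_avail_LMP: float = 0.989
    lambda_T_death: float = -0.2
    intercept_death: float = _logit(0.011)
    bw_intercept: float = 3209.0
    bw_slope: float = 150.0
    bw_sigma: float = 450.0
    lbw_cutoff: float = 2500.0
    covariate_marginals: dict[str, dict[str, Any]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_COVARIATE_MARGINALS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first offending field."""
        if not isinstance(self.n_records, (int,)) or isinstance(self.n_records, bool):
            raise ValueError("n_records: must be an integer")
        if self.n_records < 0:
            raise ValueError("n_records: must be >= 0")
        for name in ("sigma_T", "sigma_US", "sigma_FH", "sigma_LMP", "bw_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: standard deviation must be >= 0")
        for name in ("p_avail_US", "p_avail_FH", "p_avail_LMP"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}: probability must be in [0, 1]")
        lo, hi = self.T_bounds
        if not lo < hi:
            raise ValueError("T_bounds: lower bound must be < upper bound")
        if self.lbw_cutoff <= 0:
            raise ValueError("lbw_cutoff: must be positive")
        known = set(DEFAULT_COVARIATE_MARGINALS)
        unknown = set(self.covariate_marginals) - known
        if unknown:
            raise ValueError(f"covariate_marginals: unknown variables {sorted(unknown)}")
        for var, spec in self.covariate_marginals.items():
            dist = spec.get("dist")
            if dist == "categorical":
                probs = spec["probs"]
                if len(probs) != len(spec["levels"]):
                    raise ValueError(f"covariate_marginals[{var}]: probs/levels length mismatch")
                if any(p < 0 for p in probs) or sum(probs) <= 0:
                    raise ValueError(f"covariate_marginals[{var}]: invalid probs")
            elif dist == "bernoulli":
                if not (0.0 <= spec["p"] <= 1.0):
                    raise ValueError(f"covariate_marginals[{var}]: p must be in [0, 1]")
            elif dist == "normal":
                if spec["sd"] < 0:
                    raise ValueError(f"covariate_marginals[{var}]: sd must be >= 0")
            else:
                raise ValueError(f"covariate_marginals[{var}]: unknown dist {dist!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["T_bounds"] = list(self.T_bounds)
        return d

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML or JSON file.

    Every field is addressable by its name; unknown top-level keys are an
    error (typos must not silently fall back to defaults).
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path}: expected a mapping, got {type(data).__name__}")
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"config file {path}: unknown keys {sorted(unknown)}")
    if "T_bounds" in data:
        data["T_bounds"] = tuple(data["T_bounds"])
    if "covariate_marginals" in data:
        merged = copy.deepcopy(DEFAULT_COVARIATE_MARGINALS)
        for var, spec in data["covariate_marginals"].items():
            if var not in merged:
                raise ValueError(f"config file {path}: unknown covariate {var!r}")
            merged[var].update(spec)
        data["covariate_marginals"] = merged
    return SimulationConfig(**data)
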