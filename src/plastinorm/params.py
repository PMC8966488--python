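"""Model parameters for the breeding-date reaction-norm model.

The phenotype is a linear reaction norm ``y = i + b * n`` mapping an
individual's nutritional condition ``n`` to its breeding date ``y``.  The
optimal breeding date is ``theta = A + B * n``, Gaussian stabilizing
selection of width ``omega_y2`` acts on the mismatch ``theta - y``, a
maintenance cost of plasticity of width ``omega_b2`` acts directly on the
slope ``b``, and nutrition raises log fitness linearly with coefficient
``alpha`` (hard selection: good environments export more offspring).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ModelParams", "PopulationState", "load_params", "save_params", "CONFIG_KEYS"]

#: Keys accepted in flat key-value config files, in canonical order.
CONFIG_KEYS = (
    "A",
    "B",
    "alpha",
    "omega_y2",
    "omega_b2",
    "sigma_n2",
    "sigma_ai2",
    "sigma_ei2",
    "sigma_ab2",
    "sigma_eb2",
    "rho_ib",
)

#: Finite stand-in for an infinite cost width (cost-free plasticity).
NO_COST = 1e12


@dataclass(frozen=True)
class ModelParams:
    """All fixed constants of the model.

    Parameters
    ----------
    A : float
        Optimal breeding date at ``n = 0`` (days).
    B : float
        Slope of the optimum on nutrition (days per nutrition unit).
    alpha : float
        Effect of nutrition on log fitness (per nutrition unit).
    omega_y2 : float
        Width of stabilizing selection on breeding date (days^2);
        larger values mean weaker selection.
    omega_b2 : float
        Width of direct selection against plasticity (slope-units^2);
        larger values mean a cheaper plastic slope.  Use a large finite
        value (e.g. ``1e12``) to represent "no cost".
    sigma_n2 : float
        Variance of nutritional condition (mean is fixed at zero).
    sigma_ai2, sigma_ei2 : float
        Additive-genetic and environmental variance of the intercept.
    sigma_ab2, sigma_eb2 : float
        Additive-genetic and environmental variance of the slope.
    rho_ib : float
        Correlation between intercept and slope values, applied
        identically to the genetic and environmental parts.
    """

    A: float = 0.0
    B: float = -1.0
    alpha: float = 1.0
    omega_y2: float = 20.0
    omega_b2: float = 20.0
    sigma_n2: float = 1.0
    sigma_ai2: float = 1.0
    sigma_ei2: float = 0.0
    sigma_ab2: float = 1.0
    sigma_eb2: float = 0.0
    rho_ib: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_n2",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("omega_y2", "omega_b2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("sigma_ai2", "sigma_ei2", "sigma_ab2", "sigma_eb2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not abs(self.rho_ib) < 1:
            raise ValueError(f"|rho_ib| must be < 1, got {self.rho_ib!r}")

    # -- derived variances -------------------------------------------------
    @property
    def sigma_i2(self) -> float:
        """Total phenotypic variance of the intercept."""
        return self.sigma_ai2 + self.sigma_ei2

    @property
    def sigma_b2(self) -> float:
        """Total phenotypic variance of the slope."""
        return self.sigma_ab2 + self.sigma_eb2

    @property
    def sigma_ib(self) -> float:
        """Phenotypic covariance between intercept and slope."""
        return self.rho_ib * np.sqrt(self.sigma_i2 * self.sigma_b2)

    def genetic_cov(self) -> np.ndarray:
        """2x2 additive-genetic covariance matrix of (intercept, slope)."""
        c = self.rho_ib * np.sqrt(self.sigma_ai2 * self.sigma_ab2)
        return np.array([[self.sigma_ai2, c], [c, self.sigma_ab2]])

    def environmental_cov(self) -> np.ndarray:
        """2x2 environmental covariance matrix of (intercept, slope)."""
        c = self.rho_ib * np.sqrt(self.sigma_ei2 * self.sigma_eb2)
        return np.array([[self.sigma_ei2, c], [c, self.sigma_eb2]])

    def phenotypic_cov(self) -> np.ndarray:
        """2x2 phenotypic covariance matrix of (intercept, slope)."""
        return self.genetic_cov() + self.environmental_cov()

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in CONFIG_KEYS}

    def config_hash(self) -> str:
        """Short stable hash of the parameter set, for output metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PopulationState:
    """Mean reaction norm of the population: intercept ``mu_i`` (days) and
    slope ``mu_b`` (days per nutrition unit)."""

    mu_i: float
    mu_b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu_i) and np.isfinite(self.mu_b)):
            raise ValueError("population means must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu_i, self.mu_b], dtype=float)


def load_params(path: str | Path) -> ModelParams:
    """Read a :class:`ModelParams` from a flat key-value config file.

    Lines look like ``B = -1`` or ``alpha: 0.5``; blank lines and lines
    starting with ``#`` are ignored.  Unknown keys raise ``ValueError``.
    """
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, val = line.partition(sep)
                break
        else:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key = key.strip()
        if key not in CONFIG_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        try:
            values[key] = float(val.strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad value for {key!r}: {val.strip()!r}") from exc
    return ModelParams(**values)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a config file that :func:`load_params` reads back exactly."""
    lines = [f"{k} = {getattr(params, k)!r}" for k in CONFIG_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")
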