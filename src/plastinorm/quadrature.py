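"""Quadrature over the Gaussian distribution of nutritional condition.

Every population-level quantity is an expectation over ``n ~ N(0, sigma_n2)``.
The integrands are smooth and Gaussian-weighted, so Gauss-Hermite quadrature
converges extremely fast; a trapezoid scheme on a truncated grid is kept as a
slow, simple alternative used for convergence cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss

__all__ = ["QuadratureSpec", "QuadratureError"]


class QuadratureError(RuntimeError):
    """Raised when a node-doubling check indicates non-convergence."""


@dataclass(frozen=True)
class QuadratureSpec:
    """How to evaluate integrals against the nutrition density ``f(n)``.

    Parameters
    ----------
    scheme : {"gauss-hermite", "trapezoid"}
    nodes : int
        Number of quadrature nodes (>= 16).
    range_sd : float
        Truncation range in standard deviations of ``n`` (trapezoid only;
        must be >= 6).
    """

    scheme: str = "gauss-hermite"
    nodes: int = 64
    range_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.scheme not in ("gauss-hermite", "trapezoid"):
            raise ValueError(f"unknown quadrature scheme {self.scheme!r}")
        if self.nodes < 16:
            raise ValueError("nodes must be >= 16")
        if self.range_sd < 6:
            raise ValueError("range_sd must be >= 6")

    def nodes_weights(self, sigma_n2: float) -> tuple[np.ndarray, np.ndarray]:
        """Nodes ``n_k`` and weights ``w_k`` such that
        ``sum(w_k * g(n_k)) ~= E[g(n)]`` for ``n ~ N(0, sigma_n2)``."""
        sd = np.sqrt(sigma_n2)
        if self.scheme == "gauss-hermite":
            x, w = hermgauss(self.nodes)
            return np.sqrt(2.0) * sd * x, w / np.sqrt(np.pi)
        grid = np.linspace(-self.range_sd * sd, self.range_sd * sd, self.nodes)
        dens = np.exp(-0.5 * (grid / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        w = dens * np.gradient(grid)
        w[[0, -1]] *= 0.5  # trapezoid end corrections
        return grid, w

    def doubled(self) -> "QuadratureSpec":
        """Same spec with twice the nodes (for convergence checks)."""
        return QuadratureSpec(self.scheme, 2 * self.nodes, self.range_sd)


DEFAULT_QUAD = QuadratureSpec()
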