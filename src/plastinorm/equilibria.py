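"""Equilibria of the mean reaction norm: numeric solutions and the four
closed-form approximations.

At equilibrium the fitness-weighted mean selection gradients on intercept
and slope both vanish.  The joint conditions have no general closed form;
the approximations implemented here are

``cv``
    "constant variance": the phenotypic variance of breeding date,
    a quadratic in ``n``, is replaced by its average.  Yields a closed form
    for the equilibrium intercept *conditional on the mean slope*
    (:func:`approx_intercept_cv`); the slope still requires a 1-D numeric
    solve (``mode='constant'`` of the numeric solver).
``ssv``
    "small slope variance" (``sigma_b2 ~ 0``): the equilibrium slope is a
    root of a cubic (:func:`approx_slope_ssv`), independent of ``alpha``,
    and the intercept is ``A + sigma_n2*alpha*(B - mu_b)``.
``wm_cv``
    "weak mismatch" + constant variance: variation of mean fitness across
    environments is dominated by the direct nutrition effect ``alpha``;
    fully closed form, slope depends on ``alpha``.
``wm_ssv``
    weak mismatch + small slope variance: the classic cost-of-plasticity
    result ``mu_b* = B*sigma_n2*omega_b2 / (sigma_n2*omega_b2 + sigma_i2
    + omega_y2)``, independent of ``alpha``.

All methods predict hypoplasticity (``mu_b*`` between 0 and ``B``) and,
for ``B < 0`` and ``alpha > 0``, a mean breeding date displaced *earlier*
than the optimum (``mu_i* < A``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model import total_response, weighted_mean_gradients
from .params import ModelParams, PopulationState
from .quadrature import DEFAULT_QUAD, QuadratureSpec

__all__ = [
    "EquilibriumSolution",
    "EquilibriumError",
    "solve_equilibrium_numeric",
    "equilibrium_approximation",
    "approx_intercept_cv",
    "approx_intercept_ssv",
    "approx_slope_ssv",
    "approx_slope_wm_cv",
    "approx_slope_wm_ssv",
    "approx_intercept_wm_cv",
    "equilibrium_curve",
    "CLOSED_FORM_METHODS",
]

CLOSED_FORM_METHODS = ("ssv", "wm_cv", "wm_ssv")
_NUMERIC_METHODS = ("numeric_full", "numeric_constant_variance")


class EquilibriumError(RuntimeError):
    """Solver failure; carries the last state and residual reached."""

    def __init__(self, message, state=None, residual=None):
        super().__init__(message)
        self.state = state
        self.residual = residual


@dataclass
class EquilibriumSolution:
    """Equilibrium means plus method label and convergence diagnostics."""

    mu_i_star: float
    mu_b_star: float
    method: str
    converged: bool
    residual: float
    iterations: int = 0

    def state(self) -> PopulationState:
        return PopulationState(self.mu_i_star, self.mu_b_star)


# ---------------------------------------------------------------------------
# closed-form approximations
# ---------------------------------------------------------------------------


def approx_intercept_cv(mu_b: float, params: ModelParams) -> float:
    """Equilibrium intercept under constant phenotypic variance, conditional
    on the mean slope ``mu_b``.

    Exceeds ``A`` exactly when ``B > mu_b * omega_b2 / (sigma_b2 +
    omega_b2)``, so with ``B <= 0`` hyperplasticity is required for the mean
    breeding date to evolve past the optimum.  Note the dependence on the
    cost of plasticity even conditional on the mean slope.
    """
    sn2, a = params.sigma_n2, params.alpha
    sb2, wb2 = params.sigma_b2, params.omega_b2
    c1 = sb2 + wb2
    Vy = params.omega_y2 + params.sigma_i2 + sb2 * sn2
    d1 = params.B - mu_b
    return params.A + a * sn2 * Vy * (c1 * d1 + mu_b * sb2) / (c1 * Vy - d1 * sn2 * mu_b * sb2)


def approx_intercept_ssv(mu_b: float, params: ModelParams) -> float:
    """Equilibrium intercept with little slope variance:
    ``A + sigma_n2 * alpha * (B - mu_b)``.

    Any hypoplasticity (``mu_b`` shallower than ``B < 0``) displaces the
    mean breeding date earlier than the optimum; with ``B = 0`` and the
    slope pinned at -1 it recovers the classic result that the mean exceeds
    the optimum by ``sigma_n2 * alpha``.
    """
    return params.A + params.sigma_n2 * params.alpha * (params.B - mu_b)


#: identical closed form in the weak-mismatch regime
approx_intercept_wm_ssv = approx_intercept_ssv


def _ssv_cubic_coeffs(params: ModelParams) -> tuple[float, float, float, float]:
    """Coefficients (monic-izable) of the equilibrium-slope cubic
    ``sn2*m^3 - 2B*sn2*m^2 + (V + sn2*wb2 + B^2*sn2)*m - B*sn2*wb2 = 0``
    with ``V = sigma_i2 + omega_y2``; alpha does not appear."""
    sn2, B, wb2 = params.sigma_n2, params.B, params.omega_b2
    V = params.sigma_i2 + params.omega_y2
    return sn2, -2 * B * sn2, V + sn2 * wb2 + B * B * sn2, -B * sn2 * wb2


def _admissible(roots: Iterable[float], params: ModelParams) -> list[float]:
    lo, hi = min(0.0, params.B), max(0.0, params.B)
    tol = 1e-9 * (1 + abs(params.B))
    return sorted({float(r) for r in roots if lo - tol <= r <= hi + tol})


def _ssv_root_numpy(params: ModelParams) -> float:
    roots = np.roots(_ssv_cubic_coeffs(params))
    real = roots[np.abs(roots.imag) < 1e-8 * (1 + np.abs(roots.real))].real
    ok = _admissible(real, params)
    if not ok:
        raise EquilibriumError(
            f"no admissible real root of the slope cubic for B={params.B!r}; roots={roots!r}"
        )
    if len(ok) > 1:
        # select by continuity in B: follow the branch from mu_b*(B=0) = 0
        warnings.warn(
            f"multiple admissible slope roots at B={params.B!r}; selecting by continuation",
            RuntimeWarning,
        )
        prev = 0.0
        for Bk in np.linspace(0.0, params.B, 65)[1:]:
            cand = np.roots(_ssv_cubic_coeffs(params.replace(B=float(Bk))))
            cand = cand[np.abs(cand.imag) < 1e-8].real
            prev = cand[np.argmin(np.abs(cand - prev))]
        return float(prev)
    return ok[0]


def _ssv_root_cardano(params: ModelParams) -> float:
    """Closed-form (Cardano / trigonometric) real root of the slope cubic,
    on the branch continuous from ``mu_b*(B=0) = 0``."""
    c3, c2, c1, c0 = _ssv_cubic_coeffs(params)
    a, b, c = c2 / c3, c1 / c3, c0 / c3
    p = b - a * a / 3
    q = 2 * a**3 / 27 - a * b / 3 + c
    shift = -a / 3  # = 2B/3
    disc = (q / 2) ** 2 + (p / 3) ** 3
    if disc >= 0:
        s = math.sqrt(disc)
        t = math.copysign(abs(-q / 2 + s) ** (1 / 3), -q / 2 + s) + math.copysign(
            abs(-q / 2 - s) ** (1 / 3), -q / 2 - s
        )
        return t + shift
    # three real roots: pick the admissible one
    r = 2 * math.sqrt(-p / 3)
    phi = math.acos(3 * q / (p * r))
    roots = [r * math.cos((phi - 2 * math.pi * k) / 3) + shift for k in range(3)]
    ok = _admissible(roots, params)
    if not ok:
        raise EquilibriumError(f"no admissible trigonometric root for B={params.B!r}")
    return ok[0] if len(ok) == 1 else _ssv_root_numpy(params)


def approx_slope_ssv(params: ModelParams) -> float:
    """Equilibrium slope with little slope variance (root of a cubic).

    Computed both from the closed-form radical expression and from the
    numeric roots of the same cubic; the two must agree to 1e-9.  The
    result does not depend on ``alpha``, always lies between 0 and ``B``
    (hypoplasticity), and is non-monotonic in ``B``: plasticity is greatest
    at intermediate optimum slopes and is selected against when the
    environmental dependence of the optimum becomes too steep.
    """
    if params.B == 0:
        return 0.0
    closed = _ssv_root_cardano(params)
    numeric = _ssv_root_numpy(params)
    if abs(closed - numeric) > 1e-9 * (1 + abs(numeric)):
        raise EquilibriumError(
            f"cardano ({closed!r}) and numeric ({numeric!r}) cubic roots disagree"
        )
    return closed


def approx_slope_wm_cv(params: ModelParams) -> float:
    """Equilibrium slope under weak mismatch and constant variance.

    The only approximation in which the equilibrium slope depends on
    ``alpha``; the magnitude decreases monotonically in ``alpha**2``.
    """
    sn2, wb2, sb2 = params.sigma_n2, params.omega_b2, params.sigma_b2
    denom = sn2 * wb2 * (1 + sb2 * sn2 * params.alpha**2 / (sb2 + wb2)) \
        + params.sigma_i2 + params.omega_y2
    return params.B * sn2 * wb2 / denom


def approx_slope_wm_ssv(params: ModelParams) -> float:
    """Equilibrium slope under weak mismatch and little slope variance:
    ``B*sn2*wb2 / (sn2*wb2 + si2 + wy2)``.

    Equivalent to the soft-selection (cost-of-plasticity) result; tends to
    perfect plasticity ``mu_b* -> B`` as the cost vanishes, and does not
    depend on ``alpha``.
    """
    sn2, wb2 = params.sigma_n2, params.omega_b2
    return params.B * sn2 * wb2 / (sn2 * wb2 + params.sigma_i2 + params.omega_y2)


def approx_intercept_wm_cv(mu_b: float, params: ModelParams) -> float:
    """Equilibrium intercept under weak mismatch and constant variance:
    ``A + sn2*alpha*(B - mu_b*wb2/(sb2 + wb2))``."""
    wb2, sb2 = params.omega_b2, params.sigma_b2
    return params.A + params.sigma_n2 * params.alpha * (
        params.B - mu_b * wb2 / (sb2 + wb2)
    )


def equilibrium_approximation(params: ModelParams, method: str) -> EquilibriumSolution:
    """Joint (intercept, slope) equilibrium from one closed-form method."""
    if method == "ssv":
        mu_b = approx_slope_ssv(params)
        mu_i = approx_intercept_ssv(mu_b, params)
    elif method == "wm_cv":
        mu_b = approx_slope_wm_cv(params)
        mu_i = approx_intercept_wm_cv(mu_b, params)
    elif method == "wm_ssv":
        mu_b = approx_slope_wm_ssv(params)
        mu_i = approx_intercept_wm_ssv(mu_b, params)
    else:
        raise ValueError(f"unknown closed-form method {method!r}; use one of {CLOSED_FORM_METHODS}")
    return EquilibriumSolution(mu_i, mu_b, method, converged=True, residual=np.nan)


# ---------------------------------------------------------------------------
# numeric solution of the joint equilibrium conditions
# ---------------------------------------------------------------------------


def _auto_init(params: ModelParams) -> PopulationState:
    """Weak-mismatch closed forms: cheap and near the answer."""
    mu_b = approx_slope_wm_cv(params)
    return PopulationState(approx_intercept_wm_cv(mu_b, params), mu_b)


def solve_equilibrium_numeric(
    params: ModelParams,
    quad: QuadratureSpec = DEFAULT_QUAD,
    mode: str = "exact",
    init: PopulationState | str = "auto",
    damping: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> EquilibriumSolution:
    """Solve the joint equilibrium conditions numerically.

    Damped fixed-point iteration of the total response (mimicking the
    evolutionary dynamics, so the stable equilibrium is found) followed by
    derivative-free root polishing.  Coordinates without genetic variance
    are held fixed at their initial values (e.g. a slope pinned at -1),
    and the equilibrium is solved on the evolvable coordinates only.

    Raises :class:`EquilibriumError` with the last state and residual on
    non-convergence.
    """
    method = "numeric_full" if mode == "exact" else "numeric_constant_variance"
    state = _auto_init(params) if isinstance(init, str) else PopulationState(init.mu_i, init.mu_b)
    G = params.genetic_cov()
    free = np.diag(G) > 0
    if not free.any():
        raise EquilibriumError("no genetic variance in either trait; nothing evolves")

    # exact short-circuits at known fixed points
    if params.B == 0 and free.all():
        sol = EquilibriumSolution(params.A, 0.0, method, True, 0.0, 0)
        sol.residual = float(np.max(np.abs(
            total_response(sol.state(), params, quad, mode).as_array())))
        return sol
    mu = state.as_array()
    if params.alpha == 0 and free.all():
        mu[0] = params.A  # weighted intercept gradient is odd in n at mu_i = A

    def grad_free(x: np.ndarray) -> np.ndarray:
        m = mu.copy()
        m[free] = x
        return weighted_mean_gradients(PopulationState(*m), params, quad, mode)[free]

    iterations = 0
    Gff = G[np.ix_(free, free)]
    g = grad_free(mu[free])
    while np.max(np.abs(g)) > 1e-6 and iterations < max_iter:
        mu[free] = mu[free] + damping * (Gff @ g)
        g = grad_free(mu[free])
        iterations += 1

    result = optimize.root(grad_free, mu[free], method="hybr", tol=1e-13)
    mu[free] = result.x
    g = grad_free(mu[free])
    resp = Gff @ g
    residual = float(np.max(np.abs(resp)))
    converged = bool(np.max(np.abs(g)) < tol)
    if not converged:
        raise EquilibriumError(
            f"equilibrium solver did not converge (max |gradient| = {np.max(np.abs(g)):.3e})",
            state=PopulationState(*mu),
            residual=residual,
        )
    return EquilibriumSolution(float(mu[0]), float(mu[1]), method, converged, residual,
                               iterations)


# ---------------------------------------------------------------------------
# curves over a swept parameter (the analytic lines of the B- and alpha-sweeps)
# ---------------------------------------------------------------------------


def equilibrium_curve(
    params: ModelParams,
    grid: Sequence[float],
    variable: str = "B",
    methods: Sequence[str] = CLOSED_FORM_METHODS,
    quad: QuadratureSpec = DEFAULT_QUAD,
) -> pd.DataFrame:
    """Equilibrium estimates for every grid value and method.

    Returns a tidy table with columns ``method, B, alpha, mu_i_star,
    mu_b_star, residual, converged``.  ``residual`` is the maximum absolute
    total response evaluated at the returned state with the exact
    machinery, so it doubles as a measure of approximation error.  Failed
    points are marked ``converged=False`` rather than aborting the sweep.
    """
    if variable not in ("B", "alpha"):
        raise ValueError("variable must be 'B' or 'alpha'")
    rows = []
    for value in grid:
        p = params.replace(**{variable: float(value)})
        for method in methods:
            name = {"cv": "numeric_constant_variance"}.get(method, method)
            row = dict(method=name, B=p.B, alpha=p.alpha,
                       mu_i_star=np.nan, mu_b_star=np.nan,
                       residual=np.nan, converged=False)
            try:
                if name in CLOSED_FORM_METHODS:
                    sol = equilibrium_approximation(p, name)
                elif name in _NUMERIC_METHODS:
                    sol = solve_equilibrium_numeric(
                        p, quad, mode="exact" if name == "numeric_full" else "constant")
                else:
                    raise ValueError(f"unknown method {method!r}")
                resp = total_response(sol.state(), p, quad, mode="exact")
                row.update(mu_i_star=sol.mu_i_star, mu_b_star=sol.mu_b_star,
                           residual=float(np.max(np.abs(resp.as_array()))),
                           converged=True)
            except (EquilibriumError, ValueError) as exc:
                warnings.warn(f"{variable}={value}, {method}: {exc}", RuntimeWarning)
            rows.append(row)
    return pd.DataFrame(rows)
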