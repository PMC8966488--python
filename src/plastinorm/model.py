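"""Fitness, selection gradients, and fitness-weighted responses.

The model
---------
An individual has a linear reaction norm ``y = i + b * n`` for breeding date
``y`` on nutritional condition ``n``, with intercept ``i`` and plastic slope
``b`` jointly Gaussian across the population.  Absolute fitness is

    W(y, b, n) = exp( alpha*n - (theta - y)^2 / (2*omega_y2)
                              - b^2 / (2*omega_b2) ),

where ``theta = A + B*n`` is the nutrition-dependent optimum.  The ``alpha``
term makes selection *hard*: well-nourished environments contribute more
offspring to the next generation, so the total response to selection weights
each environment by its mean absolute fitness.

Within an environment ``n`` the selection gradients on the mean intercept and
mean slope are the derivatives of ``ln Wbar(n)`` (Lande), and the total
response averages the per-environment responses with weights
``Wbar(n) f(n) / Wbar`` where ``f`` is the nutrition density.

Implementation notes
--------------------
``Wbar(n) = E[W | n]`` is a bivariate Gaussian integral with an exact closed
form.  Writing the exponent of ``W`` as ``-x'Qx/2 + l'x + c`` in
``x = (i, b)``, with ``x ~ N(mu, S)``:

    Wbar(n)  = |I + S Q|^(-1/2) exp( c + l'mu - mu'Q mu/2
                                     + r'(I + S Q)^(-1) S r / 2 ),
    grad ln Wbar(n) = (I + Q S)^(-1) r,        r = l - Q mu.

These identities hold for any covariance ``S`` (including singular and
correlated cases) and reproduce the standard rational closed forms when the
intercept-slope covariance is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams, PopulationState
from .quadrature import DEFAULT_QUAD, QuadratureError, QuadratureSpec

__all__ = [
    "ResponseVector",
    "optimal_breeding_date",
    "individual_fitness",
    "env_mean_fitness",
    "selection_gradient_intercept",
    "selection_gradient_slope",
    "selection_gradients",
    "response_in_environment",
    "global_mean_fitness",
    "total_response",
    "weighted_mean_gradients",
    "environment_weights",
    "phenotypic_variance",
    "constant_phenotypic_variance",
]


@dataclass
class ResponseVector:
    """Per-generation change in the mean intercept and mean slope."""

    d_mu_i: float
    d_mu_b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d_mu_i, self.d_mu_b], dtype=float)


def optimal_breeding_date(n, params: ModelParams):
    """Optimal breeding date ``theta = A + B*n`` (days)."""
    return params.A + params.B * np.asarray(n, dtype=float)


def individual_fitness(y, b, n, params: ModelParams):
    """Absolute fitness of an individual with breeding date ``y``, plastic
    slope ``b``, in nutritional condition ``n``.  Strictly positive."""
    theta = optimal_breeding_date(n, params)
    y = np.asarray(y, dtype=float)
    b = np.asarray(b, dtype=float)
    n = np.asarray(n, dtype=float)
    return np.exp(
        params.alpha * n
        - (theta - y) ** 2 / (2 * params.omega_y2)
        - b**2 / (2 * params.omega_b2)
    )


# ---------------------------------------------------------------------------
# exact Gaussian-integral machinery (any covariance, possibly singular)
# ---------------------------------------------------------------------------


def _quadratic_pieces(n: np.ndarray, params: ModelParams):
    """Q(n), l(n), c(n) of the fitness exponent -x'Qx/2 + l'x + c, x=(i,b)."""
    n = np.atleast_1d(np.asarray(n, dtype=float))
    k = n.shape[0]
    wy2, wb2 = params.omega_y2, params.omega_b2
    theta = params.A + params.B * n
    a = np.stack([np.ones(k), n], axis=-1)  # (k, 2)
    Q = a[:, :, None] * a[:, None, :] / wy2
    Q[:, 1, 1] += 1.0 / wb2
    ell = theta[:, None] * a / wy2
    c = params.alpha * n - theta**2 / (2 * wy2)
    return Q, ell, c


def _log_wbar_and_grad(n, state: PopulationState, params: ModelParams):
    """(ln Wbar(n), grad ln Wbar(n)) for an array of environments ``n``.

    Exact for any intercept-slope correlation and for degenerate (zero)
    variances.
    """
    Q, ell, c = _quadratic_pieces(n, params)
    mu = state.as_array()
    S = params.phenotypic_cov()
    eye = np.eye(2)
    M = eye + S[None, :, :] @ Q  # I + S Q, shape (k, 2, 2)
    r = ell - Q @ mu  # (k, 2)
    det = np.linalg.det(M)
    if np.any(det <= 0):
        raise ValueError("non-positive-definite fitness integral; check omega_y2/omega_b2")
    Sr = r @ S.T
    x = np.linalg.solve(M, Sr[..., None])[..., 0]  # (I+SQ)^-1 S r
    log_wbar = c + ell @ mu - 0.5 * np.einsum("i,kij,j->k", mu, Q, mu) \
        - 0.5 * np.log(det) + 0.5 * np.einsum("ki,ki->k", r, x)
    # grad = (I + Q S)^-1 r; note (I + Q S) = M^T component-wise per node
    grad = np.linalg.solve(np.swapaxes(M, -1, -2), r[..., None])[..., 0]
    return log_wbar, grad


# ---------------------------------------------------------------------------
# constant-variance approximation
# ---------------------------------------------------------------------------


def _log_wbar_and_grad_cv(n, state: PopulationState, params: ModelParams):
    """Constant-variance approximation of (ln Wbar(n), grad ln Wbar(n)).

    The phenotypic variance of breeding date, a quadratic in ``n``, is
    replaced by its average ``sigma_y2 = sigma_i2 + sigma_b2*sigma_n2``,
    and the breeding-date and slope factors of mean fitness are treated as
    independent.  Requires zero intercept-slope correlation.
    """
    if params.rho_ib != 0:
        raise ValueError(
            "the constant-variance approximation assumes zero intercept-slope "
            "correlation; use mode='exact' for rho_ib != 0"
        )
    n = np.atleast_1d(np.asarray(n, dtype=float))
    si2, sb2 = params.sigma_i2, params.sigma_b2
    wy2, wb2 = params.omega_y2, params.omega_b2
    Vy = wy2 + constant_phenotypic_variance(params)
    Vb = wb2 + sb2
    delta = params.A + params.B * n - state.mu_i - n * state.mu_b
    log_wbar = (
        params.alpha * n
        - delta**2 / (2 * Vy)
        - state.mu_b**2 / (2 * Vb)
        + 0.5 * np.log(wy2 / Vy)
        + 0.5 * np.log(wb2 / Vb)
    )
    denom = wb2 * (wy2 + constant_phenotypic_variance(params)) + sb2 * (wy2 + si2)
    grad = np.stack(
        [
            (delta * (sb2 + wb2) + n * state.mu_b * sb2) / denom,
            (n * delta * wb2 - state.mu_b * (si2 + wy2)) / denom,
        ],
        axis=-1,
    )
    return log_wbar, grad


def _log_wbar_grad(n, state, params, mode):
    if mode == "exact":
        return _log_wbar_and_grad(n, state, params)
    if mode == "constant":
        return _log_wbar_and_grad_cv(n, state, params)
    raise ValueError(f"unknown variance mode {mode!r}")


# ---------------------------------------------------------------------------
# public per-environment quantities
# ---------------------------------------------------------------------------


def env_mean_fitness(n, state: PopulationState, params: ModelParams, mode: str = "exact"):
    """Mean absolute fitness ``Wbar(n)`` in environment ``n``."""
    log_wbar, _ = _log_wbar_grad(n, state, params, mode)
    out = np.exp(log_wbar)
    return float(out[0]) if np.isscalar(n) or np.ndim(n) == 0 else out


def selection_gradients(n, state: PopulationState, params: ModelParams, mode: str = "exact"):
    """Selection gradients ``(beta_mu_i(n), beta_mu_b(n))``.

    With zero intercept-slope covariance these equal the rational closed
    forms

        beta_mu_i(n) = [ D(n)*(sb2+wb2) + n*mu_b*sb2 ] / d(n)
        beta_mu_b(n) = [ n*D(n)*wb2 - mu_b*(si2+wy2) ] / d(n)

    with mismatch ``D(n) = A + B*n - mu_i - n*mu_b`` and denominator
    ``d(n) = (si2+wy2)*(sb2+wb2) + n^2*wb2*sb2``; the slope gradient keeps
    its direct cost term, so it is nonzero at ``n = 0`` whenever
    ``mu_b != 0``.  For nonzero correlation the exact linear-algebra path
    is used instead.
    """
    _, grad = _log_wbar_grad(n, state, params, mode)
    return grad[0] if np.isscalar(n) or np.ndim(n) == 0 else grad


def selection_gradient_intercept(n, state, params, mode: str = "exact"):
    """``d ln Wbar(n) / d mu_i``."""
    g = selection_gradients(n, state, params, mode)
    return g[..., 0] if np.ndim(n) else float(g[0])


def selection_gradient_slope(n, state, params, mode: str = "exact"):
    """``d ln Wbar(n) / d mu_b`` (includes the direct cost-of-plasticity term)."""
    g = selection_gradients(n, state, params, mode)
    return g[..., 1] if np.ndim(n) else float(g[1])


def response_in_environment(n, state, params, mode: str = "exact") -> ResponseVector:
    """Per-environment response to selection, ``G @ beta(n)`` (Lande)."""
    beta = selection_gradients(n, state, params, mode)
    d = params.genetic_cov() @ np.asarray(beta, dtype=float)
    return ResponseVector(float(d[0]), float(d[1]))


# ---------------------------------------------------------------------------
# expectations over the nutrition distribution
# ---------------------------------------------------------------------------


def _weighted_quantities(state, params, quad: QuadratureSpec, mode: str):
    """Nodes, normalized hard-selection weights w_k, gradients, and Wbar."""
    nodes, wq = quad.nodes_weights(params.sigma_n2)
    log_wbar, grad = _log_wbar_grad(nodes, state, params, mode)
    # stabilized: Wbar = sum wq*exp(log_wbar); weights w_k = wq*Wbar(n)/Wbar
    m = np.max(log_wbar)
    scaled = wq * np.exp(log_wbar - m)
    total = scaled.sum()
    wbar = float(total * np.exp(m))
    return nodes, scaled / total, grad, wbar


def global_mean_fitness(
    state: PopulationState,
    params: ModelParams,
    quad: QuadratureSpec = DEFAULT_QUAD,
    mode: str = "exact",
    check: bool = False,
) -> float:
    """Global mean fitness ``Wbar = int Wbar(n) f(n) dn``.

    With ``check=True`` a node-doubling comparison is run and a
    :class:`~plastinorm.quadrature.QuadratureError` raised if the two
    results differ by more than 1e-8 relative.
    """
    *_, wbar = _weighted_quantities(state, params, quad, mode)
    if check:
        *_, wbar2 = _weighted_quantities(state, params, quad.doubled(), mode)
        if abs(wbar2 - wbar) > 1e-8 * abs(wbar2):
            raise QuadratureError(
                f"global mean fitness not converged: {wbar!r} vs {wbar2!r} "
                f"at {quad.nodes} vs {2 * quad.nodes} nodes"
            )
    return wbar


def environment_weights(state, params, quad: QuadratureSpec = DEFAULT_QUAD, mode: str = "exact"):
    """Nodes and normalized weights ``w_k ~ Wbar(n_k) f(n_k) / Wbar``.

    The weights sum to one: they are the relative demographic contributions
    of each nutritional environment under hard selection.
    """
    nodes, w, _, _ = _weighted_quantities(state, params, quad, mode)
    return nodes, w


def weighted_mean_gradients(
    state: PopulationState,
    params: ModelParams,
    quad: QuadratureSpec = DEFAULT_QUAD,
    mode: str = "exact",
) -> np.ndarray:
    """Fitness-weighted mean selection gradients (zero at equilibrium)."""
    _, w, grad, _ = _weighted_quantities(state, params, quad, mode)
    return w @ grad


def total_response(
    state: PopulationState,
    params: ModelParams,
    quad: QuadratureSpec = DEFAULT_QUAD,
    mode: str = "exact",
) -> ResponseVector:
    """Total (fitness-weighted) response to selection across environments.

    Each environment's Lande response is weighted by the frequency of the
    environment times its relative mean fitness; reduces to the unweighted
    environment average when ``Wbar(n)`` does not vary with ``n``.
    """
    beta_bar = weighted_mean_gradients(state, params, quad, mode)
    d = params.genetic_cov() @ beta_bar
    return ResponseVector(float(d[0]), float(d[1]))


# ---------------------------------------------------------------------------
# phenotypic variance of breeding date
# ---------------------------------------------------------------------------


def phenotypic_variance(n, params: ModelParams):
    """Phenotypic variance of breeding date in environment ``n``:
    ``sigma_i2 + 2*sigma_ib*n + sigma_b2*n^2`` (a quadratic in ``n``)."""
    n = np.asarray(n, dtype=float)
    return params.sigma_i2 + 2 * params.sigma_ib * n + params.sigma_b2 * n**2


def constant_phenotypic_variance(params: ModelParams) -> float:
    """Average phenotypic variance ``sigma_i2 + sigma_b2*sigma_n2`` used by
    the constant-variance approximation (nutrition has mean zero)."""
    return params.sigma_i2 + params.sigma_b2 * params.sigma_n2
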