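"""Individual-based Wright-Fisher simulator with infinitesimal inheritance.

Each generation, every individual's absolute fitness is computed from its
breeding date ``y = i + b*n``, its slope ``b`` and its nutrition ``n``.
Mothers are drawn (with replacement) from the females and fathers from the
males, each with probability proportional to absolute fitness; this is the
hard-selection step, since productive nutritional environments export more
offspring.  Offspring breeding values are Gaussian around the midparent
with half the additive-genetic (co)variance as segregation variance
(infinitesimal model, inbreeding ignored); environmental deviations and
nutritional condition are drawn fresh every generation; the sex ratio is
held at exactly 1:1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams, PopulationState
from .model import individual_fitness

__all__ = [
    "Population",
    "SimConfig",
    "SimulationError",
    "SimulationResult",
    "initialize_population",
    "advance_generation",
    "run_simulation",
    "sweep",
    "block_bootstrap_se",
    "replicate_seed",
]


class SimulationError(RuntimeError):
    """Simulator failure (e.g. total fitness underflow); carries state."""

    def __init__(self, message, population=None):
        super().__init__(message)
        self.population = population


@dataclass
class Population:
    """Per-individual arrays for one generation.

    ``a_*`` are breeding values, ``e_*`` environmental deviations, ``n``
    nutritional condition, ``female`` the sex flag.  Phenotypes are the
    derived reaction-norm intercept ``i = a_i + e_i``, slope
    ``b = a_b + e_b`` and breeding date ``y = i + b*n``.
    """

    a_i: np.ndarray
    a_b: np.ndarray
    e_i: np.ndarray
    e_b: np.ndarray
    n: np.ndarray
    female: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        sizes = {arr.shape for arr in (self.a_i, self.a_b, self.e_i, self.e_b, self.n, self.female)}
        if len(sizes) != 1:
            raise ValueError("all per-individual arrays must have the same length")
        if self.female.sum() * 2 != self.size:
            raise ValueError("population must contain equal numbers of males and females")

    @property
    def size(self) -> int:
        return self.a_i.shape[0]

    @property
    def intercept(self) -> np.ndarray:
        return self.a_i + self.e_i

    @property
    def slope(self) -> np.ndarray:
        return self.a_b + self.e_b

    @property
    def breeding_date(self) -> np.ndarray:
        return self.intercept + self.slope * self.n

    def mean_state(self) -> PopulationState:
        """Mean reaction norm of the current generation."""
        return PopulationState(float(self.intercept.mean()), float(self.slope.mean()))


@dataclass
class SimConfig:
    """Run-length and initialization settings for the simulator.

    ``init_means`` defaults to the analytic (little-slope-variance)
    equilibrium so runs start near their attractor; pass an explicit
    :class:`PopulationState` to start elsewhere.
    """

    pop_size: int = 10_000
    generations: int = 10_000
    window: int = 5_000
    seed: int = 0
    init_means: PopulationState | None = None

    def __post_init__(self) -> None:
        if self.pop_size % 2:
            raise ValueError("pop_size must be even (equal numbers of males and females)")
        if self.window > self.generations:
            raise ValueError("averaging window cannot exceed the number of generations")


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """Matrix square root of a (possibly singular) PSD 2x2 covariance."""
    vals, vecs = np.linalg.eigh(np.asarray(cov, dtype=float))
    if np.any(vals < -1e-12 * max(1.0, np.max(np.abs(vals)))):
        raise ValueError("covariance matrix is not positive semi-definite")
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def _default_init_means(params: ModelParams) -> PopulationState:
    # approximate equilibrium: little-slope-variance closed forms
    from .equilibria import approx_intercept_ssv, approx_slope_ssv

    mu_b = approx_slope_ssv(params)
    return PopulationState(approx_intercept_ssv(mu_b, params), mu_b)


def initialize_population(
    params: ModelParams,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> Population:
    """Found the population.

    Breeding values are bivariate normal around the initial means with the
    additive-genetic (co)variance; environmental deviations and nutrition
    are independent zero-mean normals; sexes are split exactly 50/50.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    means = config.init_means or _default_init_means(params)
    N = config.pop_size
    a = means.as_array() + _draw_deviations(params.genetic_cov(), N, rng)
    e = _draw_deviations(params.environmental_cov(), N, rng)
    n = rng.normal(0.0, np.sqrt(params.sigma_n2), N)
    female = np.zeros(N, dtype=bool)
    female[: N // 2] = True
    return Population(a[:, 0], a[:, 1], e[:, 0], e[:, 1], n, female, generation=0)


def _weighted_parent_draw(idx: np.ndarray, w: np.ndarray, size: int,
                          rng: np.random.Generator, generation: int,
                          population=None, shuffle: bool = False) -> np.ndarray:
    """``size`` fitness-proportional draws (with replacement) from ``idx``.

    Inversion sampling with pre-sorted uniforms (much faster binary search);
    the result is then ordered, so when two such vectors are paired the
    second must be shuffled to keep mother-father pairing independent.
    """
    cdf = np.cumsum(w)
    total = cdf[-1]
    if not np.isfinite(total) or total <= 0:
        raise SimulationError(
            f"all fitnesses vanished in generation {generation} (numerical underflow)",
            population=population)
    parents = idx[np.searchsorted(cdf, np.sort(rng.random(size)) * total, side="right")]
    if shuffle:
        rng.shuffle(parents)
    return parents


def _draw_deviations(cov: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """(size, 2) zero-mean Gaussian draws; skips the RNG when cov is zero."""
    if not cov.any():
        return np.zeros((size, 2))
    return rng.standard_normal((size, 2)) @ _cov_factor(cov).T


def advance_generation(
    pop: Population, params: ModelParams, rng: np.random.Generator
) -> Population:
    """Produce the next generation by fitness-proportional parent sampling.

    Every one of the ``N`` offspring draws its mother from the females and
    its father from the males, each with replacement and with probability
    proportional to absolute fitness (both sexes carry nutrition and a
    breeding-date phenotype, so fitness applies to both identically).
    """
    W = individual_fitness(pop.breeding_date, pop.slope, pop.n, params)
    N = pop.size

    children_a = np.zeros((N, 2))
    for sex_mask, shuffle in ((pop.female, False), (~pop.female, True)):
        idx = np.flatnonzero(sex_mask)
        parents = _weighted_parent_draw(idx, W[idx], N, rng, pop.generation, pop,
                                        shuffle=shuffle)
        children_a[:, 0] += 0.5 * pop.a_i[parents]
        children_a[:, 1] += 0.5 * pop.a_b[parents]
    # segregation noise around the midparent mean
    children_a += _draw_deviations(params.genetic_cov() / 2.0, N, rng)

    e = _draw_deviations(params.environmental_cov(), N, rng)
    n = rng.normal(0.0, np.sqrt(params.sigma_n2), N)
    female = np.zeros(N, dtype=bool)
    female[: N // 2] = True
    return Population(children_a[:, 0], children_a[:, 1], e[:, 0], e[:, 1], n, female,
                      generation=pop.generation + 1)


@dataclass
class SimulationResult:
    """Trajectory of mean intercept/slope plus window-averaged equilibrium."""

    mu_i: np.ndarray  # per-generation mean intercept, length generations+1
    mu_b: np.ndarray
    window: int
    config: SimConfig = field(repr=False, default=None)

    @property
    def mu_i_hat(self) -> float:
        """Window-averaged equilibrium estimate of the mean intercept."""
        return float(self.mu_i[-self.window:].mean())

    @property
    def mu_b_hat(self) -> float:
        return float(self.mu_b[-self.window:].mean())

    def se(self, block: int = 100, n_boot: int = 500, seed: int = 12345) -> tuple[float, float]:
        """Block-bootstrap Monte-Carlo standard errors of the window means."""
        return (
            block_bootstrap_se(self.mu_i[-self.window:], block, n_boot, seed),
            block_bootstrap_se(self.mu_b[-self.window:], block, n_boot, seed + 1),
        )


def block_bootstrap_se(series: np.ndarray, block: int = 100, n_boot: int = 500,
                       seed: int = 12345) -> float:
    """SE of the mean of an autocorrelated series via a block bootstrap.

    The series is cut into contiguous blocks (default 100 generations, long
    relative to the mixing time of the mean-phenotype process) that are
    resampled with replacement.
    """
    series = np.asarray(series, dtype=float)
    nblocks = series.size // block
    if nblocks < 2:
        return float("nan")
    means = series[: nblocks * block].reshape(nblocks, block).mean(axis=1)
    rng = np.random.default_rng(seed)
    draws = means[rng.integers(0, nblocks, size=(n_boot, nblocks))].mean(axis=1)
    return float(draws.std(ddof=1))


def run_simulation(params: ModelParams, config: SimConfig) -> SimulationResult:
    """Evolve the population and estimate the equilibrium means.

    Deterministic given ``config.seed``: the full trajectory of
    per-generation means is returned together with the average over the
    final ``config.window`` generations.
    """
    rng = np.random.default_rng(config.seed)
    pop = initialize_population(params, config, rng)
    mu_i = np.empty(config.generations + 1)
    mu_b = np.empty(config.generations + 1)
    state = pop.mean_state()
    mu_i[0], mu_b[0] = state.mu_i, state.mu_b
    for gen in range(1, config.generations + 1):
        try:
            pop = advance_generation(pop, params, rng)
        except SimulationError as exc:
            raise SimulationError(f"generation {gen}: {exc}", population=exc.population) from exc
        state = pop.mean_state()
        mu_i[gen], mu_b[gen] = state.mu_i, state.mu_b
    return SimulationResult(mu_i, mu_b, config.window, config)


def replicate_seed(master_seed: int, grid_value: float, replicate: int) -> int:
    """Stable per-replicate seed from (master seed, grid value, replicate).

    Independent of execution order, so sweeps can be parallelized or
    subset without changing any individual run.
    """
    ss = np.random.SeedSequence(
        [int(master_seed), int(replicate)],
        spawn_key=(np.frombuffer(np.float64(grid_value).tobytes(), dtype=np.uint32) % (2**31)).tolist(),
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def sweep(
    params: ModelParams,
    config: SimConfig,
    variable: str,
    grid,
    replicates: int = 1,
) -> "pd.DataFrame":
    """Window-averaged equilibrium estimates across a swept parameter.

    One row per (grid value, replicate) with the seed used and
    block-bootstrap standard errors.  Failures are recorded per point and
    the sweep continues.
    """
    import pandas as pd

    if variable not in ("B", "alpha"):
        raise ValueError("variable must be 'B' or 'alpha'")
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    rows = []
    for value in grid:
        p = params.replace(**{variable: float(value)})
        for rep in range(replicates):
            seed = replicate_seed(config.seed, float(value), rep)
            cfg = SimConfig(config.pop_size, config.generations, config.window, seed,
                            config.init_means)
            row = dict(variable=variable, value=float(value), replicate=rep, seed=seed,
                       mu_i_hat=np.nan, mu_b_hat=np.nan, mu_i_se=np.nan, mu_b_se=np.nan,
                       ok=False)
            try:
                res = run_simulation(p, cfg)
                se_i, se_b = res.se()
                row.update(mu_i_hat=res.mu_i_hat, mu_b_hat=res.mu_b_hat,
                           mu_i_se=se_i, mu_b_se=se_b, ok=True)
            except (SimulationError, ValueError) as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
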