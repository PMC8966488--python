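# Methods

## The model

An individual's breeding date is a linear reaction norm on its nutritional
condition,

    y = i + b n,        i = a_i + e_i,   b = a_b + e_b,

with intercept `i` (breeding date at average nutrition, in days) and plastic
slope `b` (days per nutrition unit), each the sum of a breeding value and an
environmental deviation. Nutrition `n` is normal with mean zero and variance
`σn²` and is redrawn every generation (it is a non-heritable environment, not
a trait). Absolute fitness is

    W(y, b, n) = exp( αn − (θ − y)² / (2ωy²) − b² / (2ωb²) ),
    θ = A + B n,

combining three ingredients:

* **Gaussian stabilizing selection** on breeding date around a
  nutrition-dependent optimum `θ` with width `ωy²` (larger = weaker).
* **A maintenance cost of plasticity**: direct selection of width `ωb²`
  pulling the slope toward zero, independent of the phenotype.
* **Hard selection**: `αn` raises log fitness in good environments, so
  well-nourished environments export disproportionately many offspring.
  The total response to selection therefore weights each environment by
  `W̄(n) f(n) / W̄` — its frequency times its relative mean fitness — rather
  than by `f(n)` alone.

Within an environment the selection gradients on the mean intercept and mean
slope are `∂ ln W̄(n)/∂μ`, and responses follow the multivariate breeder's
equation `Δμ(n) = G β(n)` with `G` the additive-genetic covariance of
(intercept, slope). Equilibria are states where the fitness-weighted mean
gradients vanish.

## Exact Gaussian machinery

`W̄(n) = E[W | n]` is a bivariate Gaussian integral with a closed form.
Writing the fitness exponent as `−x'Qx/2 + l'x + c` in `x = (i, b)`, with
`x ~ N(μ, Σ)`:

    W̄(n) = |I + ΣQ|^(−1/2) exp( c + l'μ − μ'Qμ/2 + r'(I + ΣQ)^(−1)Σ r/2 ),
    ∇_μ ln W̄(n) = (I + QΣ)^(−1) r,          r = l − Qμ.

These identities hold for **any** phenotypic covariance Σ — including
singular (zero-variance) and correlated (ρ ≠ 0) cases — so the analytic
layer needs no finite-difference fallback for correlated traits; finite
differences serve only as an independent oracle in the test suite. With
zero intercept–slope covariance the gradients reduce to the rational closed
forms

    β_μi(n) = [Δ(n)(σb²+ωb²) + n μb σb²] / d(n)
    β_μb(n) = [n Δ(n) ωb² − μb(σi²+ωy²)] / d(n)
    d(n)    = (σi²+ωy²)(σb²+ωb²) + n² ωb² σb²,

with mean mismatch `Δ(n) = A + Bn − μi − n μb`; the slope gradient keeps its
direct cost term, so it is nonzero at `n = 0` whenever `μb ≠ 0`.

Expectations over `n` use Gauss–Hermite quadrature (64 nodes by default;
the integrands are smooth and Gaussian-weighted, and a node-doubling check
can be requested, with relative tolerance 1e−8). A trapezoid scheme on a
truncated grid (≥ 6 SD) exists for cross-checks, and scipy adaptive
quadrature is used as the oracle in tests.

## Variance modes

The phenotypic variance of breeding date is the quadratic
`σy²(n) = σi² + 2σib n + σb² n²`. Two modes are exposed throughout:

* `exact` — the full Gaussian machinery above (default);
* `constant` — the constant-variance approximation `σy² = σi² + σb²σn²`,
  which treats the breeding-date and slope factors of mean fitness as
  independent and drops the `n`-dependence of `d(n)`. It requires
  `ρ_ib = 0` and is the regime in which the conditional equilibrium
  intercept has a closed form.

## Equilibrium solvers

`solve_equilibrium_numeric` mimics the evolutionary dynamics: damped
fixed-point iteration of the total response (damping 0.5, so the stable
equilibrium is approached monotonically) followed by derivative-free root
polishing (scipy hybr) on the weighted mean gradients; convergence demands
max |gradient| < 1e−8, and the reported residual is the max |total
response| at the solution. Traits without genetic variance are pinned at
their initial value and excluded from the root-find (this is how the
fixed-slope configuration is solved). Known fixed points short-circuit:
`B = 0` returns `(A, 0)` exactly, and `α = 0` pins `μi = A` (the weighted
intercept gradient is odd in `n` there). The auto initializer uses the
weak-mismatch closed forms, which are cheap and land near the answer in
all regimes studied.

Four closed-form approximations are implemented:

* **cv** (constant variance): conditional on the mean slope,
  `μi* = A + ασn² Vy (c₁(B−μb) + μb σb²) / (c₁Vy − (B−μb)σn² μb σb²)` with
  `c₁ = σb²+ωb²`, `Vy = ωy²+σi²+σb²σn²`. It satisfies the threshold
  property `μi* > A ⇔ B > μb ωb²/(σb²+ωb²)`: with `B ≤ 0`, only
  *hyper*plasticity can push the mean breeding date past the optimum. The
  equilibrium intercept depends on the cost of plasticity even conditional
  on the mean slope; the package reproduces this dependence as a property
  of the algebra without attempting to explain it.
* **ssv** (small slope variance, `σb² ≈ 0`): the slope solves the cubic
  `σn² μ³ − 2Bσn² μ² + (σi²+ωy²+σn²ωb²+B²σn²) μ − Bσn²ωb² = 0`, computed
  both by the Cardano/trigonometric closed form and by numeric root-finding
  (the two must agree to 1e−9; the admissible branch is continuous from
  `μb*(B=0) = 0` and lies in `[B, 0]`, and in the rare multi-root corner is
  selected by continuation in `B` with a logged warning). The intercept is
  `μi* = A + σn²α(B − μb)` — this form drops out of the derivation exactly,
  which is why it coincides with the weak-mismatch version. The slope is
  independent of `α` and non-monotonic in `B`: when the optimum depends too
  steeply on the environment, mean fitness in extreme environments
  collapses, those environments stop contributing offspring, and the
  population specializes on average environments — plasticity is selected
  *against*.
* **wm_cv** (weak mismatch + constant variance): fully closed form;
  `μb* = Bσn²ωb² / (σn²ωb²(1 + σb²σn²α²/(σb²+ωb²)) + σi² + ωy²)` — the only
  approximation in which the slope depends on `α` (magnitude decreasing in
  `α²`) — and `μi* = A + σn²α(B − μb ωb²/(σb²+ωb²))`.
* **wm_ssv**: `μb* = Bσn²ωb² / (σn²ωb² + σi² + ωy²)`, the classic
  soft-selection cost-of-plasticity result, and the same intercept form as
  ssv.

All four predict hypoplasticity (`B ≤ μb* ≤ 0` for `B < 0`) and, with
`α > 0`, a mean breeding date displaced *earlier* than the optimum
(`μi* < A`) — the reversal of the classic fixed-slope prediction, where a
slope pinned at −1 under a flat optimum (`B = 0`) leaves the mean breeding
date `σn²α` *later* than the optimum.

Several printed forms of these equations circulate with ambiguous
grouping; every closed form in this package was rederived from the fitness
function and is pinned by oracle tests (finite differences for gradients,
1-D root-finds of the weighted gradients for the conditional intercepts,
bisection for the cubic).

## The individual-based simulator

The simulator is the validation layer: a Wright–Fisher-style population of
`N` individuals (default 10,000), equal numbers of males and females, with
infinitesimal-model inheritance. Each generation: fitness is computed for
every individual from Eq. above (both sexes carry nutrition and a
breeding-date phenotype, so fitness applies identically to both); each of
the `N` offspring draws its mother from the females and its father from the
males, fitness-proportionally with replacement; offspring breeding values
are normal around the midparent with segregation covariance `G/2`;
environmental deviations and nutrition are drawn fresh; the sex ratio is
reset to exactly 1:1. Inbreeding is ignored. Heritability below one is
supported through the genetic/environmental variance split (`σai²/σei²`,
`σab²/σeb²`); the default split is heritability one, which speeds
equilibration and leaves equilibria unchanged (they depend on the
(co)variances only through the phenotypic totals). The intercept–slope
correlation knob `ρ_ib` applies the same correlation to the genetic and
environmental parts, so at heritability one it equals the phenotypic
correlation.

Runs are bit-reproducible given the master seed; sweep replicate seeds are
derived stably from (master seed, grid value, replicate index), so sweeps
can be subset or parallelized without changing any run. Window-averaged
equilibrium estimates carry block-bootstrap Monte-Carlo standard errors
(blocks of 100 generations by default, long relative to the ~10–25
generation mixing time of the mean phenotype in the uncorrelated reference
regime).

## What the simulator shows — and what it does not

The simulator validates the analytic layer at two levels. First, the
replicate-averaged one-generation response from any displaced state matches
the fitness-weighted total response within Monte-Carlo error — the central
equations checked directly. Second, long-run window averages match the
numeric equilibrium closely (e.g. at the reference parameterization with
`B = −1`, simulated slope −0.457 ± 0.003 vs numeric −0.450).

Two systematic effects are worth knowing about when comparing simulations
to the closed forms:

* **Stationary-variance depletion.** Selection removes variance faster than
  segregation restores it, so the realized stationary (co)variances sit a
  few percent below their nominal founding values, and the realized
  equilibrium lies between the nominal-variance numeric solution and the
  small-slope-variance curve. The small-slope-variance approximation
  deviates from the simulated slope by about 0.007 at `B = −0.4`, 0.028 at
  `B = −1` and 0.057 at `B = −2` — invisible at figure resolution,
  resolvable with precise Monte-Carlo estimates.
* **Slow mixing under extreme correlations.** At `ρ_ib = ±0.9` the G matrix
  is near-singular and the mean trajectory mixes over hundreds of
  generations. Desk-scale windows (1,500 generations) then under-resolve
  the Monte-Carlo error of window averages, and 100-generation bootstrap
  blocks no longer respect the autocorrelation; comparisons at that scale
  should treat the reported SEs as lower bounds (longer windows and larger
  blocks are used for the correlated-trait consistency tests).

The simulator emulates the idealized protocol, not real bird populations:
discrete non-overlapping generations, no mate choice or assortative mating,
no explicit loci (infinitesimal model), no inbreeding depression, no
fluctuating optimum, and a nutrition value assigned independently each
generation. Passing tests show the analytic theory is internally
consistent and that its approximations have the stated accuracy under the
model's own assumptions — nothing more.

## Problem sizes used

* Analytic tests: 64-node Gauss–Hermite quadrature; oracle comparisons at
  10× nodes or scipy adaptive quadrature.
* Desk-scale simulations ("reduced"): N = 2,000, 3,000 generations,
  averaging window 1,500, 3 replicates, B ∈ {−0.4, −1, −2}.
* The full published protocol (N = 10,000, 10,000 generations, 101 B
  values × 100 replicates) is available behind `scale="full"` and is
  hours-scale; it is not exercised by the test suite.
* The acceptance script's α-contrast: N = 10,000, 6,000 generations with a
  5,000-generation window (runs start at the analytic equilibrium, whose
  mixing time is ~20 generations, so the published 5,000-generation burn-in
  is shortened to 1,000), 10 replicate pairs.

## Numerical choices

* "No cost" is represented by `ωb² = 1e12` rather than infinity (one code
  path).
* Weights `W̄(n)/W̄` are computed with log-sum-exp stabilization, so extreme
  mismatches underflow gracefully.
* Degenerate (zero) variances flow through the same linear-algebra path;
  the covariance factor for simulation uses an eigendecomposition clipped
  at zero, so singular G (fixed traits) is exact.
* All fitnesses vanishing in a generation (total underflow) raises a
  simulation error carrying the offending population state.
* `B = 0` and `α = 0` short-circuit the solver to their exact fixed points.
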