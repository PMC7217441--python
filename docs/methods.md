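# Methods

## Dynamics

The community state is a probability vector `x` over `n` languages. The
flow is built from pairwise transition rates

    P_ji = s_i · x_i^β · (1 − x_j)^(α−β)
    dx_i/dt = Σ_{j≠i} x_j P_ji − x_i Σ_{j≠i} P_ij,

a gain/loss balance whose terms cancel pairwise, so total mass is
conserved analytically. Parameters and their meaning:

| parameter | meaning | constraint | default source |
|---|---|---|---|
| `s_i` | utility (attractiveness) of language i | `s_i > 0`, `Σ s_i = 1` | fixture |
| `β` | majority preference: pull of an already-popular language | `β ≥ 0` | fixture |
| `α − β` | minority aversion: penalty on joining a language whose rival keeps most speakers | `α − β ≥ 0` | fixture |

The convention `0^0 = 1` is used in the rate, so a zero exponent removes
its factor even on the simplex boundary. This matters in the low-`β`
regime (the Indian-community fixture has `β ≈ 0.10`): a language at
fraction zero can still recruit speakers when `β = 0`, whereas for
`β > 0` every vertex of the simplex is absorbing.

For `n = 2` the flow reduces exactly to the classical two-language
Abrams–Strogatz form `dx₁/dt = x₂ s₁ x₁^α − x₁ s₂ x₂^α`; the tests
check this against an independently coded closed form on a parameter
grid.

## Integration and steady states

Integration is explicit Euler with `dt = 1` year by default. The rates
are bounded (`Σ s_i = 1`, all factors ≤ 1), so yearly Euler is stable
here, and a yearly step matches the census-calibrated use of the model;
`dt` is configurable, and a regression test checks that steady-state
labels agree between `dt = 1` and `dt = 0.1`. After each step the
iterate is clipped to `[0, 1]` and renormalized — the flow conserves
mass analytically, but this pins floating-point drift and makes runs
bit-reproducible.

`find_steady_state` integrates until the per-step change falls below
`tol = 1e-6` (max-norm) and reports that time as the convergence time
`τ`. The time cap is `1e5` years: generous on purpose, because critical
slowdown near tipping points stretches `τ` by orders of magnitude.
Non-convergence is a reported outcome (`converged=False`, `τ = max
time`), never an exception.

Equilibria are labelled with an extinction threshold of `1e-3` on the
equilibrium fraction: survivors are the languages at or above it,
**dominance** means exactly one survivor, **coexistence** two or more.
The threshold is a judgment call (the qualitative notion is "an
extremely low level"); `1e-3` is small enough that genuine interior
equilibria of the fixtures never straddle it at the default tolerance.
Ties for the largest fraction break to the lowest index; this only
matters at exactly symmetric points.

## Distance and calibration

The discrepancy between a census series and a parameter vector is the
summed squared difference over languages and census years (no square
root), with the model integrated at yearly steps from the first census
year and sampled at the census years. Census rows are normalized before
comparison (published rows can sum to slightly less than 1 because
residual categories are dropped); rows already on the simplex to within
float roundoff are left bit-identical, so a noise-free synthetic series
has distance exactly zero from its generating model. The initial state
is always the first census row — it is data, not a fitted quantity.

ABC-SMC follows the standard sequential scheme: iteration 0 rejection-
samples the prior against a pilot tolerance; each later iteration
resamples the previous weighted ensemble, perturbs with a Gaussian
kernel, re-simulates, and accepts under the current tolerance. The
kernel covariance is twice the weighted empirical covariance of the
ensemble in the coordinates `(α, β, s_1..s_{n−1})` (the last utility is
one minus the rest). Importance weights are prior density over the
kernel mixture of the previous ensemble, renormalized each iteration.

Prior: `α ~ U(0, 3)`, `β | α ~ U(0, α)` (which encodes both exponent
constraints by construction and makes the joint density ∝ 1/α on its
support — the exact density is what enters the weights), utilities flat
Dirichlet on the simplex. The range covers all fixture values (`α` up
to 1.21) with ample slack. Perturbation proposals violating any
constraint are rejected and redrawn rather than transformed, which
keeps the prior-density factor in the weights exact; a proposal cap
(default 1000 redraws, 1e5 simulator calls per particle per iteration)
turns pathological configurations into diagnostics instead of hangs.

Tolerance schedule: each iteration's tolerance is a quantile (default
the median) of the previous iteration's accepted discrepancies, which
makes the tolerance trace non-increasing by construction. Two
refinements proved necessary on this model. First, the prior-predictive
discrepancy distribution carries a large atom: roughly half of prior
draws (high aversion, low utility-contrast) freeze the trajectory near
its initial state and produce one identical discrepancy, so a plain
quantile can reproduce the current tolerance forever. The schedule is
therefore stall-aware: if the quantile improves by less than 1 %, it is
re-taken over the strictly improving discrepancies, and the run stops
only when fewer than 5 % of particles improve — the empirical
tolerance floor. Second, the median (rather than a higher quantile) is
the default because it reaches the noise floor of a six-point census
series within ~20 iterations; slower schedules leave `β` practically
unidentified within a 30-iteration budget.

Reported estimates are weighted posterior means with weighted standard
deviations (utility means renormalized to the simplex); the single
best-fitting particle is also reported, since with a sharp tolerance
the two can legitimately differ.

## Synthetic data

The generator emulates the structure of the real series: trajectories
produced by the model's own dynamics, sampled at sparse census years
(default six points over ~55 years, matching decennial-style spacing),
with iid Gaussian observation noise per entry (clip to `[0, 1]`, then
renormalize). Default noise sd is 0.005 in fraction units — the scale
of the scatter of census points around fitted trajectories. The
generator does not emulate migration, age structure, correlated
undercounting, or definitional changes between censuses; passing
recovery tests therefore demonstrate that the inference machinery is
correct and well-calibrated on model-generated data, not that the model
is identified from any real census series.

Fixture provenance: every numeric fixture field is tagged. Three of the
four communities publish only one initial fraction; the remaining mass
is split evenly among the other languages and tagged `assumed`. Two
published utility vectors sum to 1.01 (two-decimal rounding); they are
renormalized at model construction and tagged accordingly. Only the
Singapore whole-country fixture is fully published, and only it feeds
the headline reproductions.

## Experiments

Sweeps hold a fitted community fixed and vary one knob. Raising one
language's utility lowers the others proportionally to their current
values (`s_j' = s_j (1 − s_new)/Σ_{k≠i} s_k`); the same proportional
rule is applied when varying an initial fraction, chosen for symmetry
since only the utility rule has a stated form. Grid steps are 0.02 for
utility sweeps and 0.01 for bias sweeps; utility grids start at the
first positive grid point because a zero utility is outside the
parameter space. Threshold reports quote the bracketing grid pair
(last value where a label predicate is false, first where it is true);
"onset at X" statements refer to the last-false value. The
two-parameter phase diagram is the cross product of a `β` grid and an
`α − β` grid, each cell classified independently; by construction each
row must (and, tested, does) reproduce the corresponding 1-D sweep.

Convergence-time curves vary one language's initial fraction and record
`τ` per grid point. The demonstration configurations place each
community in a bistable regime by raising the minority aversion
(Singapore and the Chinese community at `α − β = 0.40`, the Indian
community at 1.3, Hong Kong at 1.0) and vary the initially largest
language on a 0.05 grid; in all four, the `τ` maximum falls at or next
to the grid point where the long-run label flips — critical slowdown at
the tipping point. These bias values are a documented choice: the
published curves do not state their configurations, so the peak
positions are illustrative, not reproductions.

## Problem sizes and numerical choices

The headline reproductions use the grids above (30–101 steady-state
runs per sweep, each an Euler integration of typically 10²–10⁴ yearly
steps). The recovery experiment uses 100 particles and at most 30
iterations on a six-point, three-language series (~10⁴–10⁵ simulator
calls, tens of seconds on one core). Determinism: a single
`numpy.random.Generator` seeds each stochastic run; identical seeds
give bit-identical ensembles, and all sweep/steady-state machinery is
deterministic.

## Known limitations

- Two published boundary values are not reproduced at the printed
  two-decimal parameters: the aversion value at which the initially
  largest language takes over dominance comes out at 0.33 (published:
  above 0.34), and the Mandarin/Dialect trajectory crossing comes out
  at 2001 (published: 1996). Both quantities are sensitive at the
  ±0.005 level of the rounded published parameters (a ±0.005 change in
  `α` alone moves the crossing by ~2 years), so the gaps are consistent
  with parameter rounding rather than a dynamical discrepancy; the
  package reports its computed values as-is.
- The fit-quality figure for the real Singapore series (distance
  ≈ 0.13) requires the original supplementary spreadsheet, which is not
  redistributable here; the spreadsheet importer accepts it when the
  user supplies it.
- No analytical bifurcation analysis: boundaries are grid-bracketed
  only, with resolution set by the grid step.
- The model itself has no bilingual compartments, no network or spatial
  structure, and no demographic turnover.
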