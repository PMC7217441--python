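# langshift

Competitive dynamics of multiple languages: an extended Abrams–Strogatz
model on the probability simplex, likelihood-free (ABC-SMC) calibration
to sparse census series, and the surrounding tipping-point analyses.

The package is aimed at quantitative sociolinguists and researchers in
cultural-evolution modelling who want to fit multi-language competition
dynamics to census-style data (a handful of observation years, fractions
of primary speakers per language) and then map out what the fitted
community can do: which language wins, whether the others survive, where
the tipping points sit, and how the approach to equilibrium slows down
near them.

## Model

The state is a point `x = (x_1, …, x_n)` on the simplex, `x_i` the
fraction of the population whose primary language is `i`. Speakers move
between languages at pairwise rates

```
P_ji = s_i · x_i^β · (1 − x_j)^(α−β)
dx_i/dt = Σ_{j≠i} x_j P_ji − x_i Σ_{j≠i} P_ij
```

with language utilities `s_i > 0`, `Σ s_i = 1`, majority preference
`β ≥ 0` (the pull of a language that already has many speakers) and
minority aversion `α − β ≥ 0` (the penalty on moving toward a language
whose rival retains most speakers). For `n = 2` this is exactly the
classical Abrams–Strogatz model `dx₁/dt = x₂ s₁ x₁^α − x₁ s₂ x₂^α`.

Long-run states are classified as **coexistence** (two or more languages
above the extinction threshold) or **dominance** (exactly one survivor).
Calibration is by ABC-SMC: parameter particles `θ = (α, β, s)` are
filtered through a decreasing tolerance on the summed squared
discrepancy `ε = Σ_j Σ_t (x_obs − x_sim)²` between census rows and the
simulated trajectory sampled at the census years.

Four built-in fixtures carry published calibrations (Singapore whole
country, its Chinese and Indian communities, and Hong Kong), with
per-value provenance tags distinguishing published numbers from flagged
fillers.

## Worked example

```python
import langshift as ls

fx = ls.get_fixture("singapore")        # α=1.00, β=0.76, s=(0.35, 0.29, 0.36)
model, x0 = fx.model(), fx.initial_state()

r = ls.find_steady_state(model, x0)
print(r.label, round(r.tau))            # -> coexistence:Mandarin 468

traj = ls.simulate(model, x0, horizon=100, t0=1957)
print(traj.first_crossing("Mandarin", "Dialect"))   # -> 2001.0
```

Starting from the 1957 census shares (1.8 % English, 97.5 % dialects,
0.1 % Mandarin), the fitted dynamics let Mandarin — the largest-utility
language — overtake the dialects around the turn of the century, and the
community settles into a three-way coexistence with Mandarin on top
after roughly 470 years of drift.

Calibration on synthetic census data generated from those same
parameters (observation noise sd 0.005, 100 particles):

```python
report = ls.recovery_experiment(model, ls.NoiseSpec(sd=0.005, seed=11),
                                x0=x0, census_years=fx.census_years,
                                n_particles=100, n_iterations=30, rng_seed=7)
print(round(report.error_alpha, 3), round(report.error_beta, 3))
# -> 0.036 0.057      (absolute errors on α and β)
```

The same machinery is available from the shell:

```
langshift fixtures --list
langshift sweep-bias --dataset singapore --swept aversion --grid 0:1:0.01
langshift fit --dataset singapore --seed 1
```

Every command writes tidy CSV output plus a JSON manifest of its
effective configuration.

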