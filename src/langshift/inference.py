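"""Likelihood-free calibration of the competition model to census series.

The data are sparse: a handful of census years, each giving the fraction
of primary speakers per language.  Calibration is by approximate Bayesian
computation with sequential Monte Carlo (ABC-SMC): a population of
weighted parameter "particles" theta = (alpha, beta, s_1..s_n) is pushed
through a decreasing tolerance schedule.  Each iteration resamples from
the previous weighted ensemble, perturbs with a Gaussian kernel whose
covariance is twice the weighted empirical covariance of the ensemble,
simulates the deterministic dynamics from the first census point, and
accepts the proposal when the discrepancy

    eps(theta) = sum_j sum_t (x_obs[t, j] - x_sim[t, j])**2

(summed squared differences over languages and census years, no square
root) falls below the current tolerance.  Importance weights follow the
standard SMC correction: prior density over the kernel mixture of the
previous ensemble.

Tolerances are set adaptively as a quantile of the previous iteration's
accepted discrepancies, which makes the mean discrepancy trace
non-increasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import multivariate_normal

from .model import CompetitionModel, PopulationState, _deriv, _euler_step

__all__ = [
    "ObservedSeries",
    "PriorSpec",
    "Particle",
    "PosteriorEnsemble",
    "IterationRecord",
    "PosteriorSummary",
    "trajectory_distance",
    "sample_prior",
    "perturb_particle",
    "compute_weight",
    "run_abc_smc",
    "summarize_posterior",
]

ROW_SUM_ATOL = 1e-6  # slack on census rows before renormalization


@dataclass(frozen=True)
class ObservedSeries:
    """Census fractions per language at irregular years.

    Rows are normalized on access (census tables often sum to slightly
    less than 1 because residual categories are dropped).
    """

    years: np.ndarray
    names: tuple[str, ...]
    fractions: np.ndarray  # shape (len(years), len(names)), raw values

    def __init__(self, years: Sequence[float], names: Sequence[str],
                 fractions: Sequence[Sequence[float]]):
        t = np.asarray(years, dtype=float)
        x = np.atleast_2d(np.asarray(fractions, dtype=float))
        names = tuple(str(n) for n in names)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("years must be a non-empty 1-D vector")
        if np.any(np.diff(t) <= 0):
            raise ValueError("census years must be strictly increasing")
        if x.shape != (t.size, len(names)):
            raise ValueError(f"fractions shape {x.shape} inconsistent with "
                             f"{t.size} years and {len(names)} languages")
        if np.any(x < 0) or np.any(x > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(x.sum(axis=1) <= 0):
            raise ValueError("every census row needs positive total mass")
        t.flags.writeable = False
        x.flags.writeable = False
        object.__setattr__(self, "years", t)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "fractions", x)

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def n_languages(self) -> int:
        return len(self.names)

    def normalized(self) -> np.ndarray:
        """Fractions with every row rescaled to sum to 1.

        Rows already summing to 1 within float roundoff (1e-12) are
        returned bit-identical, so re-simulating a noise-free series
        reproduces it exactly.
        """
        x = self.fractions
        sums = x.sum(axis=1, keepdims=True)
        off = np.abs(sums - 1.0) > 1e-12
        return np.where(off, x / sums, x)

    def initial_state(self) -> PopulationState:
        return PopulationState(self.normalized()[0])


def _year_offsets(years: np.ndarray, dt: float) -> np.ndarray:
    """Census years as integer step indices from the first year."""
    off = (years - years[0]) / dt
    idx = np.rint(off).astype(int)
    if np.max(np.abs(off - idx)) > 1e-9:
        raise ValueError(f"census years {years} are not aligned to the "
                         f"integration step dt={dt}")
    return idx


def _simulate_at(offsets: np.ndarray, x0: np.ndarray, s: np.ndarray,
                 alpha: float, beta: float, dt: float) -> np.ndarray:
    """Rows of the Euler solution at the requested step offsets."""
    out = np.empty((offsets.size, x0.size))
    wanted = {int(k): i for i, k in enumerate(offsets)}
    x = x0
    if 0 in wanted:
        out[wanted[0]] = x
    for k in range(1, int(offsets[-1]) + 1):
        x = _euler_step(x, s, alpha, beta, dt)
        if k in wanted:
            out[wanted[k]] = x
    return out


def trajectory_distance(observed: ObservedSeries, model: CompetitionModel,
                        x0: PopulationState | None = None,
                        dt: float = 1.0) -> float:
    """Summed squared discrepancy between census rows and the model run.

    The model is integrated at step ``dt`` (default one year) from the
    first census year, sampled at every census year, and compared to the
    normalized observations.  Zero iff the sampled simulation matches the
    observations exactly.
    """
    if model.names != observed.names:
        if set(model.names) != set(observed.names):
            raise ValueError(f"model languages {model.names} do not match "
                             f"observed languages {observed.names}")
        raise ValueError(f"language order differs: model {model.names} vs "
                         f"observed {observed.names}")
    obs = observed.normalized()
    x0v = obs[0] if x0 is None else x0.fractions
    offsets = _year_offsets(observed.years, dt)
    sim = _simulate_at(offsets, x0v, model.utilities, model.alpha, model.beta, dt)
    return float(np.sum((obs - sim) ** 2))


@dataclass(frozen=True)
class PriorSpec:
    """Prior over theta = (alpha, beta, s_1..s_n).

    alpha ~ Uniform(alpha_range); beta | alpha ~ Uniform(0, alpha), which
    enforces the exponent constraints by construction; utilities are flat
    Dirichlet on the simplex.  The joint density is proportional to
    1/alpha on its support.
    """

    n_languages: int
    alpha_range: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self):
        lo, hi = self.alpha_range
        if not (0 <= lo < hi):
            raise ValueError(f"invalid alpha range {self.alpha_range}")
        if self.n_languages < 2:
            raise ValueError("need at least two languages")

    def sample(self, rng: np.random.Generator) -> tuple[float, float, np.ndarray]:
        lo, hi = self.alpha_range
        alpha = rng.uniform(lo, hi)
        beta = rng.uniform(0.0, alpha)
        s = rng.dirichlet(np.ones(self.n_languages))
        # Dirichlet can return exact zeros at float precision; utilities
        # must be strictly positive.
        while np.any(s <= 0):
            s = rng.dirichlet(np.ones(self.n_languages))
        return float(alpha), float(beta), s

    def density(self, alpha: float, beta: float, s: np.ndarray) -> float:
        """Joint prior density (unnormalized constants included)."""
        lo, hi = self.alpha_range
        if not (lo <= alpha <= hi) or not (0.0 <= beta <= alpha) or alpha <= 0:
            return 0.0
        s = np.asarray(s, dtype=float)
        if s.size != self.n_languages or np.any(s <= 0) or abs(s.sum() - 1.0) > 1e-6:
            return 0.0
        # U(lo,hi) * U(0,alpha) * flat Dirichlet((n-1)! on the simplex)
        return (1.0 / (hi - lo)) * (1.0 / alpha) * math.factorial(self.n_languages - 1)


@dataclass
class Particle:
    """One candidate parameter vector with importance weight."""

    alpha: float
    beta: float
    utilities: np.ndarray
    weight: float = 0.0
    distance: float = math.inf

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate(([self.alpha, self.beta], self.utilities))

    def coords(self) -> np.ndarray:
        """Unconstrained kernel coordinates (alpha, beta, s_1..s_{n-1})."""
        return np.concatenate(([self.alpha, self.beta], self.utilities[:-1]))

    def model(self, names: Sequence[str]) -> CompetitionModel:
        # Guard against float drift in the last utility component.
        s = self.utilities / self.utilities.sum()
        return CompetitionModel(names, s, self.alpha, self.beta)


def _particle_from_coords(z: np.ndarray) -> Particle | None:
    """Rebuild a particle from kernel coordinates; None if invalid."""
    alpha, beta = float(z[0]), float(z[1])
    s_head = np.asarray(z[2:], dtype=float)
    s_last = 1.0 - s_head.sum()
    if beta < 0 or alpha - beta < 0:
        return None
    if np.any(s_head <= 0) or s_last <= 0:
        return None
    return Particle(alpha=alpha, beta=beta,
                    utilities=np.concatenate((s_head, [s_last])))


@dataclass
class PosteriorEnsemble:
    """Weighted particle population after one ABC-SMC iteration."""

    particles: list[Particle]
    iteration: int
    tolerance: float
    kernel_covariance: np.ndarray

    @property
    def n(self) -> int:
        return len(self.particles)

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.particles])

    @property
    def distances(self) -> np.ndarray:
        return np.array([p.distance for p in self.particles])

    def coords_matrix(self) -> np.ndarray:
        return np.vstack([p.coords() for p in self.particles])

    def best(self) -> Particle:
        return min(self.particles, key=lambda p: p.distance)


@dataclass(frozen=True)
class IterationRecord:
    """Per-iteration diagnostics of the tolerance schedule.

    ``mean_scaled`` / ``sd_scaled`` are statistics of
    eps / (n_years * n_languages) across the accepted particles, the
    per-datum scaling conventionally used to compare fits across series.
    """

    iteration: int
    tolerance: float
    mean_scaled: float
    sd_scaled: float
    n_simulations: int


def sample_prior(prior: PriorSpec, rng_seed: int | np.random.Generator) -> Particle:
    """Draw one particle from the prior (weight and distance unset)."""
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    alpha, beta, s = prior.sample(rng)
    return Particle(alpha=alpha, beta=beta, utilities=s)


def perturb_particle(source: Particle, kernel_covariance: np.ndarray,
                     rng_seed: int | np.random.Generator,
                     max_attempts: int = 1000,
                     prior: PriorSpec | None = None) -> Particle:
    """Gaussian perturbation in (alpha, beta, s_1..s_{n-1}) coordinates.

    The last utility is recomputed as one minus the rest; draws that
    violate the model invariants (or fall outside the prior support, when
    a prior is given) are rejected and redrawn.  A zero covariance
    returns the source unchanged.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    cov = np.asarray(kernel_covariance, dtype=float)
    z0 = source.coords()
    if cov.shape != (z0.size, z0.size):
        raise ValueError(f"kernel covariance shape {cov.shape} does not match "
                         f"{z0.size} coordinates")
    if not np.any(cov):
        return Particle(alpha=source.alpha, beta=source.beta,
                        utilities=source.utilities.copy())
    for _ in range(max_attempts):
        z = rng.multivariate_normal(z0, cov, method="eigh")
        cand = _particle_from_coords(z)
        if cand is None:
            continue
        if prior is not None and prior.density(cand.alpha, cand.beta, cand.utilities) == 0.0:
            continue
        return cand
    raise RuntimeError(f"no valid perturbation of {z0} found in {max_attempts} attempts; "
                       f"kernel covariance may be far too wide")


def _kernel_mixture_density(z: np.ndarray, ensemble: PosteriorEnsemble) -> float:
    """sum_j w_j N(z; z_j, Sigma) over the previous ensemble."""
    cov = ensemble.kernel_covariance
    prev = ensemble.coords_matrix()
    dens = multivariate_normal(mean=np.zeros(z.size), cov=cov,
                               allow_singular=True).pdf(prev - z)
    return float(np.dot(ensemble.weights, np.atleast_1d(dens)))


def compute_weight(particle: Particle, previous: PosteriorEnsemble,
                   prior: PriorSpec) -> float:
    """Unnormalized SMC importance weight: prior / kernel mixture."""
    num = prior.density(particle.alpha, particle.beta, particle.utilities)
    den = _kernel_mixture_density(particle.coords(), previous)
    if den <= 0.0:
        raise ZeroDivisionError("kernel mixture density vanished at the particle; "
                                "covariance is degenerate")
    return num / den


def _weighted_cov(coords: np.ndarray, weights: np.ndarray) -> np.ndarray:
    mu = weights @ coords
    d = coords - mu
    cov = (d * weights[:, None]).T @ d
    # Symmetrize and add a floor so the kernel never fully collapses.
    cov = 0.5 * (cov + cov.T)
    cov += 1e-12 * np.eye(cov.shape[0])
    return cov


def run_abc_smc(observed: ObservedSeries, prior: PriorSpec | None = None,
                n_particles: int = 100, n_iterations: int = 50,
                rng_seed: int | np.random.Generator = 0,
                acceptance_quantile: float = 0.5,
                min_improvement: float = 0.01,
                attempt_cap: int = 100_000,
                dt: float = 1.0,
                ) -> tuple[PosteriorEnsemble, list[IterationRecord]]:
    """Calibrate the competition model to a census series by ABC-SMC.

    Iteration 0 rejection-samples from the prior against a pilot
    tolerance (``acceptance_quantile`` of prior-predictive
    discrepancies); later iterations resample the previous weighted
    ensemble, perturb with a Gaussian kernel of covariance twice the
    weighted empirical covariance, and accept below a tolerance set to
    ``acceptance_quantile`` of the previous accepted discrepancies.
    Stops after ``n_iterations`` or when the tolerance improves by less
    than ``min_improvement`` (relative).

    The initial state is the first census row (normalized); it is not a
    fitted quantity.

    Returns the final ensemble and the per-iteration tolerance trace.
    """
    if n_particles < 2:
        raise ValueError("need at least two particles")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    if prior is None:
        prior = PriorSpec(n_languages=observed.n_languages)
    if prior.n_languages != observed.n_languages:
        raise ValueError(f"prior is for {prior.n_languages} languages, "
                         f"series has {observed.n_languages}")

    obs = observed.normalized()
    x0 = obs[0]
    offsets = _year_offsets(observed.years, dt)
    scale = observed.n_years * observed.n_languages

    def distance_of(p: Particle) -> float:
        s = p.utilities / p.utilities.sum()
        sim = _simulate_at(offsets, x0, s, p.alpha, p.beta, dt)
        return float(np.sum((obs - sim) ** 2))

    # Pilot prior-predictive sample sets the initial tolerance.
    n_sims = 0
    pilot = np.empty(n_particles)
    for i in range(n_particles):
        pilot[i] = distance_of(sample_prior(prior, rng))
        n_sims += 1
    epsilon = float(np.quantile(pilot, acceptance_quantile))

    # Iteration 0: plain rejection sampling from the prior.
    particles: list[Particle] = []
    for _ in range(n_particles):
        for attempt in range(attempt_cap):
            cand = sample_prior(prior, rng)
            d = distance_of(cand)
            n_sims += 1
            if d <= epsilon:
                cand.distance = d
                cand.weight = 1.0 / n_particles
                particles.append(cand)
                break
        else:
            raise RuntimeError(f"iteration 0: tolerance {epsilon:g} not reached "
                               f"within {attempt_cap} prior draws")
    coords = np.vstack([p.coords() for p in particles])
    weights = np.full(n_particles, 1.0 / n_particles)
    ensemble = PosteriorEnsemble(particles=particles, iteration=0, tolerance=epsilon,
                                 kernel_covariance=2.0 * _weighted_cov(coords, weights))
    dists = ensemble.distances / scale
    trace = [IterationRecord(0, epsilon, float(dists.mean()), float(dists.std()), n_sims)]

    for t in range(1, n_iterations):
        # Quantile descent, made stall-aware: prior-predictive distances can
        # carry an atom (e.g. parameter regions where the trajectory barely
        # moves give one identical discrepancy), and a plain quantile then
        # reproduces the current tolerance forever.  When the quantile fails
        # to improve, re-take it over the strictly improving distances; stop
        # only when almost no particle improves (the tolerance floor).
        dists_prev = ensemble.distances
        new_eps = float(np.quantile(dists_prev, acceptance_quantile))
        if epsilon > 0 and (epsilon - new_eps) < min_improvement * epsilon:
            improving = dists_prev[dists_prev < (1.0 - min_improvement) * epsilon]
            if improving.size < 0.05 * n_particles:
                break
            new_eps = float(np.quantile(improving, acceptance_quantile))
        epsilon = new_eps
        n_sims = 0
        prev_w = ensemble.weights
        new_particles: list[Particle] = []
        for _ in range(n_particles):
            accepted = None
            for attempt in range(attempt_cap):
                src = ensemble.particles[rng.choice(ensemble.n, p=prev_w)]
                try:
                    cand = perturb_particle(src, ensemble.kernel_covariance,
                                            rng, prior=prior)
                except RuntimeError:
                    continue
                d = distance_of(cand)
                n_sims += 1
                if d <= epsilon:
                    cand.distance = d
                    accepted = cand
                    break
            if accepted is None:
                raise RuntimeError(f"iteration {t}: tolerance {epsilon:g} not "
                                   f"reached within {attempt_cap} proposals")
            new_particles.append(accepted)
        for p in new_particles:
            p.weight = compute_weight(p, ensemble, prior)
        w = np.array([p.weight for p in new_particles])
        w /= w.sum()
        for p, wi in zip(new_particles, w):
            p.weight = float(wi)
        coords = np.vstack([p.coords() for p in new_particles])
        ensemble = PosteriorEnsemble(particles=new_particles, iteration=t,
                                     tolerance=epsilon,
                                     kernel_covariance=2.0 * _weighted_cov(coords, w))
        dists = ensemble.distances / scale
        trace.append(IterationRecord(t, epsilon, float(dists.mean()),
                                     float(dists.std()), n_sims))
    return ensemble, trace


@dataclass(frozen=True)
class PosteriorSummary:
    """Weighted posterior moments plus the single best-fitting particle."""

    names: tuple[str, ...]
    mean_alpha: float
    mean_beta: float
    mean_utilities: np.ndarray      # renormalized to the simplex
    sd_alpha: float
    sd_beta: float
    sd_utilities: np.ndarray
    best_particle: Particle = field(repr=False)

    def as_dict(self) -> dict[str, float]:
        out = {"alpha": self.mean_alpha, "beta": self.mean_beta,
               "alpha_sd": self.sd_alpha, "beta_sd": self.sd_beta}
        for name, m, sd in zip(self.names, self.mean_utilities, self.sd_utilities):
            out[f"s_{name}"] = float(m)
            out[f"s_{name}_sd"] = float(sd)
        return out


def summarize_posterior(ensemble: PosteriorEnsemble,
                        names: Sequence[str] | None = None) -> PosteriorSummary:
    """Weighted means and standard deviations of every parameter."""
    w = ensemble.weights
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("ensemble weights are not normalized")
    thetas = np.vstack([p.theta for p in ensemble.particles])
    mu = w @ thetas
    sd = np.sqrt(np.maximum(w @ (thetas - mu) ** 2, 0.0))
    n_lang = thetas.shape[1] - 2
    if names is None:
        names = tuple(f"L{i}" for i in range(n_lang))
    mean_s = mu[2:] / mu[2:].sum()
    return PosteriorSummary(
        names=tuple(names), mean_alpha=float(mu[0]), mean_beta=float(mu[1]),
        mean_utilities=mean_s, sd_alpha=float(sd[0]), sd_beta=float(sd[1]),
        sd_utilities=sd[2:], best_particle=ensemble.best(),
    )
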