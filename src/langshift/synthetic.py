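"""Community fixtures and census-like synthetic series.

Four fixtures encode published calibrations of the competition model to
census series: Singapore as a whole, its Chinese and Indian communities
(1957-2010), and Hong Kong (1949-2016).  Every numeric field carries a
provenance tag: ``printed`` values come from the published calibration,
``assumed`` values fill gaps (only one initial fraction per community is
published for three of the four datasets; the remaining initial mass is
split evenly among the other languages and loudly flagged).  Printed
utility vectors are rounded to two decimals and may sum to 1.01; they
are renormalized when a model object is built, with the tag
``printed-normalized``.

The generator produces census-like observations from the model's own
dynamics: yearly Euler integration sampled at sparse census years, plus
independent Gaussian observation noise, clipped and renormalized to the
simplex.  That emulates the small scatter of census points around fitted
trajectories; it does not emulate migration, birth/death structure, or
correlated undercounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .inference import ObservedSeries, PriorSpec, PosteriorSummary, run_abc_smc, summarize_posterior
from .model import CompetitionModel, PopulationState, simulate

__all__ = [
    "DatasetFixture",
    "NoiseSpec",
    "RecoveryReport",
    "builtin_fixtures",
    "get_fixture",
    "generate_observed_series",
    "recovery_experiment",
]

PRINTED = "printed"
PRINTED_NORMALIZED = "printed-normalized"
ASSUMED = "assumed"


@dataclass(frozen=True)
class DatasetFixture:
    """A community's fitted parameters, initial census row, and provenance.

    ``initial_fractions`` are raw census shares and need not sum to one
    (the 1957 Singapore row sums to 0.994 because residual categories are
    dropped); ``initial_state()`` normalizes.  ``provenance`` maps every
    numeric field to ``printed``, ``printed-normalized``, or ``assumed``.
    """

    name: str
    languages: tuple[str, ...]
    alpha: float
    beta: float
    utilities: tuple[float, ...]
    start_year: int
    initial_fractions: tuple[float, ...]
    census_years: tuple[int, ...]
    provenance: Mapping[str, str] = field(repr=False)

    @property
    def has_assumed_initials(self) -> bool:
        return any(self.provenance[f"initial:{l}"] == ASSUMED for l in self.languages)

    @property
    def fully_printed(self) -> bool:
        """True when no parameter or initial fraction is an assumed filler."""
        return all(v != ASSUMED for v in self.provenance.values())

    def model(self) -> CompetitionModel:
        s = np.asarray(self.utilities, dtype=float)
        return CompetitionModel(self.languages, s / s.sum(), self.alpha, self.beta)

    def initial_state(self) -> PopulationState:
        return PopulationState.from_counts(self.initial_fractions)

    def observed_series(self, noise: "NoiseSpec | None" = None) -> ObservedSeries:
        """Census-like series generated from the fixture's own dynamics."""
        if noise is None:
            noise = NoiseSpec(sd=0.0, seed=0)
        return generate_observed_series(self.model(), self.initial_state(),
                                        self.census_years, noise)


def _even_split_initials(printed: Mapping[str, float], languages: Sequence[str]
                         ) -> tuple[tuple[float, ...], dict[str, str]]:
    """Fill unpublished initial fractions by splitting the leftover mass evenly."""
    missing = [l for l in languages if l not in printed]
    leftover = 1.0 - sum(printed.values())
    if leftover < 0:
        raise ValueError("printed initial fractions exceed 1")
    values, tags = [], {}
    for l in languages:
        if l in printed:
            values.append(printed[l])
            tags[f"initial:{l}"] = PRINTED
        else:
            values.append(leftover / len(missing))
            tags[f"initial:{l}"] = ASSUMED
    return tuple(values), tags


def _fixture(name: str, languages: Sequence[str], alpha: float, beta: float,
             utilities: Sequence[float], start_year: int,
             printed_initials: Mapping[str, float],
             census_years: Sequence[int]) -> DatasetFixture:
    initials, tags = _even_split_initials(printed_initials, languages)
    s_tag = PRINTED if abs(sum(utilities) - 1.0) <= 1e-9 else PRINTED_NORMALIZED
    prov = {"alpha": PRINTED, "beta": PRINTED}
    for l in languages:
        prov[f"utility:{l}"] = s_tag
    prov.update(tags)
    return DatasetFixture(
        name=name, languages=tuple(languages), alpha=alpha, beta=beta,
        utilities=tuple(float(u) for u in utilities), start_year=start_year,
        initial_fractions=initials, census_years=tuple(int(y) for y in census_years),
        provenance=prov,
    )


def builtin_fixtures() -> list[DatasetFixture]:
    """The four built-in community calibrations.

    Only the Singapore whole-country fixture is fully published (all
    three 1957 initial fractions); the other three publish a single
    initial fraction each, with the rest flagged ``assumed``.
    """
    sg_years = (1957, 1970, 1980, 1990, 2000, 2010)
    return [
        _fixture("singapore", ("English", "Dialect", "Mandarin"),
                 alpha=1.00, beta=0.76, utilities=(0.35, 0.29, 0.36),
                 start_year=1957,
                 printed_initials={"English": 0.018, "Dialect": 0.975, "Mandarin": 0.001},
                 census_years=sg_years),
        _fixture("chinese-community", ("English", "Dialect", "Mandarin"),
                 alpha=0.90, beta=0.87, utilities=(0.34, 0.29, 0.37),
                 start_year=1957,
                 printed_initials={"Dialect": 0.766},
                 census_years=sg_years),
        _fixture("indian-community", ("English", "Tamil", "Malay"),
                 alpha=1.06, beta=0.10, utilities=(0.41, 0.40, 0.20),
                 start_year=1957,
                 printed_initials={"Tamil": 0.613},
                 census_years=sg_years),
        _fixture("hong-kong", ("English", "Hakka", "Hoklo", "Sze Yap"),
                 alpha=1.21, beta=0.90, utilities=(0.30, 0.26, 0.27, 0.18),
                 start_year=1949,
                 printed_initials={"Sze Yap": 0.578},
                 census_years=(1949, 1961, 1971, 1981, 1991, 2001, 2016)),
    ]


def get_fixture(name: str) -> DatasetFixture:
    for f in builtin_fixtures():
        if f.name == name:
            return f
    known = [f.name for f in builtin_fixtures()]
    raise KeyError(f"unknown fixture {name!r}; available: {known}")


@dataclass(frozen=True)
class NoiseSpec:
    """Observation noise: iid Gaussian per entry, then clip + renormalize."""

    sd: float
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.sd}")


def generate_observed_series(model: CompetitionModel, x0: PopulationState,
                             census_years: Sequence[int],
                             noise: NoiseSpec) -> ObservedSeries:
    """Simulate the dynamics and sample noisy census rows.

    Yearly Euler integration from the first census year; at each census
    year the exact state receives independent Gaussian noise of standard
    deviation ``noise.sd`` per entry, is clipped to [0, 1] and
    renormalized.  Deterministic given ``noise.seed``.
    """
    years = np.asarray(census_years, dtype=int)
    if years.size < 2 or np.any(np.diff(years) <= 0):
        raise ValueError("need at least two strictly increasing census years")
    horizon = float(years[-1] - years[0])
    traj = simulate(model, x0, horizon=horizon, dt=1.0, t0=float(years[0]))
    rows = traj.fractions[years - years[0]]
    if noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        rows = np.clip(rows + rng.normal(0.0, noise.sd, size=rows.shape), 0.0, 1.0)
        rows = rows / rows.sum(axis=1, keepdims=True)
    return ObservedSeries(years=years, names=model.names, fractions=rows)


@dataclass(frozen=True)
class RecoveryReport:
    """Truth versus ABC-SMC estimate on a synthetic series."""

    true_model: CompetitionModel
    summary: PosteriorSummary
    error_alpha: float
    error_beta: float
    errors_utilities: np.ndarray
    final_tolerance: float
    n_iterations: int

    @property
    def max_utility_error(self) -> float:
        return float(np.max(self.errors_utilities))


def recovery_experiment(true_model: CompetitionModel, noise: NoiseSpec,
                        x0: PopulationState | None = None,
                        census_years: Sequence[int] = (0, 13, 23, 33, 43, 55),
                        prior: PriorSpec | None = None,
                        n_particles: int = 100, n_iterations: int = 30,
                        rng_seed: int = 0, **abc_kwargs) -> RecoveryReport:
    """Generate data from a known model, calibrate, and report absolute errors.

    The default census pattern is six points over 55 years, emulating the
    sparse decennial-style sampling of the real series.
    """
    if x0 is None:
        # A census-like start: most speakers on the last language's rival.
        n = true_model.n
        x0 = PopulationState.from_counts([0.9] + [0.1 / (n - 1)] * (n - 1))
    observed = generate_observed_series(true_model, x0, census_years, noise)
    ensemble, trace = run_abc_smc(observed, prior=prior, n_particles=n_particles,
                                  n_iterations=n_iterations, rng_seed=rng_seed,
                                  **abc_kwargs)
    summary = summarize_posterior(ensemble, names=true_model.names)
    return RecoveryReport(
        true_model=true_model,
        summary=summary,
        error_alpha=abs(summary.mean_alpha - true_model.alpha),
        error_beta=abs(summary.mean_beta - true_model.beta),
        errors_utilities=np.abs(summary.mean_utilities - true_model.utilities),
        final_tolerance=ensemble.tolerance,
        n_iterations=len(trace),
    )
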