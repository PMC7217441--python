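"""Extended Abrams-Strogatz dynamics for n competing languages.

The state of a speech community is a point ``x`` on the probability
simplex: ``x_i`` is the fraction of the population whose primary language
is ``i``.  Speakers switch between languages at pairwise rates

    P_ji = s_i * x_i**beta * (1 - x_j)**(alpha - beta)

where ``s_i`` is the utility (intrinsic attractiveness) of language ``i``
(utilities sum to 1), ``beta >= 0`` is the majority preference — the pull
exerted by a language that already has many speakers — and
``alpha - beta >= 0`` is the minority aversion, which suppresses moves
toward a language whose competitor still retains most speakers.  For
``n = 2`` this reduces exactly to the classical Abrams-Strogatz model
``dx1/dt = x2*s1*x1**alpha - x1*s2*x2**alpha``.

The module provides the vector field, an explicit Euler integrator with a
yearly default step (matching census-calibrated use), a steady-state
finder that records the convergence time ``tau``, and a classifier of the
long-run state into coexistence (two or more surviving languages) versus
dominance (exactly one survivor above the extinction threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SIMPLEX_ATOL",
    "DEFAULT_DT",
    "DEFAULT_STEADY_TOL",
    "DEFAULT_MAX_TIME",
    "DEFAULT_EXTINCTION_THRESHOLD",
    "CompetitionModel",
    "PopulationState",
    "Trajectory",
    "StateLabel",
    "SteadyStateResult",
    "pairwise_rate",
    "flow_derivative",
    "step",
    "simulate",
    "find_steady_state",
    "classify_state",
]

# Numerical policy for the whole package.
SIMPLEX_ATOL = 1e-9            # tolerance on |sum(x) - 1|
DEFAULT_DT = 1.0               # years; census data are yearly at best
DEFAULT_STEADY_TOL = 1e-6      # max per-step fraction change at convergence
DEFAULT_MAX_TIME = 1e5         # years; generous because of critical slowdown
DEFAULT_EXTINCTION_THRESHOLD = 1e-3  # equilibrium fraction below which a
                                     # language counts as extinct


def _as_simplex(values: Sequence[float], what: str, atol: float = SIMPLEX_ATOL) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"{what} must be a 1-D vector of length >= 2, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{what} entries must lie in [0, 1], got {arr}")
    total = arr.sum()
    if abs(total - 1.0) > atol:
        raise ValueError(f"{what} must sum to 1 within {atol:g}, got sum {total!r}")
    return arr


@dataclass(frozen=True)
class CompetitionModel:
    """Parameter set of the n-language competition.

    Parameters
    ----------
    names
        Language identifiers, one per compartment.
    utilities
        Per-language utility ``s_i``; all positive, summing to 1.
    alpha
        Combined exponent; ``alpha - beta`` is the minority aversion.
    beta
        Majority preference exponent, ``beta >= 0``.
    """

    names: tuple[str, ...]
    utilities: np.ndarray
    alpha: float
    beta: float

    def __init__(self, names: Sequence[str], utilities: Sequence[float],
                 alpha: float, beta: float):
        names = tuple(str(n) for n in names)
        s = _as_simplex(utilities, "utilities")
        if np.any(s <= 0):
            raise ValueError(f"all utilities must be strictly positive, got {s}")
        if len(names) != s.size:
            raise ValueError(f"{len(names)} names but {s.size} utilities")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate language names in {names}")
        alpha = float(alpha)
        beta = float(beta)
        if beta < 0:
            raise ValueError(f"beta must be >= 0, got {beta}")
        if alpha - beta < 0:
            raise ValueError(f"alpha - beta must be >= 0, got alpha={alpha}, beta={beta}")
        s.flags.writeable = False
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "utilities", s)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def aversion(self) -> float:
        """Minority aversion ``alpha - beta``."""
        return self.alpha - self.beta

    def with_utilities(self, utilities: Sequence[float]) -> "CompetitionModel":
        return CompetitionModel(self.names, utilities, self.alpha, self.beta)

    def with_biases(self, *, alpha: float | None = None, beta: float | None = None,
                    aversion: float | None = None) -> "CompetitionModel":
        """Return a copy with modified exponents.

        Exactly two of the three quantities (alpha, beta, aversion) are
        independent; ``aversion`` may be given instead of ``alpha``.
        """
        if aversion is not None and alpha is not None:
            raise ValueError("give either alpha or aversion, not both")
        b = self.beta if beta is None else float(beta)
        if aversion is not None:
            a = b + float(aversion)
        elif alpha is not None:
            a = float(alpha)
        else:
            a = self.alpha if beta is None else b + self.aversion
        return CompetitionModel(self.names, self.utilities, a, b)

    def index(self, language: str) -> int:
        try:
            return self.names.index(language)
        except ValueError:
            raise KeyError(f"unknown language {language!r}; model has {self.names}") from None


@dataclass(frozen=True)
class PopulationState:
    """A point on the n-simplex: per-language fractions of speakers."""

    fractions: np.ndarray

    def __init__(self, fractions: Sequence[float]):
        x = _as_simplex(fractions, "fractions")
        x.flags.writeable = False
        object.__setattr__(self, "fractions", x)

    @classmethod
    def from_counts(cls, values: Sequence[float]) -> "PopulationState":
        """Normalize arbitrary nonnegative values onto the simplex."""
        v = np.asarray(values, dtype=float)
        if np.any(v < 0):
            raise ValueError(f"counts must be nonnegative, got {v}")
        total = v.sum()
        if total <= 0:
            raise ValueError("counts sum to zero; cannot normalize")
        return cls(v / total)

    @property
    def n(self) -> int:
        return self.fractions.size


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed sequence of simplex states (times in years)."""

    times: np.ndarray
    fractions: np.ndarray  # shape (len(times), n)
    names: tuple[str, ...]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.fractions, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if x.shape != (t.size, len(self.names)):
            raise ValueError(f"fractions shape {x.shape} inconsistent with "
                             f"{t.size} times and {len(self.names)} names")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", x)

    def __len__(self) -> int:
        return self.times.size

    def state(self, k: int) -> PopulationState:
        return PopulationState(self.fractions[k])

    def first_crossing(self, above: str, below: str) -> float | None:
        """First time at which ``x_above > x_below``; None if never."""
        i, j = self.names.index(above), self.names.index(below)
        hits = np.nonzero(self.fractions[:, i] > self.fractions[:, j])[0]
        return float(self.times[hits[0]]) if hits.size else None


@dataclass(frozen=True)
class StateLabel:
    """Long-run state: coexistence (>= 2 survivors) or dominance (exactly 1)."""

    kind: str                       # "coexistence" | "dominance"
    top_language: str               # largest equilibrium fraction
    survivors: frozenset[str]

    def __post_init__(self):
        if self.kind not in ("coexistence", "dominance"):
            raise ValueError(f"unknown state kind {self.kind!r}")
        if (self.kind == "dominance") != (len(self.survivors) == 1):
            raise ValueError("dominance requires exactly one survivor")
        if self.top_language not in self.survivors:
            raise ValueError("top language must be among survivors")

    @property
    def is_dominance(self) -> bool:
        return self.kind == "dominance"

    def __str__(self) -> str:
        return f"{self.kind}:{self.top_language}"


@dataclass(frozen=True)
class SteadyStateResult:
    equilibrium: PopulationState
    tau: float                 # years to convergence (== max_time if not converged)
    label: StateLabel
    converged: bool
    model: CompetitionModel = field(repr=False)


def pairwise_rate(s_i: float, x_i: float, x_j: float, alpha: float, beta: float) -> float:
    """Transition rate from language j to language i.

    ``P_ji = s_i * x_i**beta * (1 - x_j)**(alpha - beta)``, with the
    convention ``0**0 = 1`` so that a zero exponent removes its factor
    even at the simplex boundary (an extinct language can still recruit
    speakers when ``beta = 0``).
    """
    if not s_i > 0:
        raise ValueError(f"utility must be > 0, got {s_i}")
    if not (0 <= x_i <= 1 and 0 <= x_j <= 1):
        raise ValueError(f"fractions must lie in [0, 1], got x_i={x_i}, x_j={x_j}")
    if beta < 0 or alpha - beta < 0:
        raise ValueError(f"need beta >= 0 and alpha >= beta, got alpha={alpha}, beta={beta}")
    # float ** 0.0 == 1.0 even for base 0.0, which is exactly the convention.
    return s_i * x_i ** beta * (1.0 - x_j) ** (alpha - beta)


def _deriv(x: np.ndarray, s: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    # dx_i = sum_{j!=i} x_j P_ji  -  x_i sum_{j!=i} P_ij
    # with P_ji = attract_i * decay_j, attract_i = s_i x_i^beta,
    # decay_j = (1 - x_j)^(alpha-beta); both O(n) via running sums.
    attract = s * x ** beta
    decay = (1.0 - x) ** (alpha - beta)
    xd = x * decay
    gain = attract * (xd.sum() - xd)
    loss = xd * (attract.sum() - attract)
    return gain - loss


def flow_derivative(state: PopulationState, model: CompetitionModel) -> np.ndarray:
    """dx/dt of the competition ODE; components sum to zero."""
    x = state.fractions
    if x.size != model.n:
        raise ValueError(f"state has {x.size} languages, model has {model.n}")
    return _deriv(x, model.utilities, model.alpha, model.beta)


def _euler_step(x: np.ndarray, s: np.ndarray, alpha: float, beta: float, dt: float) -> np.ndarray:
    # Clip + renormalize keeps the iterate exactly on the simplex; the
    # derivative conserves mass analytically but floats drift.
    xn = np.clip(x + dt * _deriv(x, s, alpha, beta), 0.0, 1.0)
    return xn / xn.sum()


def step(state: PopulationState, model: CompetitionModel, dt: float = DEFAULT_DT) -> PopulationState:
    """One explicit Euler step of length ``dt`` years."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if state.n != model.n:
        raise ValueError(f"state has {state.n} languages, model has {model.n}")
    return PopulationState(_euler_step(state.fractions, model.utilities,
                                       model.alpha, model.beta, dt))


def simulate(model: CompetitionModel, x0: PopulationState, horizon: float,
             dt: float = DEFAULT_DT, t0: float = 0.0) -> Trajectory:
    """Integrate for ``horizon`` years from ``x0``; returns all intermediate states.

    The trajectory has ``floor(horizon/dt) + 1`` rows, the first being
    ``x0`` at time ``t0`` (``t0`` is a plain offset, e.g. a calendar year).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if horizon < dt:
        raise ValueError(f"horizon ({horizon}) must be >= dt ({dt})")
    if x0.n != model.n:
        raise ValueError(f"x0 has {x0.n} languages, model has {model.n}")
    n_steps = int(np.floor(horizon / dt + 1e-12))
    out = np.empty((n_steps + 1, model.n))
    out[0] = x0.fractions
    s, a, b = model.utilities, model.alpha, model.beta
    x = x0.fractions
    for k in range(1, n_steps + 1):
        x = _euler_step(x, s, a, b, dt)
        out[k] = x
    times = t0 + dt * np.arange(n_steps + 1)
    return Trajectory(times=times, fractions=out, names=model.names)


def classify_state(equilibrium: PopulationState,
                   extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
                   names: Sequence[str] | None = None) -> StateLabel:
    """Label an equilibrium as coexistence or dominance.

    Survivors are the languages with fraction >= ``extinction_threshold``;
    dominance means exactly one survivor.  The top language is the argmax
    fraction, ties broken by lowest index.
    """
    if not 0 < extinction_threshold < 0.5:
        raise ValueError(f"extinction threshold must be in (0, 0.5), got {extinction_threshold}")
    x = equilibrium.fractions
    if names is None:
        names = tuple(f"L{i}" for i in range(x.size))
    elif len(names) != x.size:
        raise ValueError(f"{len(names)} names for {x.size} fractions")
    alive = np.nonzero(x >= extinction_threshold)[0]
    if alive.size == 0:
        raise ValueError(f"degenerate equilibrium: all fractions below "
                         f"threshold {extinction_threshold}")
    top = int(np.argmax(x))  # np.argmax takes the first maximum: lowest index wins
    return StateLabel(
        kind="dominance" if alive.size == 1 else "coexistence",
        top_language=str(names[top]),
        survivors=frozenset(str(names[i]) for i in alive),
    )


def find_steady_state(model: CompetitionModel, x0: PopulationState,
                      tol: float = DEFAULT_STEADY_TOL,
                      max_time: float = DEFAULT_MAX_TIME,
                      dt: float = DEFAULT_DT,
                      extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
                      ) -> SteadyStateResult:
    """Integrate until the per-step change falls below ``tol``.

    Returns the first time ``tau`` at which
    ``max_i |x_i(t + dt) - x_i(t)| < tol``, the state there and its
    label.  Never raising on non-convergence: if ``max_time`` is reached
    first the result carries ``converged=False`` and ``tau = max_time``.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if x0.n != model.n:
        raise ValueError(f"x0 has {x0.n} languages, model has {model.n}")
    s, a, b = model.utilities, model.alpha, model.beta
    x = x0.fractions
    n_steps = int(np.ceil(max_time / dt - 1e-12))
    tau = float(max_time)
    converged = False
    for k in range(n_steps):
        xn = _euler_step(x, s, a, b, dt)
        if np.max(np.abs(xn - x)) < tol:
            x = xn
            tau = (k + 1) * dt
            converged = True
            break
        x = xn
    eq = PopulationState(x)
    label = classify_state(eq, extinction_threshold, model.names)
    return SteadyStateResult(equilibrium=eq, tau=tau, label=label,
                             converged=converged, model=model)
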