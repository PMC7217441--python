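"""Parameter sweeps, phase diagrams, and tipping-point diagnostics.

Each experiment perturbs one knob of a calibrated community — a language
utility, the majority preference beta, the minority aversion
alpha - beta, or an initial fraction — while keeping the rest at the
fitted values, integrates to the steady state, and records the
equilibrium with its coexistence/dominance label.  Thresholds (the grid
point where the long-run label flips) are read off the sweep; the
convergence time tau exhibits critical slowdown, peaking where the label
changes, which makes it an early-warning signal for tipping points.

Utilities are coupled through their unit sum, so raising one language's
utility lowers the others proportionally to their current values; the
same proportional rule is applied to initial fractions.

Everything here is deterministic given its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_DT,
    DEFAULT_EXTINCTION_THRESHOLD,
    DEFAULT_MAX_TIME,
    DEFAULT_STEADY_TOL,
    CompetitionModel,
    PopulationState,
    StateLabel,
    SteadyStateResult,
    find_steady_state,
)

__all__ = [
    "SweepSpec",
    "SweepResult",
    "PhaseDiagram",
    "ConvergenceCurve",
    "ThresholdReport",
    "redistribute_utilities",
    "rescale_initials",
    "utility_sweep",
    "bias_sweep",
    "phase_diagram",
    "convergence_time_sweep",
    "detect_threshold",
]


def _proportional_reassign(values: np.ndarray, index: int, new_value: float) -> np.ndarray:
    if not 0.0 <= new_value < 1.0:
        raise ValueError(f"new value must lie in [0, 1), got {new_value}")
    out = np.asarray(values, dtype=float).copy()
    if not 0 <= index < out.size:
        raise IndexError(f"index {index} out of range for {out.size} languages")
    rest = out.sum() - out[index]
    if rest <= 0:
        raise ValueError("remaining languages carry no mass to redistribute")
    scale = (1.0 - new_value) / rest
    out *= scale
    out[index] = new_value
    return out


def redistribute_utilities(base: Sequence[float], index: int, new_value: float) -> np.ndarray:
    """Set utility ``index`` to ``new_value``; rescale the rest proportionally.

    ``s_j' = s_j * (1 - new_value) / sum_{k != index} s_k`` for j != index,
    keeping the vector on the simplex.
    """
    s = np.asarray(base, dtype=float)
    if abs(s.sum() - 1.0) > 1e-9:
        raise ValueError(f"base utilities must sum to 1, got {s.sum()!r}")
    return _proportional_reassign(s, index, new_value)


def rescale_initials(base: PopulationState, index: int, new_value: float) -> PopulationState:
    """Proportional reassignment of initial fractions (same rule as utilities)."""
    return PopulationState(_proportional_reassign(base.fractions, index, new_value))


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional sweep description.

    ``swept`` is one of ``"utility"``, ``"aversion"`` (alpha - beta with
    beta held at the base model's value), ``"beta"`` (aversion held), or
    ``"initial"``.  ``language`` is required for utility/initial sweeps.
    """

    base_model: CompetitionModel
    base_x0: PopulationState
    swept: str
    grid: np.ndarray
    language: str | None = None

    def __post_init__(self):
        if self.swept not in ("utility", "aversion", "beta", "initial"):
            raise ValueError(f"unknown swept quantity {self.swept!r}")
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 1 or g.size == 0 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be 1-D, non-empty, strictly increasing")
        object.__setattr__(self, "grid", g)
        if self.swept in ("utility", "initial"):
            if self.language is None:
                raise ValueError(f"{self.swept} sweep needs a language")
            self.base_model.index(self.language)  # raises on unknown name

    def configuration(self, value: float) -> tuple[CompetitionModel, PopulationState]:
        """Model and initial state induced by one grid value."""
        m, x0 = self.base_model, self.base_x0
        if self.swept == "utility":
            i = m.index(self.language)
            return m.with_utilities(redistribute_utilities(m.utilities, i, value)), x0
        if self.swept == "initial":
            i = m.index(self.language)
            return m, rescale_initials(x0, i, value)
        if self.swept == "aversion":
            return m.with_biases(aversion=value), x0
        return m.with_biases(beta=value, aversion=m.aversion), x0


@dataclass(frozen=True)
class SweepResult:
    spec: SweepSpec
    results: tuple[SteadyStateResult, ...]

    @property
    def grid(self) -> np.ndarray:
        return self.spec.grid

    @property
    def labels(self) -> tuple[StateLabel, ...]:
        return tuple(r.label for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per grid value."""
        names = self.spec.base_model.names
        rows = []
        for g, r in zip(self.grid, self.results):
            row = {"value": g, "tau": r.tau, "converged": r.converged,
                   "kind": r.label.kind, "top": r.label.top_language}
            for name, xi in zip(names, r.equilibrium.fractions):
                row[f"Xeq_{name}"] = xi
            rows.append(row)
        return pd.DataFrame(rows)


def _run_sweep(spec: SweepSpec, tol: float, max_time: float, dt: float,
               extinction_threshold: float) -> SweepResult:
    results = []
    for value in spec.grid:
        model, x0 = spec.configuration(float(value))
        results.append(find_steady_state(model, x0, tol=tol, max_time=max_time,
                                         dt=dt, extinction_threshold=extinction_threshold))
    return SweepResult(spec=spec, results=tuple(results))


def utility_sweep(spec: SweepSpec, tol: float = DEFAULT_STEADY_TOL,
                  max_time: float = DEFAULT_MAX_TIME, dt: float = DEFAULT_DT,
                  extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD) -> SweepResult:
    """Steady states as one language's utility varies (others rescaled)."""
    if spec.swept != "utility":
        raise ValueError(f"utility_sweep needs a utility spec, got {spec.swept!r}")
    return _run_sweep(spec, tol, max_time, dt, extinction_threshold)


def bias_sweep(spec: SweepSpec, tol: float = DEFAULT_STEADY_TOL,
               max_time: float = DEFAULT_MAX_TIME, dt: float = DEFAULT_DT,
               extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD) -> SweepResult:
    """Steady states as beta (aversion fixed) or aversion (beta fixed) varies."""
    if spec.swept not in ("aversion", "beta"):
        raise ValueError(f"bias_sweep needs an aversion or beta spec, got {spec.swept!r}")
    return _run_sweep(spec, tol, max_time, dt, extinction_threshold)


@dataclass(frozen=True)
class PhaseDiagram:
    """Long-run label over the (beta, aversion) plane for one community."""

    beta_grid: np.ndarray
    aversion_grid: np.ndarray
    kinds: np.ndarray          # (len(beta), len(aversion)) of "coexistence"/"dominance"
    top_languages: np.ndarray  # same shape, language names

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.beta_grid):
            for j, a in enumerate(self.aversion_grid):
                rows.append({"beta": b, "aversion": a,
                             "kind": self.kinds[i, j], "top": self.top_languages[i, j]})
        return pd.DataFrame(rows)


def phase_diagram(model: CompetitionModel, x0: PopulationState,
                  beta_grid: Sequence[float], aversion_grid: Sequence[float],
                  tol: float = DEFAULT_STEADY_TOL, max_time: float = DEFAULT_MAX_TIME,
                  dt: float = DEFAULT_DT,
                  extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD) -> PhaseDiagram:
    """Cross-product of beta and aversion values, each cell a steady-state label.

    Utilities and initial fractions stay at the community's fitted values.
    """
    bg = np.asarray(beta_grid, dtype=float)
    ag = np.asarray(aversion_grid, dtype=float)
    kinds = np.empty((bg.size, ag.size), dtype=object)
    tops = np.empty((bg.size, ag.size), dtype=object)
    for i, b in enumerate(bg):
        for j, a in enumerate(ag):
            m = model.with_biases(beta=b, aversion=a)
            r = find_steady_state(m, x0, tol=tol, max_time=max_time, dt=dt,
                                  extinction_threshold=extinction_threshold)
            kinds[i, j] = r.label.kind
            tops[i, j] = r.label.top_language
    return PhaseDiagram(beta_grid=bg, aversion_grid=ag, kinds=kinds, top_languages=tops)


@dataclass(frozen=True)
class ConvergenceCurve:
    """Convergence time tau versus the initial fraction of one language."""

    language: str
    grid: np.ndarray
    results: tuple[SteadyStateResult, ...]

    @property
    def taus(self) -> np.ndarray:
        return np.array([r.tau for r in self.results])

    @property
    def labels(self) -> tuple[StateLabel, ...]:
        return tuple(r.label for r in self.results)

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.taus))

    @property
    def peak_location(self) -> float:
        return float(self.grid[self.peak_index])

    def to_frame(self) -> pd.DataFrame:
        names = self.results[0].model.names
        rows = []
        for g, r in zip(self.grid, self.results):
            row = {"initial": g, "tau": r.tau, "converged": r.converged,
                   "kind": r.label.kind, "top": r.label.top_language}
            for name, xi in zip(names, r.equilibrium.fractions):
                row[f"Xeq_{name}"] = xi
            rows.append(row)
        return pd.DataFrame(rows)


def convergence_time_sweep(model: CompetitionModel, x0: PopulationState,
                           varied_language: str, grid: Sequence[float],
                           tol: float = DEFAULT_STEADY_TOL,
                           max_time: float = DEFAULT_MAX_TIME, dt: float = DEFAULT_DT,
                           extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
                           ) -> ConvergenceCurve:
    """tau and equilibrium as the initial fraction of one language grows.

    Non-converged runs are recorded with ``tau = max_time`` and flagged
    by ``converged=False``; critical slowdown makes tau peak where the
    steady-state label changes.
    """
    spec = SweepSpec(base_model=model, base_x0=x0, swept="initial",
                     grid=np.asarray(grid, dtype=float), language=varied_language)
    sweep = _run_sweep(spec, tol, max_time, dt, extinction_threshold)
    return ConvergenceCurve(language=varied_language, grid=spec.grid,
                            results=sweep.results)


@dataclass(frozen=True)
class ThresholdReport:
    """Grid bracketing of a label change along a sweep.

    ``last_false``/``first_true`` bracket the onset of the predicate
    ("exceeds X" statements quote ``last_false``).  When the predicate
    flips more than once every change point is listed and the first
    bracket is reported.
    """

    predicate_name: str
    last_false: float | None
    first_true: float | None
    change_points: tuple[tuple[float, float], ...]

    @property
    def found(self) -> bool:
        return self.last_false is not None and self.first_true is not None

    @property
    def monotone(self) -> bool:
        return len(self.change_points) <= 1


def detect_threshold(result: SweepResult,
                     predicate: Callable[[StateLabel], bool],
                     name: str = "predicate") -> ThresholdReport:
    """Locate where a label predicate switches from false to true.

    Returns the adjacent grid pair (last value where the predicate is
    false, first where it is true).  A predicate that never becomes true
    (or never false) yields a report with the corresponding side None —
    an outcome, not an error.
    """
    grid = result.grid
    flags = np.array([bool(predicate(lbl)) for lbl in result.labels])
    changes = [(float(grid[k]), float(grid[k + 1]))
               for k in range(flags.size - 1) if flags[k] != flags[k + 1]]
    onsets = [(lo, hi) for (lo, hi), k in zip(changes, np.nonzero(np.diff(flags))[0])
              if not flags[k]]  # false -> true transitions only
    if flags.all():
        return ThresholdReport(name, None, float(grid[0]), tuple(changes))
    if not flags.any():
        return ThresholdReport(name, float(grid[-1]), None, tuple(changes))
    if onsets:
        lo, hi = onsets[0]
        return ThresholdReport(name, lo, hi, tuple(changes))
    # Predicate starts true and only switches off: no onset to bracket.
    return ThresholdReport(name, None, float(grid[0]), tuple(changes))
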