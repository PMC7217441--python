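"""File formats, run configuration, and manifests.

The canonical on-disk carrier for census data is a plain CSV with header
``year,<language>,...`` and one row per census year; an optional
spreadsheet importer accepts the same layout in XLSX.  Posterior
ensembles, sweeps, and phase diagrams are written as tidy CSVs so runs
diff cleanly.  Every CLI run also writes a JSON manifest with the full
effective configuration, seed, and package version, sufficient to rerun
the command bit-for-bit.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .inference import ROW_SUM_ATOL, ObservedSeries, Particle, PosteriorEnsemble

__all__ = [
    "SeriesFormatError",
    "read_series",
    "write_series",
    "read_series_xlsx",
    "write_posterior",
    "read_posterior",
    "write_manifest",
    "RunConfig",
]

log = logging.getLogger("langshift")


class SeriesFormatError(ValueError):
    """Malformed series file; message carries file and line context."""


def read_series(path: str | Path) -> ObservedSeries:
    """Parse a ``year,<lang>,...`` CSV into an ObservedSeries.

    Rows whose fractions do not sum to 1 (beyond 1e-6) are accepted and
    normalized downstream, with a logged warning — census tables commonly
    drop residual categories.  Structural problems (ragged rows,
    non-numeric cells, non-increasing years) raise
    :class:`SeriesFormatError` with ``file:line`` context.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SeriesFormatError(f"{path}:1: empty file") from None
        header = [h.strip() for h in header]
        if len(header) < 3 or header[0].lower() != "year":
            raise SeriesFormatError(
                f"{path}:1: header must be 'year' followed by >=2 language "
                f"names, got {header}")
        names = header[1:]
        years: list[float] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(reader, start=2):
            if not raw or all(not c.strip() for c in raw):
                continue
            if len(raw) != len(header):
                raise SeriesFormatError(
                    f"{path}:{lineno}: expected {len(header)} cells, got {len(raw)}")
            try:
                values = [float(c) for c in raw]
            except ValueError as exc:
                raise SeriesFormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            year, fracs = values[0], values[1:]
            if years and year <= years[-1]:
                raise SeriesFormatError(
                    f"{path}:{lineno}: year {year} not greater than previous {years[-1]}")
            if any(f < 0 or f > 1 for f in fracs):
                raise SeriesFormatError(
                    f"{path}:{lineno}: fractions must lie in [0, 1], got {fracs}")
            total = sum(fracs)
            if abs(total - 1.0) > ROW_SUM_ATOL:
                log.warning("%s:%d: row sums to %.6g, will be normalized",
                            path, lineno, total)
            years.append(year)
            rows.append(fracs)
    if not rows:
        raise SeriesFormatError(f"{path}: no data rows")
    try:
        return ObservedSeries(years=years, names=names, fractions=rows)
    except ValueError as exc:
        raise SeriesFormatError(f"{path}: {exc}") from None


def write_series(series: ObservedSeries, path: str | Path) -> None:
    """Write a series CSV at full double precision (lossless round-trip)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", *series.names])
        for year, row in zip(series.years, series.fractions):
            year = int(year) if float(year).is_integer() else year
            writer.writerow([year, *(repr(float(v)) for v in row)])


def read_series_xlsx(path: str | Path, sheet: int | str = 0) -> ObservedSeries:
    """Import a spreadsheet with the same layout (first column year).

    Accepts user-supplied supplementary tables; requires openpyxl.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    names = [str(c) for c in df.columns[1:]]
    return ObservedSeries(years=df.iloc[:, 0].to_numpy(dtype=float),
                          names=names,
                          fractions=df.iloc[:, 1:].to_numpy(dtype=float))


def write_posterior(ensemble: PosteriorEnsemble, names: list[str],
                    path: str | Path) -> None:
    """One particle per row: alpha, beta, s_<lang>..., weight, distance."""
    rows = []
    for p in ensemble.particles:
        row: dict[str, float] = {"alpha": p.alpha, "beta": p.beta}
        for name, s in zip(names, p.utilities):
            row[f"s_{name}"] = float(s)
        row["weight"] = p.weight
        row["distance"] = p.distance
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_posterior(path: str | Path) -> tuple[list[Particle], list[str]]:
    """Inverse of :func:`write_posterior`; returns particles and language names."""
    df = pd.read_csv(path, float_precision="round_trip")
    s_cols = [c for c in df.columns if c.startswith("s_")]
    names = [c[2:] for c in s_cols]
    particles = [
        Particle(alpha=row["alpha"], beta=row["beta"],
                 utilities=row[s_cols].to_numpy(dtype=float),
                 weight=row["weight"], distance=row["distance"])
        for _, row in df.iterrows()
    ]
    return particles, names


@dataclass
class RunConfig:
    """Flat run configuration; YAML files mirror these fields one-to-one."""

    dataset: str | None = None
    series: str | None = None
    dt: float = 1.0
    horizon: float = 200.0
    steady_tol: float = 1e-6
    max_time: float = 1e5
    extinction_threshold: float = 1e-3
    grid_start: float = 0.0
    grid_stop: float = 1.0
    grid_step: float = 0.01
    n_particles: int = 100
    n_iterations: int = 50
    noise_sd: float = 0.005
    seed: int = 0
    outdir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key/value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}; "
                             f"known keys: {sorted(known)}")
        return cls(**raw)

    def updated(self, **overrides: Any) -> "RunConfig":
        """Copy with non-None overrides applied (CLI flags beat file values)."""
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)


def write_manifest(path: str | Path, command: str, config: dict[str, Any]) -> None:
    """Record the effective parameters of a run for exact reproduction."""
    from . import __version__

    manifest = {"command": command, "package_version": __version__,
                "parameters": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                               for k, v in config.items()}}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
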