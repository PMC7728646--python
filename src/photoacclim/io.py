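"""Delimited-text readers and writers shared by all modules.

Signals travel as two-column text files: `#`-prefixed header lines carry
``key=value`` metadata (kind, preset, seed, units), followed by one
delimited row per sample. A JSON sidecar (``<file>.json``) can hold the
full generating parameters. The dialect (column delimiter, decimal mark)
is configurable so spreadsheet exports with comma decimals parse too.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .containers import GlowCurve, Spectrum, TimeSeries

__all__ = [
    "Dialect",
    "read_table",
    "write_table",
    "read_timeseries",
    "write_timeseries",
    "read_spectrum",
    "write_spectrum",
    "read_glow_curve",
    "write_glow_curve",
]


@dataclass(frozen=True)
class Dialect:
    """Delimiter and decimal-mark options for the two-column text format."""

    delimiter: str = "\t"
    decimal: str = "."

    def __post_init__(self) -> None:
        if self.delimiter == self.decimal:
            raise ValueError("delimiter and decimal mark must differ")


def _parse_header(lines: list[str]) -> dict:
    meta: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        for chunk in body.split(";"):
            if "=" in chunk:
                key, _, val = chunk.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def read_table(path, dialect: Dialect = Dialect()):
    """Read a two-column delimited text file.

    Returns ``(meta, col0, col1)``. Unparseable rows raise a ``ValueError``
    listing their line numbers; an empty file is an error.
    """
    path = Path(path)
    header, rows, bad = [], [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                header.append(line)
                continue
            parts = [p.strip() for p in line.split(dialect.delimiter)]
            if dialect.decimal != ".":
                parts = [p.replace(dialect.decimal, ".") for p in parts]
            try:
                x, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                bad.append(lineno)
                continue
            rows.append((x, y))
    if bad:
        raise ValueError(f"unparseable rows in {path} at line(s) {bad}")
    if not rows:
        raise ValueError(f"no data rows in {path}")
    data = np.array(rows)
    return _parse_header(header), data[:, 0], data[:, 1]


def write_table(path, col0: np.ndarray, col1: np.ndarray, meta: dict,
                columns: tuple[str, str], dialect: Dialect = Dialect(),
                sidecar: dict | None = None) -> None:
    path = Path(path)
    pairs = "; ".join(f"{k}={v}" for k, v in meta.items() if v is not None)
    with path.open("w") as fh:
        if pairs:
            fh.write(f"# {pairs}\n")
        fh.write(f"# columns={columns[0]},{columns[1]}\n")
        for x, y in zip(col0, col1):
            row = f"{x:.12g}{dialect.delimiter}{y:.12g}"
            if dialect.decimal != ".":
                row = row.replace(".", dialect.decimal)
            fh.write(row + "\n")
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2,
                                                        default=str))


def write_timeseries(ts: TimeSeries, path, dialect: Dialect = Dialect(),
                     sidecar: dict | None = None) -> None:
    meta = {"kind": ts.kind, **{k: v for k, v in ts.meta.items()
                                if np.isscalar(v) or v is None}}
    write_table(path, ts.time, ts.values, meta,
                columns=(f"time_{ts.time_unit}", "value"), dialect=dialect,
                sidecar=sidecar)


def read_timeseries(path, dialect: Dialect = Dialect()) -> TimeSeries:
    """Read a TimeSeries written by :func:`write_timeseries`.

    Rows are sorted by time (with a warning if they were out of order);
    duplicate time points are rejected.
    """
    meta, t, v = read_table(path, dialect)
    order = np.argsort(t, kind="stable")
    if not np.array_equal(order, np.arange(len(t))):
        warnings.warn(f"rows in {path} were out of order and have been sorted")
        t, v = t[order], v[order]
    if np.any(np.diff(t) == 0):
        raise ValueError(f"duplicate time points in {path}")
    time_unit = "s"
    for key, val in meta.items():
        if key.startswith("columns"):
            first = val.split(",")[0]
            if first.startswith("time_"):
                time_unit = first[len("time_"):]
    kind = meta.pop("kind", "generic")
    meta.pop("columns", None)
    return TimeSeries(t, v, kind=kind, time_unit=time_unit, meta=meta)


def write_spectrum(spec: Spectrum, path, dialect: Dialect = Dialect(),
                   sidecar: dict | None = None) -> None:
    meta = {"kind": "spectrum", **{k: v for k, v in spec.meta.items()
                                   if np.isscalar(v) or v is None}}
    write_table(path, spec.wavelengths, spec.intensities, meta,
                columns=("wavelength_nm", "intensity"), dialect=dialect,
                sidecar=sidecar)


def read_spectrum(path, dialect: Dialect = Dialect()) -> Spectrum:
    meta, w, v = read_table(path, dialect)
    order = np.argsort(w, kind="stable")
    if not np.array_equal(order, np.arange(len(w))):
        warnings.warn(f"rows in {path} were out of order and have been sorted")
        w, v = w[order], v[order]
    meta.pop("columns", None)
    meta.pop("kind", None)
    return Spectrum(w, v, meta=meta)


def write_glow_curve(curve: GlowCurve, path, dialect: Dialect = Dialect(),
                     sidecar: dict | None = None) -> None:
    meta = {"kind": "glow", "beta_K_per_s": curve.beta, "T0_K": curve.T0,
            **{k: v for k, v in curve.meta.items() if np.isscalar(v) or v is None}}
    write_table(path, curve.temperatures_c, curve.intensities, meta,
                columns=("temperature_C", "intensity"), dialect=dialect,
                sidecar=sidecar)


def read_glow_curve(path, dialect: Dialect = Dialect()) -> GlowCurve:
    meta, t_c, v = read_table(path, dialect)
    try:
        beta = float(meta.pop("beta_K_per_s"))
        T0 = float(meta.pop("T0_K"))
    except KeyError as exc:
        raise ValueError(f"glow-curve file {path} lacks ramp metadata "
                         f"({exc})") from None
    meta.pop("columns", None)
    meta.pop("kind", None)
    return GlowCurve(t_c + 273.15, v, beta=beta, T0=T0, meta=meta)
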