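"""Reading and writing spectrum sets.

Two CSV dialects are supported losslessly:

* ``csv-wide`` — one row per spectrum: the metadata columns first, then
  3601 value columns named by integer wavenumber (``400`` ... ``4000``).
* ``csv-long`` — columns ``spectrum_id, wavenumber_cm1, absorbance`` plus
  the per-spectrum metadata columns repeated on every row.

A minimal JCAMP-DX reader handles the common AFFN ``(X++(Y..Y))`` XYDATA
table (one spectrum per file, read-only).

Input grids finer than 1 cm^-1 are linearly interpolated onto the
canonical grid; grids that do not cover 400–4000 cm^-1, or are coarser
than 1 cm^-1, are rejected rather than extrapolated.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .grid import canonical_grid
from .spectra import META_COLUMNS, SpectrumSet

_FORMATS = ("csv-wide", "csv-long", "jcamp")


def _to_canonical(nu: np.ndarray, values: np.ndarray, name: str) -> np.ndarray:
    """Validate/resample one trace onto the canonical grid."""
    grid = canonical_grid()
    order = np.argsort(nu)
    nu, values = nu[order], values[order]
    if nu[0] > grid.start or nu[-1] < grid.end:
        raise ValueError(
            f"grid incomplete for {name!r}: covers {nu[0]:g}-{nu[-1]:g} cm^-1, "
            f"need {grid.start}-{grid.end}"
        )
    target = grid.points
    if nu.size == target.size and np.array_equal(nu, target):
        return values.astype(float)
    max_step = float(np.diff(nu).max())
    if max_step > grid.step:
        raise ValueError(
            f"grid for {name!r} is coarser than {grid.step} cm^-1 "
            f"(max spacing {max_step:g}); refusing to invent data"
        )
    return np.interp(target, nu, values)


def _numeric(series: pd.Series, context: str) -> np.ndarray:
    converted = pd.to_numeric(series, errors="coerce")
    bad = converted.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"non-numeric absorbance in {context} at row {row}: {series[row]!r}"
        )
    if converted.isna().any():
        row = int(converted.isna().idxmax())
        raise ValueError(f"missing absorbance in {context} at row {row}")
    return converted.to_numpy(dtype=float)


def _read_wide(path: str) -> SpectrumSet:
    df = pd.read_csv(path, float_precision="round_trip")
    value_cols, nus = [], []
    for col in df.columns:
        try:
            nus.append(float(col))
            value_cols.append(col)
        except ValueError:
            continue
    if not value_cols:
        raise ValueError(f"no wavenumber columns found in {path}")
    nu = np.asarray(nus)
    meta_cols = [c for c in df.columns if c not in value_cols]
    raw = np.column_stack(
        [_numeric(df[c], f"column {c}") for c in value_cols]
    )
    rows = [
        _to_canonical(nu, raw[i], df[meta_cols[0]][i] if meta_cols else f"row {i}")
        for i in range(len(df))
    ]
    meta = df[meta_cols] if meta_cols else None
    return SpectrumSet(np.vstack(rows), meta)


def _read_long(path: str) -> SpectrumSet:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("spectrum_id", "wavenumber_cm1", "absorbance"):
        if col not in df.columns:
            raise ValueError(f"long-format CSV missing column {col!r}")
    df["absorbance"] = _numeric(df["absorbance"], path)
    traces, metas = [], []
    meta_cols = [c for c in META_COLUMNS if c in df.columns and c != "spectrum_id"]
    # groupby(sort=False) preserves first-appearance order of spectra
    for sid, g in df.groupby("spectrum_id", sort=False):
        nu = g["wavenumber_cm1"].to_numpy(dtype=float)
        traces.append(_to_canonical(nu, g["absorbance"].to_numpy(), str(sid)))
        row = {"spectrum_id": sid}
        for c in meta_cols:
            row[c] = g[c].iloc[0]
        metas.append(row)
    return SpectrumSet(np.vstack(traces), pd.DataFrame(metas))


def _read_jcamp(path: str) -> SpectrumSet:
    """Minimal AFFN (X++(Y..Y)) XYDATA reader; one spectrum per file."""
    headers: dict[str, str] = {}
    ys: list[float] = []
    in_table = False
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                if key == "XYDATA":
                    in_table = True
                    continue
                if key == "END":
                    in_table = False
                headers[key] = value.strip()
                continue
            if in_table and line:
                parts = line.replace(",", " ").split()
                # first number on each line is the X start value
                ys.extend(float(p) for p in parts[1:])
    if not ys:
        raise ValueError(f"no XYDATA table found in {path}")
    firstx = float(headers.get("FIRSTX", "nan"))
    lastx = float(headers.get("LASTX", "nan"))
    yfactor = float(headers.get("YFACTOR", "1"))
    xfactor = float(headers.get("XFACTOR", "1"))
    npoints = int(float(headers.get("NPOINTS", len(ys))))
    if npoints != len(ys):
        raise ValueError(f"NPOINTS={npoints} but {len(ys)} Y values in {path}")
    nu = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    values = np.asarray(ys) * yfactor
    sid = headers.get("TITLE", os.path.basename(path)) or os.path.basename(path)
    trace = _to_canonical(nu, values, sid)
    return SpectrumSet(trace[None, :], pd.DataFrame({"spectrum_id": [sid]}))


def read_spectra(path: str, format: str | None = None) -> SpectrumSet:
    """Read a SpectrumSet from ``csv-wide``, ``csv-long`` or ``jcamp``.

    When ``format`` is None it is inferred: ``.jdx``/``.dx`` extension for
    JCAMP, otherwise the CSV header decides (a ``wavenumber_cm1`` column
    marks the long dialect).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        if ext in (".jdx", ".dx"):
            format = "jcamp"
        else:
            header = pd.read_csv(path, nrows=0).columns
            format = "csv-long" if "wavenumber_cm1" in header else "csv-wide"
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "csv-wide":
        return _read_wide(path)
    if format == "csv-long":
        return _read_long(path)
    return _read_jcamp(path)


def write_spectra(sset: SpectrumSet, path: str, format: str = "csv-wide") -> str:
    """Persist a set losslessly (values round-trip bit-for-bit via repr)."""
    if len(sset) == 0:
        raise ValueError("refusing to write an empty spectrum set")
    if format not in ("csv-wide", "csv-long"):
        raise ValueError(f"unsupported write format {format!r}")
    nu = sset.wavenumbers
    if format == "csv-wide":
        values = pd.DataFrame(sset.absorbance, columns=[str(int(v)) for v in nu])
        df = pd.concat([sset.meta.reset_index(drop=True), values], axis=1)
        df.to_csv(path, index=False)
        return path
    frames: Iterable[pd.DataFrame] = (
        pd.DataFrame(
            {
                "spectrum_id": row["spectrum_id"],
                "wavenumber_cm1": nu,
                "absorbance": sset.absorbance[i],
                **{
                    c: row[c]
                    for c in META_COLUMNS
                    if c != "spectrum_id"
                },
            }
        )
        for i, row in sset.meta.iterrows()
    )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
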