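"""Spectrum containers and the two preprocessing transforms.

Preprocessing follows the fixed order used throughout the package:

1. baseline correction — subtract the straight line (linear gradient)
   through the absorbance values at 400 and 4000 cm^-1, so both endpoints
   become exactly zero;
2. total-sum normalization — rescale so the absorbance values of each
   spectrum sum to one million.

Negative post-baseline values are kept (clipping would destroy linearity),
and normalization uses the signed sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .grid import WavenumberGrid, canonical_grid

CLASS_LABELS = ("control", "heat")
TOTAL_DEFAULT = 1e6

#: metadata columns carried by every SpectrumSet, in storage order
META_COLUMNS = (
    "spectrum_id",
    "class_label",
    "plant_id",
    "disk_id",
    "repeat_index",
    "baseline_corrected",
    "normalized",
)


@dataclass
class SpectrumMeta:
    """Replicate metadata and preprocessing state for one spectrum.

    The replicate hierarchy is plant > disk (pressed KBr pellet) > repeat
    scan. ``normalized`` implies ``baseline_corrected`` because the
    pipeline order is fixed.
    """

    spectrum_id: str = ""
    class_label: str | None = None
    plant_id: str | None = None
    disk_id: str | None = None
    repeat_index: int = 1
    baseline_corrected: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.normalized and not self.baseline_corrected:
            raise ValueError("normalized spectrum must be baseline-corrected first")
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")


@dataclass
class Spectrum:
    """One absorbance trace on a wavenumber grid."""

    absorbance: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)
    grid: WavenumberGrid = field(default_factory=canonical_grid)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 1 or len(self.absorbance) != len(self.grid):
            raise ValueError(
                f"absorbance length {self.absorbance.size} does not match "
                f"grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid.points

    def at(self, wavenumber: float) -> float:
        """Absorbance at an on-grid wavenumber."""
        return float(self.absorbance[self.grid.index_of(wavenumber)])


class SpectrumSet:
    """An ordered collection of spectra sharing one grid.

    Internally a dense ``(n_spectra, n_points)`` matrix plus a metadata
    DataFrame — the layout every downstream chemometric step consumes.
    """

    def __init__(
        self,
        absorbance: np.ndarray,
        meta: pd.DataFrame | None = None,
        grid: WavenumberGrid | None = None,
    ):
        self.grid = grid if grid is not None else canonical_grid()
        A = np.asarray(absorbance, dtype=float)
        if A.ndim != 2 or A.shape[1] != len(self.grid):
            raise ValueError(
                f"absorbance matrix shape {A.shape} incompatible with grid of "
                f"{len(self.grid)} points"
            )
        if not np.all(np.isfinite(A)):
            raise ValueError("absorbance contains non-finite values")
        self.absorbance = A
        n = A.shape[0]
        if meta is None:
            meta = pd.DataFrame(index=range(n))
        meta = meta.reset_index(drop=True).copy()
        if len(meta) != n:
            raise ValueError("metadata row count does not match spectrum count")
        if "spectrum_id" not in meta:
            meta["spectrum_id"] = [f"s{i:04d}" for i in range(n)]
        for col, default in (
            ("class_label", None),
            ("plant_id", None),
            ("disk_id", None),
            ("repeat_index", 1),
        ):
            if col not in meta:
                meta[col] = default
        for col in ("baseline_corrected", "normalized"):
            if col not in meta:
                meta[col] = False
            meta[col] = meta[col].astype(bool)
        if meta["spectrum_id"].duplicated().any():
            raise ValueError("duplicate spectrum_id in set")
        self.meta = meta[list(META_COLUMNS)]

    # -- construction -------------------------------------------------
    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectrumSet":
        if not spectra:
            raise ValueError("empty spectrum collection")
        grid = spectra[0].grid
        for s in spectra:
            if s.grid != grid:
                raise ValueError("all spectra in a set must share one grid")
        A = np.vstack([s.absorbance for s in spectra])
        rows = []
        for i, s in enumerate(spectra):
            m = s.meta
            rows.append(
                {
                    "spectrum_id": m.spectrum_id or f"s{i:04d}",
                    "class_label": m.class_label,
                    "plant_id": m.plant_id,
                    "disk_id": m.disk_id,
                    "repeat_index": m.repeat_index,
                    "baseline_corrected": m.baseline_corrected,
                    "normalized": m.normalized,
                }
            )
        return cls(A, pd.DataFrame(rows), grid)

    # -- container protocol -------------------------------------------
    def __len__(self) -> int:
        return self.absorbance.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self.spectrum(i)

    def spectrum(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        meta = SpectrumMeta(
            spectrum_id=row["spectrum_id"],
            class_label=row["class_label"] if pd.notna(row["class_label"]) else None,
            plant_id=row["plant_id"] if pd.notna(row["plant_id"]) else None,
            disk_id=row["disk_id"] if pd.notna(row["disk_id"]) else None,
            repeat_index=int(row["repeat_index"]),
            baseline_corrected=bool(row["baseline_corrected"]),
            normalized=bool(row["normalized"]),
        )
        return Spectrum(self.absorbance[i].copy(), meta, self.grid)

    # -- derived views ------------------------------------------------
    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid.points

    @property
    def class_counts(self) -> dict:
        counts = self.meta["class_label"].value_counts(dropna=False).to_dict()
        return {k: int(v) for k, v in counts.items()}

    def absorbance_at(self, wavenumber: float) -> np.ndarray:
        """Per-spectrum absorbance at one on-grid wavenumber."""
        return self.absorbance[:, self.grid.index_of(wavenumber)]

    def restrict(self, low: float, high: float) -> tuple[np.ndarray, np.ndarray]:
        """(wavenumbers, matrix) view limited to [low, high] cm^-1."""
        nu = self.wavenumbers
        mask = (nu >= low) & (nu <= high)
        return nu[mask], self.absorbance[:, mask]

    def select_ids(self, ids: Sequence[str]) -> "SpectrumSet":
        """Subset by spectrum_id, preserving the order of ``ids``."""
        lookup = {sid: i for i, sid in enumerate(self.meta["spectrum_id"])}
        try:
            idx = [lookup[sid] for sid in ids]
        except KeyError as exc:
            raise KeyError(f"unknown spectrum_id {exc.args[0]!r}") from None
        return SpectrumSet(self.absorbance[idx], self.meta.iloc[idx], self.grid)

    def class_mask(self, label: str) -> np.ndarray:
        return (self.meta["class_label"] == label).to_numpy()

    def mean_spectrum(self, label: str | None = None) -> Spectrum:
        """Mean trace, pooled or per class; inherits preprocessing flags."""
        A = self.absorbance if label is None else self.absorbance[self.class_mask(label)]
        if A.shape[0] == 0:
            raise ValueError(f"no spectra with label {label!r}")
        meta = SpectrumMeta(
            spectrum_id=f"mean_{label or 'all'}",
            class_label=label,
            baseline_corrected=bool(self.meta["baseline_corrected"].all()),
            normalized=bool(self.meta["normalized"].all()),
        )
        return Spectrum(A.mean(axis=0), meta, self.grid)


# ---------------------------------------------------------------------
# preprocessing transforms
# ---------------------------------------------------------------------

def _baseline_matrix(A: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Subtract, per row, the chord through the first and last grid point."""
    a0 = A[:, [0]]
    a1 = A[:, [-1]]
    frac = (nu - nu[0]) / (nu[-1] - nu[0])
    return A - (a0 + (a1 - a0) * frac[None, :])


def baseline_correct(s: Spectrum) -> Spectrum:
    """Remove the linear gradient through A(400) and A(4000).

    Both endpoints of the returned spectrum are exactly zero; interior
    values may go negative.
    """
    if not s.grid.is_canonical():
        raise ValueError("baseline correction requires the canonical 400-4000 grid")
    corrected = _baseline_matrix(s.absorbance[None, :], s.wavenumbers)[0]
    meta = replace(s.meta, baseline_corrected=True)
    return Spectrum(corrected, meta, s.grid)


def normalize_total(s: Spectrum, total: float = TOTAL_DEFAULT) -> Spectrum:
    """Rescale so the spectrum's absorbance values sum to ``total``.

    Requires a baseline-corrected spectrum with a positive signed sum;
    idempotent and invariant to positive rescaling of the input.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not s.meta.baseline_corrected:
        raise ValueError("normalize_total requires a baseline-corrected spectrum")
    current = float(s.absorbance.sum())
    if current <= 0:
        raise ValueError(
            f"cannot normalize spectrum {s.meta.spectrum_id!r}: nonpositive total {current:g}"
        )
    meta = replace(s.meta, normalized=True)
    return Spectrum(s.absorbance * (total / current), meta, s.grid)


def preprocess_set(
    sset: SpectrumSet, total: float = TOTAL_DEFAULT, drop_failures: bool = False
) -> SpectrumSet:
    """Baseline-correct then total-sum normalize every member, in order.

    Members whose signed sum is nonpositive cannot be normalized; they are
    reported by spectrum_id and either raise (default) or are dropped.
    """
    if not sset.grid.is_canonical():
        raise ValueError("preprocessing requires the canonical 400-4000 grid")
    A = _baseline_matrix(sset.absorbance, sset.wavenumbers)
    sums = A.sum(axis=1)
    bad = sums <= 0
    if bad.any():
        names = list(sset.meta.loc[bad, "spectrum_id"])
        if not drop_failures:
            raise ValueError(f"cannot normalize spectra (nonpositive total): {names}")
        keep = ~bad
        A, sums = A[keep], sums[keep]
        meta = sset.meta.loc[keep]
    else:
        meta = sset.meta
    A = A * (total / sums[:, None])
    meta = meta.assign(baseline_corrected=True, normalized=True)
    return SpectrumSet(A, meta, sset.grid)
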