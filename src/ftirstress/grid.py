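"""Canonical wavenumber grid for mid-infrared absorbance spectra.

Spectra are stored on an ascending integer grid from 400 to 4000 cm^-1 at
1 cm^-1 spacing (3601 points). Instrument software typically displays the
axis descending; that is a display concern only — ascending storage makes
``index(nu) == nu - 400`` and keeps slicing trivial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRID_START = 400
GRID_END = 4000
GRID_STEP = 1
N_POINTS = (GRID_END - GRID_START) // GRID_STEP + 1  # 3601


@dataclass(frozen=True)
class WavenumberGrid:
    """An inclusive, ascending, evenly spaced wavenumber axis in cm^-1."""

    start: int = GRID_START
    end: int = GRID_END
    step: int = GRID_STEP

    def __post_init__(self) -> None:
        if self.end <= self.start or self.step <= 0:
            raise ValueError(f"invalid grid {self.start}..{self.end} step {self.step}")
        if (self.end - self.start) % self.step != 0:
            raise ValueError("grid end not reachable from start with given step")

    def __len__(self) -> int:
        return (self.end - self.start) // self.step + 1

    @property
    def points(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1, self.step)

    def is_canonical(self) -> bool:
        return (self.start, self.end, self.step) == (GRID_START, GRID_END, GRID_STEP)

    def index_of(self, wavenumber: float) -> int:
        """Index of an on-grid wavenumber; raises if off-grid."""
        offset = wavenumber - self.start
        idx, rem = divmod(offset, self.step)
        if rem != 0 or not (0 <= idx < len(self)):
            raise ValueError(f"wavenumber {wavenumber} cm^-1 is not on the grid")
        return int(idx)

    def contains(self, wavenumber: float) -> bool:
        try:
            self.index_of(wavenumber)
        except ValueError:
            return False
        return True


def canonical_grid() -> WavenumberGrid:
    """The 400–4000 cm^-1, 1 cm^-1 grid (3601 points) used throughout."""
    return WavenumberGrid()
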