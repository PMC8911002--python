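"""Synthetic FTIR-like spectrum sets with the study's replicate hierarchy.

No measured spectra are deposited for the wheat heat-stress study this
package models, so every downstream stage is exercised on simulated data
that emulates the measurement design: two classes (control / heat), six
plants per class, ten KBr-pellet disks per plant, three repeat scans per
disk — with one heat-class disk scanned only once — giving 180 control and
178 heat spectra.

Each spectrum is a mixture of Gaussian absorption bands (the twelve major
leaf bands plus narrow marker bands and one broad 2700–3700 cm^-1 O-H/N-H
envelope), with:

* class effects — multiplicative amplitude changes of the band nearest
  each effect wavenumber in the heat class (multiplicative so the effect
  survives total-sum normalization as a compositional shift);
* hierarchical noise — independent log-normal amplitude factors per band
  at plant, disk and repeat level (amplitudes are positive, so log-normal);
* linear baseline drift per scan;
* additive "knurl" noise restricted to the low-wavenumber 405–480 cm^-1
  interval, as seen in the instrument's spectra.

Every random draw comes from a dedicated ``numpy`` SeedSequence keyed by
(seed, class, plant[, disk[, repeat]]), so changing the repeat count of one
disk never perturbs any other cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import canonical_grid
from .spectra import SpectrumSet


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band: center (cm^-1), sigma (cm^-1), amplitude."""

    center: float
    width: float
    base_amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if not canonical_grid().start <= self.center <= canonical_grid().end:
            raise ValueError(f"band center {self.center} outside the grid")


@dataclass(frozen=True)
class ClassEffect:
    """Amplitude multiplier applied in the heat class near one wavenumber."""

    wavenumber: float
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Dispersion parameters for the nested noise structure.

    plant_sd / disk_sd / repeat_sd are log-scale sds of per-band amplitude
    factors; baseline_slope_sd is in absorbance per cm^-1; floor_sd is the
    white detector-noise floor present at every wavenumber; knurl_sd is an
    extra additive absorbance sd inside knurl_band.
    """

    plant_sd: float = 0.05
    disk_sd: float = 0.03
    repeat_sd: float = 0.02
    baseline_slope_sd: float = 2e-5
    floor_sd: float = 0.004
    knurl_band: tuple[float, float] = (405.0, 480.0)
    knurl_sd: float = 0.004

    def __post_init__(self) -> None:
        for name in ("plant_sd", "disk_sd", "repeat_sd", "baseline_slope_sd", "floor_sd", "knurl_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# The twelve major leaf bands plus the broad hydroxyl/amine envelope.
# Widths and amplitudes are synthetic choices shaped to the morphology of
# a dried-leaf KBr-pellet spectrum: a dominant broad 2700-3700 envelope,
# sharp C-H bands near 2900, and a dense fingerprint region below 1800.
TABLE_BANDS: tuple[BandModel, ...] = (
    BandModel(3293, 40, 0.60),
    BandModel(2960, 10, 0.25),
    BandModel(2925, 10, 0.35),
    BandModel(2852, 9, 0.22),
    BandModel(1651, 22, 0.55),
    BandModel(1541, 18, 0.40),
    BandModel(1385, 14, 0.30),
    BandModel(1241, 16, 0.28),
    BandModel(1158, 12, 0.25),
    BandModel(1106, 10, 0.28),
    BandModel(1055, 14, 0.35),
    BandModel(618, 14, 0.15),
)

BROAD_ENVELOPE = BandModel(3250, 230, 0.75)

# Narrow bands at the marker wavenumbers so that a class effect placed
# there multiplies a band centred exactly on it.
MARKER_BANDS: tuple[BandModel, ...] = (
    BandModel(1465, 3, 0.16),
    BandModel(1729, 4, 0.14),
    BandModel(1251, 3, 0.15),
    BandModel(576, 5, 0.12),
    BandModel(1502, 3, 0.13),
    BandModel(482, 4, 0.10),
)

DEFAULT_BANDS: tuple[BandModel, ...] = TABLE_BANDS + MARKER_BANDS + (BROAD_ENVELOPE,)


def default_effects() -> tuple[ClassEffect, ...]:
    """Default implanted class effects: up at 1465 and 1729, down at 1251."""
    return (
        ClassEffect(1465, 1.30),
        ClassEffect(1729, 1.22),
        ClassEffect(1251, 0.75),
    )


def study_marker_effects() -> tuple[ClassEffect, ...]:
    """Effects at all six marker wavenumbers (two up, four down)."""
    return (
        ClassEffect(1465, 1.30),
        ClassEffect(1729, 1.22),
        ClassEffect(1251, 0.75),
        ClassEffect(576, 0.80),
        ClassEffect(1502, 0.85),
        ClassEffect(482, 0.85),
    )


@dataclass(frozen=True)
class SimDesign:
    """Full description of one simulated measurement campaign."""

    n_plants_per_class: int = 6
    n_disks_per_plant: int = 10
    n_repeats_per_disk: int = 3
    #: (class_label, plant_number, disk_number, n_repeats) overrides, 1-based
    short_measured_disks: tuple[tuple[str, int, int, int], ...] = ()
    noise: NoiseModel = field(default_factory=NoiseModel)
    effects: tuple[ClassEffect, ...] = field(default_factory=default_effects)
    bands: tuple[BandModel, ...] = DEFAULT_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_plants_per_class, self.n_disks_per_plant, self.n_repeats_per_disk) < 1:
            raise ValueError("all design counts must be >= 1")
        for label, plant, disk, reps in self.short_measured_disks:
            if label not in ("control", "heat"):
                raise ValueError(f"unknown class {label!r} in override")
            if not (1 <= plant <= self.n_plants_per_class):
                raise ValueError(f"override references missing plant {plant}")
            if not (1 <= disk <= self.n_disks_per_plant):
                raise ValueError(f"override references missing disk {disk}")
            if reps < 1:
                raise ValueError("override repeat count must be >= 1")

    def n_repeats(self, label: str, plant: int, disk: int) -> int:
        for olabel, oplant, odisk, reps in self.short_measured_disks:
            if (olabel, oplant, odisk) == (label, plant, disk):
                return reps
        return self.n_repeats_per_disk

    def total_spectra(self) -> int:
        total = 0
        for label in ("control", "heat"):
            for p in range(1, self.n_plants_per_class + 1):
                for d in range(1, self.n_disks_per_plant + 1):
                    total += self.n_repeats(label, p, d)
        return total


def study_design(
    seed: int = 0,
    effects: tuple[ClassEffect, ...] | None = None,
    noise: NoiseModel | None = None,
) -> SimDesign:
    """The study layout: 2 x 6 plants x 10 disks x 3 scans, one heat disk
    scanned once -> 180 control + 178 heat spectra."""
    return SimDesign(
        short_measured_disks=(("heat", 1, 1, 1),),
        effects=default_effects() if effects is None else effects,
        noise=NoiseModel() if noise is None else noise,
        seed=seed,
    )


def null_design(seed: int = 0) -> SimDesign:
    """A no-signal design with exchangeable spectra.

    No class effects, and only repeat-level noise: with per-plant or
    per-disk random effects a spectrum-level train/test split would leak
    replicate identity into the test set (each plant belongs to one class),
    so the clean chance-level reference keeps spectra iid.
    """
    return replace(
        study_design(seed=seed),
        effects=(),
        noise=NoiseModel(plant_sd=0.0, disk_sd=0.0, repeat_sd=0.03),
    )


def _effect_band_multipliers(design: SimDesign) -> np.ndarray:
    """Per-band heat-class multiplier (1.0 where no effect applies)."""
    grid = canonical_grid()
    centers = np.array([b.center for b in design.bands])
    mult = np.ones(len(design.bands))
    for eff in design.effects:
        if not (grid.start <= eff.wavenumber <= grid.end):
            raise ValueError(f"effect wavenumber {eff.wavenumber} outside the grid")
        mult[int(np.argmin(np.abs(centers - eff.wavenumber)))] *= eff.multiplier
    return mult


def simulate_set(design: SimDesign) -> SpectrumSet:
    """Draw one raw spectrum per (class, plant, disk, repeat) cell."""
    grid = canonical_grid()
    nu = grid.points.astype(float)
    n_bands = len(design.bands)
    profiles = np.vstack(
        [
            b.base_amplitude * np.exp(-0.5 * ((nu - b.center) / b.width) ** 2)
            for b in design.bands
        ]
    )
    heat_mult = _effect_band_multipliers(design)
    noise = design.noise
    knurl_mask = (nu >= noise.knurl_band[0]) & (nu <= noise.knurl_band[1])
    n_knurl = int(knurl_mask.sum())

    traces, rows = [], []
    for class_i, label in enumerate(("control", "heat")):
        class_mult = heat_mult if label == "heat" else np.ones(n_bands)
        for p in range(1, design.n_plants_per_class + 1):
            z_plant = np.random.default_rng([design.seed, class_i, 101, p]).standard_normal(n_bands)
            plant_id = f"{label[0]}{p}"
            for d in range(1, design.n_disks_per_plant + 1):
                z_disk = np.random.default_rng(
                    [design.seed, class_i, 202, p, d]
                ).standard_normal(n_bands)
                disk_id = f"{plant_id}-d{d:02d}"
                for r in range(1, design.n_repeats(label, p, d) + 1):
                    rng = np.random.default_rng([design.seed, class_i, 303, p, d, r])
                    z_rep = rng.standard_normal(n_bands)
                    log_factor = (
                        noise.plant_sd * z_plant
                        + noise.disk_sd * z_disk
                        + noise.repeat_sd * z_rep
                    )
                    amps = class_mult * np.exp(log_factor)
                    trace = amps @ profiles
                    slope = rng.normal(0.0, noise.baseline_slope_sd)
                    trace = trace + slope * (nu - nu[0])
                    if noise.floor_sd > 0:
                        trace = trace + rng.normal(0.0, noise.floor_sd, nu.size)
                    if noise.knurl_sd > 0 and n_knurl:
                        trace[knurl_mask] += rng.normal(0.0, noise.knurl_sd, n_knurl)
                    traces.append(trace)
                    rows.append(
                        {
                            "spectrum_id": f"{disk_id}-r{r}",
                            "class_label": label,
                            "plant_id": plant_id,
                            "disk_id": disk_id,
                            "repeat_index": r,
                        }
                    )
    return SpectrumSet(np.vstack(traces), pd.DataFrame(rows), grid)


def describe_truth(design: SimDesign) -> dict[float, str]:
    """Ground-truth class direction per effect wavenumber (heat vs control).

    Effects with multiplier exactly 1 are omitted — they are undetectable
    by construction.
    """
    truth: dict[float, str] = {}
    for eff in design.effects:
        if eff.multiplier == 1.0:
            continue
        truth[eff.wavenumber] = "up" if eff.multiplier > 1.0 else "down"
    return dict(sorted(truth.items()))
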