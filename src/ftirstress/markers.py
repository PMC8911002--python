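"""Anchor-normalized Fm spectral biomarkers.

An Fm marker reads the absorbance at a discriminative target wavenumber
relative to two nearby anchor wavenumbers::

    Fm = (A_target - A_anchor1) / (A_anchor2 - A_anchor1)

which maps anchor1 to 0 and anchor2 to 1 and makes the value invariant
under any affine transform a*A + b of the whole spectrum — the marker's
normalization property. Targets come from the extrema of the LD1 loading
curve (|loading| above a threshold, default 0.15); anchor pairs are scanned
among visually discernible landmarks (peaks, minima, inflections of the
pooled mean spectrum) within 150 cm^-1 on opposite sides of the target,
keeping the pair whose between-class Student's t-test on Fm values is most
significant, subject to p below 1e-4.

Anchor orientation: anchor1 is the anchor with the lower pooled-mean
absorbance (the "0" end of the local slope) and anchor2 the higher, so an
increase of target absorbance raises Fm. No multiple-testing correction is
applied in the scan; the fixed 1e-4 threshold is taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import ttest_ind

from .chemometrics import LdaModel
from .spectra import Spectrum, SpectrumSet

DEFAULT_LOADING_THRESHOLD = 0.15
DEFAULT_MAX_DISTANCE = 150.0
DEFAULT_P_THRESHOLD = 1e-4
DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class DiscriminativePoint:
    """A local extremum of the LD1 loading curve above threshold."""

    wavenumber: float
    loading: float


@dataclass
class FmMarker:
    """A (target, anchor1, anchor2) wavenumber triple."""

    name: str
    target: float
    anchor1: float
    anchor2: float
    loading: float = float("nan")
    selection_p: float = float("nan")
    max_distance: float = DEFAULT_MAX_DISTANCE

    def __post_init__(self) -> None:
        if self.anchor1 == self.anchor2:
            raise ValueError("anchors must differ")
        if self.target in (self.anchor1, self.anchor2):
            raise ValueError("target must differ from both anchors")
        for a in (self.anchor1, self.anchor2):
            if abs(a - self.target) > self.max_distance:
                raise ValueError(
                    f"anchor {a} is more than {self.max_distance} cm^-1 from target {self.target}"
                )


@dataclass
class MarkerEvaluation:
    """Per-class medians, heat/control ratio and t-test for one marker."""

    marker: FmMarker
    median_fm_control: float
    median_fm_heat: float
    ratio_heat_control: float
    t_statistic: float
    p_value: float
    direction: str  # "up" iff median heat > median control


@dataclass
class MarkerConfig:
    """Knobs of the discovery pipeline, with the published defaults."""

    loading_threshold: float = DEFAULT_LOADING_THRESHOLD
    min_separation: float = 10.0
    max_distance: float = DEFAULT_MAX_DISTANCE
    p_threshold: float = DEFAULT_P_THRESHOLD
    landmark_window: int = 11
    anchor_mode: str = "landmarks"  # or "grid": scan every grid point
    equal_var: bool = True  # classic pooled-variance Student's t


@dataclass
class DiscoveryResult:
    evaluations: list[MarkerEvaluation] = field(default_factory=list)
    skipped: list[tuple[float, str]] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """The marker table (one row per marker, Table-2-style schema)."""
        rows = [
            {
                "name": ev.marker.name,
                "target": ev.marker.target,
                "anchor1": ev.marker.anchor1,
                "anchor2": ev.marker.anchor2,
                "loading": ev.marker.loading,
                "median_C": ev.median_fm_control,
                "median_H": ev.median_fm_heat,
                "ratio": ev.ratio_heat_control,
                "t": ev.t_statistic,
                "p": ev.p_value,
                "direction": ev.direction,
            }
            for ev in self.evaluations
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "name", "target", "anchor1", "anchor2", "loading",
                "median_C", "median_H", "ratio", "t", "p", "direction",
            ],
        )


# ---------------------------------------------------------------------
# Fm computation
# ---------------------------------------------------------------------

def compute_fm(s: Spectrum, marker: FmMarker) -> float:
    """Fm value of one spectrum; raises on degenerate (equal) anchors."""
    a_t = s.at(marker.target)
    a_1 = s.at(marker.anchor1)
    a_2 = s.at(marker.anchor2)
    if abs(a_2 - a_1) < DEGENERATE_TOL:
        raise ZeroDivisionError(
            f"degenerate anchors for {marker.name} in spectrum {s.meta.spectrum_id!r}"
        )
    return (a_t - a_1) / (a_2 - a_1)


def fm_values(sset: SpectrumSet, marker: FmMarker) -> np.ndarray:
    """Vectorized Fm over a set; raises naming the first degenerate spectrum."""
    a_t = sset.absorbance_at(marker.target)
    a_1 = sset.absorbance_at(marker.anchor1)
    a_2 = sset.absorbance_at(marker.anchor2)
    denom = a_2 - a_1
    bad = np.abs(denom) < DEGENERATE_TOL
    if bad.any():
        sid = sset.meta["spectrum_id"].iloc[int(np.argmax(bad))]
        raise ZeroDivisionError(f"degenerate anchors for {marker.name} in spectrum {sid!r}")
    return (a_t - a_1) / denom


# ---------------------------------------------------------------------
# target selection and landmarks
# ---------------------------------------------------------------------

def select_discriminative_wavenumbers(
    wavenumbers: np.ndarray,
    loadings: np.ndarray,
    threshold: float = DEFAULT_LOADING_THRESHOLD,
    min_separation: float = 10.0,
) -> list[DiscriminativePoint]:
    """Local extrema of the loading curve with |loading| above threshold.

    Extrema closer than ``min_separation`` keep only the larger |loading|.
    Returned sorted by descending |loading|.
    """
    loadings = np.asarray(loadings, dtype=float)
    peaks, _ = find_peaks(loadings)
    troughs, _ = find_peaks(-loadings)
    candidates = [
        (wavenumbers[i], loadings[i])
        for i in np.concatenate([peaks, troughs])
        if abs(loadings[i]) > threshold
    ]
    candidates.sort(key=lambda c: -abs(c[1]))
    kept: list[DiscriminativePoint] = []
    for nu, val in candidates:
        if all(abs(nu - k.wavenumber) >= min_separation for k in kept):
            kept.append(DiscriminativePoint(float(nu), float(val)))
    return kept


def find_landmarks(mean_spectrum: Spectrum, window: int = 11) -> np.ndarray:
    """Visually discernible landmarks of a pooled mean spectrum.

    Landmarks are local maxima, local minima, and inflection points (sign
    changes of a Savitzky-Golay-smoothed second derivative). ``window`` is
    the smoothing window in grid points (forced odd, >= 5).
    """
    y = mean_spectrum.absorbance
    nu = mean_spectrum.wavenumbers
    window = max(5, int(window) | 1)
    smooth = savgol_filter(y, window, polyorder=3)
    maxima, _ = find_peaks(smooth)
    minima, _ = find_peaks(-smooth)
    d2 = savgol_filter(y, window, polyorder=3, deriv=2)
    sign = np.sign(d2)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    # take whichever side of the flip is closer to the zero crossing
    inflections = np.where(np.abs(d2[flips]) <= np.abs(d2[flips + 1]), flips, flips + 1)
    idx = np.unique(np.concatenate([maxima, minima, inflections]))
    return nu[idx].astype(float)


# ---------------------------------------------------------------------
# anchor scan and evaluation
# ---------------------------------------------------------------------

def _class_split(sset: SpectrumSet) -> tuple[np.ndarray, np.ndarray]:
    heat = sset.class_mask("heat")
    ctrl = sset.class_mask("control")
    if not heat.any() or not ctrl.any():
        raise ValueError("both classes must be present")
    return ctrl, heat


def scan_anchors(
    sset: SpectrumSet,
    target: float,
    landmarks: np.ndarray,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    equal_var: bool = True,
) -> FmMarker:
    """Choose the anchor pair whose Fm best separates the classes.

    Candidate anchors are landmarks within ``max_distance`` of the target,
    one on each side. A pair is admissible when no spectrum has (near-)
    equal anchor absorbances and the two-sided t-test p-value is below
    ``p_threshold``. Ties on p break by total anchor distance, then by the
    lower wavenumber pair. Raises when no admissible pair exists (a
    non-markable wavenumber).
    """
    ctrl, heat = _class_split(sset)
    grid = sset.grid
    grid.index_of(target)  # validates target on grid
    landmarks = np.asarray(landmarks, dtype=float)
    left = landmarks[(landmarks < target) & (landmarks >= target - max_distance)]
    right = landmarks[(landmarks > target) & (landmarks <= target + max_distance)]
    mean_trace = sset.absorbance.mean(axis=0)
    a_t = sset.absorbance_at(target)

    best_key, best = None, None
    for lo in left:
        a_lo = sset.absorbance_at(lo)
        for hi in right:
            a_hi = sset.absorbance_at(hi)
            # orient: anchor1 = lower pooled-mean absorbance
            if mean_trace[grid.index_of(lo)] <= mean_trace[grid.index_of(hi)]:
                a1_nu, a2_nu, a_1, a_2 = lo, hi, a_lo, a_hi
            else:
                a1_nu, a2_nu, a_1, a_2 = hi, lo, a_hi, a_lo
            denom = a_2 - a_1
            if np.abs(denom).min() < DEGENERATE_TOL:
                continue
            fm = (a_t - a_1) / denom
            t, p = ttest_ind(fm[heat], fm[ctrl], equal_var=equal_var)
            if not np.isfinite(p) or p >= p_threshold:
                continue
            key = (
                float(p),
                abs(lo - target) + abs(hi - target),
                min(a1_nu, a2_nu),
                max(a1_nu, a2_nu),
            )
            if best_key is None or key < best_key:
                best_key = key
                best = (a1_nu, a2_nu, float(p))
    if best is None:
        raise ValueError(f"no valid anchors for target {target:g} cm^-1")
    a1_nu, a2_nu, p = best
    return FmMarker(
        name=f"Fm{int(round(target))}",
        target=float(target),
        anchor1=float(a1_nu),
        anchor2=float(a2_nu),
        selection_p=p,
        max_distance=max_distance,
    )


def evaluate_marker(
    sset: SpectrumSet, marker: FmMarker, equal_var: bool = True
) -> MarkerEvaluation:
    """Per-class Fm medians, heat/control ratio and Student's t-test."""
    ctrl, heat = _class_split(sset)
    fm = fm_values(sset, marker)
    median_c = float(np.median(fm[ctrl]))
    median_h = float(np.median(fm[heat]))
    ratio = median_h / median_c if median_c != 0 else float("nan")
    t, p = ttest_ind(fm[heat], fm[ctrl], equal_var=equal_var)
    return MarkerEvaluation(
        marker=marker,
        median_fm_control=median_c,
        median_fm_heat=median_h,
        ratio_heat_control=float(ratio),
        t_statistic=float(t),
        p_value=float(p),
        direction="up" if median_h > median_c else "down",
    )


def discover_markers(
    sset: SpectrumSet,
    lda: LdaModel,
    config: MarkerConfig | None = None,
) -> DiscoveryResult:
    """Full marker-discovery pipeline from a fitted discriminant.

    Targets are the loading-curve extrema; each is anchor-scanned and
    evaluated. Targets without admissible anchors are recorded as skipped,
    not fatal. Output keeps the descending-|loading| target order.
    """
    config = config or MarkerConfig()
    points = select_discriminative_wavenumbers(
        lda.wavenumbers,
        lda.ld1_loadings,
        threshold=config.loading_threshold,
        min_separation=config.min_separation,
    )
    if config.anchor_mode == "grid":
        landmarks = sset.wavenumbers.astype(float)
    else:
        landmarks = find_landmarks(sset.mean_spectrum(), window=config.landmark_window)
    result = DiscoveryResult()
    for point in points:
        try:
            marker = scan_anchors(
                sset,
                point.wavenumber,
                landmarks,
                max_distance=config.max_distance,
                p_threshold=config.p_threshold,
                equal_var=config.equal_var,
            )
        except (ValueError, ZeroDivisionError) as exc:
            result.skipped.append((point.wavenumber, str(exc)))
            continue
        marker.loading = point.loading
        result.evaluations.append(evaluate_marker(sset, marker, equal_var=config.equal_var))
    return result


def diagnose(sset: SpectrumSet, evaluations: list[MarkerEvaluation]) -> pd.DataFrame:
    """Per-spectrum heat/control verdict by majority vote over markers.

    For each marker a spectrum votes heat when its Fm lies on the heat
    side of the midpoint between the class medians; an Fm exactly at the
    midpoint casts no vote. Vote ties abstain.
    """
    if not evaluations:
        raise ValueError("diagnosis requires at least one marker")
    out = pd.DataFrame(
        {
            "spectrum_id": sset.meta["spectrum_id"].to_numpy(),
            "class_label": sset.meta["class_label"].to_numpy(),
        }
    )
    heat_votes = np.zeros(len(sset), dtype=int)
    ctrl_votes = np.zeros(len(sset), dtype=int)
    for ev in evaluations:
        fm = fm_values(sset, ev.marker)
        midpoint = (ev.median_fm_control + ev.median_fm_heat) / 2.0
        heat_side = fm > midpoint if ev.direction == "up" else fm < midpoint
        ctrl_side = fm < midpoint if ev.direction == "up" else fm > midpoint
        heat_votes += heat_side.astype(int)
        ctrl_votes += ctrl_side.astype(int)
        out[f"fm_{ev.marker.name}"] = fm
    out["votes_heat"] = heat_votes
    out["votes_control"] = ctrl_votes
    out["verdict"] = np.select(
        [heat_votes > ctrl_votes, ctrl_votes > heat_votes],
        ["heat", "control"],
        default="abstain",
    )
    return out
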