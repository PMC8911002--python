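"""Fm biomarkers: formula, selection, landmarks, anchor scan, diagnosis."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ftirstress as ft
from ftirstress.grid import N_POINTS
from ftirstress.simulate import BROAD_ENVELOPE, TABLE_BANDS

from conftest import flat_set

NU = ft.canonical_grid().points.astype(float)
GRID = ft.canonical_grid()


def spectrum_with(values: dict[int, float], base: float = 0.0) -> ft.Spectrum:
    vals = np.full(N_POINTS, base)
    for nu, v in values.items():
        vals[GRID.index_of(nu)] = v
    return ft.Spectrum(vals)


class TestComputeFm:
    marker = ft.FmMarker("Fm1465", 1465, 1480, 1399)

    @pytest.mark.parametrize(
        "a1, a2, at, expected",
        [
            (0.4, 0.9, 0.4, 0.0),  # target at anchor1 -> offset 0
            (0.4, 0.9, 0.9, 1.0),  # target at anchor2 -> offset 1
            (0.5, 0.9, 0.7, 0.5),  # midpoint
        ],
    )
    def test_offset_definition(self, a1, a2, at, expected):
        s = spectrum_with({1480: a1, 1399: a2, 1465: at})
        assert ft.compute_fm(s, self.marker) == pytest.approx(expected)

    def test_degenerate_anchors_raise(self):
        s = spectrum_with({1480: 0.5, 1399: 0.5, 1465: 0.7})
        with pytest.raises(ZeroDivisionError, match="degenerate"):
            ft.compute_fm(s, self.marker)

    @given(
        a=st.floats(min_value=0.05, max_value=20.0),
        b=st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_affine_invariance(self, a, b):
        s = spectrum_with({1480: 0.3, 1399: 0.8, 1465: 0.55}, base=0.1)
        transformed = ft.Spectrum(a * s.absorbance + b)
        assert ft.compute_fm(transformed, self.marker) == pytest.approx(
            ft.compute_fm(s, self.marker), rel=1e-9
        )

    def test_marker_invariants_enforced(self):
        with pytest.raises(ValueError):
            ft.FmMarker("bad", 1465, 1480, 1480)  # equal anchors
        with pytest.raises(ValueError):
            ft.FmMarker("bad", 1465, 1700, 1399)  # anchor too far


class TestSelection:
    def test_six_printed_intensities_give_six_points(self):
        # loading curve embedding the six published extremum intensities
        peaks = {1465: 0.398, 1729: 0.176, 1251: -0.318, 576: -0.250,
                 1502: -0.224, 482: -0.183}
        nu = np.arange(400.0, 3601.0)
        curve = np.zeros_like(nu)
        for center, height in peaks.items():
            curve += height * np.exp(-0.5 * ((nu - center) / 8.0) ** 2)
        points = ft.select_discriminative_wavenumbers(nu, curve, threshold=0.15)
        assert len(points) == 6
        got = {round(p.wavenumber): round(p.loading, 3) for p in points}
        assert got == {k: round(v, 3) for k, v in peaks.items()}
        # sorted by descending |loading|
        mags = [abs(p.loading) for p in points]
        assert mags == sorted(mags, reverse=True)

    def test_all_zero_loadings_give_empty_list(self):
        assert ft.select_discriminative_wavenumbers(NU, np.zeros(N_POINTS)) == []

    def test_single_triangular_peak(self):
        nu = np.arange(400.0, 3601.0)
        curve = np.maximum(0.0, 0.2 - 0.01 * np.abs(nu - 2000))
        points = ft.select_discriminative_wavenumbers(nu, curve, threshold=0.15)
        assert [p.wavenumber for p in points] == [2000.0]

    def test_min_separation_keeps_larger_magnitude(self):
        nu = np.arange(400.0, 3601.0)
        curve = 0.3 * np.exp(-0.5 * ((nu - 1000) / 3) ** 2) + 0.25 * np.exp(
            -0.5 * ((nu - 1006) / 2) ** 2
        )
        points = ft.select_discriminative_wavenumbers(
            nu, curve, threshold=0.15, min_separation=10
        )
        assert len(points) == 1
        assert abs(points[0].wavenumber - 1000) <= 2


class TestLandmarks:
    def test_gaussian_band_yields_peak_and_inflections(self):
        vals = np.exp(-0.5 * ((NU - 2000) / 20.0) ** 2)
        lm = ft.find_landmarks(ft.Spectrum(vals))
        assert np.min(np.abs(lm - 2000)) <= 2  # maximum
        assert np.min(np.abs(lm - 1980)) <= 2  # inflection at -sigma
        assert np.min(np.abs(lm - 2020)) <= 2  # inflection at +sigma

    def test_strictly_monotone_segment_has_no_landmarks(self):
        vals = 0.001 * NU
        lm = ft.find_landmarks(ft.Spectrum(vals))
        inside = lm[(lm > 500) & (lm < 3900)]
        assert inside.size == 0

    def test_band_mixture_landmarks_contain_each_band_center(self):
        design = dataclasses.replace(
            ft.study_design(seed=0),
            noise=ft.NoiseModel(0, 0, 0, 0, 0, (405, 480), 0),
            bands=TABLE_BANDS + (BROAD_ENVELOPE,), effects=(),
            n_plants_per_class=1, n_disks_per_plant=1, short_measured_disks=(),
        )
        mean = ft.simulate_set(design).mean_spectrum()
        lm = ft.find_landmarks(mean)
        for band in TABLE_BANDS:
            assert np.min(np.abs(lm - band.center)) <= 3, band.center


class TestScanAndEvaluate:
    def test_scan_recovers_up_effect_at_1465(self, recovery_pre):
        landmarks = ft.find_landmarks(recovery_pre.mean_spectrum())
        marker = ft.scan_anchors(recovery_pre, 1465.0, landmarks)
        ev = ft.evaluate_marker(recovery_pre, marker)
        assert marker.selection_p < 1e-4
        assert ev.median_fm_heat > ev.median_fm_control
        assert (marker.anchor1 - 1465) * (marker.anchor2 - 1465) < 0  # opposite sides

    def test_edge_target_with_one_sided_landmarks_fails(self, recovery_pre):
        with pytest.raises(ValueError, match="no valid anchors"):
            ft.scan_anchors(recovery_pre, 405.0, np.array([430.0, 460.0, 501.0]))

    @pytest.mark.parametrize(
        "median_c, median_h, expected",
        [
            (0.345, 0.381, 1.104),  # up marker
            (1.436, 0.899, 0.626),  # down marker
        ],
    )
    def test_ratio_from_constructed_medians(self, median_c, median_h, expected):
        vals = np.zeros((6, N_POINTS))
        i_t, i_1, i_2 = GRID.index_of(1465), GRID.index_of(1480), GRID.index_of(1399)
        targets = [median_c - 0.01, median_c, median_c + 0.01,
                   median_h - 0.01, median_h, median_h + 0.01]
        vals[:, i_1] = 0.0
        vals[:, i_2] = 1.0
        vals[:, i_t] = targets
        sset = flat_set(vals, labels=["control"] * 3 + ["heat"] * 3)
        ev = ft.evaluate_marker(sset, ft.FmMarker("Fm1465", 1465, 1480, 1399))
        assert round(ev.ratio_heat_control, 3) == expected

    def test_identical_class_distributions_give_ratio_one(self):
        vals = np.zeros((8, N_POINTS))
        i_t, i_1, i_2 = GRID.index_of(1000), GRID.index_of(950), GRID.index_of(1050)
        fm_targets = [0.2, 0.4, 0.6, 0.8] * 2
        vals[:, i_1], vals[:, i_2] = 0.0, 1.0
        vals[:, i_t] = fm_targets
        sset = flat_set(vals, labels=["control"] * 4 + ["heat"] * 4)
        ev = ft.evaluate_marker(sset, ft.FmMarker("Fm1000", 1000, 950, 1050))
        assert ev.ratio_heat_control == pytest.approx(1.0)
        assert ev.p_value == pytest.approx(1.0)

    def test_degenerate_anchor_in_one_spectrum_names_it(self):
        vals = np.zeros((2, N_POINTS))
        i_t, i_1, i_2 = GRID.index_of(1000), GRID.index_of(950), GRID.index_of(1050)
        vals[0, i_2] = 1.0  # s1 left degenerate
        vals[:, i_t] = 0.5
        sset = flat_set(vals, labels=["control", "heat"])
        with pytest.raises(ZeroDivisionError, match="s1"):
            ft.fm_values(sset, ft.FmMarker("Fm1000", 1000, 950, 1050))


class TestDiscoveryAndDiagnosis:
    def test_recovery_of_implanted_effects(self, recovery_pre, recovery_lda, recovery_discovery):
        truth = ft.describe_truth(ft.study_design())
        recovered = sum(
            any(
                abs(ev.marker.target - w) <= 10 and ev.direction == direction
                for ev in recovery_discovery.evaluations
            )
            for w, direction in truth.items()
        )
        assert recovered >= 2  # at least 2 of the 3 implanted effects

    def test_marker_direction_agrees_with_loading_sign(self, recovery_discovery):
        evs = recovery_discovery.evaluations
        assert evs, "expected at least one discovered marker"
        agree = sum(
            (ev.direction == "up") == (ev.marker.loading > 0) for ev in evs
        )
        assert agree / len(evs) >= 0.9

    def test_no_signal_simulation_discovers_nothing(self):
        pre = ft.preprocess_set(ft.simulate_set(ft.null_design(seed=42)))
        split = ft.split_set(pre, 0.6, seed=43)
        lda = ft.lda_fit(pre, split)
        result = ft.discover_markers(pre, lda)
        assert result.evaluations == []

    def test_class_mean_spectra_diagnosed_correctly(self, recovery_pre, recovery_discovery):
        means = ft.SpectrumSet(
            np.vstack(
                [
                    recovery_pre.mean_spectrum("heat").absorbance,
                    recovery_pre.mean_spectrum("control").absorbance,
                ]
            ),
            meta=pd.DataFrame(
                {"spectrum_id": ["mh", "mc"], "class_label": ["heat", "control"]}
            ),
        )
        verdicts = ft.diagnose(means, recovery_discovery.evaluations)
        assert verdicts.loc[verdicts["spectrum_id"] == "mh", "verdict"].item() == "heat"
        assert verdicts.loc[verdicts["spectrum_id"] == "mc", "verdict"].item() == "control"

    def test_fm_exactly_at_midpoint_abstains(self):
        ev = ft.MarkerEvaluation(
            marker=ft.FmMarker("Fm1000", 1000, 950, 1050),
            median_fm_control=0.2,
            median_fm_heat=0.6,
            ratio_heat_control=3.0,
            t_statistic=5.0,
            p_value=1e-9,
            direction="up",
        )
        vals = np.zeros((1, N_POINTS))
        i_t, i_1, i_2 = GRID.index_of(1000), GRID.index_of(950), GRID.index_of(1050)
        vals[0, i_2] = 1.0
        vals[0, i_t] = 0.4  # exactly the midpoint of the medians
        sset = flat_set(vals, labels=["heat"])
        out = ft.diagnose(sset, [ev])
        assert out["verdict"][0] == "abstain"

    def test_diagnosis_accuracy_on_recovery_set(self, recovery_pre, recovery_discovery):
        out = ft.diagnose(recovery_pre, recovery_discovery.evaluations)
        decided = out[out["verdict"] != "abstain"]
        acc = (decided["verdict"] == decided["class_label"]).mean()
        assert acc >= 0.9
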