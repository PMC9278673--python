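import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from pfqa.analyze import (
    AnalysisConfig,
    FieldNotFoundError,
    MeasurementError,
    absolute_center_config,
    analyze_image,
    check_tolerances,
    compute_thresholds,
    locate_template,
    measure_slit,
    relative_global_config,
    relative_local_config,
)
from pfqa.errors import ErrorSpec, apply_error
from pfqa.simulate import BeamModel, EPIDImage, ImagerSpec, render_image


class TestMeasureSlitOracles:
    def test_trapezoid_matches_closed_form(self):
        """Linear-ramp trapezoid: crossings are exact linear interpolations."""
        x = np.arange(-8.0, 8.0, 0.05)
        a, b, c, d = -2.0, -1.0, 1.5, 3.0  # ramp up a..b, plateau, ramp down c..d
        prof = np.clip(np.minimum((x - a) / (b - a), (d - x) / (d - c)), 0, 1)
        t = 0.37
        m = measure_slit(x, prof, t, 0.0, 6.0, 0.0, slit=1, pair_label=1)
        left = a + t * (b - a)
        right = d - t * (d - c)
        assert m.position == pytest.approx(0.5 * (left + right), abs=1e-3)
        assert m.width == pytest.approx(right - left, abs=1e-3)

    def test_gaussian_boxcar_matches_closed_form(self):
        """Gaussian-convolved boxcar: crossings from the erf closed form."""
        sigma, half = 0.8, 0.5
        center = 12.0

        def f(u):
            return norm.cdf((u - center + half) / sigma) - norm.cdf((u - center - half) / sigma)

        x = np.arange(center - 8, center + 8, 0.05)
        prof = f(x)
        peak = f(center)
        t = 0.5 * peak
        m = measure_slit(x, prof, t, center, 6.0, 0.0, slit=1, pair_label=1)
        left = brentq(lambda u: f(u) - t, center - 5, center)
        right = brentq(lambda u: f(u) - t, center, center + 5)
        assert m.position == pytest.approx(center, abs=1e-3)
        assert m.width == pytest.approx(right - left, abs=1e-3)

    def test_three_pixel_rectangle_width(self):
        x = np.arange(10) * 0.336
        prof = np.zeros(10)
        prof[3:6] = 1.0
        m = measure_slit(x, prof, 0.5, x[4], 1.5, 0.0, slit=1, pair_label=1)
        assert m.width == pytest.approx(3 * 0.336, abs=1e-9)

    def test_bad_threshold_rejected(self):
        x = np.arange(20) * 0.336
        prof = np.exp(-0.5 * ((x - 3.0) / 0.8) ** 2)
        with pytest.raises(MeasurementError, match="threshold"):
            measure_slit(x, prof, 1.5, 3.0, 3.0, 0.0, slit=2, pair_label=7)

    def test_missing_crossing_rejected(self):
        x = np.arange(20) * 0.336
        prof = np.full(20, 1.0)  # never drops below any valid threshold
        with pytest.raises(MeasurementError, match="slit 3, pair 9"):
            measure_slit(x, prof, 0.5, x[10], 3.0, 0.0, slit=3, pair_label=9)


class TestThresholds:
    def test_equal_peaks_make_strategies_coincide(self):
        peaks = {(b, s): 2.0 for b in (1, 2) for s in (1, 2, 3)}
        bgs = {1: 0.5, 2: 0.5}
        cfg_l = AnalysisConfig(threshold_strategy="local", threshold_fraction=0.5)
        cfg_g = AnalysisConfig(threshold_strategy="global", threshold_fraction=0.5)
        tl = compute_thresholds(peaks, bgs, cfg_l)
        tg = compute_thresholds(peaks, bgs, cfg_g)
        assert tl == tg

    def test_local_formula(self):
        t = compute_thresholds({(1, 1): 2.0}, {1: 1.0}, AnalysisConfig(threshold_strategy="local"))
        assert t[(1, 1)] == pytest.approx(1.5)

    def test_one_high_peak_raises_global_everywhere_local_only_there(self):
        peaks = {(1, 1): 1.0, (1, 2): 1.5, (1, 3): 1.0}
        bgs = {1: 0.0}
        tl = compute_thresholds(peaks, bgs, AnalysisConfig(threshold_strategy="local"))
        tg = compute_thresholds(peaks, bgs, AnalysisConfig(threshold_strategy="global"))
        assert tl[(1, 1)] == 0.5 and tl[(1, 2)] == 0.75
        assert all(v == 0.75 for v in tg.values())


class TestTemplate:
    def test_field_edge_maps_physical_pairs(self, reference_image_m120, m120_plan, m120):
        cfg = relative_local_config()
        tpl = locate_template(reference_image_m120, m120_plan, m120, cfg)
        assert tpl.y_edges is not None
        top, bottom = tpl.y_edges
        assert top == pytest.approx(180.0, abs=0.5)
        assert bottom == pytest.approx(-180.0, abs=0.5)
        assert abs(tpl.y_origin) < 0.2
        assert len(tpl.windows) == 10

    def test_field_edge_tracks_lateral_shift(self, m120_plan, m120, beam):
        img = render_image(
            m120_plan, ImagerSpec(translation=(0.0, 5.0, 0.0)), beam, noise=False
        )
        tpl = locate_template(img, m120_plan, m120, relative_local_config())
        assert tpl.x_shift == pytest.approx(-5.0, abs=0.2)

    def test_image_center_requires_no_plan(self, reference_image_m120, m120):
        tpl = locate_template(reference_image_m120, None, m120, absolute_center_config())
        assert len(tpl.windows) == 10
        assert tpl.y_origin == 0.0

    def test_blank_image_rejected(self, m120):
        blank = EPIDImage(
            pixels=np.full((320, 320), 0.01), pitch=1.344, recorded_sdd=1000.0,
            sad=1000.0, mu=100.0, collimator_angle=0.0,
        )
        with pytest.raises(FieldNotFoundError):
            locate_template(blank, None, m120, absolute_center_config())


class TestLeafPairIdentification:
    def test_hidden_pairs_shift_image_center_labels(self, mlc, beam, imager):
        """With two pairs hidden behind each Y jaw, the image-center template
        labels physical pair 30 as 28 (labels count from the first
        signal-bearing band), while the field-edge template keeps 30."""
        from pfqa.mlc import build_reference_plan

        plan = build_reference_plan(mlc)
        fault = apply_error(
            plan, ErrorSpec("local_position", 0.5, target_pairs=(30,), bank="A")
        )
        img = render_image(fault, imager, beam, seed=3)
        res = analyze_image(img, None, mlc, absolute_center_config())
        assert res.first_signal_band == 3
        assert res.absolute.max_error_cell[1] == 28
        res_edge = analyze_image(img, plan, mlc, relative_local_config())
        ref = analyze_image(render_image(plan, imager, beam, seed=103), plan, mlc,
                            relative_local_config())
        dev = {
            c: res_edge.relative.intra_slit_deviation[c]
            - ref.relative.intra_slit_deviation.get(c, 0.0)
            for c in res_edge.relative.intra_slit_deviation
        }
        assert max(dev, key=lambda c: abs(dev[c]))[1] == 30

    def test_jaw_calibration_blurs_pair_30_31_attribution(self, hd120, hd120_plan, imager):
        """A Y-jaw calibration offset of about half an HD120 leaf makes the
        field-edge template attribute a pair-30 fault to pair 30 or 31."""
        beam = BeamModel(jaw_y_calibration_error=1.25)
        fault = apply_error(
            hd120_plan, ErrorSpec("local_position", 0.5, target_pairs=(30,), bank="A")
        )
        cfg = relative_local_config()
        ref = analyze_image(render_image(hd120_plan, imager, beam, seed=50),
                            hd120_plan, hd120, cfg)
        for seed in (0, 1, 2):
            res = analyze_image(render_image(fault, imager, beam, seed=seed),
                                hd120_plan, hd120, cfg)
            dev = {
                c: res.relative.intra_slit_deviation[c]
                - ref.relative.intra_slit_deviation.get(c, 0.0)
                for c in res.relative.intra_slit_deviation
            }
            top = max(dev, key=lambda c: abs(dev[c]))
            assert top[1] in (30, 31)


class TestRelativeMetrics:
    def test_uniform_shift_invisible(self, m120_plan, m120, imager, beam,
                                     reference_result_m120):
        shifted = apply_error(m120_plan, ErrorSpec("global_position", 0.3))
        img = render_image(shifted, imager, beam, noise=False)
        res = analyze_image(img, m120_plan, m120, relative_local_config())
        deltas = [
            res.relative.position_error[c] - reference_result_m120.relative.position_error[c]
            for c in res.relative.position_error
        ]
        assert np.abs(deltas).max() < 0.02

    def test_central_slit_shift_blamed_on_others(self, m120_plan, m120, imager, beam):
        shifted = apply_error(m120_plan, ErrorSpec("global_position", 0.3, target_slits=(5,)))
        img = render_image(shifted, imager, beam, noise=False)
        res = analyze_image(img, m120_plan, m120, relative_local_config())
        for s, v in res.relative.mean_position.items():
            if s == 5:
                assert v == 0.0
            else:
                assert abs(abs(v) - 0.3) < 0.02

    def test_reference_slit_error_identically_zero(self, reference_result_m120):
        assert reference_result_m120.relative.mean_position[5] == 0.0

    def test_width_against_stored_baseline(self, m120_plan, m120, imager, beam,
                                           reference_result_m120):
        img = render_image(m120_plan, imager, beam, noise=False)
        res = analyze_image(img, m120_plan, m120, relative_local_config(),
                            baseline=reference_result_m120)
        assert res.relative.baseline_source == "baseline"
        assert max(abs(v) for v in res.relative.width_error.values()) < 0.01


class TestAbsoluteMetrics:
    def test_noiseless_reference_passes_everywhere(self, reference_absolute_m120):
        ab = reference_absolute_m120.absolute
        assert ab.pass_rate == 100.0
        assert ab.mean_spacing == pytest.approx(15.0, abs=0.01)
        assert ab.max_error < 0.05

    def test_uniform_shift_moves_every_picket_offset(self, m120_plan, m120, imager, beam,
                                                     reference_absolute_m120):
        shifted = apply_error(m120_plan, ErrorSpec("global_position", 0.3))
        img = render_image(shifted, imager, beam, noise=False)
        res = analyze_image(img, None, m120, absolute_center_config())
        for s, v in res.absolute.picket_offsets.items():
            assert v - reference_absolute_m120.absolute.picket_offsets[s] == pytest.approx(
                0.3, abs=0.02
            )

    def test_lateral_shift_moves_offsets_not_relative(self, m120_plan, m120, beam,
                                                      reference_absolute_m120,
                                                      reference_result_m120):
        img = render_image(
            m120_plan, ImagerSpec(translation=(0.0, 5.0, 0.0)), beam, noise=False
        )
        res_abs = analyze_image(img, None, m120, absolute_center_config())
        for s, v in res_abs.absolute.picket_offsets.items():
            assert v - reference_absolute_m120.absolute.picket_offsets[s] == pytest.approx(
                -5.0, abs=0.05
            )
        res_rel = analyze_image(img, m120_plan, m120, relative_local_config())
        deltas = [
            res_rel.relative.position_error[c]
            - reference_result_m120.relative.position_error.get(c, 0.0)
            for c in res_rel.relative.position_error
        ]
        assert np.abs(deltas).max() < 0.05


class TestTolerances:
    def test_clean_image_raises_no_alerts(self, reference_image_m120, m120_plan, m120):
        cfg = replace(relative_local_config(), tolerances={"position_mm": 0.2})
        res = analyze_image(reference_image_m120, m120_plan, m120, cfg)
        assert res.alerts == []

    def test_shifted_slit_alert_names_slit_2(self, m120_plan, m120, imager, beam):
        shifted = apply_error(m120_plan, ErrorSpec("global_position", 0.5, target_slits=(2,)))
        img = render_image(shifted, imager, beam, noise=False)
        cfg = replace(relative_local_config(), tolerances={"position_mm": 0.2})
        res = analyze_image(img, m120_plan, m120, cfg)
        assert any(a[0] == "position" and a[1] == 2 for a in res.alerts)

    def test_empty_tolerance_table_is_silent(self, reference_result_m120):
        assert check_tolerances(reference_result_m120, {}) == []


class TestProfiles:
    def test_reference_profile_has_ten_maxima(self, reference_image_m120, m120_plan, m120):
        from pfqa.analyze import extract_profile
        from scipy.signal import find_peaks

        cfg = relative_local_config()
        tpl = locate_template(reference_image_m120, m120_plan, m120, cfg)
        band = next(b for b in tpl.bands if b.tiling_index == 30)
        x, prof = extract_profile(reference_image_m120, band, cfg)
        peaks, _ = find_peaks(prof, prominence=0.3 * prof.max(), distance=20)
        assert len(peaks) == 10

    def test_unit_window_is_identity(self, reference_image_m120, m120_plan, m120):
        from pfqa.analyze import extract_profile

        cfg1 = replace(relative_local_config(), smoothing_window=1)
        tpl = locate_template(reference_image_m120, m120_plan, m120, cfg1)
        band = next(b for b in tpl.bands if b.tiling_index == 30)
        x, prof = extract_profile(reference_image_m120, band, cfg1)
        y = reference_image_m120.y_mm()
        half = 0.5 * (band.y_high - band.y_low) * cfg1.roi_fraction
        rows = np.abs(y - band.y_center) <= half
        assert np.allclose(prof, reference_image_m120.pixels[rows].mean(axis=0))
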