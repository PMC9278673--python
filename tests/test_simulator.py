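import math
from dataclasses import replace

import numpy as np
import pydicom
import pytest

from pfqa.dicom_io import DicomReadError, read_rtimage, write_rtimage
from pfqa.errors import ErrorSpec, apply_error
from pfqa.simulate import (
    BeamModel,
    ImagerSpec,
    SimulationError,
    blurred_fluence,
    ideal_fluence,
    render_image,
)


def _parabolic_peak(x, prof, center, halfwidth):
    """Sub-pixel peak position by parabola through the three top samples."""
    sel = np.nonzero(np.abs(x - center) <= halfwidth)[0]
    i = sel[np.argmax(prof[sel])]
    a, b, c = prof[i - 1], prof[i], prof[i + 1]
    denom = a - 2 * b + c
    frac = 0.5 * (a - c) / denom if denom != 0 else 0.0
    return x[i] + frac * (x[1] - x[0])


class TestIdealFluence:
    def test_point_values(self, m120_plan, beam):
        x = np.array([0.5, 40.0, 141.0])  # slit-5 center, under leaves, outside X2
        y = np.array([2.5])  # mid pair 30, clear of the interleaf ridges
        f = ideal_fluence(m120_plan, beam, x, y)[0]
        assert f[0] == 1.0
        assert abs(f[1] - beam.leaf_transmission) < 2 * beam.interleaf_leak_amplitude
        assert f[2] == beam.jaw_transmission

    def test_hidden_pairs_dark(self, m120_plan, beam):
        # pair 1 (y ~ 195) lies behind the Y jaws
        f = ideal_fluence(m120_plan, beam, np.array([0.5]), np.array([195.0]))
        assert f[0, 0] == beam.jaw_transmission

    def test_rotation_shifts_slit_intercept(self, m120_plan, imager):
        """A 2 deg collimator rotation moves a slit's intercept at y=+100 mm
        by about -100*tan(2 deg) relative to the beam axis row."""
        beam = BeamModel(noise_level=0.0)
        plan = replace(m120_plan, collimator_angle=2.0)
        img = render_image(plan, imager, beam, noise=False)
        x, y = img.x_mm(), img.y_mm()
        row0 = np.argmin(np.abs(y - 0.0))
        row100 = np.argmin(np.abs(y - 100.0))
        p0 = _parabolic_peak(x, img.pixels[row0], 0.5, 8.0)
        p100 = _parabolic_peak(x, img.pixels[row100], 0.5 - 100 * math.tan(math.radians(2)), 8.0)
        assert p100 - p0 == pytest.approx(-100 * math.tan(math.radians(2)), abs=0.3)


class TestBlurredFluence:
    def test_blur_conserves_integral(self, m120_plan):
        """Grid sum of the blurred fluence equals the exact analytic integral
        of the ideal fluence (rectangle arithmetic oracle), leak off."""
        beam = BeamModel(interleaf_leak_amplitude=0.0)
        h = 0.336
        x = np.arange(-215.0, 215.0, h) + h / 2
        y = x.copy()
        total = blurred_fluence(m120_plan, beam, x, y).sum() * h * h
        grid_area = (x[-1] - x[0] + h) * (y[-1] - y[0] + h)
        jaw_area = (m120_plan.jaw_x1 + m120_plan.jaw_x2) * 2 * m120_plan.jaw_y
        slit_area = 0.0
        edges = m120_plan.mlc.pair_edges()
        for s in range(10):
            for p in range(60):
                y0, y1 = max(edges[p + 1], -m120_plan.jaw_y), min(edges[p], m120_plan.jaw_y)
                if y1 > y0:
                    slit_area += (m120_plan.tip_a[s, p] - m120_plan.tip_b[s, p]) * (y1 - y0)
        expected = (
            beam.jaw_transmission * grid_area
            + (beam.leaf_transmission - beam.jaw_transmission) * jaw_area
            + (1 - beam.leaf_transmission) * slit_area
        )
        assert total == pytest.approx(expected, rel=1e-6)

    def test_slit_integral_tracks_width(self, m120_plan, imager, beam):
        """Opening one slit 1.0 -> 1.3 mm raises its background-subtracted
        integral by 30% +- 1% (noiseless)."""
        opened = apply_error(m120_plan, ErrorSpec("global_width", 0.3, target_slits=(5,), bank="A"))
        img0 = render_image(m120_plan, imager, beam, noise=False)
        img1 = render_image(opened, imager, beam, noise=False)
        y = img0.y_mm()
        rows = np.abs(y) < 10
        x = img0.x_mm()
        win = np.abs(x - 0.5) <= 5
        bgsel = (np.abs(x - 8.0) <= 1.5)
        ratios = []
        for img in (img0, img1):
            prof = img.pixels[rows].mean(axis=0)
            ratios.append((prof[win] - np.median(prof[bgsel])).sum())
        assert ratios[1] / ratios[0] == pytest.approx(1.30, abs=0.01)


class TestRenderImage:
    def test_mu_scales_signal_exactly(self, m120_plan, imager, beam):
        img100 = render_image(m120_plan, imager, beam, noise=False)
        img105 = render_image(replace(m120_plan, mu=105.0), imager, beam, noise=False)
        assert np.allclose(img105.pixels, 1.05 * img100.pixels, rtol=1e-12)

    def test_vertical_offset_magnifies_spacing(self, m120_plan, beam):
        """+5 mm panel drop magnifies the apparent picket spacing to
        15 * 1005/1000 = 15.075 mm (peak-finding oracle)."""
        img = render_image(m120_plan, ImagerSpec(translation=(5.0, 0.0, 0.0)), beam, noise=False)
        x, y = img.x_mm(), img.y_mm()
        row = np.argmin(np.abs(y))
        centers = np.asarray(m120_plan.slit_centers) * 1.005
        peaks = [_parabolic_peak(x, img.pixels[row], c, 5.0) for c in centers]
        assert np.mean(np.diff(peaks)) == pytest.approx(15.075, abs=0.01)

    def test_reference_is_inplane_symmetric(self, reference_image_m120):
        p = reference_image_m120.pixels
        assert np.allclose(p, np.flipud(p), rtol=1e-9, atol=1e-12)

    def test_noise_is_seeded(self, m120_plan, beam):
        im = ImagerSpec().scaled(4)
        a = render_image(m120_plan, im, beam, seed=11)
        b = render_image(m120_plan, im, beam, seed=11)
        c = render_image(m120_plan, im, beam, seed=12)
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_nonpositive_penumbra_rejected(self, m120_plan, imager):
        with pytest.raises(SimulationError, match="penumbra_sigma"):
            render_image(m120_plan, imager, BeamModel(penumbra_sigma=0.0))


class TestDicomRoundtrip:
    @pytest.fixture()
    def small_image(self, m120_plan, beam):
        return render_image(m120_plan, ImagerSpec().scaled(4), beam, seed=5)

    def test_pixels_and_metadata_survive(self, small_image, tmp_path):
        path = tmp_path / "pf.dcm"
        write_rtimage(small_image, path)
        back = read_rtimage(path)
        assert back.n_rows == small_image.n_rows and back.n_cols == small_image.n_cols
        assert back.pitch == pytest.approx(small_image.pitch)
        assert back.recorded_sdd == small_image.recorded_sdd
        assert back.mu == small_image.mu
        slope = small_image.pixels.max() / 60000
        assert np.abs(back.pixels - small_image.pixels).max() <= 0.51 * slope
        # re-writing the read image is exact at stored precision
        path2 = tmp_path / "pf2.dcm"
        write_rtimage(back, path2)
        again = read_rtimage(path2)
        assert np.allclose(again.pixels, back.pixels, rtol=1e-9)

    def test_full_panel_tags(self, reference_image_m120, tmp_path):
        path = tmp_path / "full.dcm"
        write_rtimage(reference_image_m120, path)
        ds = pydicom.dcmread(path)
        assert ds.Rows == ds.Columns == 1280
        assert float(ds.ImagePlanePixelSpacing[0]) == 0.336
        assert ds.Modality == "RTIMAGE"

    def test_missing_mandatory_tag_named(self, small_image, tmp_path):
        path = tmp_path / "pf.dcm"
        write_rtimage(small_image, path)
        ds = pydicom.dcmread(path)
        del ds.RTImageSID
        ds.save_as(path, enforce_file_format=True)
        with pytest.raises(DicomReadError, match="RTImageSID"):
            read_rtimage(path)
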