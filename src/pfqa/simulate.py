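"""Synthetic integrated-mode EPID rendering of picket-fence plans.

The fluence behind the collimator is a weighted sum of axis-aligned
rectangles (jaw opening, slit apertures) plus narrow Gaussian ridges at the
leaf-pair boundaries (interleaf leakage).  The finite source size /
detector blur is modelled as an isotropic Gaussian of ``penumbra_sigma``
mm at isocenter, applied analytically: each rectangle convolved with a
Gaussian is a separable product of error-function terms, so no discrete
convolution is ever performed and the rendering is exact to floating point
at any pixel pitch.

Pixels are point samples of the blurred fluence at pixel centers (the
pixel aperture is much smaller than the penumbra, so midpoint sampling of
the pixel integral is exact to well below the noise floor).  Collimator
rotation rotates the MLC/jaw pattern about the beam axis; the radial
off-axis ratio stays fixed to the beam.  Imager pose errors move the
panel -- and therefore the sampling grid -- while the DICOM metadata keeps
recording the nominal geometry, exactly as a miscalibrated imager would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .mlc import PFPlan

__all__ = ["ImagerSpec", "BeamModel", "EPIDImage", "SimulationError",
           "ideal_fluence", "blurred_fluence", "render_image"]


class SimulationError(ValueError):
    """Invalid simulation parameter."""


@dataclass(frozen=True)
class ImagerSpec:
    """Panel geometry and (hidden) pose of the portal imager.

    ``translation`` is the actual pose error (vertical = along the beam
    axis away from the source, lateral = crossplane, longitudinal =
    inplane), in mm.  ``nominal_sdd`` is what the metadata records; the
    true source-detector distance is ``nominal_sdd + vertical``.
    """

    n_rows: int = 1280
    n_cols: int = 1280
    pitch: float = 0.336  # mm per pixel at the panel
    sad: float = 1000.0  # mm
    nominal_sdd: float = 1000.0  # mm
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def recorded_sdd(self) -> float:
        return self.nominal_sdd

    def scaled(self, factor: int) -> "ImagerSpec":
        """Coarser panel covering the same sensitive area (for fast studies)."""
        return replace(
            self,
            n_rows=self.n_rows // factor,
            n_cols=self.n_cols // factor,
            pitch=self.pitch * factor,
        )


@dataclass(frozen=True)
class BeamModel:
    """Beam and detection model parameters.

    * ``penumbra_sigma`` -- Gaussian penumbra, mm at isocenter (typical
      6 MV EPID value).
    * ``oar_coeffs`` -- radial off-axis-ratio polynomial
      ``1 + c2*r^2 + c4*r^4`` (r in mm); defaults give a ~3% rise at
      r = 180 mm, emulating the horn structure of a flattened beam.
    * ``leaf_transmission``, ``jaw_transmission`` -- fractional
      transmission under closed leaves / jaws.
    * ``interleaf_leak_amplitude`` -- peak fractional leakage of the
      Gaussian ridges (sigma ``interleaf_sigma``) at pair boundaries.
    * ``jaw_y_calibration_error`` -- common-mode inplane offset of both Y
      jaw edges: the field center moves while the MLC pattern stays put.
    * ``noise_level`` -- relative standard deviation of the multiplicative
      Gaussian noise at open-field signal (integrated images are
      high-count, so noise is small and multiplicative).
    """

    penumbra_sigma: float = 0.8
    oar_coeffs: tuple[float, float] = (6.0e-7, 8.0e-12)
    leaf_transmission: float = 0.015
    interleaf_leak_amplitude: float = 0.003
    interleaf_sigma: float = 0.2
    jaw_transmission: float = 0.005
    jaw_y_calibration_error: float = 0.0
    noise_level: float = 0.002
    seed: int = 0

    def oar(self, r: np.ndarray) -> np.ndarray:
        c2, c4 = self.oar_coeffs
        r2 = np.square(r)
        return 1.0 + c2 * r2 + c4 * r2 * r2


@dataclass
class EPIDImage:
    """Rendered (or read) portal image: pixel matrix plus recorded metadata.

    ``pixels`` are floating-point intensities in arbitrary integrated
    units; row index runs from +y to -y, column index from -x to +x.
    The recorded metadata describe the *nominal* geometry.
    """

    pixels: np.ndarray
    pitch: float
    recorded_sdd: float
    sad: float
    mu: float
    collimator_angle: float
    meta: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def mm_per_pixel(self) -> float:
        """Isocenter-plane mm spanned by one pixel under the recorded geometry."""
        return self.pitch * self.sad / self.recorded_sdd

    def x_mm(self) -> np.ndarray:
        """Crossplane coordinate of each column (mm, recorded geometry)."""
        n = self.n_cols
        return (np.arange(n) - (n - 1) / 2.0) * self.mm_per_pixel

    def y_mm(self) -> np.ndarray:
        """Inplane coordinate of each row (mm, descending)."""
        n = self.n_rows
        return ((n - 1) / 2.0 - np.arange(n)) * self.mm_per_pixel


# ---------------------------------------------------------------------------
# fluence assembly

def _collect_rectangles(plan: PFPlan, beam: BeamModel):
    """Weighted rectangles (x0, x1, y0, y1, w) whose sum is the fluence.

    jaw_T + (leaf_T - jaw_T)*JawBox + sum (1 - leaf_T)*SlitCell gives
    1 inside apertures, leaf_T under leaves, jaw_T outside the jaws.
    """
    e = beam.jaw_y_calibration_error
    jy0, jy1 = -plan.jaw_y + e, plan.jaw_y + e
    jx0, jx1 = -plan.jaw_x1, plan.jaw_x2
    rects = [(jx0, jx1, jy0, jy1, beam.leaf_transmission - beam.jaw_transmission)]
    edges = plan.mlc.pair_edges()
    w_slit = 1.0 - beam.leaf_transmission
    for s in range(plan.n_slits):
        for p in range(plan.mlc.n_pairs):
            x0, x1 = plan.tip_b[s, p], plan.tip_a[s, p]
            y0, y1 = edges[p + 1], edges[p]
            x0, x1 = max(x0, jx0), min(x1, jx1)
            y0, y1 = max(y0, jy0), min(y1, jy1)
            if x1 > x0 and y1 > y0:
                rects.append((x0, x1, y0, y1, w_slit))
    return rects


def _collect_ridges(plan: PFPlan, beam: BeamModel):
    """Interleaf-leakage ridges: (y_boundary, amplitude, x0, x1)."""
    if beam.interleaf_leak_amplitude <= 0:
        return []
    e = beam.jaw_y_calibration_error
    jy0, jy1 = -plan.jaw_y + e, plan.jaw_y + e
    edges = plan.mlc.pair_edges()[1:-1]  # interior boundaries
    return [
        (float(yb), beam.interleaf_leak_amplitude, -plan.jaw_x1, plan.jaw_x2)
        for yb in edges
        if jy0 < yb < jy1
    ]


_SQRT2 = math.sqrt(2.0)


def _edge_profile(coord: np.ndarray, lo: float, hi: float, sigma: float) -> np.ndarray:
    """Indicator of [lo, hi) convolved with a Gaussian, evaluated at coord."""
    if sigma <= 0.0:
        return ((coord >= lo) & (coord < hi)).astype(float)
    s = sigma * _SQRT2
    return 0.5 * (erf((coord - lo) / s) - erf((coord - hi) / s))


def _window(coord: np.ndarray, lo: float, hi: float, pad: float):
    """Slice of a monotone coordinate vector covering [lo-pad, hi+pad]."""
    ascending = coord[0] <= coord[-1]
    c = coord if ascending else coord[::-1]
    i0 = np.searchsorted(c, lo - pad, side="left")
    i1 = np.searchsorted(c, hi + pad, side="right")
    n = len(coord)
    if ascending:
        return slice(int(i0), int(i1))
    return slice(int(n - i1), int(n - i0))


def _field_separable(rects, ridges, const, x, y, sigma, leak_sigma):
    """Blurred fluence on a separable grid (unrotated pattern)."""
    out = np.full((len(y), len(x)), const)
    pad = 6.0 * sigma + 1.0
    for x0, x1, y0, y1, w in rects:
        sx = _window(x, x0, x1, pad)
        sy = _window(y, y0, y1, pad)
        gx = _edge_profile(x[sx], x0, x1, sigma)
        gy = _edge_profile(y[sy], y0, y1, sigma)
        out[sy, sx] += w * np.outer(gy, gx)
    sig_eff = math.hypot(sigma, leak_sigma)
    for yb, amp, x0, x1 in ridges:
        amp_eff = amp * (leak_sigma / sig_eff if sigma > 0 else 1.0)
        sy = _window(y, yb, yb, 6.0 * sig_eff + 1.0)
        gy = amp_eff * np.exp(-0.5 * ((y[sy] - yb) / sig_eff) ** 2)
        gx = _edge_profile(x, x0, x1, sigma)
        out[sy, :] += np.outer(gy, gx)
    return out


def _field_rotated(rects, ridges, const, x, y, sigma, leak_sigma, angle_deg):
    """Blurred fluence with the pattern rotated about the beam axis.

    An isotropic Gaussian commutes with rotation, so the rotated blurred
    pattern is the blurred pattern evaluated at back-rotated coordinates.
    """
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    X = x[None, :]
    Y = y[:, None]
    xr = c * X + s * Y
    yr = -s * X + c * Y
    out = np.full(xr.shape, const)
    # row/col windows: back-rotated coords differ from the unrotated ones by
    # at most |sin th| * half-extent, absorbed into the padding.
    swing = abs(s) * max(np.abs(x).max(), np.abs(y).max()) + 1.0
    pad = 6.0 * sigma + 1.0 + swing
    for x0, x1, y0, y1, w in rects:
        sx = _window(x, x0, x1, pad)
        sy = _window(y, y0, y1, pad)
        sub_x = xr[sy, sx]
        sub_y = yr[sy, sx]
        out[sy, sx] += w * _edge_profile(sub_x, x0, x1, sigma) * _edge_profile(
            sub_y, y0, y1, sigma
        )
    sig_eff = math.hypot(sigma, leak_sigma)
    for yb, amp, x0, x1 in ridges:
        amp_eff = amp * (leak_sigma / sig_eff if sigma > 0 else 1.0)
        sy = _window(y, yb, yb, 6.0 * sig_eff + 1.0 + swing)
        sub_y = yr[sy, :]
        sub_x = xr[sy, :]
        gy = amp_eff * np.exp(-0.5 * ((sub_y - yb) / sig_eff) ** 2)
        out[sy, :] += gy * _edge_profile(sub_x, x0, x1, sigma)
    return out


def _evaluate_fluence(plan, beam, x, y, sigma):
    rects = _collect_rectangles(plan, beam)
    ridges = _collect_ridges(plan, beam)
    if plan.collimator_angle == 0.0:
        return _field_separable(
            rects, ridges, beam.jaw_transmission, x, y, sigma, beam.interleaf_sigma
        )
    return _field_rotated(
        rects,
        ridges,
        beam.jaw_transmission,
        x,
        y,
        sigma,
        beam.interleaf_sigma,
        plan.collimator_angle,
    )


def ideal_fluence(plan: PFPlan, beam: BeamModel, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unblurred transmission map of the collimated beam on an isocenter grid.

    ``x`` and ``y`` must be monotone coordinate vectors (mm).
    1 inside any slit aperture within the jaws, ``leaf_transmission`` under
    leaves, ``jaw_transmission`` outside the jaws, plus interleaf-leak
    ridges; collimator rotation is applied to the whole pattern.
    """
    return _evaluate_fluence(plan, beam, np.asarray(x, float), np.asarray(y, float), 0.0)


def blurred_fluence(plan: PFPlan, beam: BeamModel, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Penumbra-blurred transmission map on an isocenter grid (no OAR, MU, noise)."""
    return _evaluate_fluence(
        plan, beam, np.asarray(x, float), np.asarray(y, float), beam.penumbra_sigma
    )


def render_image(
    plan: PFPlan,
    imager: ImagerSpec,
    beam: BeamModel,
    *,
    seed: int | None = None,
    noise: bool = True,
) -> EPIDImage:
    """Render one integrated EPID acquisition of ``plan``.

    Pipeline: blurred fluence -> radial off-axis ratio -> MU scaling ->
    projection onto the (possibly displaced) panel -> multiplicative
    Gaussian noise.  Metadata record the nominal geometry.
    """
    if beam.penumbra_sigma <= 0:
        raise SimulationError("penumbra_sigma must be > 0")
    vert, lat, long_ = imager.translation
    actual_sdd = imager.nominal_sdd + vert
    mag = actual_sdd / imager.sad
    # panel-plane pixel positions relative to the panel center
    u = (np.arange(imager.n_cols) - (imager.n_cols - 1) / 2.0) * imager.pitch
    v = ((imager.n_rows - 1) / 2.0 - np.arange(imager.n_rows)) * imager.pitch
    # isocenter-plane pierce points of each pixel's ray
    x_iso = (u + lat) / mag
    y_iso = (v + long_) / mag
    img = _evaluate_fluence(plan, beam, x_iso, y_iso, beam.penumbra_sigma)
    r2 = np.add.outer(np.square(y_iso), np.square(x_iso))
    c2, c4 = beam.oar_coeffs
    img *= 1.0 + c2 * r2 + c4 * r2 * r2
    img *= plan.mu / 100.0
    if noise and beam.noise_level > 0:
        rng = np.random.default_rng(beam.seed if seed is None else seed)
        img = img * (1.0 + beam.noise_level * rng.standard_normal(img.shape))
        np.maximum(img, 0.0, out=img)
    return EPIDImage(
        pixels=img,
        pitch=imager.pitch,
        recorded_sdd=imager.recorded_sdd,
        sad=imager.sad,
        mu=plan.mu,
        collimator_angle=plan.collimator_angle,
        meta={"mlc": plan.mlc.name},
    )
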