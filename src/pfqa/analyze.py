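"""Picket-fence image analysis: template, profiles, thresholds, slit metrics.

Two template strategies are implemented:

* ``field_edge`` -- the template is anchored on the radiative field: the Y
  jaw edges are located at 50% of the in-field signal and leaf-pair bands
  are mapped to *physical* pair indices through the plan's jaw aperture;
  the crossplane slit windows follow the detected field laterally.
* ``image_center`` -- the template is laid out from the DICOM image center
  assuming every leaf pair is visible, and bands are labelled sequentially
  from the first signal-bearing one.  This strategy deliberately ignores
  the plan: when the jaws hide peripheral pairs, or the imager moves, the
  reported pair labels drift away from the physical ones.

Slit positions and widths come from the threshold-midpoint rule: the two
crossings of the profile with a threshold are found by linear interpolation
between samples, the position is their midpoint and the width their
distance, giving sub-pixel output on a 0.336 mm-pitch image.  Thresholds
are either local (a fraction of each slit's own peak above background) or
global (one threshold per image, keyed to the extreme slit peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .mlc import PFPlan, MLCModel
from .simulate import EPIDImage

__all__ = [
    "AnalysisConfig",
    "AnalysisError",
    "FieldNotFoundError",
    "MeasurementError",
    "DegenerateFitError",
    "BandClippedError",
    "Band",
    "Template",
    "SlitMeasurement",
    "RelativeMetrics",
    "AbsoluteMetrics",
    "AnalysisResult",
    "locate_template",
    "extract_profile",
    "compute_thresholds",
    "measure_slit",
    "analyze_image",
    "check_tolerances",
]


class AnalysisError(ValueError):
    pass


class FieldNotFoundError(AnalysisError):
    """No radiative field (or no slit peaks) detectable in the image."""


class MeasurementError(AnalysisError):
    """A slit profile could not be measured; names the (slit, pair)."""


class DegenerateFitError(AnalysisError):
    """Too few measured pairs to fit a picket line."""


class BandClippedError(AnalysisError):
    """A template band falls outside the image."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Switchable analysis strategy and its numeric settings.

    ``threshold_fraction`` is the fraction of the (background-subtracted)
    peak at which crossings are taken; the commercial systems' values are
    proprietary, so it is an explicit setting here.  ``roi_fraction`` is
    the central fraction of each leaf-pair band averaged into the profile.
    """

    name: str = "custom"
    template_strategy: str = "field_edge"  # or "image_center"
    threshold_strategy: str = "local"  # or "global"
    threshold_fraction: float = 0.5
    smoothing_window: int = 3  # pixels, centered moving average
    smoothing_mm: float | None = None  # overrides smoothing_window if set
    reference_slit: int = 5
    position_criterion: float = 0.3  # mm, pass-rate criterion
    roi_fraction: float = 0.5
    peak_window_halfwidth: float = 5.0  # mm search window around nominal slits
    signal_floor_fraction: float = 0.25  # band counts as signal-bearing above this
    exclude_edge_bands: int = 1  # bands skipped at each end, clear of jaw penumbra
    has_width_metrics: bool = True
    has_signal_metric: bool = True
    alerting: bool = True
    tolerances: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.threshold_fraction < 1.0:
            raise AnalysisError("threshold_fraction must be in (0, 1)")
        if not 1 <= self.reference_slit <= 10:
            raise AnalysisError("reference_slit must be in 1..10")


def relative_local_config() -> AnalysisConfig:
    """Plan-anchored template, per-slit threshold, slit-signal metric.

    Emulates licensed QA platforms that compare each slit to a reference
    slit, threshold each peak locally, and report a calibrated slit signal.
    """
    return AnalysisConfig(
        name="relative_local",
        template_strategy="field_edge",
        threshold_strategy="local",
        has_signal_metric=True,
        alerting=True,
    )


def relative_global_config() -> AnalysisConfig:
    """Plan-anchored template with one image-wide threshold from the extreme peak.

    Uses a wide (6 mm) moving average before thresholding.  With a
    smoothing support much wider than the slit and a 50% threshold, the
    crossings sit at the edges of the smoothing support offset by the
    slit-profile median, so the measured width is insensitive to uniform
    sub-millimeter gap changes while remaining sensitive to a threshold
    pulled up by a single anomalous slit -- the characteristic behavior of
    image-wide-threshold width analysis.
    """
    return AnalysisConfig(
        name="relative_global",
        template_strategy="field_edge",
        threshold_strategy="global",
        smoothing_mm=6.0,
        has_signal_metric=False,
        alerting=True,
    )


def absolute_center_config() -> AnalysisConfig:
    """Image-center template with absolute picket metrics and no alerting.

    Emulates open-source picket-fence tools that place the template from
    EPID coordinates alone and return picket offsets, spacing, pass rate,
    median and maximum error, without width or signal metrics.
    """
    return AnalysisConfig(
        name="absolute_center",
        template_strategy="image_center",
        threshold_strategy="local",
        has_width_metrics=False,
        has_signal_metric=False,
        alerting=False,
    )


# ---------------------------------------------------------------------------
# template


@dataclass(frozen=True)
class Band:
    """One leaf-pair row band of the rigid template (image coordinates, mm)."""

    tiling_index: int  # 1-based position in the pair tiling
    label: int | None  # reported pair index (None until labelled)
    y_low: float
    y_high: float

    @property
    def y_center(self) -> float:
        return 0.5 * (self.y_low + self.y_high)


@dataclass
class Template:
    strategy: str
    bands: list[Band]
    windows: np.ndarray  # crossplane window centers, ascending, one per slit
    y_origin: float  # inplane template anchor (image coordinates)
    x_shift: float  # detected lateral offset applied to the plan windows
    y_edges: tuple[float, float] | None  # detected (top, bottom) jaw edges


def _detect_y_edges(image: EPIDImage) -> tuple[float, float]:
    """Radiative Y-jaw edges at 50% of the in-field signal (mm, top > bottom)."""
    n = image.n_cols
    cols = slice(n // 4, n - n // 4)
    prof = image.pixels[:, cols].mean(axis=1)
    lo, hi = np.percentile(prof, [1, 99])
    if hi <= lo * 1.5:
        raise FieldNotFoundError("no detectable field: flat inplane profile")
    level = 0.5 * (lo + hi)
    above = prof > level
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        raise FieldNotFoundError("no rows above the 50% field level")
    y = image.y_mm()

    def cross(i_out, i_in):
        if i_out < 0 or i_out >= len(prof) or prof[i_in] == prof[i_out]:
            return y[i_in]
        f = (level - prof[i_out]) / (prof[i_in] - prof[i_out])
        return y[i_out] + f * (y[i_in] - y[i_out])

    top = cross(idx[0] - 1, idx[0])
    bottom = cross(idx[-1] + 1, idx[-1])
    return float(top), float(bottom)


def _detect_slit_peaks(image: EPIDImage, y_edges: tuple[float, float]) -> np.ndarray:
    """Crossplane positions of the slit peaks from an in-field row average."""
    y = image.y_mm()
    top, bottom = y_edges
    shrink = 0.1 * (top - bottom)
    rows = (y < top - shrink) & (y > bottom + shrink)
    if not rows.any():
        raise FieldNotFoundError("field too narrow to average rows")
    prof = image.pixels[rows, :].mean(axis=0)
    x = image.x_mm()
    min_dist = max(1, int(round(10.0 / image.mm_per_pixel)))
    prom = 0.3 * (prof.max() - np.median(prof))
    peaks, props = find_peaks(prof, distance=min_dist, prominence=prom)
    if peaks.size == 0:
        raise FieldNotFoundError("no slit peaks detected")
    if peaks.size > 10:
        keep = np.argsort(props["prominences"])[-10:]
        peaks = np.sort(peaks[keep])
    return x[peaks]


def locate_template(
    image: EPIDImage,
    plan: PFPlan | None,
    mlc: MLCModel,
    config: AnalysisConfig,
) -> Template:
    """Place the rigid per-pair template on the image.

    ``field_edge`` requires ``plan`` (for the pair mapping and nominal slit
    positions); ``image_center`` ignores it by design.
    """
    y_edges = None
    if config.template_strategy == "field_edge":
        if plan is None:
            raise AnalysisError("field_edge template requires the plan")
        y_edges = _detect_y_edges(image)
        y_origin = 0.5 * (y_edges[0] + y_edges[1])
        peaks = _detect_slit_peaks(image, y_edges)
        centers = np.asarray(plan.slit_centers)
        diffs = [
            float(peaks[np.argmin(np.abs(peaks - c))] - c)
            for c in centers
            if np.abs(peaks - c).min() < 7.0
        ]
        x_shift = float(np.median(diffs)) if len(diffs) >= 3 else 0.0
        windows = centers + x_shift
    elif config.template_strategy == "image_center":
        y_origin = 0.0
        x_shift = 0.0
        try:
            y_edges = _detect_y_edges(image)
        except FieldNotFoundError:
            y_edges = None
        windows = _detect_slit_peaks(
            image,
            y_edges
            if y_edges is not None
            else (image.y_mm()[0] * 0.5, image.y_mm()[-1] * 0.5),
        )
    else:
        raise AnalysisError(f"unknown template strategy {config.template_strategy!r}")

    edges = mlc.pair_edges() + y_origin
    y_top, y_bot = image.y_mm()[0], image.y_mm()[-1]
    bands = [
        Band(i + 1, None, float(edges[i + 1]), float(edges[i]))
        for i in range(mlc.n_pairs)
        if edges[i + 1] >= y_bot and edges[i] <= y_top
    ]
    return Template(
        strategy=config.template_strategy,
        bands=bands,
        windows=np.sort(np.asarray(windows, float)),
        y_origin=float(y_origin),
        x_shift=x_shift,
        y_edges=y_edges,
    )


# ---------------------------------------------------------------------------
# profiles and measurement


def extract_profile(
    image: EPIDImage, band: Band, config: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Crossplane intensity profile under one band (mm-indexed).

    Averages the rows of the central ``roi_fraction`` of the band, then
    applies a centered moving average of ``smoothing_window`` pixels.
    """
    y = image.y_mm()
    half = 0.5 * (band.y_high - band.y_low) * config.roi_fraction
    rows = np.abs(y - band.y_center) <= half
    if not rows.any():
        raise BandClippedError(
            f"band {band.tiling_index} ({band.y_low:.1f}..{band.y_high:.1f} mm) "
            "has no pixel rows inside the image"
        )
    prof = image.pixels[rows, :].mean(axis=0)
    if config.smoothing_mm is not None:
        w = int(round(config.smoothing_mm / image.mm_per_pixel))
        w += 1 - w % 2  # odd, so the average stays centered
    else:
        w = int(config.smoothing_window)
    if w > 1:
        prof = np.convolve(prof, np.ones(w) / w, mode="same")
    return image.x_mm(), prof


def _background(x: np.ndarray, prof: np.ndarray, windows: np.ndarray, hw: float) -> float:
    """Median profile level outside all slit search windows, between slits."""
    span = (x >= windows.min() - 1.5 * hw) & (x <= windows.max() + 1.5 * hw)
    outside = np.ones_like(x, bool)
    for wc in windows:
        outside &= np.abs(x - wc) > hw
    sel = span & outside
    if not sel.any():
        sel = outside
    return float(np.median(prof[sel]))


def compute_thresholds(
    peaks: dict, backgrounds: dict, config: AnalysisConfig
) -> dict:
    """Per-(band, slit) threshold intensities.

    local: ``T = bg + f * (peak - bg)`` per slit and band.
    global: a single ``T = bg + f * (max peak - bg)`` for the whole image,
    keyed to the extreme slit peak.
    """
    f = config.threshold_fraction
    if config.threshold_strategy == "local":
        return {
            key: backgrounds[key[0]] + f * (pk - backgrounds[key[0]])
            for key, pk in peaks.items()
        }
    if config.threshold_strategy == "global":
        bg = float(np.median(list(backgrounds.values())))
        t = bg + f * (max(peaks.values()) - bg)
        return {key: t for key in peaks}
    raise AnalysisError(f"unknown threshold strategy {config.threshold_strategy!r}")


@dataclass(frozen=True)
class SlitMeasurement:
    """One slit under one leaf pair: threshold-midpoint position and width."""

    slit: int
    pair_label: int
    tiling_index: int
    position: float  # mm, midpoint of the threshold crossings
    width: float  # mm, distance between crossings
    peak: float
    integral: float  # background-subtracted summed intensity * mm


def measure_slit(
    x: np.ndarray,
    prof: np.ndarray,
    threshold: float,
    window_center: float,
    halfwidth: float,
    background: float,
    slit: int,
    pair_label: int,
    tiling_index: int = 0,
) -> SlitMeasurement:
    """Threshold-crossing measurement of one slit within its search window."""
    sel = np.nonzero(np.abs(x - window_center) <= halfwidth)[0]
    if sel.size < 3:
        raise MeasurementError(f"slit {slit}, pair {pair_label}: window empty")
    i0, i1 = sel[0], sel[-1]
    seg = prof[i0 : i1 + 1]
    pk = int(np.argmax(seg)) + i0
    if not background < threshold < prof[pk]:
        raise MeasurementError(
            f"slit {slit}, pair {pair_label}: threshold {threshold:.4g} not between "
            f"background {background:.4g} and peak {prof[pk]:.4g}"
        )

    def cross(start, step):
        i = start
        while i0 <= i + step <= i1 and prof[i] >= threshold:
            i += step
        if prof[i] >= threshold:  # never dropped below within the window
            return None
        a, b = i - step, i  # prof[a] >= T > prof[b]
        f = (threshold - prof[a]) / (prof[b] - prof[a])
        return float(x[a] + f * (x[b] - x[a]))

    left = cross(pk, -1)
    right = cross(pk, +1)
    if left is None or right is None:
        raise MeasurementError(
            f"slit {slit}, pair {pair_label}: fewer than 2 threshold crossings"
        )
    center = 0.5 * (left + right)
    dx = abs(float(x[1] - x[0]))
    # integrate centered on the *measured* slit, so a displaced or tilted
    # pattern does not clip the signal asymmetrically
    support = np.abs(x - center) <= 0.8 * halfwidth
    integral = float((prof[support] - background).sum() * dx)
    return SlitMeasurement(
        slit=slit,
        pair_label=pair_label,
        tiling_index=tiling_index,
        position=center,
        width=abs(right - left),
        peak=float(prof[pk]),
        integral=integral,
    )


# ---------------------------------------------------------------------------
# rolled-up metrics


@dataclass
class RelativeMetrics:
    """Per-slit metrics referenced to the central slit and a width baseline."""

    position_error: dict  # (slit, pair_label) -> mm, vs the reference slit
    intra_slit_deviation: dict  # (slit, pair_label) -> mm, vs the slit's own line fit
    width_error: dict  # (slit, pair_label) -> mm
    signal: dict  # slit -> mean background-subtracted integral
    mean_position: dict  # slit -> mm
    max_position: dict  # slit -> (mm, pair_label)
    mean_width: dict
    max_width: dict
    baseline_source: str  # "baseline" or "nominal"


@dataclass
class AbsoluteMetrics:
    """Image-anchored picket metrics."""

    picket_offsets: dict  # slit -> fitted position at the central axis (mm)
    mean_spacing: float
    deviations: dict  # (slit, pair_label) -> mm from the picket offset
    pass_rate: float  # percent within the position criterion
    median_error: float
    max_error: float
    max_error_cell: tuple[int, int]  # (slit, pair_label)


@dataclass
class AnalysisResult:
    config_name: str
    mlc_name: str
    measurements: list[SlitMeasurement]
    template: Template
    relative: RelativeMetrics | None
    absolute: AbsoluteMetrics | None
    first_signal_band: int
    last_signal_band: int
    failures: list[str]
    alerts: list[tuple] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Flat per-measurement table."""
        return pd.DataFrame(
            [
                {
                    "slit": m.slit,
                    "pair_label": m.pair_label,
                    "position_mm": m.position,
                    "width_mm": m.width,
                    "peak": m.peak,
                    "integral": m.integral,
                }
                for m in self.measurements
            ]
        )

    def by_cell(self) -> dict:
        return {(m.slit, m.pair_label): m for m in self.measurements}


def _relative_metrics(
    measurements: list[SlitMeasurement],
    plan: PFPlan,
    config: AnalysisConfig,
    baseline: AnalysisResult | None,
    bands_by_label: dict,
) -> RelativeMetrics:
    ref = config.reference_slit
    cells = {(m.slit, m.pair_label): m for m in measurements}
    nominal = np.asarray(plan.slit_centers)
    base_cells = baseline.by_cell() if baseline is not None else {}
    pos_err, width_err = {}, {}
    for (s, b), m in cells.items():
        ref_m = cells.get((ref, b))
        if ref_m is None:
            continue
        pos_err[(s, b)] = (m.position - ref_m.position) - (
            nominal[s - 1] - nominal[ref - 1]
        )
        base = base_cells.get((s, b))
        width_err[(s, b)] = m.width - (base.width if base else plan.nominal_gap)
    # deviation of each pair from its slit's fitted line: catches a leaf fault
    # present on every slit (which the inter-slit comparison cancels) while a
    # rigid rotation of the whole pattern is absorbed by the fit
    intra = {}
    for s in sorted({m.slit for m in measurements}):
        ms = [m for m in measurements if m.slit == s]
        if len(ms) < 3:
            continue
        yc = np.array([bands_by_label[m.pair_label].y_center for m in ms])
        p = np.array([m.position for m in ms])
        coeff = np.polyfit(yc, p, 1)
        for m, res in zip(ms, p - np.polyval(coeff, yc)):
            intra[(s, m.pair_label)] = float(res)
    slits = sorted({s for s, _ in cells})
    mean_pos, max_pos, mean_w, max_w, signal = {}, {}, {}, {}, {}
    for s in slits:
        pe = {b: v for (sl, b), v in pos_err.items() if sl == s}
        we = {b: v for (sl, b), v in width_err.items() if sl == s}
        if pe:
            mean_pos[s] = float(np.mean(list(pe.values())))
            bmax = max(pe, key=lambda b: abs(pe[b]))
            max_pos[s] = (pe[bmax], bmax)
        if we:
            mean_w[s] = float(np.mean(list(we.values())))
            bmax = max(we, key=lambda b: abs(we[b]))
            max_w[s] = (we[bmax], bmax)
        signal[s] = float(np.mean([m.integral for m in measurements if m.slit == s]))
    return RelativeMetrics(
        position_error=pos_err,
        intra_slit_deviation=intra,
        width_error=width_err,
        signal=signal,
        mean_position=mean_pos,
        max_position=max_pos,
        mean_width=mean_w,
        max_width=max_w,
        baseline_source="baseline" if baseline is not None else "nominal",
    )


def _absolute_metrics(
    measurements: list[SlitMeasurement],
    bands_by_label: dict,
    config: AnalysisConfig,
) -> AbsoluteMetrics:
    slits = sorted({m.slit for m in measurements})
    offsets, deviations = {}, {}
    for s in slits:
        ms = [m for m in measurements if m.slit == s]
        if len(ms) < 2:
            raise DegenerateFitError(f"slit {s}: fewer than 2 measured pairs")
        yc = np.array([bands_by_label[m.pair_label].y_center for m in ms])
        p = np.array([m.position for m in ms])
        slope, intercept = np.polyfit(yc, p, 1)
        offsets[s] = float(intercept)  # fitted picket position on the central axis
        for m in ms:
            deviations[(s, m.pair_label)] = float(m.position - offsets[s])
    dev = np.array(list(deviations.values()))
    pass_rate = float(100.0 * np.mean(np.abs(dev) <= config.position_criterion))
    max_cell = max(deviations, key=lambda k: abs(deviations[k]))
    ordered = [offsets[s] for s in slits]
    spacing = float(np.mean(np.diff(ordered))) if len(ordered) > 1 else float("nan")
    return AbsoluteMetrics(
        picket_offsets=offsets,
        mean_spacing=spacing,
        deviations=deviations,
        pass_rate=pass_rate,
        median_error=float(np.median(np.abs(dev))),
        max_error=float(np.max(np.abs(dev))),
        max_error_cell=max_cell,
    )


def analyze_image(
    image: EPIDImage,
    plan: PFPlan | None,
    mlc: MLCModel,
    config: AnalysisConfig,
    baseline: AnalysisResult | None = None,
) -> AnalysisResult:
    """Full slit analysis of one picket-fence image.

    Returns both metric families where computable: relative metrics need the
    plan (field-edge strategy); absolute metrics are always computed.
    Per-cell measurement failures are recorded and skipped, not fatal.
    """
    template = locate_template(image, plan, mlc, config)
    hw = config.peak_window_halfwidth

    profiles = {}
    band_peak = {}
    for band in template.bands:
        x, prof = extract_profile(image, band, config)
        profiles[band.tiling_index] = (x, prof)
        band_peak[band.tiling_index] = max(
            float(prof[np.abs(x - wc) <= hw].max()) if (np.abs(x - wc) <= hw).any() else 0.0
            for wc in template.windows
        )
    if not band_peak:
        raise FieldNotFoundError("no usable template bands")
    top_signal = max(band_peak.values())
    signal_bands = [
        b for b in template.bands
        if band_peak[b.tiling_index] > config.signal_floor_fraction * top_signal
    ]
    if not signal_bands:
        raise FieldNotFoundError("no signal-bearing bands")
    first_idx = signal_bands[0].tiling_index
    last_idx = signal_bands[-1].tiling_index
    k = config.exclude_edge_bands
    if k > 0 and len(signal_bands) > 2 * k + 2:
        measured_bands = signal_bands[k:-k]
    else:
        measured_bands = signal_bands
    labelled = []
    for band in measured_bands:
        label = (
            band.tiling_index
            if config.template_strategy == "field_edge"
            else band.tiling_index - first_idx + 1
        )
        labelled.append(replace(band, label=label))

    backgrounds = {}
    peaks = {}
    for band in labelled:
        x, prof = profiles[band.tiling_index]
        backgrounds[band.label] = _background(x, prof, template.windows, hw)
        for s, wc in enumerate(template.windows, start=1):
            sel = np.abs(x - wc) <= hw
            if not sel.any():
                continue
            peaks[(band.label, s)] = float(prof[sel].max())
    thresholds = compute_thresholds(peaks, backgrounds, config)

    measurements, failures = [], []
    for band in labelled:
        x, prof = profiles[band.tiling_index]
        bg = backgrounds[band.label]
        for s, wc in enumerate(template.windows, start=1):
            if (band.label, s) not in thresholds:
                continue
            try:
                measurements.append(
                    measure_slit(
                        x, prof, thresholds[(band.label, s)], wc, hw, bg,
                        slit=s, pair_label=band.label,
                        tiling_index=band.tiling_index,
                    )
                )
            except MeasurementError as exc:
                failures.append(str(exc))
    if not measurements:
        raise FieldNotFoundError("no slit could be measured")

    bands_by_label = {b.label: b for b in labelled}
    relative = None
    if plan is not None and config.template_strategy == "field_edge":
        relative = _relative_metrics(measurements, plan, config, baseline, bands_by_label)
    absolute = _absolute_metrics(measurements, bands_by_label, config)

    result = AnalysisResult(
        config_name=config.name,
        mlc_name=mlc.name,
        measurements=measurements,
        template=template,
        relative=relative,
        absolute=absolute,
        first_signal_band=first_idx,
        last_signal_band=last_idx,
        failures=failures,
    )
    result.alerts = check_tolerances(result, config.tolerances, config)
    return result


def check_tolerances(
    result: AnalysisResult, tolerances: dict, config: AnalysisConfig | None = None
) -> list[tuple]:
    """One alert per violated (metric, slit/pair): (metric, where, value, bound).

    An empty tolerance table yields no alerts.  Recognized keys:
    ``position_mm`` and ``width_mm`` (per-slit maxima of the relative
    metrics), ``pass_rate_pct`` (lower bound on the absolute pass rate).
    """
    alerts: list[tuple] = []
    if not tolerances:
        return alerts
    ref = config.reference_slit if config is not None else 5
    tol_p = tolerances.get("position_mm")
    tol_w = tolerances.get("width_mm")
    if result.relative is not None:
        if tol_p is not None:
            for s, (v, b) in result.relative.max_position.items():
                if s != ref and abs(v) > tol_p:
                    alerts.append(("position", s, v, tol_p))
        if tol_w is not None:
            for s, (v, b) in result.relative.max_width.items():
                if abs(v) > tol_w:
                    alerts.append(("width", s, v, tol_w))
    tol_pr = tolerances.get("pass_rate_pct")
    if tol_pr is not None and result.absolute is not None:
        if result.absolute.pass_rate < tol_pr:
            alerts.append(("pass_rate", "all", result.absolute.pass_rate, tol_pr))
    return alerts
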