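"""Sensitivity evaluation: run the fault matrix, score detections, build the grid.

Each scenario image is analyzed by every configured method family and the
result is compared cell-by-cell against the same family's analysis of the
unaltered reference acquisition.  A metric "departs" when it moves beyond a
detection floor: three times its across-seed standard deviation on
reference renders, but never below the method's stated resolution (0.1 mm
for positions and widths -- the accuracy the threshold-midpoint measurement
is specified to; 0.5% for the slit signal).  The floors guarantee zero
false positives on reference images while keeping 0.1 mm-scale faults
detectable.

Verdicts:

* ``indicated`` -- a metric departs, the departing cells localize the
  fault's true slit/pair, the recovered magnitude agrees with the injected
  one within 0.1 mm (position faults only), and the method family alerts.
* ``sensitive_unindicated`` -- a metric departs without all of the above;
  for imager/beam faults this is rendered as "impacted".
* ``insensitive`` -- nothing departs.
* ``not_applicable`` -- the family has no metric of the faulted kind
  (width faults under a family without width metrics).

Width-fault verdicts are capped at ``sensitive_unindicated``: a
threshold-crossing width cannot be related quantitatively to the injected
gap change, so width faults are never "indicated".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analyze import (
    AnalysisConfig,
    AnalysisError,
    AnalysisResult,
    absolute_center_config,
    analyze_image,
    relative_global_config,
    relative_local_config,
)
from .errors import Scenario, enumerate_matrix
from .mlc import build_mlc_model, build_reference_plan
from .simulate import BeamModel, ImagerSpec, render_image

__all__ = [
    "INDICATED",
    "SENSITIVE",
    "INSENSITIVE",
    "NOT_APPLICABLE",
    "DetectionFloors",
    "SensitivityCell",
    "MatrixRun",
    "default_configs",
    "estimate_floors",
    "run_matrix",
    "classify_sensitivity",
    "classify_run",
    "position_recovery_error",
    "sensitivity_table",
    "baseline_trend",
    "TrendError",
]

INDICATED = "indicated"
SENSITIVE = "sensitive_unindicated"
INSENSITIVE = "insensitive"
NOT_APPLICABLE = "not_applicable"

_VERDICT_RANK = {INSENSITIVE: 0, SENSITIVE: 1, INDICATED: 2}
_SYMBOL = {INDICATED: "✓", SENSITIVE: "≈", INSENSITIVE: "✗",
           NOT_APPLICABLE: "NA"}

#: Row order of the sensitivity grid (scenario families).
FAMILIES = [
    "gp_slit2",
    "gp_central",
    "gp_all",
    "lp_pair30",
    "lp_pairs30_31",
    "gw_slit2",
    "gw_all",
    "signal",
    "rotation",
    "trans_vertical",
    "trans_lateral",
    "trans_longitudinal",
]
_IMAGER_FAMILIES = {"signal", "rotation", "trans_vertical", "trans_lateral",
                    "trans_longitudinal"}
_WIDTH_FAMILIES = {"gw_slit2", "gw_all"}


def default_configs() -> list[AnalysisConfig]:
    """The three method families evaluated against each other."""
    return [relative_local_config(), relative_global_config(), absolute_center_config()]


@dataclass
class DetectionFloors:
    """Per-metric detection floors (see module docstring)."""

    position: float = 0.1  # mm
    width: float = 0.1  # mm
    signal: float = 0.005  # relative
    offset: float = 0.1  # mm
    spacing: float = 0.02  # mm
    scalar_error: float = 0.1  # mm, median/max deviation
    pass_rate: float = 1.0  # percentage points
    band_index: float = 0.5  # template labeling shift, bands


# minimum floors: the measurement resolution; seed scatter can only raise them
_MIN_FLOORS = DetectionFloors()


def estimate_floors(
    mlc_name: str,
    config: AnalysisConfig,
    imager: ImagerSpec,
    beam: BeamModel,
    n_seeds: int = 20,
    master_seed: int = 0,
) -> DetectionFloors:
    """Floors from seeded reference renders: max(3 x seed std, resolution floor)."""
    mlc = build_mlc_model(mlc_name)
    plan = build_reference_plan(mlc)
    seeds = np.random.SeedSequence(master_seed).generate_state(n_seeds) % (2**31)
    results = [
        analyze_image(render_image(plan, imager, beam, seed=int(s)), plan, mlc, config)
        for s in seeds
    ]

    def spread(values_per_seed):
        arr = np.asarray(values_per_seed, float)
        return float(3.0 * arr.std(axis=0).max()) if arr.size else 0.0

    cells = sorted(set.intersection(*[set(r.by_cell()) for r in results]))
    pos = spread([[r.by_cell()[c].position for c in cells] for r in results])
    wid = spread([[r.by_cell()[c].width for c in cells] for r in results])
    sig = 0.0
    if results[0].relative is not None:
        slits = sorted(results[0].relative.signal)
        mat = np.array([[r.relative.signal[s] for s in slits] for r in results])
        sig = float(3.0 * (mat / mat.mean(axis=0)).std(axis=0).max())
    off = spread([[r.absolute.picket_offsets[s] for s in sorted(r.absolute.picket_offsets)]
                  for r in results])
    spc = spread([[r.absolute.mean_spacing] for r in results])
    sca = spread([[r.absolute.max_error] for r in results])
    pr = spread([[r.absolute.pass_rate] for r in results])
    m = _MIN_FLOORS
    return DetectionFloors(
        position=max(pos, m.position),
        width=max(wid, m.width),
        signal=max(sig, m.signal),
        offset=max(off, m.offset),
        spacing=max(spc, m.spacing),
        scalar_error=max(sca, m.scalar_error),
        pass_rate=max(pr, m.pass_rate),
        band_index=m.band_index,
    )


# ---------------------------------------------------------------------------
# matrix execution


@dataclass
class MatrixRun:
    """All analysis results of one evaluation run, keyed by (scenario, config)."""

    results: dict = field(default_factory=dict)  # (scenario_id, config_name) -> result
    references: dict = field(default_factory=dict)  # (mlc, config_name) -> result
    scenarios: dict = field(default_factory=dict)  # scenario_id -> Scenario
    configs: dict = field(default_factory=dict)  # config_name -> AnalysisConfig
    errors: dict = field(default_factory=dict)  # (scenario_id, config_name) -> message


def run_matrix(
    scenarios: list[Scenario] | None = None,
    configs: list[AnalysisConfig] | None = None,
    imager: ImagerSpec | None = None,
    beam: BeamModel | None = None,
    master_seed: int = 0,
) -> MatrixRun:
    """Render and analyze every scenario with every config.

    Deterministic given ``master_seed``: each scenario gets a stable child
    seed, so repeating a run reproduces it bit-for-bit.  Per-scenario
    analysis failures are recorded in ``errors`` and the run continues.
    """
    scenarios = enumerate_matrix() if scenarios is None else scenarios
    configs = default_configs() if configs is None else configs
    imager = ImagerSpec() if imager is None else imager
    beam = BeamModel() if beam is None else beam
    if not configs:
        raise ValueError("configs list must be nonempty")
    run = MatrixRun()
    run.configs = {cfg.name: cfg for cfg in configs}
    base_imager = imager
    for i, sc in enumerate(scenarios):
        run.scenarios[sc.scenario_id] = sc
        plan, translation = sc.realize()
        sc_imager = (
            base_imager
            if translation == (0.0, 0.0, 0.0)
            else ImagerSpec(
                n_rows=base_imager.n_rows,
                n_cols=base_imager.n_cols,
                pitch=base_imager.pitch,
                sad=base_imager.sad,
                nominal_sdd=base_imager.nominal_sdd,
                translation=translation,
            )
        )
        seed = int(np.random.SeedSequence((master_seed, i)).generate_state(1)[0] % (2**31))
        image = render_image(plan, sc_imager, beam, seed=seed)
        ref_plan = build_reference_plan(plan.mlc)
        for cfg in configs:
            key = (sc.scenario_id, cfg.name)
            baseline = run.references.get((sc.mlc_name, cfg.name))
            try:
                res = analyze_image(image, ref_plan, plan.mlc, cfg, baseline=baseline)
                run.results[key] = res
                if sc.spec is None:
                    run.references[(sc.mlc_name, cfg.name)] = res
            except AnalysisError as exc:
                run.errors[key] = str(exc)
    return run


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class SensitivityCell:
    family: str
    config_name: str
    mlc_name: str
    verdict: str
    departing_metrics: tuple[str, ...] = ()

    @property
    def symbol(self) -> str:
        return _SYMBOL[self.verdict]


def _common_cells(a: AnalysisResult, b: AnalysisResult):
    return sorted(set(a.by_cell()) & set(b.by_cell()))


def _departures(result, reference, config, floors):
    """(metric name, cell, |delta|, signed delta) for every floor exceedance."""
    out = []
    cells = _common_cells(result, reference)
    rm, fm = result.by_cell(), reference.by_cell()
    if result.relative is not None and reference.relative is not None:
        for c in cells:
            pr = result.relative.position_error.get(c)
            pf = reference.relative.position_error.get(c)
            if pr is not None and pf is not None and abs(pr - pf) > floors.position:
                out.append(("rel_position", c, abs(pr - pf), pr - pf))
        for c in cells:
            dr = result.relative.intra_slit_deviation.get(c)
            df = reference.relative.intra_slit_deviation.get(c)
            if dr is not None and df is not None and abs(dr - df) > floors.position:
                out.append(("intra_slit", c, abs(dr - df), dr - df))
        if config.has_width_metrics:
            for c in cells:
                dw = rm[c].width - fm[c].width
                if abs(dw) > floors.width:
                    out.append(("rel_width", c, abs(dw), dw))
        if config.has_signal_metric:
            # per-slit means over the cells measured in *both* results, so a
            # band dropping out does not masquerade as a signal change
            for s in sorted({c[0] for c in cells}):
                sc = [c for c in cells if c[0] == s]
                if not sc:
                    continue
                r_mean = np.mean([rm[c].integral for c in sc])
                f_mean = np.mean([fm[c].integral for c in sc])
                rel = float(r_mean / f_mean - 1.0)
                if abs(rel) > floors.signal:
                    out.append(("signal", (s, None), abs(rel), rel))
    if config.template_strategy == "image_center":
        ra, fa = result.absolute, reference.absolute
        for s in sorted(set(ra.picket_offsets) & set(fa.picket_offsets)):
            d = ra.picket_offsets[s] - fa.picket_offsets[s]
            if abs(d) > floors.offset:
                out.append(("picket_offset", (s, None), abs(d), d))
        if abs(ra.mean_spacing - fa.mean_spacing) > floors.spacing:
            out.append(("mean_spacing", None, abs(ra.mean_spacing - fa.mean_spacing),
                        ra.mean_spacing - fa.mean_spacing))
        if abs(ra.max_error - fa.max_error) > floors.scalar_error:
            out.append(("max_error", ra.max_error_cell, abs(ra.max_error - fa.max_error),
                        ra.max_error - fa.max_error))
        if abs(ra.median_error - fa.median_error) > floors.scalar_error:
            out.append(("median_error", None, abs(ra.median_error - fa.median_error),
                        ra.median_error - fa.median_error))
        if abs(ra.pass_rate - fa.pass_rate) > floors.pass_rate:
            out.append(("pass_rate", None, abs(ra.pass_rate - fa.pass_rate),
                        ra.pass_rate - fa.pass_rate))
        d_first = result.first_signal_band - reference.first_signal_band
        d_last = result.last_signal_band - reference.last_signal_band
        if abs(d_first) > floors.band_index or abs(d_last) > floors.band_index:
            out.append(("template_labeling", None, float(max(abs(d_first), abs(d_last))),
                        float(d_first or d_last)))
    return out


def classify_sensitivity(
    scenario: Scenario,
    result: AnalysisResult,
    reference: AnalysisResult,
    config: AnalysisConfig,
    floors: DetectionFloors,
) -> SensitivityCell:
    """Verdict for one (scenario, method family) pair; see module docstring."""
    truth = scenario.truth()
    is_width_fault = scenario.category == "global_width"
    if is_width_fault and not config.has_width_metrics and not config.has_signal_metric:
        return SensitivityCell(scenario.family, config.name, scenario.mlc_name,
                               NOT_APPLICABLE)
    deps = _departures(result, reference, config, floors)
    if not deps:
        return SensitivityCell(scenario.family, config.name, scenario.mlc_name,
                               INSENSITIVE)
    metrics = tuple(sorted({d[0] for d in deps}))
    if is_width_fault or scenario.category in (
        "signal", "rotation", "translation", "reference"
    ):
        # width magnitudes cannot be related to the injected gap change, and
        # imager faults have no per-cell location: sensitivity only
        return SensitivityCell(scenario.family, config.name, scenario.mlc_name,
                               SENSITIVE, metrics)
    # position fault: can the method *indicate* it?
    if not config.alerting:
        return SensitivityCell(scenario.family, config.name, scenario.mlc_name,
                               SENSITIVE, metrics)
    pos_deps = [d for d in deps if d[0] in ("rel_position", "intra_slit", "picket_offset")]
    if not pos_deps:
        return SensitivityCell(scenario.family, config.name, scenario.mlc_name,
                               SENSITIVE, metrics)
    top = max(pos_deps, key=lambda d: d[2])
    slit, pair = top[1]
    localized = slit in truth.target_slits and (
        pair is None or pair in truth.target_pairs
    )
    expected = float(np.abs(truth.center_delta).max())
    magnitude_ok = abs(top[2] - expected) <= 0.1
    verdict = INDICATED if (localized and magnitude_ok) else SENSITIVE
    return SensitivityCell(scenario.family, config.name, scenario.mlc_name,
                           verdict, metrics)


def sensitivity_table(cells: list[SensitivityCell]) -> pd.DataFrame:
    """Scenario-family x method-family grid of verdict symbols.

    A family's verdict is the strongest over its magnitudes (a fault class
    counts as detected if any injected magnitude is).  Missing combinations
    are reported as explicit gaps ("?") rather than dropped.
    """
    configs = sorted({c.config_name for c in cells})
    mlcs = sorted({c.mlc_name for c in cells})
    rows = []
    for mlc in mlcs:
        for fam in FAMILIES:
            row = {"mlc": mlc, "family": fam}
            for cfg in configs:
                sub = [c for c in cells
                       if c.family == fam and c.config_name == cfg and c.mlc_name == mlc]
                if not sub:
                    row[cfg] = "?"
                elif all(c.verdict == NOT_APPLICABLE for c in sub):
                    row[cfg] = _SYMBOL[NOT_APPLICABLE]
                else:
                    best = max(
                        (c.verdict for c in sub if c.verdict != NOT_APPLICABLE),
                        key=lambda v: _VERDICT_RANK[v],
                    )
                    row[cfg] = _SYMBOL[best]
            rows.append(row)
    return pd.DataFrame(rows)


def classify_run(run: MatrixRun, floors_by_key: dict) -> list[SensitivityCell]:
    """Classify every non-reference scenario of a matrix run.

    ``floors_by_key`` maps (mlc_name, config_name) to DetectionFloors.
    """
    cells = []
    for (sid, cfg_name), result in run.results.items():
        sc = run.scenarios[sid]
        if sc.spec is None:
            continue
        reference = run.references.get((sc.mlc_name, cfg_name))
        if reference is None:
            continue
        cfg = run.configs[cfg_name]
        floors = floors_by_key[(sc.mlc_name, cfg_name)]
        cells.append(classify_sensitivity(sc, result, reference, cfg, floors))
    return cells


# ---------------------------------------------------------------------------
# baseline trending


POSITION_FAMILIES = (
    "reference", "gp_slit2", "gp_central", "gp_all", "lp_pair30", "lp_pairs30_31",
)


def position_recovery_error(
    master_seed: int,
    imager: ImagerSpec | None = None,
    beam: BeamModel | None = None,
) -> tuple[float, int]:
    """Worst |recovered - injected| slit-center shift over all position faults.

    Renders the 25 global/local position-error scenarios per MLC (plus the
    references) with default noise, analyzes them with the field-edge
    template, and compares each targeted cell's measured position change
    against the injected center delta.  Returns (max error in mm, number
    of compared cells).
    """
    scenarios = [s for s in enumerate_matrix() if s.family in POSITION_FAMILIES]
    run = run_matrix(
        scenarios=scenarios,
        configs=[relative_local_config()],
        imager=ImagerSpec() if imager is None else imager,
        beam=BeamModel() if beam is None else beam,
        master_seed=master_seed,
    )
    worst, n = 0.0, 0
    for (sid, cfg_name), result in run.results.items():
        scenario = run.scenarios[sid]
        if scenario.spec is None:
            continue
        reference = run.references[(scenario.mlc_name, cfg_name)]
        truth = scenario.truth()
        rm, fm = result.by_cell(), reference.by_cell()
        for s, p in sorted(set(rm) & set(fm)):
            injected = float(truth.center_delta[s - 1, p - 1])
            if injected == 0.0:
                continue
            recovered = rm[(s, p)].position - fm[(s, p)].position
            worst = max(worst, abs(recovered - injected))
            n += 1
    return worst, n


class TrendError(ValueError):
    """Inconsistent series (mixed MLC models or configs)."""


def baseline_trend(
    dated_results: list[tuple[str, AnalysisResult]],
    metric: str = "max_position",
    tolerance: float | None = None,
) -> pd.DataFrame:
    """Constancy check of one metric over dated runs.

    The first run is the baseline; the report lists each run's value,
    deviation from baseline, and whether it breaches ``tolerance``.
    Supported metrics: ``max_position`` / ``mean_position`` (worst slit of
    the relative family), ``pass_rate``, ``mean_spacing``, ``max_error``.
    """
    if len(dated_results) < 2:
        raise TrendError("need at least 2 dated results")
    mlcs = {r.mlc_name for _, r in dated_results}
    cfgs = {r.config_name for _, r in dated_results}
    if len(mlcs) > 1:
        raise TrendError(f"mixed MLC models in one series: {sorted(mlcs)}")
    if len(cfgs) > 1:
        raise TrendError(f"mixed analysis configs in one series: {sorted(cfgs)}")

    def value(r: AnalysisResult) -> float:
        if metric in ("max_position", "mean_position"):
            if r.relative is None:
                raise TrendError(f"{metric} needs relative metrics")
            table = getattr(r.relative, metric)
            vals = [v[0] if isinstance(v, tuple) else v for v in table.values()]
            return float(max(np.abs(vals)))
        if metric in ("pass_rate", "mean_spacing", "max_error"):
            return float(getattr(r.absolute, metric))
        raise TrendError(f"unknown trend metric {metric!r}")

    base = value(dated_results[0][1])
    rows = []
    for date, res in dated_results:
        v = value(res)
        dev = v - base
        rows.append({
            "date": date,
            "value": v,
            "deviation": dev,
            "breach": bool(tolerance is not None and abs(dev) > tolerance),
        })
    return pd.DataFrame(rows)
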