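"""Fault injection: the altered-plan / imager scenario matrix with ground truth.

Each scenario carries exactly one injected fault.  MLC faults are realized
as explicit tip arithmetic on the plan; signal faults scale the MU; rotation
faults set the plan collimator angle; translation faults displace the imager
pose.  One-bank shifts move the bank-A tip outward (the aperture grows), so
a shift of ``d`` adds ``d`` to the slit width and ``d/2`` to the slit center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .mlc import MLCModel, PFPlan, build_mlc_model, build_reference_plan

__all__ = [
    "ErrorSpec",
    "GroundTruth",
    "Scenario",
    "InjectionError",
    "apply_error",
    "ground_truth",
    "enumerate_matrix",
    "scenario_manifest",
]

MLC_CATEGORIES = ("global_position", "local_position", "global_width")
IMAGER_CATEGORIES = ("signal", "rotation", "translation")

POSITION_MAGNITUDES = (0.1, 0.2, 0.3, 0.4, 0.5)  # mm
WIDTH_MAGNITUDES = POSITION_MAGNITUDES  # mm
SIGNAL_MAGNITUDES = (101.0, 102.0, 103.0, 104.0, 105.0)  # MU
ROTATION_MAGNITUDES = (0.1, 0.3, 0.5, 1.0, 2.0)  # degrees
TRANSLATION_MAGNITUDES = (1.0, 2.0, 5.0)  # mm
TRANSLATION_AXES = ("vertical", "lateral", "longitudinal")

#: The reference slit used by the relative analysis (the central, 5th slit).
CENTRAL_SLIT = 5
#: Leaf pairs targeted by local faults.
LOCAL_PAIRS_SINGLE = (30,)
LOCAL_PAIRS_DOUBLE = (30, 31)


class InjectionError(ValueError):
    """Invalid fault specification."""


@dataclass(frozen=True)
class ErrorSpec:
    """One injected fault.

    ``magnitude`` is in mm for position/width/translation faults, degrees for
    rotation, and MU for signal faults.  ``target_slits``/``target_pairs``
    are 1-based tuples, or ``"all"``.
    """

    category: str
    magnitude: float
    target_slits: tuple[int, ...] | str = "all"
    target_pairs: tuple[int, ...] | str = "all"
    bank: str = "BOTH"
    axis: str | None = None  # translation only

    def __post_init__(self):
        if self.category not in MLC_CATEGORIES + IMAGER_CATEGORIES:
            raise InjectionError(f"unknown error category {self.category!r}")
        if self.bank not in ("A", "B", "BOTH"):
            raise InjectionError(f"unknown bank {self.bank!r}")
        if self.category == "global_position" and self.bank != "BOTH":
            raise InjectionError("global_position faults move both banks")
        if self.category in ("local_position", "global_width") and self.bank != "A":
            raise InjectionError(f"{self.category} faults open the A bank")
        if self.category == "translation" and self.axis not in TRANSLATION_AXES:
            raise InjectionError(f"translation needs axis in {TRANSLATION_AXES}")


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-cell deltas implied by one fault.

    ``center_delta``/``width_delta`` have shape ``(n_slits, n_pairs)`` in mm.
    ``signal_scale`` is MU/100; ``pose_delta`` is (vertical, lateral,
    longitudinal) in mm and ``rotation_delta`` in degrees.
    """

    center_delta: np.ndarray
    width_delta: np.ndarray
    signal_scale: float = 1.0
    pose_delta: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_delta: float = 0.0

    @property
    def target_cells(self) -> set[tuple[int, int]]:
        """1-based (slit, pair) cells whose geometry the fault changes."""
        rows, cols = np.nonzero(
            (self.center_delta != 0.0) | (self.width_delta != 0.0)
        )
        return {(int(r) + 1, int(c) + 1) for r, c in zip(rows, cols)}

    @property
    def target_slits(self) -> set[int]:
        return {s for s, _ in self.target_cells}

    @property
    def target_pairs(self) -> set[int]:
        return {p for _, p in self.target_cells}


def _target_indices(spec_targets, n: int) -> np.ndarray:
    if isinstance(spec_targets, str):
        if spec_targets != "all":
            raise InjectionError(f"bad target spec {spec_targets!r}")
        return np.arange(n)
    idx = np.asarray(spec_targets, dtype=int) - 1
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise InjectionError(f"target index out of range 1..{n}")
    return idx


def apply_error(plan: PFPlan, spec: ErrorSpec) -> PFPlan:
    """Return a new plan with the MLC fault applied via tip arithmetic.

    Only the targeted tip coordinates change: ``bank BOTH`` moves both tips
    by ``+d``; ``bank A`` moves the bank-A tip outward by ``+d``.  Targets
    hidden behind the Y jaws are still applied (the fault exists on the
    machine whether or not it is visible).
    """
    if spec.category not in MLC_CATEGORIES:
        raise InjectionError(
            f"apply_error handles MLC categories only, got {spec.category!r}"
        )
    slits = _target_indices(spec.target_slits, plan.n_slits)
    pairs = _target_indices(spec.target_pairs, plan.mlc.n_pairs)
    hidden = (
        set(int(p) for p in pairs + 1) - set(int(p) for p in plan.visible_pairs())
        if not isinstance(spec.target_pairs, str)
        else set()
    )
    if hidden:
        warnings.warn(
            f"fault targets pairs hidden behind the Y jaws: {sorted(hidden)}; "
            "applied anyway",
            stacklevel=2,
        )
    tip_a = plan.tip_a.copy()
    tip_b = plan.tip_b.copy()
    cells = np.ix_(slits, pairs)
    d = spec.magnitude
    if spec.bank == "BOTH":
        tip_a[cells] += d
        tip_b[cells] += d
    elif spec.bank == "A":
        tip_a[cells] += d
    else:  # bank B moves outward, toward negative crossplane
        tip_b[cells] -= d
    return replace(plan, tip_a=tip_a, tip_b=tip_b)


def ground_truth(spec: ErrorSpec | None, plan: PFPlan) -> GroundTruth:
    """Exact expected deltas for one scenario (``None`` = reference)."""
    shape = (plan.n_slits, plan.mlc.n_pairs)
    center = np.zeros(shape)
    width = np.zeros(shape)
    if spec is None:
        return GroundTruth(center, width)
    if spec.category in MLC_CATEGORIES:
        slits = _target_indices(spec.target_slits, plan.n_slits)
        pairs = _target_indices(spec.target_pairs, plan.mlc.n_pairs)
        cells = np.ix_(slits, pairs)
        if spec.bank == "BOTH":
            center[cells] = spec.magnitude
        else:  # one-bank opening: width grows by d, center moves d/2
            width[cells] = spec.magnitude
            sign = 1.0 if spec.bank == "A" else -1.0
            center[cells] = sign * spec.magnitude / 2.0
        return GroundTruth(center, width)
    if spec.category == "signal":
        return GroundTruth(center, width, signal_scale=spec.magnitude / 100.0)
    if spec.category == "rotation":
        return GroundTruth(center, width, rotation_delta=spec.magnitude)
    pose = [0.0, 0.0, 0.0]
    pose[TRANSLATION_AXES.index(spec.axis)] = spec.magnitude
    return GroundTruth(center, width, pose_delta=tuple(pose))


@dataclass(frozen=True)
class Scenario:
    """One entry of the evaluation matrix.

    ``family`` groups scenarios that share a row in the sensitivity table
    (e.g. all five magnitudes of the 2nd-slit shift).
    """

    scenario_id: str
    mlc_name: str
    family: str
    spec: ErrorSpec | None

    @property
    def category(self) -> str:
        return self.spec.category if self.spec is not None else "reference"

    def realize(self) -> tuple[PFPlan, tuple[float, float, float]]:
        """Build (plan, imager translation) for this scenario."""
        plan = build_reference_plan(build_mlc_model(self.mlc_name))
        translation = (0.0, 0.0, 0.0)
        if self.spec is None:
            return plan, translation
        s = self.spec
        if s.category in MLC_CATEGORIES:
            plan = apply_error(plan, s)
        elif s.category == "signal":
            plan = replace(plan, mu=s.magnitude)
        elif s.category == "rotation":
            plan = replace(plan, collimator_angle=s.magnitude)
        else:
            pose = [0.0, 0.0, 0.0]
            pose[TRANSLATION_AXES.index(s.axis)] = s.magnitude
            translation = tuple(pose)
        return plan, translation

    def truth(self) -> GroundTruth:
        plan = build_reference_plan(build_mlc_model(self.mlc_name))
        return ground_truth(self.spec, plan)


def _mlc_scenarios(mlc_name: str) -> list[Scenario]:
    out = [Scenario(f"{mlc_name}-reference", mlc_name, "reference", None)]

    def add(family, spec, tag):
        out.append(Scenario(f"{mlc_name}-{family}-{tag}", mlc_name, family, spec))

    for slits, fam in ((2,), "gp_slit2"), ((CENTRAL_SLIT,), "gp_central"), ("all", "gp_all"):
        for d in POSITION_MAGNITUDES:
            add(fam, ErrorSpec("global_position", d, target_slits=slits), f"{d:g}mm")
    for pairs, fam in (LOCAL_PAIRS_SINGLE, "lp_pair30"), (LOCAL_PAIRS_DOUBLE, "lp_pairs30_31"):
        for d in POSITION_MAGNITUDES:
            add(
                fam,
                ErrorSpec("local_position", d, target_pairs=pairs, bank="A"),
                f"{d:g}mm",
            )
    for slits, fam in ((2,), "gw_slit2"), ("all", "gw_all"):
        for d in WIDTH_MAGNITUDES:
            add(fam, ErrorSpec("global_width", d, target_slits=slits, bank="A"), f"{d:g}mm")
    for mu in SIGNAL_MAGNITUDES:
        add("signal", ErrorSpec("signal", mu), f"{mu:g}MU")
    for ang in ROTATION_MAGNITUDES:
        add("rotation", ErrorSpec("rotation", ang), f"{ang:g}deg")
    for axis in TRANSLATION_AXES:
        for d in TRANSLATION_MAGNITUDES:
            add(
                f"trans_{axis}",
                ErrorSpec("translation", d, axis=axis),
                f"{d:g}mm",
            )
    return out


def enumerate_matrix(mlc_names: tuple[str, ...] = ("M120", "HD120")) -> list[Scenario]:
    """The full evaluation matrix: 55 scenarios per MLC, 110 for both.

    Per MLC: 1 reference + 15 global-position (3 targets x 5 magnitudes)
    + 10 local-position + 10 global-width + 5 signal + 5 rotation
    + 9 translation (3 axes x 3 magnitudes).  Deterministic order, stable IDs.
    """
    scenarios: list[Scenario] = []
    for name in mlc_names:
        scenarios.extend(_mlc_scenarios(name))
    ids = [s.scenario_id for s in scenarios]
    assert len(ids) == len(set(ids))
    return scenarios


def scenario_manifest(scenarios: list[Scenario]) -> pd.DataFrame:
    """Flat manifest of the matrix: one row per scenario with its ground truth summary."""
    rows = []
    for sc in scenarios:
        truth = sc.truth()
        spec = sc.spec
        rows.append(
            {
                "scenario_id": sc.scenario_id,
                "mlc": sc.mlc_name,
                "family": sc.family,
                "category": sc.category,
                "magnitude": spec.magnitude if spec else 0.0,
                "bank": spec.bank if spec else "",
                "axis": (spec.axis or "") if spec else "",
                "target_slits": str(spec.target_slits) if spec else "",
                "target_pairs": str(spec.target_pairs) if spec else "",
                "max_center_delta_mm": float(np.abs(truth.center_delta).max()),
                "max_width_delta_mm": float(np.abs(truth.width_delta).max()),
                "signal_scale": truth.signal_scale,
                "rotation_delta_deg": truth.rotation_delta,
                "pose_delta_mm": str(truth.pose_delta),
            }
        )
    return pd.DataFrame(rows)
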