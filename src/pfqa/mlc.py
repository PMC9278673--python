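"""MLC geometry and picket-fence plan construction.

Coordinate frame: beam's-eye view at the isocenter plane, in mm.
Crossplane ``x`` is the leaf-travel direction, positive toward the bank-A
tips; inplane ``y`` is positive toward leaf pair 1.  All plan quantities
are expressed at isocenter scale -- panel magnification is handled by the
imager model, never by the plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "MLCModel",
    "PFPlan",
    "PlanError",
    "PlanParseError",
    "build_mlc_model",
    "build_reference_plan",
    "leaf_pair_span",
    "write_plan",
    "read_plan",
]

N_SLITS = 10
SLIT_SPACING = 15.0  # mm, center to center
NOMINAL_GAP = 1.0  # mm
#: Slit centers chosen so each X jaw edge sits 15 mm beyond the outer edge
#: of the adjacent slit, reproducing the X1 = 75 mm / X2 = 91 mm apertures.
SLIT_CENTERS = tuple(-59.5 + SLIT_SPACING * i for i in range(N_SLITS))
JAW_MARGIN = 15.0  # mm between outermost slit edge and X jaw edge

_M120_WIDTHS = (10.0,) * 10 + (5.0,) * 40 + (10.0,) * 10
_HD120_WIDTHS = (5.0,) * 14 + (2.5,) * 32 + (5.0,) * 14
#: Symmetric inplane half-apertures of the Y jaws.  Two leaf pairs are
#: excluded at each inplane end to stay clear of the imager edge.
_JAW_Y = {"M120": 180.0, "HD120": 100.0}


class PlanError(ValueError):
    """Invalid MLC or plan specification."""


class PlanParseError(PlanError):
    """A plan file failed validation; the message names the offending field."""


@dataclass(frozen=True)
class MLCModel:
    """Leaf-pair widths and bank geometry of one collimator type.

    ``pair_widths`` are inplane widths (mm at isocenter), ordered from the
    positive-y end (pair 1) to the negative-y end (pair 60).
    """

    name: str
    pair_widths: tuple[float, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pair_widths)

    @property
    def inplane_extent(self) -> float:
        """Total inplane extent covered by the leaf bank (mm)."""
        return float(sum(self.pair_widths))

    def pair_edges(self) -> np.ndarray:
        """Inplane edges of the pair intervals, descending from +extent/2.

        ``edges[i-1]`` is the high edge of pair ``i``; ``edges[i]`` its low
        edge.  Pairs tile ``[-extent/2, +extent/2)`` symmetrically about the
        inplane axis with no gaps.
        """
        half = self.inplane_extent / 2.0
        return half - np.concatenate([[0.0], np.cumsum(self.pair_widths)])


def build_mlc_model(name: str) -> MLCModel:
    """Return the leaf-width table for ``"M120"`` or ``"HD120"``."""
    if name == "M120":
        return MLCModel("M120", _M120_WIDTHS)
    if name == "HD120":
        return MLCModel("HD120", _HD120_WIDTHS)
    raise PlanError(f"unknown MLC model {name!r}; expected 'M120' or 'HD120'")


def leaf_pair_span(mlc: MLCModel, pair_index: int) -> tuple[float, float]:
    """Half-open inplane interval ``[low, high)`` of one leaf pair (mm).

    ``pair_index`` is 1-based from the positive-y end.  Adjacent intervals
    abut exactly; their union tiles the full inplane extent.
    """
    if not 1 <= pair_index <= mlc.n_pairs:
        raise PlanError(
            f"pair_index {pair_index} out of range 1..{mlc.n_pairs} for {mlc.name}"
        )
    edges = mlc.pair_edges()
    return float(edges[pair_index]), float(edges[pair_index - 1])


@dataclass(frozen=True)
class PFPlan:
    """One picket-fence acquisition: slit layout, jaws, MU, collimator angle.

    ``tip_a``/``tip_b`` hold per-slit, per-pair crossplane tip coordinates,
    shape ``(n_slits, n_pairs)``; bank-A tips lie on the positive-crossplane
    side of each slit, so ``tip_a - tip_b`` is the slit gap.
    """

    mlc: MLCModel
    slit_centers: tuple[float, ...]
    nominal_gap: float
    jaw_x1: float  # positive magnitude of the negative-crossplane opening
    jaw_x2: float  # positive magnitude of the positive-crossplane opening
    jaw_y: float  # symmetric inplane half-aperture
    mu: float
    collimator_angle: float  # degrees
    tip_a: np.ndarray = field(repr=False)
    tip_b: np.ndarray = field(repr=False)

    @property
    def n_slits(self) -> int:
        return len(self.slit_centers)

    def visible_pairs(self) -> np.ndarray:
        """1-based indices of pairs whose span intersects the Y jaw opening."""
        edges = self.mlc.pair_edges()
        high, low = edges[:-1], edges[1:]
        mask = (high > -self.jaw_y) & (low < self.jaw_y)
        return np.nonzero(mask)[0] + 1

    def copy(self) -> "PFPlan":
        return replace(self, tip_a=self.tip_a.copy(), tip_b=self.tip_b.copy())

    def allclose(self, other: "PFPlan", tol: float = 1e-6) -> bool:
        return (
            self.mlc == other.mlc
            and np.allclose(self.slit_centers, other.slit_centers, atol=tol)
            and abs(self.nominal_gap - other.nominal_gap) <= tol
            and abs(self.jaw_x1 - other.jaw_x1) <= tol
            and abs(self.jaw_x2 - other.jaw_x2) <= tol
            and abs(self.jaw_y - other.jaw_y) <= tol
            and abs(self.mu - other.mu) <= tol
            and abs(self.collimator_angle - other.collimator_angle) <= tol
            and np.allclose(self.tip_a, other.tip_a, atol=tol)
            and np.allclose(self.tip_b, other.tip_b, atol=tol)
        )


def build_reference_plan(mlc: MLCModel) -> PFPlan:
    """Reference picket-fence plan: 10 slits of 1 mm gap spaced 15 mm.

    The X jaw edges sit 15 mm outside the outer edges of the first and last
    slits (X1 = 75 mm, X2 = 91 mm); the symmetric Y aperture excludes two
    leaf pairs at each inplane end (360 mm for M120, 200 mm for HD120).
    100 MU, collimator at 0 degrees.
    """
    centers = np.asarray(SLIT_CENTERS)
    half_gap = NOMINAL_GAP / 2.0
    tip_a = np.tile((centers + half_gap)[:, None], (1, mlc.n_pairs))
    tip_b = np.tile((centers - half_gap)[:, None], (1, mlc.n_pairs))
    return PFPlan(
        mlc=mlc,
        slit_centers=SLIT_CENTERS,
        nominal_gap=NOMINAL_GAP,
        jaw_x1=abs(SLIT_CENTERS[0]) + half_gap + JAW_MARGIN,
        jaw_x2=SLIT_CENTERS[-1] + half_gap + JAW_MARGIN,
        jaw_y=_JAW_Y[mlc.name],
        mu=100.0,
        collimator_angle=0.0,
        tip_a=tip_a,
        tip_b=tip_b,
    )


_SCHEMA_VERSION = 1


def write_plan(plan: PFPlan, path) -> None:
    """Serialize a plan as structured YAML text with explicit units (mm, MU, deg)."""
    doc = {
        "pfqa_plan": {
            "schema_version": _SCHEMA_VERSION,
            "units": {"length": "mm", "angle": "deg", "output": "MU"},
            "mlc": plan.mlc.name,
            "slit_centers_mm": [float(c) for c in plan.slit_centers],
            "nominal_gap_mm": float(plan.nominal_gap),
            "jaw_x1_mm": float(plan.jaw_x1),
            "jaw_x2_mm": float(plan.jaw_x2),
            "jaw_y_mm": float(plan.jaw_y),
            "mu": float(plan.mu),
            "collimator_angle_deg": float(plan.collimator_angle),
            "tip_a_mm": plan.tip_a.tolist(),
            "tip_b_mm": plan.tip_b.tolist(),
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_plan(path) -> PFPlan:
    """Read a plan written by :func:`write_plan`, validating its invariants."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "pfqa_plan" not in doc:
        raise PlanParseError("missing top-level 'pfqa_plan' mapping")
    body = doc["pfqa_plan"]
    for key in (
        "schema_version",
        "mlc",
        "slit_centers_mm",
        "nominal_gap_mm",
        "jaw_x1_mm",
        "jaw_x2_mm",
        "jaw_y_mm",
        "mu",
        "collimator_angle_deg",
        "tip_a_mm",
        "tip_b_mm",
    ):
        if key not in body:
            raise PlanParseError(f"missing field '{key}'")
    if body["schema_version"] != _SCHEMA_VERSION:
        raise PlanParseError(f"unsupported schema_version {body['schema_version']}")
    mlc = build_mlc_model(body["mlc"])
    centers = body["slit_centers_mm"]
    if len(centers) != N_SLITS:
        raise PlanParseError(
            f"slit_centers_mm has {len(centers)} entries, expected {N_SLITS}"
        )
    tip_a = np.asarray(body["tip_a_mm"], dtype=float)
    tip_b = np.asarray(body["tip_b_mm"], dtype=float)
    expected = (N_SLITS, mlc.n_pairs)
    if tip_a.shape != expected:
        raise PlanParseError(f"tip_a_mm has shape {tip_a.shape}, expected {expected}")
    if tip_b.shape != expected:
        raise PlanParseError(f"tip_b_mm has shape {tip_b.shape}, expected {expected}")
    return PFPlan(
        mlc=mlc,
        slit_centers=tuple(float(c) for c in centers),
        nominal_gap=float(body["nominal_gap_mm"]),
        jaw_x1=float(body["jaw_x1_mm"]),
        jaw_x2=float(body["jaw_x2_mm"]),
        jaw_y=float(body["jaw_y_mm"]),
        mu=float(body["mu"]),
        collimator_angle=float(body["collimator_angle_deg"]),
        tip_a=tip_a,
        tip_b=tip_b,
    )
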