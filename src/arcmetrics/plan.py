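"""Data model for dual-arc VMAT plans.

A plan is an ordered list of arcs; an arc is an ordered list of control
points (gantry angle, MLC bank positions, cumulative meterset weight).
Monitor units (MU) delivered between consecutive control points follow
from the cumulative meterset weights and the arc's total MU.

Coordinate convention (IEC 61217, MLCX): leaf-edge positions are signed
millimetres along the leaf-travel axis.  ``left`` holds the bank-A edges
and ``right`` the bank-B edges, so the opening of leaf pair *n* is
``right[n] - left[n]`` and must be nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: openings more negative than this are validation errors; anything in
#: (-POSITION_SNAP_MM, 0) is snapped shut at construction time.
POSITION_SNAP_MM = 1e-3

#: leaf pairs with an opening at or below this gap (mm) count as closed.
DEFAULT_CLOSED_LEAF_GAP_MM = 0.5


class PlanValidationError(ValueError):
    """A plan violates a structural invariant (raised by strict loaders)."""


@dataclass
class MLCBankPositions:
    """Leaf-edge coordinates of both MLC banks at one control point.

    Parameters
    ----------
    left, right
        Leaf-edge coordinates in mm, one entry per leaf pair.  Equal
        length; ``right - left`` is the per-pair opening.
    leaf_width_mm
        Width of each leaf pair along the axis perpendicular to leaf
        travel.  Fixed to 5 mm for the MLC modelled here, overridable.
    """

    left: np.ndarray
    right: np.ndarray
    leaf_width_mm: float = 5.0

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.ndim != 1 or self.right.ndim != 1:
            raise PlanValidationError("bank positions must be 1-D arrays")
        if self.left.shape != self.right.shape:
            raise PlanValidationError(
                f"bank lengths differ: {self.left.size} vs {self.right.size}"
            )
        if self.left.size < 1:
            raise PlanValidationError("MLC banks need at least one leaf pair")
        # snap numerically-negative openings shut (DICOM round-off)
        gap = self.right - self.left
        tiny = (gap < 0) & (gap > -POSITION_SNAP_MM)
        if np.any(tiny):
            mid = 0.5 * (self.left[tiny] + self.right[tiny])
            self.left = self.left.copy()
            self.right = self.right.copy()
            self.left[tiny] = mid
            self.right[tiny] = mid

    @property
    def n_pairs(self) -> int:
        return int(self.left.size)

    @property
    def openings(self) -> np.ndarray:
        """Per-pair opening widths, mm (nonnegative for a valid plan)."""
        return self.right - self.left

    def open_pairs(self, closed_gap_mm: float = DEFAULT_CLOSED_LEAF_GAP_MM) -> np.ndarray:
        """Boolean mask of leaf pairs considered dosimetrically open."""
        return self.openings > closed_gap_mm


@dataclass
class ControlPoint:
    """Machine-state snapshot along an arc."""

    gantry_deg: float
    mlc: MLCBankPositions
    cum_weight: float
    collimator_deg: float = 0.0


@dataclass
class Arc:
    """One full 360-degree VMAT arc.

    ``increment_deg`` is the sector width used during optimisation (leaves
    reverse travel direction at sector boundaries); it is metadata here —
    control-point spacing is independent of it.
    """

    control_points: list[ControlPoint]
    arc_mu: float
    increment_deg: float
    direction: str = "CW"

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)

    @property
    def cum_weights(self) -> np.ndarray:
        return np.array([cp.cum_weight for cp in self.control_points], dtype=float)

    def gantry_span_deg(self) -> float:
        """Total gantry travel, unwrapping angles according to direction."""
        angles = np.array([cp.gantry_deg for cp in self.control_points], dtype=float)
        steps = np.diff(angles)
        if self.direction.upper() == "CW":
            steps = np.mod(steps, 360.0)
        else:
            steps = np.mod(-steps, 360.0)
        return float(steps.sum())


@dataclass
class Plan:
    """A treatment plan: arcs plus prescription metadata."""

    arcs: list[Arc]
    prescription_gy: float = 70.0
    fractions: int = 35
    group_label: str | None = None
    patient_id: str | None = None
    leaf_width_mm: float = field(default=5.0)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    @property
    def total_mu(self) -> float:
        return float(sum(a.arc_mu for a in self.arcs))


def segment_mu(arc: Arc) -> np.ndarray:
    """MU delivered in each inter-control-point segment of an arc.

    Element *j* is ``(w[j+1] - w[j]) * arc_mu``; the values sum to
    ``arc_mu`` exactly (up to floating point) because cumulative weights
    run from 0 to 1.
    """
    if arc.n_control_points < 2:
        raise PlanValidationError("an arc needs at least two control points")
    return np.diff(arc.cum_weights) * arc.arc_mu


#: canonical arc-increment combinations of the three study groups
GROUP_BY_INCREMENTS = {
    (30.0, 30.0): "A",
    (15.0, 15.0): "B",
    (15.0, 30.0): "C",
}


def infer_group_label(plan: Plan) -> str | None:
    """Map the plan's (sorted) arc increments to a study group, if any."""
    key = tuple(sorted(a.increment_deg for a in plan.arcs))
    return GROUP_BY_INCREMENTS.get(key)


def validate_plan(plan: Plan) -> list[str]:
    """Check every structural invariant; return a list of violations.

    An empty list means the plan is ready for metric computation.  The
    function never raises: it is a reporting operation.
    """
    problems: list[str] = []
    if plan.n_arcs < 1:
        problems.append("plan has no arcs")
    if plan.prescription_gy <= 0:
        problems.append(f"nonpositive prescription: {plan.prescription_gy} Gy")
    if plan.fractions < 1:
        problems.append(f"invalid fraction count: {plan.fractions}")
    if plan.n_arcs >= 1 and plan.total_mu <= 0:
        problems.append(f"nonpositive total MU: {plan.total_mu}")

    for k, arc in enumerate(plan.arcs):
        tag = f"arc {k}"
        if arc.n_control_points < 2:
            problems.append(f"{tag}: fewer than 2 control points")
            continue
        if arc.arc_mu <= 0:
            problems.append(f"{tag}: nonpositive arc MU {arc.arc_mu}")
        w = arc.cum_weights
        if abs(w[0]) > 1e-9:
            problems.append(f"{tag}: first cumulative weight is {w[0]}, not 0")
        if abs(w[-1] - 1.0) > 1e-9:
            problems.append(f"{tag}: last cumulative weight is {w[-1]}, not 1")
        drops = np.nonzero(np.diff(w) < -1e-12)[0]
        for j in drops:
            problems.append(
                f"{tag}: cumulative meterset weight decreases at control point {j + 1}"
            )
        span = arc.gantry_span_deg()
        if abs(span - 360.0) > 1e-6:
            problems.append(f"{tag}: gantry span {span:.3f} deg is not a full arc")
        for i, cp in enumerate(arc.control_points):
            gap = cp.mlc.openings
            bad = np.nonzero(gap < -POSITION_SNAP_MM)[0]
            for n in bad:
                problems.append(
                    f"{tag}, control point {i}: negative opening at leaf pair {n} "
                    f"({gap[n]:.3f} mm)"
                )
            if cp.mlc.leaf_width_mm <= 0:
                problems.append(f"{tag}, control point {i}: nonpositive leaf width")
    return problems
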