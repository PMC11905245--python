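"""MU-weighted MLC-aperture complexity metrics for VMAT plans.

Two metric families are computed from the control-point sequence:

* the modulation complexity score adapted to VMAT (Masi-style): per
  control point, leaf-sequence variability (LSV) and aperture-area
  variability (AAV); per arc, the MU-weighted pairwise-averaged product
  MCS_arc; per plan, MCS_v as the plain mean over arcs.  MCS_v = 1 means
  no modulation, values toward 0 mean heavy modulation.

* aperture-geometry metrics (Du-style): aperture area AA, perimeter AP
  and irregularity AI = AP^2 / (4*pi*AA) per control point; MU-weighted
  beam area/irregularity/modulation BA, BI, BM per arc (BM uses the
  union area U of all apertures in the arc); and MU-weighted plan
  aggregates PA, PI, PM.

All geometry treats the aperture as the union of per-leaf-pair
axis-aligned rectangles of height ``leaf_width_mm``; leaf pairs whose
gap is at or below the closed-pair threshold are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .plan import (
    Arc,
    DEFAULT_CLOSED_LEAF_GAP_MM,
    MLCBankPositions,
    Plan,
    segment_mu,
)


class DegenerateBeamError(ValueError):
    """Every aperture in the arc is closed; beam metrics are undefined."""


@dataclass
class ApertureGeometry:
    """Geometry of the MLC opening at one control point.

    ``irregularity`` is NaN when the aperture is fully closed (area 0);
    for any open aperture it is bounded below by 4/pi, the rectilinear
    isoperimetric limit attained by a square.
    """

    area_mm2: float
    perimeter_mm: float
    irregularity: float
    open_pair_count: int


@dataclass
class ArcComplexity:
    """Per-arc complexity breakdown."""

    mcs_arc: float
    lsv: np.ndarray
    aav: np.ndarray
    ba_mm2: float
    bi: float
    bm: float
    union_area_mm2: float
    arc_mu: float
    aav_degenerate: bool = False


@dataclass
class ComplexityResult:
    """Plan-level complexity metrics plus per-arc detail."""

    mcs_v: float
    total_mu: float
    pa_mm2: float
    pi: float
    pm: float
    per_arc: list[ArcComplexity] = field(default_factory=list)


# ---------------------------------------------------------------------------
# control-point phase
# ---------------------------------------------------------------------------

def _lsv_bank(pos: np.ndarray) -> float:
    """One bank's LSV factor: 1 - mean adjacent-leaf jump / position spread."""
    n = pos.size
    if n < 2:
        return 1.0
    pos_max = float(pos.max() - pos.min())
    if pos_max <= 0.0:
        # zero spread: no variability by convention (0/0 limit -> 1)
        return 1.0
    jumps = np.abs(np.diff(pos))
    return float(np.sum(pos_max - jumps) / ((n - 1) * pos_max))


def lsv_cp(
    mlc: MLCBankPositions,
    closed_gap_mm: float = DEFAULT_CLOSED_LEAF_GAP_MM,
) -> float:
    """Leaf-sequence variability of one control point, in [0, 1].

    Computed over the in-field (open) leaf pairs as the product of the
    two per-bank factors.  Fewer than two open pairs gives 1 by the
    zero-spread convention.
    """
    sel = mlc.open_pairs(closed_gap_mm)
    if sel.sum() < 2:
        return 1.0
    return _lsv_bank(mlc.left[sel]) * _lsv_bank(mlc.right[sel])


@dataclass
class ArcLeafExtents:
    """Per-leaf maximal bank excursions over one arc.

    ``max_right[a] - min_left[a]`` is the widest extent leaf pair *a*
    reaches anywhere in the arc (0 for a pair that never opens); the sum
    of extents is the AAV denominator shared by every control point of
    the arc.
    """

    min_left: np.ndarray
    max_right: np.ndarray

    @property
    def extents(self) -> np.ndarray:
        return self.max_right - self.min_left

    @property
    def total_extent(self) -> float:
        return float(self.extents.sum())


def arc_leaf_extents(
    arc: Arc, closed_gap_mm: float = DEFAULT_CLOSED_LEAF_GAP_MM
) -> ArcLeafExtents:
    """Per-leaf arc-maximal bank positions (closed pairs excluded)."""
    n = arc.control_points[0].mlc.n_pairs
    min_left = np.full(n, np.inf)
    max_right = np.full(n, -np.inf)
    for cp in arc.control_points:
        sel = cp.mlc.open_pairs(closed_gap_mm)
        min_left[sel] = np.minimum(min_left[sel], cp.mlc.left[sel])
        max_right[sel] = np.maximum(max_right[sel], cp.mlc.right[sel])
    never = ~np.isfinite(min_left)
    min_left[never] = 0.0
    max_right[never] = 0.0
    return ArcLeafExtents(min_left=min_left, max_right=max_right)


def aav_cp(
    mlc: MLCBankPositions,
    extents: ArcLeafExtents,
    closed_gap_mm: float = DEFAULT_CLOSED_LEAF_GAP_MM,
) -> float:
    """Aperture-area variability of one control point, in [0, 1].

    Ratio of the summed per-leaf openings at this control point to the
    summed per-leaf maximal extents over the whole arc.  Equals 1 when
    every pair sits at its arc-maximal excursion.  An all-closed arc
    (zero denominator) returns 1 by convention; callers that need to
    distinguish this flag it via :func:`arc_complexity`.
    """
    denom = extents.total_extent
    if denom <= 0.0:
        return 1.0
    sel = mlc.open_pairs(closed_gap_mm)
    num = float(mlc.openings[sel].sum())
    return num / denom


# ---------------------------------------------------------------------------
# aperture geometry
# ---------------------------------------------------------------------------

def aperture_geometry_cp(
    mlc: MLCBankPositions,
    closed_gap_mm: float = DEFAULT_CLOSED_LEAF_GAP_MM,
) -> ApertureGeometry:
    """Area, perimeter and irregularity of one control point's aperture.

    The aperture is the union of the open leaf-pair rectangles.  Its
    rectilinear perimeter has a closed form: each open pair contributes
    two lateral edges of length ``t`` plus its top and bottom opening
    widths, minus twice the x-overlap with each physically adjacent open
    pair (shared, interior edges).  Closed pairs split the opening into
    separate connected components whose perimeters simply add.
    """
    t = mlc.leaf_width_mm
    sel = mlc.open_pairs(closed_gap_mm)
    openings = np.where(sel, mlc.openings, 0.0)
    n_open = int(sel.sum())
    area = t * float(openings.sum())
    if n_open == 0:
        return ApertureGeometry(0.0, 0.0, float("nan"), 0)

    both_open = sel[:-1] & sel[1:]
    overlap = np.minimum(mlc.right[:-1], mlc.right[1:]) - np.maximum(
        mlc.left[:-1], mlc.left[1:]
    )
    overlap = np.where(both_open, np.maximum(overlap, 0.0), 0.0)
    perimeter = 2.0 * t * n_open + 2.0 * float(openings.sum()) - 2.0 * float(
        overlap.sum()
    )
    ai = perimeter**2 / (4.0 * math.pi * area)
    return ApertureGeometry(area, perimeter, ai, n_open)


def union_aperture_area(
    arc: Arc, closed_gap_mm: float = DEFAULT_CLOSED_LEAF_GAP_MM
) -> float:
    """Area of the union of every control point's aperture in an arc.

    Exact: per leaf row the union of the (at most I) open intervals is
    merged analytically and multiplied by the leaf width.
    """
    n = arc.control_points[0].mlc.n_pairs
    t = arc.control_points[0].mlc.leaf_width_mm
    total = 0.0
    for a in range(n):
        intervals = []
        for cp in arc.control_points:
            if cp.mlc.openings[a] > closed_gap_mm:
                intervals.append((float(cp.mlc.left[a]), float(cp.mlc.right[a])))
        if not intervals:
            continue
        intervals.sort()
        merged_len = 0.0
        lo, hi = intervals[0]
        for a_lo, a_hi in intervals[1:]:
            if a_lo > hi:
                merged_len += hi - lo
                lo, hi = a_lo, a_hi
            else:
                hi = max(hi, a_hi)
        merged_len += hi - lo
        total += t * merged_len
    return total


# ---------------------------------------------------------------------------
# arc phase
# ---------------------------------------------------------------------------

def _segment_scalars(values: np.ndarray, attribution: str) -> np.ndarray:
    """Map per-CP scalars to per-segment scalars.

    ``segment-mean`` averages the two bounding control points (the same
    pairwise structure MCS_arc uses); ``per-cp`` is handled by the
    caller through MU re-attribution instead.
    """
    if attribution != "segment-mean":
        raise ValueError(f"unknown attribution mode: {attribution}")
    return 0.5 * (values[:-1] + values[1:])


def beam_metrics(
    arc: Arc,
    closed_gap_mm: float = DEFAULT_CLOSED_LEAF_GAP_MM,
    attribution: str = "segment-mean",
) -> dict:
    """MU-weighted beam area, irregularity, modulation and union area.

    ``attribution`` chooses how segment MU meets control-point apertures:
    ``"segment-mean"`` (default) pairs each segment's MU with the mean of
    its two bounding apertures' scalars; ``"per-cp"`` splits each
    segment's MU half-and-half onto its bounding control points.
    Segments (or control points) with zero aperture area carry no
    irregularity; their MU is excluded from the BI average only.
    """
    mu_seg = segment_mu(arc)
    mu_arc = float(mu_seg.sum())
    geoms = [aperture_geometry_cp(cp.mlc, closed_gap_mm) for cp in arc.control_points]
    aa_cp = np.array([g.area_mm2 for g in geoms])
    ai_cp = np.array([g.irregularity for g in geoms])
    if not np.any(aa_cp > 0):
        raise DegenerateBeamError("every aperture in the arc is closed")

    if attribution == "per-cp":
        mu_w = np.zeros(arc.n_control_points)
        mu_w[:-1] += 0.5 * mu_seg
        mu_w[1:] += 0.5 * mu_seg
        aa_w, ai_w = aa_cp, ai_cp
    else:
        mu_w = mu_seg
        aa_w = _segment_scalars(aa_cp, attribution)
        # average AI over the bounding CPs where defined
        ai_pairs = np.stack([ai_cp[:-1], ai_cp[1:]])
        with np.errstate(invalid="ignore"):
            ai_w = np.nanmean(ai_pairs, axis=0)

    ba = float(np.sum(mu_w * aa_w) / mu_arc)
    defined = ~np.isnan(ai_w)
    mu_def = float(np.sum(mu_w[defined]))
    bi = float(np.sum(mu_w[defined] * ai_w[defined]) / mu_def) if mu_def > 0 else float("nan")
    union = union_aperture_area(arc, closed_gap_mm)
    bm = 1.0 - float(np.sum(mu_w * aa_w)) / (mu_arc * union)
    return {"ba": ba, "bi": bi, "bm": bm, "union_area": union}


def mcs_arc_from_components(
    lsv: np.ndarray, aav: np.ndarray, mu_segments: np.ndarray
) -> float:
    """MCS_arc from per-CP LSV/AAV arrays and per-segment MU.

    Sum over segments of the pairwise-averaged AAV times the pairwise-
    averaged LSV, weighted by the segment's share of arc MU.
    """
    lsv = np.asarray(lsv, dtype=float)
    aav = np.asarray(aav, dtype=float)
    mu = np.asarray(mu_segments, dtype=float)
    if lsv.size != aav.size or mu.size != lsv.size - 1:
        raise ValueError("need I control-point values and I-1 segment MUs")
    aav_seg = 0.5 * (aav[:-1] + aav[1:])
    lsv_seg = 0.5 * (lsv[:-1] + lsv[1:])
    return float(np.sum(aav_seg * lsv_seg * mu) / mu.sum())


def arc_complexity(
    arc: Arc,
    closed_gap_mm: float = DEFAULT_CLOSED_LEAF_GAP_MM,
    attribution: str = "segment-mean",
) -> ArcComplexity:
    """All per-arc complexity quantities for one arc."""
    extents = arc_leaf_extents(arc, closed_gap_mm)
    degenerate = extents.total_extent <= 0.0
    lsv = np.array([lsv_cp(cp.mlc, closed_gap_mm) for cp in arc.control_points])
    aav = np.array(
        [aav_cp(cp.mlc, extents, closed_gap_mm) for cp in arc.control_points]
    )
    mcs = mcs_arc_from_components(lsv, aav, segment_mu(arc))
    beam = beam_metrics(arc, closed_gap_mm, attribution)
    return ArcComplexity(
        mcs_arc=mcs,
        lsv=lsv,
        aav=aav,
        ba_mm2=beam["ba"],
        bi=beam["bi"],
        bm=beam["bm"],
        union_area_mm2=beam["union_area"],
        arc_mu=arc.arc_mu,
        aav_degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# plan phase
# ---------------------------------------------------------------------------

def mcs_plan(
    plan: Plan, closed_gap_mm: float = DEFAULT_CLOSED_LEAF_GAP_MM
) -> dict:
    """MCS_v (plain mean over arcs) and the per-arc MCS_arc values."""
    per_arc = []
    for arc in plan.arcs:
        extents = arc_leaf_extents(arc, closed_gap_mm)
        lsv = np.array([lsv_cp(cp.mlc, closed_gap_mm) for cp in arc.control_points])
        aav = np.array(
            [aav_cp(cp.mlc, extents, closed_gap_mm) for cp in arc.control_points]
        )
        per_arc.append(mcs_arc_from_components(lsv, aav, segment_mu(arc)))
    return {"mcs_v": float(np.mean(per_arc)), "mcs_arc": per_arc}


def plan_complexity(
    plan: Plan,
    closed_gap_mm: float = DEFAULT_CLOSED_LEAF_GAP_MM,
    attribution: str = "segment-mean",
) -> ComplexityResult:
    """Every plan-level complexity metric with per-arc detail.

    PA, PI and PM are the beam-level values averaged with weights equal
    to each arc's share of plan MU; MCS_v is the plain mean of MCS_arc.
    """
    per_arc = [arc_complexity(a, closed_gap_mm, attribution) for a in plan.arcs]
    mu = np.array([a.arc_mu for a in per_arc])
    mu_p = float(mu.sum())
    pa = float(np.sum([a.ba_mm2 * a.arc_mu for a in per_arc]) / mu_p)
    pi_ = float(np.sum([a.bi * a.arc_mu for a in per_arc]) / mu_p)
    pm = float(np.sum([a.bm * a.arc_mu for a in per_arc]) / mu_p)
    mcs_v = float(np.mean([a.mcs_arc for a in per_arc]))
    return ComplexityResult(
        mcs_v=mcs_v, total_mu=mu_p, pa_mm2=pa, pi=pi_, pm=pm, per_arc=per_arc
    )
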