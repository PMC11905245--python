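"""Complexity metrics against hand values and independent oracles."""

import math

import numpy as np
import pytest
from shapely.geometry import box
from shapely.ops import unary_union

from arcmetrics import (
    DegenerateBeamError,
    aav_cp,
    aperture_geometry_cp,
    arc_complexity,
    arc_leaf_extents,
    beam_metrics,
    generate_plan,
    lsv_cp,
    mcs_arc_from_components,
    mcs_plan,
    plan_complexity,
    segment_mu,
    union_aperture_area,
)
from conftest import make_arc, make_mlc, make_plan, random_arc, random_mlc
from oracles import brute_force_mcs_arc, raster_perimeter


def shapely_arc_union(arc, closed_gap=0.5):
    """Union area of every control point's open rectangles via shapely."""
    t = arc.control_points[0].mlc.leaf_width_mm
    rects = []
    for cp in arc.control_points:
        for a in range(cp.mlc.n_pairs):
            if cp.mlc.openings[a] > closed_gap:
                rects.append(
                    box(cp.mlc.left[a], a * t, cp.mlc.right[a], (a + 1) * t)
                )
    return unary_union(rects).area if rects else 0.0


# ---------------------------------------------------------------------------
# LSV
# ---------------------------------------------------------------------------

class TestLSV:
    def test_zero_spread_convention(self):
        assert lsv_cp(make_mlc([5.0, 5.0, 5.0], [25.0, 25.0, 25.0])) == 1.0

    def test_maximal_adjacent_jump_gives_zero(self):
        assert lsv_cp(make_mlc([0.0, 10.0], [20.0, 20.0])) == 0.0

    def test_hand_evaluated_three_pair_case(self):
        # left spread 10, jumps 5+5 -> (5+5)/(2*10) = 0.5 per bank
        assert lsv_cp(make_mlc([0.0, 5.0, 10.0], [20.0, 25.0, 30.0])) == pytest.approx(0.25)

    def test_bounds_on_random_apertures(self, rng):
        for _ in range(200):
            v = lsv_cp(random_mlc(rng, n_pairs=int(rng.integers(1, 12))))
            assert 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# AAV
# ---------------------------------------------------------------------------

class TestAAV:
    def test_arc_maximal_aperture_scores_one(self):
        wide = make_mlc([-10.0, -10.0], [10.0, 10.0])
        narrow = make_mlc([-5.0, -5.0], [5.0, 5.0])
        arc = make_arc([wide, narrow, wide])
        ext = arc_leaf_extents(arc)
        assert aav_cp(wide, ext) == pytest.approx(1.0)

    def test_half_open_scores_half(self):
        # openings [5, 5] against arc-wide maxima [10, 10]
        wide = make_mlc([-5.0, -5.0], [5.0, 5.0])
        half = make_mlc([-2.5, -2.5], [2.5, 2.5])
        ext = arc_leaf_extents(make_arc([wide, half]))
        assert aav_cp(half, ext) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_arcs(self, rng):
        for _ in range(20):
            arc = random_arc(rng, n_cp=3, n_pairs=6)
            _, _, aav_oracle = brute_force_mcs_arc(arc)
            ext = arc_leaf_extents(arc)
            ours = [aav_cp(cp.mlc, ext) for cp in arc.control_points]
            np.testing.assert_allclose(ours, aav_oracle, rtol=1e-12)
            assert np.all((aav_oracle >= 0) & (aav_oracle <= 1 + 1e-12))


# ---------------------------------------------------------------------------
# aperture geometry
# ---------------------------------------------------------------------------

class TestApertureGeometry:
    def test_area_is_leaf_sum(self):
        geo = aperture_geometry_cp(make_mlc([0.0] * 3, [10.0] * 3))
        assert geo.area_mm2 == pytest.approx(150.0)

    def test_square_reaches_isoperimetric_floor(self):
        geo = aperture_geometry_cp(make_mlc([0.0] * 4, [20.0] * 4))
        assert geo.area_mm2 == pytest.approx(400.0)
        assert geo.perimeter_mm == pytest.approx(80.0)
        assert geo.irregularity == pytest.approx(80.0**2 / (4 * math.pi * 400.0))
        assert geo.irregularity == pytest.approx(4.0 / math.pi)

    def test_staircase_matches_raster_oracle(self):
        mlc = make_mlc([0.0, 0.0, 0.0], [10.0, 20.0, 10.0])
        geo = aperture_geometry_cp(mlc)
        assert geo.perimeter_mm == pytest.approx(raster_perimeter(mlc), abs=1e-9)

    def test_random_apertures_match_raster_oracle(self, rng):
        for _ in range(10):
            mlc = random_mlc(rng, n_pairs=6)
            geo = aperture_geometry_cp(mlc)
            if geo.open_pair_count == 0:
                continue
            # raster snaps edges to 0.1 mm; allow that much per edge
            assert geo.perimeter_mm == pytest.approx(
                raster_perimeter(mlc), abs=0.2 * 4 * 6
            )
            assert geo.irregularity >= 4.0 / math.pi - 1e-12

    def test_closed_aperture_has_undefined_irregularity(self):
        geo = aperture_geometry_cp(make_mlc([0.0, 5.0], [0.0, 5.0]))
        assert geo.area_mm2 == 0.0 and math.isnan(geo.irregularity)


class TestUnionArea:
    def test_union_bounds(self, rng):
        for _ in range(20):
            arc = random_arc(rng, n_cp=4, n_pairs=6)
            areas = [aperture_geometry_cp(cp.mlc).area_mm2 for cp in arc.control_points]
            u = union_aperture_area(arc)
            assert u >= max(areas) - 1e-9
            assert u <= sum(areas) + 1e-9

    def test_matches_shapely(self, rng):
        for _ in range(10):
            arc = random_arc(rng, n_cp=4, n_pairs=6)
            assert union_aperture_area(arc) == pytest.approx(
                shapely_arc_union(arc), rel=1e-9
            )


# ---------------------------------------------------------------------------
# beam and plan phases
# ---------------------------------------------------------------------------

class TestBeamMetrics:
    def test_static_aperture_has_zero_modulation(self):
        mlc = make_mlc([-10.0] * 4, [10.0] * 4)
        arc = make_arc([mlc] * 3, weights=[0.0, 0.3, 1.0])
        res = beam_metrics(arc)
        assert res["bm"] == pytest.approx(0.0, abs=1e-12)
        assert res["union_area"] == pytest.approx(aperture_geometry_cp(mlc).area_mm2)

    def test_disjoint_equal_apertures_give_half_modulation(self):
        left_ap = make_mlc([-30.0, -30.0], [-10.0, -10.0])
        right_ap = make_mlc([10.0, 10.0], [30.0, 30.0])
        arc = make_arc([left_ap, left_ap, right_ap], weights=[0.0, 0.5, 1.0])
        res = beam_metrics(arc)
        assert res["union_area"] == pytest.approx(2 * 200.0)
        assert res["bm"] == pytest.approx(0.5)

    def test_ba_matches_direct_sum_oracle(self, rng):
        for _ in range(20):
            arc = random_arc(rng, n_cp=5, n_pairs=6, closed_prob=0.1)
            areas = [aperture_geometry_cp(cp.mlc).area_mm2 for cp in arc.control_points]
            mu = segment_mu(arc)
            expect = sum(
                m * 0.5 * (areas[j] + areas[j + 1]) for j, m in enumerate(mu)
            ) / mu.sum()
            assert beam_metrics(arc)["ba"] == pytest.approx(expect, rel=1e-12)

    def test_all_closed_arc_rejected(self):
        closed = make_mlc([0.0, 0.0], [0.0, 0.0])
        with pytest.raises(DegenerateBeamError):
            beam_metrics(make_arc([closed, closed]))

    def test_per_cp_attribution_agrees_for_static_plan(self):
        mlc = make_mlc([-10.0] * 4, [10.0] * 4)
        arc = make_arc([mlc] * 3, weights=[0.0, 0.7, 1.0])
        seg = beam_metrics(arc, attribution="segment-mean")
        cp = beam_metrics(arc, attribution="per-cp")
        assert seg["ba"] == pytest.approx(cp["ba"])


class TestMCS:
    def test_hand_evaluated_two_point_arc(self):
        val = mcs_arc_from_components([1.0, 0.5], [1.0, 0.5], [1.0])
        assert val == pytest.approx(0.75 * 0.75)

    def test_plan_mean_is_unweighted(self):
        # MCS_v is the plain 1/K mean regardless of arc MU
        plan = generate_plan(5, (30.0, 15.0), 0.8)
        per_arc = mcs_plan(plan)["mcs_arc"]
        assert mcs_plan(plan)["mcs_v"] == pytest.approx(np.mean(per_arc))

    def test_static_plan_is_exactly_one(self):
        plan = generate_plan(9, (30.0, 30.0), 0.0)
        assert mcs_plan(plan)["mcs_v"] == 1.0

    def test_matches_brute_force_on_random_arcs(self, rng):
        for _ in range(20):
            arc = random_arc(rng, n_cp=5, n_pairs=6)
            oracle, lsv_o, _ = brute_force_mcs_arc(arc)
            res = arc_complexity(arc)
            np.testing.assert_allclose(res.lsv, lsv_o, rtol=1e-12)
            assert res.mcs_arc == pytest.approx(oracle, rel=1e-12)
            assert 0.0 < res.mcs_arc <= 1.0


class TestPlanComplexity:
    def test_pa_is_mu_weighted_mean_of_beam_areas(self):
        a1 = make_arc([make_mlc([0.0] * 4, [15.0] * 4)] * 2, arc_mu=100.0)
        a2 = make_arc([make_mlc([0.0] * 4, [20.0] * 4)] * 2, arc_mu=100.0)
        res = plan_complexity(make_plan([a1, a2]))
        assert res.pa_mm2 == pytest.approx(0.5 * (300.0 + 400.0))
        assert res.pm == pytest.approx(0.0, abs=1e-12)
        assert res.mcs_v == 1.0

    def test_invariant_under_mu_rescaling(self):
        plan = generate_plan(13, (30.0, 15.0), 0.7)
        base = plan_complexity(plan)
        for arc in plan.arcs:
            arc.arc_mu *= 3.7
        scaled = plan_complexity(plan)
        for attr in ("mcs_v", "pa_mm2", "pi", "pm"):
            assert getattr(scaled, attr) == pytest.approx(getattr(base, attr), rel=1e-12)
        assert scaled.total_mu == pytest.approx(3.7 * base.total_mu)

    def test_cp_values_bounded_on_generated_plans(self):
        plan = generate_plan(17, (15.0, 15.0), 1.0)
        res = plan_complexity(plan)
        for arc_res in res.per_arc:
            assert np.all((arc_res.lsv >= 0) & (arc_res.lsv <= 1))
            assert np.all((arc_res.aav >= 0) & (arc_res.aav <= 1 + 1e-12))
        assert 0.0 < res.mcs_v <= 1.0
        assert 0.0 <= res.pm < 1.0
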