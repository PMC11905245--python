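"""Synthetic cohort generator: kinematics, determinism, dose phantoms."""

import numpy as np
import pytest
from scipy import stats as sps

from arcmetrics import (
    CohortSpec,
    compute_dvh,
    d_at_volume,
    generate_cohort,
    generate_dose_phantom,
    generate_plan,
    leaf_travel_reversals,
    mcs_plan,
    normalize_to_coverage,
    ptv_indices,
    sample_anatomy,
    validate_plan,
)


class TestPlanKinematics:
    def test_sector_count_and_reversals(self):
        """A 30-deg increment splits a full arc into 12 sectors; leaves
        reverse direction at each of the 11 interior boundaries."""
        plan = generate_plan(3, (30.0, 30.0), 0.8, cp_spacing_deg=2.0)
        arc = plan.arcs[0]
        assert 360.0 / arc.increment_deg == 12
        open_rows = [
            a for a in range(40)
            if arc.control_points[0].mlc.openings[a] > 0.5
        ]
        for a in open_rows[:5]:
            assert leaf_travel_reversals(arc, a, "left") == 11
            assert leaf_travel_reversals(arc, a, "right") == 11

    def test_fifteen_degree_increment_has_23_reversals(self):
        plan = generate_plan(3, (15.0, 15.0), 0.8)
        arc = plan.arcs[0]
        a = next(
            i for i in range(40) if arc.control_points[0].mlc.openings[i] > 0.5
        )
        assert leaf_travel_reversals(arc, a, "left") == 23

    def test_zero_modulation_is_static(self):
        plan = generate_plan(7, (30.0, 15.0), 0.0)
        first = plan.arcs[0].control_points[0].mlc
        for arc in plan.arcs:
            for cp in arc.control_points:
                np.testing.assert_array_equal(cp.mlc.left, first.left)
                np.testing.assert_array_equal(cp.mlc.right, first.right)
        assert mcs_plan(plan)["mcs_v"] == 1.0

    def test_deterministic_for_fixed_seed(self):
        p1 = generate_plan(123, (30.0, 15.0), 0.7)
        p2 = generate_plan(123, (30.0, 15.0), 0.7)
        for a1, a2 in zip(p1.arcs, p2.arcs):
            assert a1.arc_mu == a2.arc_mu
            for c1, c2 in zip(a1.control_points, a2.control_points):
                np.testing.assert_array_equal(c1.mlc.left, c2.mlc.left)
                np.testing.assert_array_equal(c1.mlc.right, c2.mlc.right)
                assert c1.cum_weight == c2.cum_weight

    def test_spacing_must_divide_increment(self):
        with pytest.raises(ValueError, match="does not divide"):
            generate_plan(1, (30.0, 15.0), 0.5, cp_spacing_deg=2.0)

    def test_generated_plans_validate_clean(self):
        for seed, inc in [(1, (30.0, 30.0)), (2, (15.0, 15.0)), (3, (30.0, 15.0))]:
            assert validate_plan(generate_plan(seed, inc, 0.9)) == []


class TestModulationOrdering:
    def test_mcs_decreases_with_modulation_level(self):
        levels = np.linspace(0.1, 1.0, 5)
        seeds = range(10)
        lv, mv = [], []
        for level in levels:
            for s in seeds:
                lv.append(level)
                mv.append(mcs_plan(generate_plan(s, (30.0, 30.0), level))["mcs_v"])
        rho = sps.spearmanr(lv, mv).statistic
        assert rho < -0.5

    def test_finer_increments_are_more_modulated(self):
        a = [mcs_plan(generate_plan(s, (30.0, 30.0), 0.7))["mcs_v"] for s in range(10)]
        b = [mcs_plan(generate_plan(s, (15.0, 15.0), 0.7))["mcs_v"] for s in range(10)]
        assert np.mean(b) < np.mean(a)


class TestDosePhantom:
    @pytest.fixture
    def spec(self):
        return CohortSpec(seed=0, grid_spacing_mm=4.0)

    def test_gi_matches_analytic_shell_ratio(self):
        """With a homogeneous PTV the 50% isodose radius is known in
        closed form: d50 = falloff * ln(2 m)."""
        spec = CohortSpec(seed=0, grid_spacing_mm=2.0, homogeneity_sd=0.0,
                          dose_noise_sd=0.0)
        anatomy = sample_anatomy(np.random.default_rng(4), spec.anatomy_ranges)
        dose, masks = generate_dose_phantom(5, "A", anatomy, spec)
        idx = ptv_indices(dose, masks["ptv"], spec.prescription_gy)
        m = spec.peripheral_scale["A"]
        d50 = spec.falloff_mm * np.log(2.0 * m)
        analytic = ((anatomy.ptv_radius_mm + d50) / anatomy.ptv_radius_mm) ** 3
        assert idx["GI"] == pytest.approx(analytic, rel=0.02)

    def test_zero_homogeneity_gives_zero_hi(self):
        spec = CohortSpec(seed=0, grid_spacing_mm=4.0, homogeneity_sd=0.0)
        anatomy = sample_anatomy(np.random.default_rng(4), spec.anatomy_ranges)
        dose, masks = generate_dose_phantom(5, "B", anatomy, spec)
        idx = ptv_indices(dose, masks["ptv"], spec.prescription_gy)
        assert idx["HI"] == 0.0

    def test_group_c_spares_cord_for_every_patient(self, spec):
        cohort = generate_cohort(
            CohortSpec(n_patients=3, seed=9, grid_spacing_mm=4.0),
            groups=("A", "C"),
        )
        for patient in cohort.patients:
            doses = {}
            for g in ("A", "C"):
                dose, masks = patient.doses[g]
                normed = normalize_to_coverage(dose, masks["ptv"], 70.0)
                dvh = compute_dvh(normed, masks["spinal_cord"])
                doses[g] = d_at_volume(dvh, 0.03)
            assert doses["C"] < doses["A"]

    def test_overlapping_anatomy_is_pushed_out(self):
        ranges = dict(CohortSpec().anatomy_ranges)
        ranges["cord_distance_mm"] = (10.0, 12.0)  # would sit inside the PTV
        with pytest.warns(UserWarning, match="overlaps the PTV"):
            anatomy = sample_anatomy(np.random.default_rng(0), ranges)
        assert anatomy.cord_distance_mm > anatomy.ptv_radius_mm


class TestCohortAssembly:
    def test_default_spec_shape(self):
        spec = CohortSpec(seed=1)
        assert spec.n_patients == 10 and set(spec.groups) == {"A", "B", "C"}

    def test_minimal_cohort_runs(self):
        cohort = generate_cohort(
            CohortSpec(n_patients=1, seed=5, grid_spacing_mm=4.0)
        )
        assert len(cohort.patients) == 1
        assert set(cohort.patients[0].plans) == {"A", "B", "C"}
        manifest = cohort.manifest()
        assert manifest["patients"] == ["P01"]
        assert "seed" in str(manifest["spec"])

    def test_cohort_reproducible_and_paired(self):
        spec = CohortSpec(n_patients=2, seed=17, grid_spacing_mm=4.0)
        c1 = generate_cohort(spec, include_dose=False)
        c2 = generate_cohort(spec, include_dose=False)
        for pat1, pat2 in zip(c1.patients, c2.patients):
            assert pat1.anatomy == pat2.anatomy
            for g in ("A", "B", "C"):
                a1 = pat1.plans[g].arcs[0]
                a2 = pat2.plans[g].arcs[0]
                assert a1.arc_mu == a2.arc_mu

    def test_group_subset_preserves_pairing(self):
        spec = CohortSpec(n_patients=2, seed=17, grid_spacing_mm=4.0)
        full = generate_cohort(spec, include_dose=False)
        subset = generate_cohort(spec, include_dose=False, groups=("A", "C"))
        for pf, ps in zip(full.patients, subset.patients):
            assert set(ps.plans) == {"A", "C"}
            assert pf.plans["C"].arcs[0].arc_mu == ps.plans["C"].arcs[0].arc_mu

    def test_invalid_increment_rejected(self):
        with pytest.raises(ValueError, match="not in"):
            CohortSpec(groups={"A": (20.0, 30.0)})
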