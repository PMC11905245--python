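"""Synthetic paired cohort: dual-arc plans and analytic dose phantoms.

The generator emulates the study design this package analyzes: each
synthetic patient receives three dual-arc head-and-neck VMAT plans that
differ only in their arc-increment combination — 30/30 (group A), 15/15
(group B) and 30/15 (group C) — prescribed 70 Gy in 35 fractions, plus
a matching dose phantom with a spherical PTV and organ-at-risk masks
(spinal cord, brain stem, both parotid glands) placed at clinically
plausible center-to-center distances.

Plan kinematics follow the sector picture of arc-increment VMAT
optimisation: a 360-degree arc with sector width equal to the increment
has ``S = 360/increment`` sectors, leaves sweep monotonically within a
sector and reverse direction at each of the ``S - 1`` interior sector
boundaries.  Smaller increments allow the optimiser proportionally
deeper leaf excursions, which the generator mirrors by scaling the
sweep amplitude with sector density (amplitude ~ 30/increment).  At
``modulation_level = 0`` every control point shows the same rectangular
aperture.

Dose phantoms are analytic fields, not beam transport: the PTV receives
the prescription with a controllable inhomogeneity, and dose outside
falls off exponentially with distance from the PTV surface, scaled by a
group-dependent peripheral factor.  The group effect on organ-at-risk
dose is therefore multiplicative and its expected size is known in
closed form (:meth:`CohortSpec.injected_reduction_percent`), which is
what parameter-recovery tests check against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .dose import DoseGrid, StructureMask
from .plan import Arc, ControlPoint, MLCBankPositions, Plan

#: anatomy sampling ranges (mm), spanning the spread of a ten-patient
#: head-and-neck cohort: PTV volume and OAR center-to-center distances.
DEFAULT_ANATOMY_RANGES = {
    "ptv_volume_cc": (323.0, 772.0),
    "cord_distance_mm": (53.0, 94.0),
    "brainstem_distance_mm": (98.0, 139.0),
    "parotid_l_distance_mm": (69.0, 120.0),
    "parotid_r_distance_mm": (78.0, 106.0),
}

OAR_NAMES = ("spinal_cord", "brain_stem", "parotid_l", "parotid_r")


@dataclass
class Anatomy:
    """Sampled patient geometry (PTV at the origin, mm)."""

    ptv_radius_mm: float
    cord_distance_mm: float
    brainstem_distance_mm: float
    parotid_l_distance_mm: float
    parotid_r_distance_mm: float


@dataclass
class CohortSpec:
    """Study-shaped cohort configuration.

    Defaults reproduce the study conditions: 10 patients, three paired
    plans each (A = 30/30, B = 15/15, C = 30/15 degree increments), 70
    Gy in 35 fractions, 2.5-degree control-point spacing (the coarsest spacing dividing both sector widths), 2-mm dose grid.
    The effect model gives group C the lowest peripheral dose scale, so
    organ-at-risk doses drop by a known multiplicative factor.
    """

    n_patients: int = 10
    seed: int = 0
    groups: dict = field(
        default_factory=lambda: {"A": (30.0, 30.0), "B": (15.0, 15.0), "C": (30.0, 15.0)}
    )
    cp_spacing_deg: float = 2.5
    prescription_gy: float = 70.0
    fractions: int = 35
    modulation_level: float = 0.7
    n_leaf_pairs: int = 40
    leaf_width_mm: float = 5.0
    grid_spacing_mm: float = 2.0
    anatomy_ranges: dict = field(default_factory=lambda: dict(DEFAULT_ANATOMY_RANGES))
    #: peripheral dose scale just outside the PTV, per group
    peripheral_scale: dict = field(
        default_factory=lambda: {"A": 0.80, "B": 0.74, "C": 0.60}
    )
    falloff_mm: float = 40.0
    dose_noise_sd: float = 0.05
    homogeneity_sd: float = 0.015

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        for g, (inc1, inc2) in self.groups.items():
            for inc in (inc1, inc2):
                if inc not in (15.0, 30.0):
                    raise ValueError(f"group {g}: arc increment {inc} not in {{15, 30}}")
                if (inc / self.cp_spacing_deg) % 1 != 0:
                    raise ValueError(
                        f"cp spacing {self.cp_spacing_deg} does not divide increment {inc}"
                    )

    def injected_reduction_percent(self, reference: str, comparison: str) -> float:
        """Expected percent reduction in OAR dose between two groups.

        OAR dose scales as ``peripheral_scale * exp(eps)`` with
        ``eps ~ N(0, dose_noise_sd^2)`` independently per plan, so the
        expected ratio of comparison to reference dose at any fixed
        point is ``(m_cmp / m_ref) * exp(dose_noise_sd^2)``.
        """
        m_ref = self.peripheral_scale[reference]
        m_cmp = self.peripheral_scale[comparison]
        return 100.0 * (1.0 - (m_cmp / m_ref) * np.exp(self.dose_noise_sd**2))


# ---------------------------------------------------------------------------
# plan generation
# ---------------------------------------------------------------------------

#: base half-field and sweep geometry of the synthetic aperture (mm)
_BASE_LEFT = -40.0
_BASE_RIGHT = 40.0
_SWEEP_AMPLITUDE = 18.0
_BASE_ARC_MU = 550.0


def _arc_leaf_offsets(
    rng: np.random.Generator,
    n_open: int,
    n_sectors: int,
    amplitude: float,
) -> np.ndarray:
    """Per-leaf offsets at each sector knot, alternating in sign.

    Returns shape (n_open, n_sectors + 1).  Leaf *a* swings between
    ``+A_a * m`` and ``-A_a * m`` at successive knots (random magnitude
    ``m`` per knot), which makes its travel monotone inside every sector
    and reverse direction exactly at each interior boundary.
    """
    amp = amplitude * rng.uniform(0.3, 1.0, size=n_open)
    sign = rng.choice([-1.0, 1.0], size=n_open)
    mags = rng.uniform(0.5, 1.0, size=(n_open, n_sectors + 1))
    alt = (-1.0) ** np.arange(n_sectors + 1)
    return sign[:, None] * amp[:, None] * mags * alt[None, :]


def generate_arc(
    rng: np.random.Generator,
    increment_deg: float,
    modulation_level: float,
    cp_spacing_deg: float = 2.5,
    n_leaf_pairs: int = 40,
    leaf_width_mm: float = 5.0,
    direction: str = "CW",
    collimator_deg: float = 45.0,
    start_angle_deg: float = 180.0,
) -> Arc:
    """One full synthetic arc with sector-reversal leaf kinematics."""
    if (increment_deg / cp_spacing_deg) % 1 != 0:
        raise ValueError(
            f"cp spacing {cp_spacing_deg} does not divide increment {increment_deg}"
        )
    n_sectors = int(round(360.0 / increment_deg))
    n_cp = int(round(360.0 / cp_spacing_deg)) + 1

    open_rows = np.arange(n_leaf_pairs // 2 - 10, n_leaf_pairs // 2 + 11)
    # optimisers exploit finer sectors with proportionally deeper sweeps
    amplitude = modulation_level * _SWEEP_AMPLITUDE * (30.0 / increment_deg)
    off_left = _arc_leaf_offsets(rng, open_rows.size, n_sectors, amplitude)
    off_right = _arc_leaf_offsets(rng, open_rows.size, n_sectors, amplitude)

    seg_w = rng.uniform(0.5, 1.5, size=n_cp - 1)
    cum = np.concatenate([[0.0], np.cumsum(seg_w)]) / seg_w.sum()
    cum[-1] = 1.0
    arc_mu = _BASE_ARC_MU * (1.0 + 0.25 * modulation_level) * float(
        rng.lognormal(0.0, 0.08)
    )

    sweep = np.arange(n_cp) * cp_spacing_deg
    sgn = 1.0 if direction.upper() == "CW" else -1.0
    cps: list[ControlPoint] = []
    for i, theta in enumerate(sweep):
        sector = min(int(theta // increment_deg), n_sectors - 1)
        u = (theta - sector * increment_deg) / increment_deg
        f = 0.5 * (1.0 - np.cos(np.pi * u))  # monotone ease within the sector
        d_left = off_left[:, sector] * (1 - f) + off_left[:, sector + 1] * f
        d_right = off_right[:, sector] * (1 - f) + off_right[:, sector + 1] * f

        left = np.zeros(n_leaf_pairs)
        right = np.zeros(n_leaf_pairs)
        left[open_rows] = _BASE_LEFT + d_left
        right[open_rows] = _BASE_RIGHT + d_right
        squeeze = right[open_rows] - left[open_rows] < 1.0
        if np.any(squeeze):  # never triggered at default geometry
            mid = 0.5 * (left[open_rows][squeeze] + right[open_rows][squeeze])
            left[open_rows[squeeze]] = mid - 0.5
            right[open_rows[squeeze]] = mid + 0.5
        cps.append(
            ControlPoint(
                gantry_deg=float((start_angle_deg + sgn * theta) % 360.0),
                cum_weight=float(cum[i]),
                collimator_deg=collimator_deg,
                mlc=MLCBankPositions(left, right, leaf_width_mm),
            )
        )
    return Arc(
        control_points=cps,
        arc_mu=arc_mu,
        increment_deg=increment_deg,
        direction=direction,
    )


def generate_plan(
    patient_seed: int | np.random.SeedSequence,
    increments: tuple[float, float],
    modulation_level: float,
    cp_spacing_deg: float = 2.5,
    n_leaf_pairs: int = 40,
    leaf_width_mm: float = 5.0,
    prescription_gy: float = 70.0,
    fractions: int = 35,
    group_label: str | None = None,
    patient_id: str | None = None,
) -> Plan:
    """A dual-arc plan with the given arc-increment combination.

    Deterministic for a fixed seed.  ``modulation_level`` in [0, 1]
    scales the leaf-sweep amplitude; 0 yields a static rectangular
    aperture at every control point.
    """
    if not 0.0 <= modulation_level <= 1.0:
        raise ValueError("modulation_level must lie in [0, 1]")
    rng = np.random.default_rng(patient_seed)
    arcs = []
    for k, inc in enumerate(increments):
        arcs.append(
            generate_arc(
                rng,
                increment_deg=inc,
                modulation_level=modulation_level,
                cp_spacing_deg=cp_spacing_deg,
                n_leaf_pairs=n_leaf_pairs,
                leaf_width_mm=leaf_width_mm,
                direction="CW" if k % 2 == 0 else "CCW",
                collimator_deg=45.0 if k % 2 == 0 else 315.0,
                start_angle_deg=180.0,
            )
        )
    return Plan(
        arcs=arcs,
        prescription_gy=prescription_gy,
        fractions=fractions,
        group_label=group_label,
        patient_id=patient_id,
        leaf_width_mm=leaf_width_mm,
    )


def leaf_travel_reversals(arc: Arc, pair_index: int, bank: str = "left") -> int:
    """Count direction changes of one leaf's trajectory over the arc."""
    traj = np.array(
        [
            cp.mlc.left[pair_index] if bank == "left" else cp.mlc.right[pair_index]
            for cp in arc.control_points
        ]
    )
    steps = np.diff(traj)
    signs = np.sign(steps[np.abs(steps) > 1e-9])
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs) != 0))


# ---------------------------------------------------------------------------
# dose phantom
# ---------------------------------------------------------------------------

_CORD_RADIUS = 7.5
_CORD_HALFLEN = 50.0
_BS_SEMI = (25.0, 15.0, 15.0)   # (z, y, x) semi-axes
_PG_SEMI = (25.0, 20.0, 15.0)
_BS_DIR = np.array([0.937, -0.35, 0.0])     # (z, y, x) unit direction
_PG_DIR = np.array([0.30, -0.25, 0.92])     # x sign flips for left/right


def sample_anatomy(rng: np.random.Generator, ranges: dict | None = None) -> Anatomy:
    """Draw one patient's geometry, conditioned on PTV/OAR clearance.

    Center-to-center distances are sampled within their configured range
    but above the no-overlap floor implied by the sampled PTV radius
    (spherical PTVs need more standoff than real, non-spherical targets
    of equal volume).  A range that cannot clear the PTV at all is
    clamped to the floor with a warning.
    """
    r = ranges or DEFAULT_ANATOMY_RANGES
    vol = rng.uniform(*r["ptv_volume_cc"])
    radius = (3.0 * vol * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    clearance = 4.0
    floors = {
        "cord_distance_mm": radius + _CORD_RADIUS + clearance,
        "brainstem_distance_mm": radius + max(_BS_SEMI) + clearance,
        "parotid_l_distance_mm": radius + max(_PG_SEMI) + clearance,
        "parotid_r_distance_mm": radius + max(_PG_SEMI) + clearance,
    }
    distances = {}
    for attr, floor in floors.items():
        lo, hi = r[attr]
        if floor > hi:
            warnings.warn(
                f"{attr} range ({lo}, {hi}) overlaps the PTV; pushed out to "
                f"{floor:.1f} mm",
                stacklevel=2,
            )
            distances[attr] = floor
        else:
            distances[attr] = float(rng.uniform(max(lo, floor), hi))
    return Anatomy(ptv_radius_mm=radius, **distances)


def _structure_centers(anatomy: Anatomy) -> dict[str, np.ndarray]:
    return {
        "spinal_cord": np.array([0.0, -anatomy.cord_distance_mm, 0.0]),
        "brain_stem": _BS_DIR * anatomy.brainstem_distance_mm,
        "parotid_l": _PG_DIR * anatomy.parotid_l_distance_mm,
        "parotid_r": _PG_DIR * np.array([1.0, 1.0, -1.0]) * anatomy.parotid_r_distance_mm,
    }


def generate_dose_phantom(
    patient_seed: int | np.random.SeedSequence,
    group_label: str,
    anatomy: Anatomy,
    spec: CohortSpec | None = None,
) -> tuple[DoseGrid, dict[str, StructureMask]]:
    """Analytic dose field plus voxel masks for one plan.

    The PTV (sphere at the origin) receives the prescription modulated
    by a smooth inhomogeneity field; dose outside the PTV is
    ``rx * m_g * exp(eps) * exp(-d / falloff)`` with ``d`` the distance
    to the PTV surface, ``m_g`` the group's peripheral scale and ``eps``
    per-plan lognormal noise.  The returned grid is unnormalised; run
    :func:`arcmetrics.dose.normalize_to_coverage` before extracting
    metrics, as a planning system would.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(patient_seed)
    rx = spec.prescription_gy
    R = anatomy.ptv_radius_mm
    centers = _structure_centers(anatomy)

    # grid bounds: every structure plus a falloff margin
    pad = 12.0
    los = [np.array([-R, -R, -R])]
    his = [np.array([R, R, R])]
    half = {
        "spinal_cord": np.array([_CORD_HALFLEN, _CORD_RADIUS, _CORD_RADIUS]),
        "brain_stem": np.array(_BS_SEMI),
        "parotid_l": np.array(_PG_SEMI),
        "parotid_r": np.array(_PG_SEMI),
    }
    for name, c in centers.items():
        los.append(c - half[name])
        his.append(c + half[name])
    lo = np.min(los, axis=0) - pad
    hi = np.max(his, axis=0) + pad

    sp = spec.grid_spacing_mm
    z = np.arange(lo[0], hi[0] + sp, sp)
    y = np.arange(lo[1], hi[1] + sp, sp)
    x = np.arange(lo[2], hi[2] + sp, sp)
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")

    r = np.sqrt(Z**2 + Y**2 + X**2)
    ptv = r <= R
    d_out = np.maximum(r - R, 0.0)

    # smooth inhomogeneity: a few random cosine modes, unit variance
    n_modes = 4
    g = np.zeros_like(r)
    for _ in range(n_modes):
        k_dir = rng.normal(size=3)
        k_dir /= np.linalg.norm(k_dir)
        k_mag = 2.0 * np.pi / rng.uniform(60.0, 120.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        g += np.cos(k_mag * (k_dir[0] * Z + k_dir[1] * Y + k_dir[2] * X) + phase)
    g /= np.sqrt(n_modes / 2.0)

    eps = float(rng.normal(0.0, spec.dose_noise_sd))
    m_g = spec.peripheral_scale[group_label] * np.exp(eps)
    dose = np.where(
        ptv,
        rx * (1.0 + spec.homogeneity_sd * g),
        rx * m_g * np.exp(-d_out / spec.falloff_mm),
    )
    dose = np.maximum(dose, 0.0)
    grid = DoseGrid(dose, (sp, sp, sp), tuple(float(v) for v in lo))

    masks = {"ptv": StructureMask("ptv", ptv)}
    c = centers["spinal_cord"]
    masks["spinal_cord"] = StructureMask(
        "spinal_cord",
        (np.sqrt((Y - c[1]) ** 2 + (X - c[2]) ** 2) <= _CORD_RADIUS)
        & (np.abs(Z - c[0]) <= _CORD_HALFLEN),
    )
    for name, semi in (("brain_stem", _BS_SEMI), ("parotid_l", _PG_SEMI), ("parotid_r", _PG_SEMI)):
        c = centers[name]
        masks[name] = StructureMask(
            name,
            ((Z - c[0]) / semi[0]) ** 2
            + ((Y - c[1]) / semi[1]) ** 2
            + ((X - c[2]) / semi[2]) ** 2
            <= 1.0,
        )
    return grid, masks


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    patient_id: str
    anatomy: Anatomy
    plans: dict[str, Plan] = field(default_factory=dict)
    doses: dict[str, tuple[DoseGrid, dict[str, StructureMask]]] = field(
        default_factory=dict
    )


@dataclass
class Cohort:
    spec: CohortSpec
    patients: list[PatientRecord]

    def manifest(self) -> dict:
        """Everything needed to regenerate the cohort bit-for-bit."""
        spec_doc = asdict(self.spec)
        return {
            "spec": spec_doc,
            "patients": [p.patient_id for p in self.patients],
            "seed_scheme": (
                "SeedSequence(spec.seed).spawn(n_patients); per patient, child 0 "
                "draws anatomy and children (1 + 2i, 2 + 2i) drive the plan and "
                "dose phantom of the i-th group (groups in spec order)"
            ),
        }


def generate_cohort(
    spec: CohortSpec,
    include_dose: bool = True,
    include_plans: bool = True,
    groups: tuple[str, ...] | None = None,
) -> Cohort:
    """Generate the full paired cohort (plans, and optionally phantoms).

    All randomness flows from ``spec.seed`` through a documented
    seed-splitting scheme, so the same spec always reproduces the same
    cohort.  ``groups`` restricts generation to a subset of the paired
    groups (the pairing structure is preserved: skipped groups consume
    no randomness of the kept ones).
    """
    group_names = list(spec.groups)
    keep = set(groups if groups is not None else group_names)
    root = np.random.SeedSequence(spec.seed)
    patients = []
    for p_idx, pseq in enumerate(root.spawn(spec.n_patients)):
        children = pseq.spawn(1 + 2 * len(group_names))
        anatomy = sample_anatomy(np.random.default_rng(children[0]))
        record = PatientRecord(patient_id=f"P{p_idx + 1:02d}", anatomy=anatomy)
        for g_idx, g in enumerate(group_names):
            if g not in keep:
                continue
            plan_seq = children[1 + 2 * g_idx]
            dose_seq = children[2 + 2 * g_idx]
            if include_plans:
                record.plans[g] = generate_plan(
                    plan_seq,
                    increments=spec.groups[g],
                    modulation_level=spec.modulation_level,
                    cp_spacing_deg=spec.cp_spacing_deg,
                    n_leaf_pairs=spec.n_leaf_pairs,
                    leaf_width_mm=spec.leaf_width_mm,
                    prescription_gy=spec.prescription_gy,
                    fractions=spec.fractions,
                    group_label=g,
                    patient_id=record.patient_id,
                )
            if include_dose:
                record.doses[g] = generate_dose_phantom(
                    dose_seq, g, anatomy, spec
                )
        patients.append(record)
    return Cohort(spec=spec, patients=patients)
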