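"""Dose grids, structure masks, DVHs and PTV quality indices.

The dose substrate is a 3-D scalar grid (Gy) with uniform spacing;
structures are boolean voxel masks congruent with the grid (voxel-center
membership, no partial volumes).  From these the module computes
cumulative DVHs, the standard D_x% / D_xcc / V_y% queries, the coverage
normalisation (prescription covers 95% of the PTV), and three scalar
plan-quality indices on the target:

* conformity number  CN = (V_T,ref / V_T) * (V_T,ref / V_ref)
* homogeneity index  HI = (D_2% - D_98%) / D_50%
* gradient index     GI = V_50% / V_100%

where V_ref and V_y% are measured over the entire dose grid and V_T,ref
is the PTV volume covered by the prescription isodose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class EmptyStructureError(ValueError):
    """The structure mask selects no voxels."""


@dataclass
class DoseGrid:
    """3-D dose distribution.

    ``values`` is indexed ``[z, y, x]``; ``spacing_mm`` is the matching
    ``(dz, dy, dx)`` voxel pitch and ``origin_mm`` the position of voxel
    (0, 0, 0) in patient coordinates.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dose grid must be 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("negative dose values")

    @property
    def voxel_volume_cc(self) -> float:
        dz, dy, dx = self.spacing_mm
        return dz * dy * dx / 1000.0

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.values * factor, self.spacing_mm, self.origin_mm)


@dataclass
class StructureMask:
    """Voxelized region congruent with a dose grid."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    def volume_cc(self, dose: DoseGrid) -> float:
        if self.mask.shape != dose.values.shape:
            raise ValueError(
                f"mask {self.name}: shape {self.mask.shape} does not match dose "
                f"grid {dose.values.shape}"
            )
        return float(self.mask.sum()) * dose.voxel_volume_cc


@dataclass
class CumulativeDVH:
    """Cumulative dose-volume histogram of one structure.

    ``volume_cc[k]`` is the exact volume receiving at least
    ``dose_edges_gy[k]``; between edges the curve is interpolated
    linearly.  ``min_dose_gy``/``max_dose_gy`` are the raw voxel extrema
    and bound every dose query (so uniform regions resolve exactly).
    """

    structure: str
    dose_edges_gy: np.ndarray
    volume_cc: np.ndarray
    min_dose_gy: float
    max_dose_gy: float

    @property
    def total_volume_cc(self) -> float:
        return float(self.volume_cc[0])


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_gy: float = 0.01) -> CumulativeDVH:
    """Cumulative DVH of ``mask`` at resolution ``bin_gy``."""
    if bin_gy <= 0:
        raise ValueError("bin width must be positive")
    if mask.mask.shape != dose.values.shape:
        raise ValueError("mask and dose grid are not congruent")
    voxels = dose.values[mask.mask]
    if voxels.size == 0:
        raise EmptyStructureError(f"empty structure: {mask.name}")
    dmax = float(voxels.max())
    edges = np.arange(0.0, dmax + 2 * bin_gy, bin_gy)
    sorted_doses = np.sort(voxels)
    # volume receiving >= edge, exact at every edge
    at_or_above = voxels.size - np.searchsorted(sorted_doses, edges, side="left")
    return CumulativeDVH(
        structure=mask.name,
        dose_edges_gy=edges,
        volume_cc=at_or_above * dose.voxel_volume_cc,
        min_dose_gy=float(voxels.min()),
        max_dose_gy=dmax,
    )


def d_at_volume(dvh: CumulativeDVH, volume_cc: float) -> float:
    """Dose (Gy) such that exactly ``volume_cc`` receives at least it.

    Piecewise-linear inverse of the cumulative curve, ties broken toward
    the higher-dose edge; the result is clamped to the raw voxel dose
    range, which makes degenerate (uniform) structures exact.
    """
    if volume_cc > dvh.total_volume_cc + 1e-12:
        raise ValueError(
            f"requested volume {volume_cc} cc exceeds structure volume "
            f"{dvh.total_volume_cc} cc"
        )
    vols = dvh.volume_cc
    edges = dvh.dose_edges_gy
    # last edge with volume >= target (ties -> higher dose)
    idx = int(np.nonzero(vols >= volume_cc - 1e-12)[0][-1])
    if idx == len(vols) - 1 or vols[idx] <= volume_cc:
        d = edges[idx]
    else:
        v0, v1 = vols[idx], vols[idx + 1]
        frac = (v0 - volume_cc) / (v0 - v1)
        d = edges[idx] + frac * (edges[idx + 1] - edges[idx])
    return float(np.clip(d, dvh.min_dose_gy, dvh.max_dose_gy))


def d_at_percent(dvh: CumulativeDVH, percent: float) -> float:
    """D_x%: dose received by the hottest ``percent`` of the structure."""
    if not 0 < percent <= 100:
        raise ValueError("percent must lie in (0, 100]")
    return d_at_volume(dvh, dvh.total_volume_cc * percent / 100.0)


def v_at_dose(dvh: CumulativeDVH, dose_gy: float) -> float:
    """Volume (cc) of the structure receiving at least ``dose_gy``."""
    if dose_gy <= dvh.dose_edges_gy[0]:
        return dvh.total_volume_cc
    if dose_gy > dvh.max_dose_gy:
        return 0.0
    return float(np.interp(dose_gy, dvh.dose_edges_gy, dvh.volume_cc))


def dose_mean(dose: DoseGrid, mask: StructureMask) -> float:
    """Mean structure dose from the raw voxels (no binning bias)."""
    voxels = dose.values[mask.mask]
    if voxels.size == 0:
        raise EmptyStructureError(f"empty structure: {mask.name}")
    return float(voxels.mean())


def volume_at_least(dose: DoseGrid, threshold_gy: float) -> float:
    """Volume (cc) of the *whole grid* receiving at least ``threshold_gy``."""
    return float(np.count_nonzero(dose.values >= threshold_gy)) * dose.voxel_volume_cc


def normalize_to_coverage(
    dose: DoseGrid,
    ptv: StructureMask,
    rx_gy: float,
    coverage_percent: float = 95.0,
    bin_gy: float = 0.01,
) -> DoseGrid:
    """Rescale so the prescription covers ``coverage_percent`` of the PTV.

    Returns a new grid scaled by ``rx / D_95%(PTV)``; afterwards
    D_95%(PTV) equals the prescription within one DVH bin (exactly, for
    a dose uniform over the PTV).
    """
    dvh = compute_dvh(dose, ptv, bin_gy)
    d_cov = d_at_percent(dvh, coverage_percent)
    if d_cov <= 0:
        raise ValueError(
            f"D_{coverage_percent:g}% of the PTV is zero; cannot normalize"
        )
    return dose.scaled(rx_gy / d_cov)


def ptv_indices(
    dose: DoseGrid,
    ptv: StructureMask,
    rx_gy: float,
    bin_gy: float = 0.01,
    normalize: bool = False,
) -> dict:
    """Conformity number, homogeneity index and gradient index.

    Expects an already-normalized dose unless ``normalize=True``, in
    which case the 95%-coverage normalisation is applied first.
    """
    if normalize:
        dose = normalize_to_coverage(dose, ptv, rx_gy, bin_gy=bin_gy)

    v_t = ptv.volume_cc(dose)
    v_ref = volume_at_least(dose, rx_gy)
    v_t_ref = float(np.count_nonzero(dose.values[ptv.mask] >= rx_gy)) * dose.voxel_volume_cc
    cn = 0.0 if v_ref == 0 else (v_t_ref / v_t) * (v_t_ref / v_ref)

    dvh = compute_dvh(dose, ptv, bin_gy)
    d2 = d_at_percent(dvh, 2.0)
    d98 = d_at_percent(dvh, 98.0)
    d50 = d_at_percent(dvh, 50.0)
    hi = (d2 - d98) / d50

    v100 = v_ref
    if v100 == 0:
        raise ValueError("V_100% is zero; gradient index undefined")
    v50 = volume_at_least(dose, 0.5 * rx_gy)
    gi = v50 / v100
    return {"CN": cn, "HI": hi, "GI": gi, "V_ref_cc": v_ref, "V_50_cc": v50}
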