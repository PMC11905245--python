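"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — explicit loops, literal
enumeration, pixel marching — and shares no code with the implementation
it verifies.
"""

import itertools

import numpy as np
from scipy import stats as sps

from arcmetrics import segment_mu


def raster_perimeter(mlc, closed_gap=0.5, pixel=0.1):
    """Pixel-marching perimeter of the aperture union: count exposed faces."""
    sel = mlc.open_pairs(closed_gap)
    if not sel.any():
        return 0.0
    x0 = float(mlc.left[sel].min()) - 1.0
    x1 = float(mlc.right[sel].max()) + 1.0
    nx = int(round((x1 - x0) / pixel))
    rows_per_pair = int(round(mlc.leaf_width_mm / pixel))
    img = np.zeros((mlc.n_pairs * rows_per_pair, nx), dtype=bool)
    for a in range(mlc.n_pairs):
        if not sel[a]:
            continue
        c0 = int(round((mlc.left[a] - x0) / pixel))
        c1 = int(round((mlc.right[a] - x0) / pixel))
        img[a * rows_per_pair:(a + 1) * rows_per_pair, c0:c1] = True
    pad = np.pad(img, 1)
    faces = 0
    for axis in (0, 1):
        faces += np.count_nonzero(np.diff(pad, axis=axis))
    return faces * pixel


def brute_force_mcs_arc(arc, closed_gap=0.5):
    """Independent re-derivation: explicit loops over banks, leaves, CPs.

    Returns (mcs_arc, lsv per CP, aav per CP).
    """
    cps = arc.control_points
    n = cps[0].mlc.n_pairs
    ext_left, ext_right = {}, {}
    for a in range(n):
        lefts = [cp.mlc.left[a] for cp in cps if cp.mlc.openings[a] > closed_gap]
        rights = [cp.mlc.right[a] for cp in cps if cp.mlc.openings[a] > closed_gap]
        ext_left[a] = min(lefts) if lefts else 0.0
        ext_right[a] = max(rights) if rights else 0.0
    denom = sum(ext_right[a] - ext_left[a] for a in range(n))

    lsv, aav = [], []
    for cp in cps:
        open_idx = [a for a in range(n) if cp.mlc.openings[a] > closed_gap]
        if len(open_idx) < 2:
            lsv.append(1.0)
        else:
            factors = []
            for bank in ("left", "right"):
                pos = [getattr(cp.mlc, bank)[a] for a in open_idx]
                pmax = max(pos) - min(pos)
                if pmax <= 0:
                    factors.append(1.0)
                    continue
                s = sum(pmax - abs(pos[i] - pos[i + 1]) for i in range(len(pos) - 1))
                factors.append(s / ((len(pos) - 1) * pmax))
            lsv.append(factors[0] * factors[1])
        if denom <= 0:
            aav.append(1.0)
        else:
            aav.append(sum(cp.mlc.openings[a] for a in open_idx) / denom)

    mu = segment_mu(arc)
    total = 0.0
    for j in range(len(cps) - 1):
        total += 0.5 * (aav[j] + aav[j + 1]) * 0.5 * (lsv[j] + lsv[j + 1]) * mu[j]
    return total / arc.arc_mu, np.array(lsv), np.array(aav)


def brute_force_beam_area(arc, areas):
    """MU-weighted beam area by direct summation over segments."""
    mu = segment_mu(arc)
    return sum(m * 0.5 * (areas[j] + areas[j + 1]) for j, m in enumerate(mu)) / mu.sum()


def enumeration_wilcoxon(x, y):
    """Two-sided exact p by literally enumerating all 2^m sign patterns."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=m)
        ]
    )
    tol = 1e-9
    cdf = np.mean(w_all <= w_obs + tol)
    sf = np.mean(w_all >= w_obs - tol)
    return min(1.0, 2.0 * min(cdf, sf))


def sort_oracle_d_at_volume(voxels, voxel_cc, volume_cc):
    """Dose such that `volume_cc` receives at least it, by direct sort."""
    k = max(int(np.ceil(volume_cc / voxel_cc)), 1)
    return float(np.sort(voxels)[::-1][k - 1])
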