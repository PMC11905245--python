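# Methods

`arcmetrics` analyzes dual-arc VMAT treatment plans along two axes: how
good the dose distribution is (dose-volumetric indices on the target and
organs at risk) and how hard the MLC has to work to deliver it
(aperture-complexity metrics). A synthetic cohort generator produces
paired plans and dose phantoms so the whole pipeline — including the
paired statistics — is testable end to end without patient data.

## Plan model

A plan is a list of full 360° arcs; an arc is an ordered list of control
points, each holding the gantry angle, the two MLC bank positions (one
leaf-edge coordinate per leaf pair, IEC 61217 MLCX convention, opening =
bank-B edge − bank-A edge ≥ 0) and the cumulative meterset weight in
[0, 1]. MU delivered in segment *j* is `(w[j+1] − w[j]) · MU_arc`, which
telescopes to the arc MU. Leaf pairs with a gap at or below 0.5 mm
(configurable) are treated as closed: real MLCs park closed pairs with a
small dosimetric gap, and all aperture geometry is defined over the open
pairs. No jaw model is carried, so "in field" means "open" — plans whose
modulation relies on jaw tracking are outside the model. Openings
negative by less than 1 µm (DICOM round-off) are snapped shut at load;
larger negative openings are validation errors.

## Complexity metrics

Per control point:

* **LSV** (leaf-sequence variability): for each bank,
  `Σ_n (pos_max − |pos_n − pos_{n+1}|) / ((N−1)·pos_max)` over the N open
  pairs, where `pos_max` is that bank's position spread; the two bank
  factors are multiplied. A bank with zero spread contributes factor 1
  (the 0/0 limit must make an unmodulated plan score 1), and fewer than
  two open pairs gives LSV = 1 by the same convention.
* **AAV** (aperture-area variability): summed per-leaf openings divided
  by the summed per-leaf maximal excursions over the whole arc
  (per-bank extrema taken leaf by leaf). Equals 1 when every leaf sits
  at its arc-wide extreme; an all-closed arc returns 1 with a degenerate
  flag. The source formula is typographically ambiguous about whether
  bank means or per-leaf sums are intended; we sum per-leaf openings,
  the construction used in the original MCS literature.
* **AA / AP / AI**: aperture area is `t · Σ openings` (leaf width t,
  default 5 mm). The aperture is a union of axis-aligned rectangles, one
  per open pair, so its perimeter has an exact closed form: each open
  pair contributes `2t` plus its top and bottom widths minus twice the
  x-overlap with each physically adjacent open pair. Closed pairs split
  the aperture into components whose perimeters add. Irregularity is
  `AP²/(4π·AA)`, bounded below by 4/π (square), undefined (NaN) for a
  closed aperture.

Per arc: `MCS_arc = Σ_j ((AAV_j+AAV_{j+1})/2) · ((LSV_j+LSV_{j+1})/2) ·
MU_j/MU_arc`; beam area/irregularity `BA, BI` are MU-weighted means, and
beam modulation `BM = 1 − Σ_j MU_j·AA_j / (MU_arc · U)` with `U` the
union area of all apertures in the arc. `U` is computed exactly by
merging, per leaf row, the open intervals contributed by every control
point (tests verify against a shapely polygon union and a 0.1 mm raster
oracle). The source tables index apertures by control point but MU by
segment; by default a segment takes the mean of its two bounding
apertures' scalars (the same pairwise structure MCS_arc uses), with a
`per-cp` switch that instead splits each segment's MU half-and-half onto
its bounding control points. Segments with zero aperture area carry no
irregularity and are excluded from the BI average only.

Per plan: `PA/PI/PM` are arc values weighted by each arc's share of plan
MU. `MCS_v` is the plain 1/K mean over arcs, exactly as the source
defines it, *not* MU-weighted (some literature differs). MCS_v = 1 means
no modulation; values toward 0 mean heavy modulation.

## Dose metrics

Dose lives on a uniform 3-D grid (Gy); structures are voxel-center
boolean masks (no partial volumes), matching the 2 mm grids clinical
systems export. The cumulative DVH stores the exact at-or-above volume
at every bin edge (default bin 0.01 Gy); `D_x%`, `D_xcc` and `V_y%`
queries interpolate linearly between edges with ties broken toward the
higher dose, and results are clamped to the raw voxel dose range so
uniform regions resolve exactly. `D_mean` always comes from raw voxels,
never the binned curve. Queried quantities therefore agree with a direct
voxel sort to within one bin width (tested at 0.1 and 0.01 Gy).

Plans are normalized so 100% of the prescription covers 95% of the PTV:
the grid is scaled by `rx / D_95%(PTV)`. The PTV indices are

* conformity number `CN = (V_T,ref/V_T) · (V_T,ref/V_ref)`,
* homogeneity index `HI = (D_2% − D_98%) / D_50%`,
* gradient index `GI = V_50% / V_100%`,

with `V_ref` and `V_y%` measured over the *entire* grid by exact voxel
counting (they are defined as total covered volumes, not per-structure
quantities). Limits behave as required: a prescription isodose equal to
the PTV gives CN = 1; a binary step field gives GI = 1 and HI = 0; on a
spherical phantom with radial falloff GI matches the analytic shell
ratio within 2% voxelization error.

## Paired statistics

Groups are compared with the paired two-sided Wilcoxon signed-rank test.
Zero differences are dropped before ranking (Wilcoxon's original
convention — the add-in software used in typical clinical analyses does
not document this level of detail, so we fix it explicitly); tied
absolute differences receive average ranks. For m ≤ 25 remaining pairs
the p-value is exact: the null distribution of the positive-rank sum is
built by convolving the doubled ranks, which enumerates all 2^m sign
assignments implicitly; the two-sided p doubles the smaller tail, capped
at 1. Above m = 25 a normal approximation with continuity and tie
corrections is used (within 0.01 of exact at the boundary for untied
data). Percent reductions are `100·(ref − cmp)/ref`, reported to one
decimal. No multiple-testing correction is applied by default, mirroring
common practice for this design (each comparison judged at p < 0.05); a
Holm option exists but is off.

## Synthetic cohort

Each synthetic patient gets three dual-arc plans differing only in the
arc-increment combination — A = 30°/30°, B = 15°/15°, C = 30°/15° — at
70 Gy / 35 fractions, collimator 45°/315°, and a matching dose phantom.
Defaults: 10 patients, 40 leaf pairs of 5 mm, control points every 2.5°
(the coarsest spacing dividing both sector widths), 2 mm dose grid.

**Plan kinematics.** An arc with increment `inc` has `S = 360/inc`
sectors. Each leaf is assigned a random amplitude and sign per arc and
swings between alternating-sign offsets at the sector knots, with a
cosine ease in between: travel is monotone inside every sector and
reverses exactly at the S−1 interior boundaries. The sweep amplitude
scales with `modulation_level` (0 = static rectangular aperture, MCS_v
exactly 1) and with sector density (∝ 30/inc), emulating an optimizer
that exploits finer sectors with deeper modulation; consequently 15°/15°
plans average lower MCS_v than 30°/30° ones, reproducing the direction
(not the TPS-specific magnitude) of the increment effect. Segment MU
weights are uniform random; arc MU grows mildly with modulation.

**Dose phantoms.** Analytic fields, not beam transport. The spherical
PTV (volume sampled from 323–772 cc) receives the prescription times
`1 + h·g(x)` with `g` a smooth unit-variance cosine field and
`h = 0.015` (giving HI ≈ 0.06); dose outside falls off as
`rx · m_group · exp(eps) · exp(−d/40 mm)` with `d` the distance to the
PTV surface, `eps ~ N(0, 0.05²)` per plan, and peripheral scales
`m_A = 0.80, m_B = 0.74, m_C = 0.60`. Because the group effect is a
pure scale, the expected A→C reduction of any OAR dose statistic is
`1 − (m_C/m_A)·e^{σ²} ≈ 24.8%`, independent of anatomy and voxel size —
the closed-form target the parameter-recovery test checks — and sits in
the 20–26% band clinical comparisons of these increment combinations
report. OAR masks (spinal-cord cylinder, brain-stem and parotid
ellipsoids) are placed at center-to-center distances sampled
conditional on a 4 mm clearance from the PTV (a spherical PTV needs
more standoff than a real, non-spherical target of equal volume); a
distance range that cannot clear the PTV at all is clamped to the
clearance floor with a warning. The grid auto-sizes to the structures plus a 12 mm margin.

All randomness flows from one cohort seed via `numpy.random.SeedSequence`
spawning (one child per patient; grandchildren for anatomy and for each
group's plan and phantom), so any subset of groups regenerates
identically and every output is reproducible from the manifest.

**What the phantom does not emulate.** No beam transport, no
arc-geometry coupling between plan modulation and the dose field, OAR
falloff identical in every direction, and a dose discontinuity at the
PTV surface. Passing tests therefore demonstrate that the *metric and
statistics pipeline* is correct and recovers known injected effects at
study scale; they say nothing about whether a real optimizer produces
such effects.

## Problem sizes and runtimes

Unit tests use toy arcs (2–5 control points, ≤ 12 leaf pairs) and small
grids (≤ 12³ voxels). The analytic-limit checks run on 100³ voxel grids.
The parameter-recovery study uses 200 replicate cohorts of 10 patients,
groups A and C, on a 4 mm phantom grid — about a minute on one core;
these sizes are the package's own choice of simulation budget and are
easily raised through `CohortSpec`.

## Known limitations

* No jaw or interdigitation model; machine deliverability is out of scope.
* Fractional-volume (partial voxel) masks are not supported.
* The DICOM writers produce minimal, standard-conformant objects for
  round-tripping and testing, not clinically deliverable plans.
* MCS_v aggregation follows the plain 1/K mean; comparing against
  MU-weighted MCS_v values from other software requires care.
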