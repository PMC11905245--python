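# arcmetrics

Plan-quality and MLC-aperture complexity analysis for dual-arc VMAT
radiotherapy plans.

In volumetric-modulated arc therapy (VMAT) the optimizer splits each
360° gantry rotation into sectors of a chosen *arc increment*; the MLC
leaves reverse travel direction at sector boundaries, so the increment
controls how much modulation a plan can carry. Comparing increment
combinations (e.g. 30°/30° vs 15°/15° vs a mixed 30°/15° pair of arcs)
requires two kinds of numbers per plan, and paired statistics across
plans. `arcmetrics` computes both, for medical physicists and for
anyone building planning-study tooling:

* **Dose-volumetric indices** from a 3-D dose grid and structure masks:
  cumulative DVHs with `D_x%`, `D_0.03cc`, `V_y%` queries, `D_mean`,
  the coverage normalisation (prescription covers 95% of the PTV), and
  the PTV indices

  - conformity number `CN = (V_T,ref / V_T) · (V_T,ref / V_ref)`
  - homogeneity index `HI = (D_2% − D_98%) / D_50%`
  - gradient index `GI = V_50% / V_100%`

* **Complexity metrics** from the control-point sequence, MU-weighted
  at every level: leaf-sequence and aperture-area variability (LSV,
  AAV) and the modulation complexity score `MCS_arc`/`MCS_v`; aperture
  area/perimeter/irregularity (`AA`, `AP`, `AI = AP²/4πAA`); beam- and
  plan-level aggregates `BA/BI/BM` and `PA/PI/PM` (with `BM` defined
  against the union area of all apertures in the arc).

* **Paired group comparison**: mean ± SD tables and exact two-sided
  Wilcoxon signed-rank p-values (full sign-assignment enumeration for
  n ≤ 25, ties and zeros handled explicitly), plus percent-reduction
  summaries.

Plans are read from DICOM RT Plan files or a plain-JSON fixture dialect
(`src/arcmetrics/schemas/plan_fixture.schema.json`); dose grids and
structures from DICOM RT Dose / RT Structure Set or `.npz` bundles. A
synthetic cohort generator produces paired dual-arc plans with correct
sector-reversal kinematics and analytic dose phantoms with a known,
group-dependent organ-at-risk effect, so every stage is testable
without patient data. See `docs/methods.md` for the model details.

## Worked example

Simulate a small paired cohort (4 patients × groups A/B/C, 4 mm
phantom grid) and run the full analysis:

```python
from arcmetrics import CohortSpec, RunConfig, run_pipeline

spec = CohortSpec(n_patients=4, seed=3, grid_spacing_mm=4.0)
tables = run_pipeline(RunConfig(mode="simulate", cohort=spec, out_dir="out"))
print(tables["percent_reductions"].to_string(index=False))
```

prints

```
                metric reference_group comparison_group  percent_reduction
spinal_cord_d003cc_cgy               A                C               26.7
spinal_cord_d003cc_cgy               B                C               21.3
 brain_stem_d003cc_cgy               A                C               26.8
 brain_stem_d003cc_cgy               B                C               21.5
   parotid_l_dmean_cgy               A                C               25.1
   parotid_l_dmean_cgy               B                C               20.7
   parotid_r_dmean_cgy               A                C               25.4
   parotid_r_dmean_cgy               B                C               20.7
```

i.e. group C (30°/15°) spares each organ at risk by ≈ 21–27% relative
to groups A and B — the generator injects a known ≈ 24.8% A→C effect
(see `docs/methods.md`), and the pipeline recovers it. The comparison
tables carry the group means, SDs and paired p-values, e.g.

```
                          mean_A    mean_B    mean_C  p_A-B  p_A-C  p_B-C
spinal_cord_d003cc_cgy  3542.480  3300.001  2596.029   0.25  0.125  0.125
gi                         2.995     2.686     1.729   0.25  0.125  0.125
cn                         0.950     0.950     0.950   1.00  0.500  1.000
```

(at n = 4 the smallest attainable two-sided exact p is 2/2⁴ = 0.125;
run 10 patients for study-scale power). `out/` then contains
`plan_metrics.csv`, rounded and full-precision comparison tables,
`percent_reductions.csv` and a `run_log.yaml` with the seeds and config
needed to reproduce the run byte-for-byte.

The same analysis is available from a shell:

```bash
arcmetrics simulate --patients 10 --seed 1 --out-dir out
arcmetrics complexity plan1.json plan2.dcm
arcmetrics compare out/plan_metrics.csv
```

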