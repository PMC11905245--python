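"""End-to-end orchestration: cohort -> metrics -> comparison reports.

``run_pipeline`` takes a :class:`RunConfig`, obtains plans (simulated,
JSON fixtures or DICOM RT Plans), computes per-plan complexity and —
when dose grids exist — dose-volumetric metrics, then writes:

* ``plan_metrics.csv`` — one row per plan, full precision;
* ``complexity_comparison.csv`` / ``dose_comparison.csv`` — group mean,
  SD and pairwise Wilcoxon p-values, rounded to reporting precision,
  each with a ``*_full.csv`` full-precision companion;
* ``percent_reductions.csv`` — percent reductions of group C relative
  to A and B for the organ-at-risk metrics;
* ``run_log.yaml`` — config echo plus the cohort manifest.

Doses are reported in cGy (indices unitless), matching clinical
reporting conventions: doses rounded to 0.1 cGy, indices to 0.01,
percentages to 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .cohort import Cohort, CohortSpec, OAR_NAMES, generate_cohort
from .complexity import plan_complexity
from .dose import (
    DoseGrid,
    StructureMask,
    compute_dvh,
    d_at_volume,
    dose_mean,
    normalize_to_coverage,
    ptv_indices,
)
from .io import load_plan_fixture, load_rtplan
from .plan import Plan, validate_plan
from .stats import comparison_frame, percent_reduction, summarize_and_compare

#: parotid-gland mean-dose planning constraint (Gy), flagged informationally
PAROTID_MEAN_CONSTRAINT_GY = 26.0

DOSE_METRIC_COLUMNS = [
    "ptv_d003cc_cgy", "cn", "hi", "gi",
    "spinal_cord_d003cc_cgy", "spinal_cord_dmean_cgy",
    "brain_stem_d003cc_cgy", "brain_stem_dmean_cgy",
    "parotid_l_d003cc_cgy", "parotid_l_dmean_cgy",
    "parotid_r_d003cc_cgy", "parotid_r_dmean_cgy",
]
COMPLEXITY_COLUMNS = ["mcs_v", "mu", "pa_mm2", "pi", "pm"]

#: organ-at-risk metrics whose group-C reductions are summarized
REDUCTION_METRICS = [
    "spinal_cord_d003cc_cgy", "brain_stem_d003cc_cgy",
    "parotid_l_dmean_cgy", "parotid_r_dmean_cgy",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one input mode)."""

    mode: str = "simulate"                  # simulate | fixture | dicom
    out_dir: str | Path = "arcmetrics_out"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_dir: str | Path | None = None     # fixture/dicom modes
    dvh_bin_gy: float = 0.01
    closed_gap_mm: float = 0.5
    holm: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "fixture", "dicom"):
            raise ValueError(f"unknown input mode: {self.mode}")
        if self.mode != "simulate" and self.input_dir is None:
            raise ValueError(f"mode {self.mode} needs input_dir")


def complexity_row(plan: Plan, closed_gap_mm: float = 0.5) -> dict:
    """Per-plan complexity metrics as a flat record."""
    res = plan_complexity(plan, closed_gap_mm=closed_gap_mm)
    return {
        "patient_id": plan.patient_id,
        "group": plan.group_label,
        "mcs_v": res.mcs_v,
        "mu": res.total_mu,
        "pa_mm2": res.pa_mm2,
        "pi": res.pi,
        "pm": res.pm,
    }


def dose_metric_row(
    dose: DoseGrid,
    masks: dict[str, StructureMask],
    rx_gy: float,
    bin_gy: float = 0.01,
) -> dict:
    """Per-plan dose-volumetric metrics after coverage normalisation."""
    norm = normalize_to_coverage(dose, masks["ptv"], rx_gy, bin_gy=bin_gy)
    ptv_dvh = compute_dvh(norm, masks["ptv"], bin_gy)
    idx = ptv_indices(norm, masks["ptv"], rx_gy, bin_gy=bin_gy)
    row = {
        "ptv_d003cc_cgy": 100.0 * d_at_volume(ptv_dvh, 0.03),
        "cn": idx["CN"],
        "hi": idx["HI"],
        "gi": idx["GI"],
    }
    for name in OAR_NAMES:
        dvh = compute_dvh(norm, masks[name], bin_gy)
        row[f"{name}_d003cc_cgy"] = 100.0 * d_at_volume(dvh, 0.03)
        row[f"{name}_dmean_cgy"] = 100.0 * dose_mean(norm, masks[name])
    row["parotids_within_mean_constraint"] = bool(
        row["parotid_l_dmean_cgy"] < 100.0 * PAROTID_MEAN_CONSTRAINT_GY
        and row["parotid_r_dmean_cgy"] < 100.0 * PAROTID_MEAN_CONSTRAINT_GY
    )
    return row


def _load_plans(config: RunConfig) -> list[Plan]:
    root = Path(config.input_dir)
    if config.mode == "fixture":
        paths = sorted(root.glob("*.json"))
        loader = load_plan_fixture
    else:
        paths = sorted(root.glob("*.dcm"))
        loader = load_rtplan
    if not paths:
        raise FileNotFoundError(f"no plans found under {root}")
    return [loader(p) for p in paths]


def _round_report(df: pd.DataFrame) -> pd.DataFrame:
    """Reporting precision: doses 0.1 cGy, indices 0.01, percents 0.1."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind not in "fc":
            continue
        name = f"{out.index.name or ''} {col}".lower() if out.index.name else col.lower()
        ref = (str(out.index.tolist()) + " " + col).lower()
        if "cgy" in ref or "mu" in ref:
            out[col] = out[col].round(1)
        elif col.startswith("p_") or "percent" in name:
            out[col] = out[col].round(3 if col.startswith("p_") else 1)
        else:
            out[col] = out[col].round(2)
    return out


def _split_metric_rounding(df: pd.DataFrame) -> pd.DataFrame:
    """Round a comparison table row-wise by metric units."""
    out = df.copy()
    for metric in out.index:
        is_dose = "cgy" in str(metric) or str(metric) == "mu"
        for col in out.columns:
            v = out.loc[metric, col]
            if not isinstance(v, (int, float)):
                continue
            if col.startswith("p_"):
                out.loc[metric, col] = round(v, 3)
            else:
                out.loc[metric, col] = round(v, 1 if is_dose else 2)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute one full analysis run; return the tables it wrote."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {}
    rows: list[dict] = []
    if config.mode == "simulate":
        cohort = generate_cohort(config.cohort, include_dose=True)
        manifest = cohort.manifest()
        for patient in cohort.patients:
            for g, plan in patient.plans.items():
                problems = validate_plan(plan)
                if problems:
                    raise ValueError(
                        f"{patient.patient_id}/{g}: invalid generated plan: {problems[0]}"
                    )
                row = complexity_row(plan, config.closed_gap_mm)
                dose, masks = patient.doses[g]
                row.update(
                    dose_metric_row(
                        dose, masks, config.cohort.prescription_gy, config.dvh_bin_gy
                    )
                )
                rows.append(row)
    else:
        for plan in _load_plans(config):
            rows.append(complexity_row(plan, config.closed_gap_mm))

    metrics = pd.DataFrame(rows)
    metrics.to_csv(out_dir / "plan_metrics.csv", index=False)

    tables: dict[str, pd.DataFrame] = {"plan_metrics": metrics}
    have_groups = metrics["group"].notna().all() and metrics["group"].nunique() > 1
    if have_groups:
        groups = tuple(sorted(metrics["group"].unique()))
        comp_cols = ["patient_id", "group"] + [
            c for c in COMPLEXITY_COLUMNS if c in metrics
        ]
        comp_tables = summarize_and_compare(
            metrics[comp_cols], groups=groups, holm=config.holm
        )
        comp_frame = comparison_frame(comp_tables)
        comp_frame.to_csv(out_dir / "complexity_comparison_full.csv")
        _split_metric_rounding(comp_frame).to_csv(out_dir / "complexity_comparison.csv")
        tables["complexity_comparison"] = comp_frame

        dose_cols = [c for c in DOSE_METRIC_COLUMNS if c in metrics]
        if dose_cols:
            dose_tables = summarize_and_compare(
                metrics[["patient_id", "group"] + dose_cols],
                groups=groups,
                holm=config.holm,
            )
            dose_frame = comparison_frame(dose_tables)
            dose_frame.to_csv(out_dir / "dose_comparison_full.csv")
            _split_metric_rounding(dose_frame).to_csv(out_dir / "dose_comparison.csv")
            tables["dose_comparison"] = dose_frame

            if {"A", "B", "C"} <= set(groups):
                red_rows = []
                for metric in REDUCTION_METRICS:
                    if metric not in dose_tables:
                        continue
                    t = dose_tables[metric]
                    for ref in ("A", "B"):
                        red_rows.append(
                            {
                                "metric": metric,
                                "reference_group": ref,
                                "comparison_group": "C",
                                "percent_reduction": percent_reduction(
                                    t.means[ref], t.means["C"]
                                ),
                            }
                        )
                reductions = pd.DataFrame(red_rows)
                reductions.to_csv(out_dir / "percent_reductions.csv", index=False)
                tables["percent_reductions"] = reductions

    log = {"config": _config_doc(config), "manifest": manifest}
    with open(out_dir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return tables


def _config_doc(config: RunConfig) -> dict:
    doc = asdict(config)
    doc["out_dir"] = str(doc["out_dir"])
    if doc.get("input_dir") is not None:
        doc["input_dir"] = str(doc["input_dir"])
    return doc
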