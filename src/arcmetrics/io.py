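"""Reading and writing VMAT plans.

Two on-disk representations are supported and are metric-equivalent:

* DICOM RT Plan (the format treatment planning systems export), via
  :mod:`pydicom`;
* a plain-JSON fixture dialect documented by
  ``schemas/plan_fixture.schema.json``, convenient for tests and for the
  synthetic cohort generator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .plan import (
    Arc,
    ControlPoint,
    MLCBankPositions,
    Plan,
    PlanValidationError,
    infer_group_label,
)

RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"


class PlanFormatError(ValueError):
    """The file is not a plan in the expected format."""


class FixtureSchemaError(PlanFormatError):
    """A JSON fixture violates the plan-fixture schema."""


# ---------------------------------------------------------------------------
# JSON fixture dialect
# ---------------------------------------------------------------------------

_TOP_KEYS = {"patient_id", "group", "prescription_gy", "fractions", "arcs"}
_ARC_KEYS = {"increment_deg", "direction", "arc_mu", "control_points"}
_CP_KEYS = {"gantry_deg", "cum_weight", "left_mm", "right_mm"}


def _require_keys(obj: dict, required: set[str], where: str) -> None:
    missing = sorted(required - obj.keys())
    if missing:
        raise FixtureSchemaError(f"{where}: missing keys {missing}")


def load_plan_fixture(path: str | Path) -> Plan:
    """Load a plan from the JSON fixture dialect.

    Raises
    ------
    FixtureSchemaError
        naming the offending keys on any schema violation.
    PlanValidationError
        when cumulative meterset weights are not monotone.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise FixtureSchemaError("top level: expected a JSON object")
    _require_keys(doc, _TOP_KEYS, "top level")
    if not isinstance(doc["arcs"], list) or len(doc["arcs"]) == 0:
        raise FixtureSchemaError("top level: 'arcs' must be a non-empty list")

    leaf_width = float(doc.get("leaf_width_mm", 5.0))
    arcs: list[Arc] = []
    for k, arc_doc in enumerate(doc["arcs"]):
        _require_keys(arc_doc, _ARC_KEYS, f"arcs[{k}]")
        cps_doc = arc_doc["control_points"]
        if not isinstance(cps_doc, list) or len(cps_doc) < 2:
            raise FixtureSchemaError(
                f"arcs[{k}]: 'control_points' must hold at least 2 entries"
            )
        cps: list[ControlPoint] = []
        for i, cp_doc in enumerate(cps_doc):
            _require_keys(cp_doc, _CP_KEYS, f"arcs[{k}].control_points[{i}]")
            cps.append(
                ControlPoint(
                    gantry_deg=float(cp_doc["gantry_deg"]),
                    cum_weight=float(cp_doc["cum_weight"]),
                    collimator_deg=float(cp_doc.get("collimator_deg", 0.0)),
                    mlc=MLCBankPositions(
                        left=np.asarray(cp_doc["left_mm"], dtype=float),
                        right=np.asarray(cp_doc["right_mm"], dtype=float),
                        leaf_width_mm=leaf_width,
                    ),
                )
            )
        _check_monotone_weights([c.cum_weight for c in cps], f"arcs[{k}]")
        arcs.append(
            Arc(
                control_points=cps,
                arc_mu=float(arc_doc["arc_mu"]),
                increment_deg=float(arc_doc["increment_deg"]),
                direction=str(arc_doc["direction"]),
            )
        )
    plan = Plan(
        arcs=arcs,
        prescription_gy=float(doc["prescription_gy"]),
        fractions=int(doc["fractions"]),
        group_label=doc.get("group"),
        patient_id=str(doc["patient_id"]),
        leaf_width_mm=leaf_width,
    )
    if plan.group_label is None:
        plan.group_label = infer_group_label(plan)
    return plan


def save_plan_fixture(plan: Plan, path: str | Path) -> None:
    """Write a plan in the JSON fixture dialect."""
    doc = {
        "patient_id": plan.patient_id or "anon",
        "group": plan.group_label,
        "prescription_gy": plan.prescription_gy,
        "fractions": plan.fractions,
        "leaf_width_mm": plan.leaf_width_mm,
        "arcs": [
            {
                "increment_deg": arc.increment_deg,
                "direction": arc.direction,
                "arc_mu": arc.arc_mu,
                "control_points": [
                    {
                        "gantry_deg": cp.gantry_deg,
                        "cum_weight": cp.cum_weight,
                        "collimator_deg": cp.collimator_deg,
                        "left_mm": cp.mlc.left.tolist(),
                        "right_mm": cp.mlc.right.tolist(),
                    }
                    for cp in arc.control_points
                ],
            }
            for arc in plan.arcs
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _check_monotone_weights(weights: list[float], where: str) -> None:
    w = np.asarray(weights, dtype=float)
    drops = np.nonzero(np.diff(w) < -1e-12)[0]
    if drops.size:
        raise PlanValidationError(
            f"{where}: cumulative meterset weight decreases at control point "
            f"{int(drops[0]) + 1}"
        )


# ---------------------------------------------------------------------------
# DICOM RT Plan
# ---------------------------------------------------------------------------

def load_rtplan(path: str | Path) -> Plan:
    """Read a DICOM RT Plan into the in-memory plan model.

    Per-arc MU comes from ``BeamMeterset`` in the fraction group; segment
    MU then follows from the cumulative meterset weights.  Beams must
    carry MLCX position sequences.
    """
    ds = pydicom.dcmread(str(path))
    if "BeamSequence" not in ds or len(ds.BeamSequence) == 0:
        raise PlanFormatError("RT Plan has no BeamSequence")

    metersets: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    arcs: list[Arc] = []
    leaf_width = 5.0
    for beam in ds.BeamSequence:
        beam_no = int(beam.BeamNumber)
        if beam_no not in metersets:
            raise PlanFormatError(f"beam {beam_no}: no BeamMeterset in fraction group")
        boundaries = None
        for bld in getattr(beam, "BeamLimitingDeviceSequence", []):
            if bld.RTBeamLimitingDeviceType == "MLCX":
                boundaries = np.asarray(bld.LeafPositionBoundaries, dtype=float)
        if boundaries is None:
            raise PlanFormatError(f"beam {beam_no}: no MLCX in BeamLimitingDeviceSequence")
        widths = np.diff(boundaries)
        leaf_width = float(widths[0])

        increment = 30.0
        desc = str(getattr(beam, "BeamDescription", ""))
        if "increment=" in desc:
            increment = float(desc.split("increment=")[1].split(";")[0])

        direction = "CW"
        collimator = 0.0
        final_w = float(getattr(beam, "FinalCumulativeMetersetWeight", 1.0))
        cps: list[ControlPoint] = []
        for i, cp in enumerate(beam.ControlPointSequence):
            if "GantryRotationDirection" in cp and cp.GantryRotationDirection in ("CW", "CC"):
                direction = "CCW" if cp.GantryRotationDirection == "CC" else "CW"
            if "BeamLimitingDeviceAngle" in cp:
                collimator = float(cp.BeamLimitingDeviceAngle)
            mlc_positions = None
            for bldp in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                if bldp.RTBeamLimitingDeviceType == "MLCX":
                    mlc_positions = np.asarray(bldp.LeafJawPositions, dtype=float)
            if mlc_positions is None:
                if i == 0:
                    raise PlanFormatError(
                        f"beam {beam_no}: first control point lacks MLCX positions"
                    )
                mlc_positions = prev_positions  # static leaves between CPs
            prev_positions = mlc_positions
            n = mlc_positions.size // 2
            cps.append(
                ControlPoint(
                    gantry_deg=float(cp.GantryAngle) % 360.0,
                    cum_weight=float(cp.CumulativeMetersetWeight) / final_w,
                    collimator_deg=collimator,
                    mlc=MLCBankPositions(
                        left=mlc_positions[:n],
                        right=mlc_positions[n:],
                        leaf_width_mm=leaf_width,
                    ),
                )
            )
        _check_monotone_weights([c.cum_weight for c in cps], f"beam {beam_no}")
        arcs.append(
            Arc(
                control_points=cps,
                arc_mu=metersets[beam_no],
                increment_deg=increment,
                direction=direction,
            )
        )

    rx_gy, fractions = 70.0, 35
    for fg in getattr(ds, "FractionGroupSequence", []):
        fractions = int(getattr(fg, "NumberOfFractionsPlanned", fractions))
    for dr in getattr(ds, "DoseReferenceSequence", []):
        if "TargetPrescriptionDose" in dr:
            rx_gy = float(dr.TargetPrescriptionDose)
    plan = Plan(
        arcs=arcs,
        prescription_gy=rx_gy,
        fractions=fractions,
        group_label=str(getattr(ds, "RTPlanLabel", "")) or None,
        patient_id=str(getattr(ds, "PatientID", "")) or None,
        leaf_width_mm=leaf_width,
    )
    if plan.group_label is None:
        plan.group_label = infer_group_label(plan)
    return plan


def write_rtplan(plan: Plan, path: str | Path) -> None:
    """Write the plan as a minimal, standard-conformant DICOM RT Plan."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTPLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.PatientID = plan.patient_id or "anon"
    ds.PatientName = plan.patient_id or "anon"
    ds.RTPlanLabel = plan.group_label or ""
    ds.RTPlanGeometry = "PATIENT"

    dr = Dataset()
    dr.DoseReferenceNumber = 1
    dr.DoseReferenceStructureType = "SITE"
    dr.DoseReferenceType = "TARGET"
    dr.TargetPrescriptionDose = plan.prescription_gy
    ds.DoseReferenceSequence = [dr]

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = plan.fractions
    fg.NumberOfBeams = plan.n_arcs
    fg.ReferencedBeamSequence = []

    ds.BeamSequence = []
    for k, arc in enumerate(plan.arcs):
        n = arc.control_points[0].mlc.n_pairs
        width = arc.control_points[0].mlc.leaf_width_mm
        beam = Dataset()
        beam.BeamNumber = k + 1
        beam.BeamName = f"Arc{k + 1}"
        beam.BeamDescription = f"increment={arc.increment_deg:g}"
        beam.BeamType = "DYNAMIC"
        beam.RadiationType = "PHOTON"
        beam.TreatmentDeliveryType = "TREATMENT"
        beam.NumberOfWedges = 0
        beam.NumberOfCompensators = 0
        beam.NumberOfBoli = 0
        beam.NumberOfBlocks = 0
        beam.FinalCumulativeMetersetWeight = 1.0
        beam.NumberOfControlPoints = arc.n_control_points

        bld = Dataset()
        bld.RTBeamLimitingDeviceType = "MLCX"
        bld.NumberOfLeafJawPairs = n
        half = 0.5 * n * width
        bld.LeafPositionBoundaries = [(-half + j * width) for j in range(n + 1)]
        beam.BeamLimitingDeviceSequence = [bld]

        beam.ControlPointSequence = []
        for i, cp in enumerate(arc.control_points):
            cpd = Dataset()
            cpd.ControlPointIndex = i
            cpd.GantryAngle = cp.gantry_deg
            cpd.GantryRotationDirection = "CW" if arc.direction.upper() == "CW" else "CC"
            cpd.CumulativeMetersetWeight = cp.cum_weight
            if i == 0:
                cpd.BeamLimitingDeviceAngle = cp.collimator_deg
                cpd.NominalBeamEnergy = 6
            pos = Dataset()
            pos.RTBeamLimitingDeviceType = "MLCX"
            pos.LeafJawPositions = [*cp.mlc.left.tolist(), *cp.mlc.right.tolist()]
            cpd.BeamLimitingDevicePositionSequence = [pos]
            beam.ControlPointSequence.append(cpd)
        ds.BeamSequence.append(beam)

        rb = Dataset()
        rb.ReferencedBeamNumber = k + 1
        rb.BeamMeterset = arc.arc_mu
        fg.ReferencedBeamSequence.append(rb)

    ds.FractionGroupSequence = [fg]
    ds.save_as(str(path), enforce_file_format=True)
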