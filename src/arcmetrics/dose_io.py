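"""DICOM RT Dose / RT Structure Set I/O and array fixtures.

RT Dose grids are read honoring ``DoseGridScaling`` and
``GridFrameOffsetVector``; structure-set contours are rasterized to
voxel masks on a reference grid (voxel-center membership).  For tests
and synthetic cohorts, dose grids and masks can also round-trip through
a plain ``.npz`` array container.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage.draw import polygon2mask

from .dose import DoseGrid, StructureMask

RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


# ---------------------------------------------------------------------------
# RT Dose
# ---------------------------------------------------------------------------

def load_rtdose(path: str | Path) -> DoseGrid:
    """Read a DICOM RT Dose file into a :class:`DoseGrid` (Gy)."""
    ds = pydicom.dcmread(str(path))
    values = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) if offsets.size > 1 else 1.0
    ox, oy, oz = (float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values, (abs(dz), dy, dx), (oz + float(offsets[0]), oy, ox))


def write_rtdose(dose: DoseGrid, path: str | Path) -> None:
    """Write a :class:`DoseGrid` as a 32-bit DICOM RT Dose file."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"

    nz, ny, nx = dose.values.shape
    dz, dy, dx = dose.spacing_mm
    oz, oy, ox = dose.origin_mm
    dmax = float(dose.values.max())
    scaling = dmax / (2**32 - 1) if dmax > 0 else 1.0
    pixels = np.round(dose.values / scaling).astype(np.uint32)

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = nz
    ds.Rows = ny
    ds.Columns = nx
    ds.PixelSpacing = [dy, dx]
    ds.GridFrameOffsetVector = [i * dz for i in range(nz)]
    ds.ImagePositionPatient = [ox, oy, oz]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.DoseGridScaling = scaling
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# RT Structure Set
# ---------------------------------------------------------------------------

def load_rtstruct(path: str | Path, grid: DoseGrid) -> dict[str, StructureMask]:
    """Rasterize every ROI of an RT Structure Set onto ``grid``.

    Contours are matched to grid slices by nearest z; each planar
    contour is filled with a voxel-center point-in-polygon test.
    """
    ds = pydicom.dcmread(str(path))
    names = {
        int(r.ROINumber): str(r.ROIName)
        for r in getattr(ds, "StructureSetROISequence", [])
    }
    nz, ny, nx = grid.values.shape
    dz, dy, dx = grid.spacing_mm
    oz, oy, ox = grid.origin_mm

    out: dict[str, StructureMask] = {}
    for roi in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(roi.ReferencedROINumber), f"roi{roi.ReferencedROINumber}")
        mask = np.zeros((nz, ny, nx), dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            k = int(round((pts[0, 2] - oz) / dz))
            if not 0 <= k < nz:
                continue
            rows = (pts[:, 1] - oy) / dy
            cols = (pts[:, 0] - ox) / dx
            poly = np.column_stack([rows, cols])
            mask[k] |= polygon2mask((ny, nx), poly)
        out[name] = StructureMask(name=name, mask=mask)
    return out


def write_rtstruct_spheres(
    spheres: dict[str, tuple[tuple[float, float, float], float]],
    grid: DoseGrid,
    path: str | Path,
) -> None:
    """Write spherical ROIs (center mm, radius mm) as an RT Structure Set.

    Each sphere becomes a stack of circular contours, one per grid slice
    it intersects — enough structure to exercise the rasterization path.
    """
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTSTRUCT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "synthetic"

    nz = grid.values.shape[0]
    dz, _, _ = grid.spacing_mm
    oz, _, _ = grid.origin_mm

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, (name, ((cx, cy, cz), radius)) in enumerate(spheres.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        theta = np.linspace(0.0, 2.0 * np.pi, 73)[:-1]
        for k in range(nz):
            z = oz + k * dz
            r2 = radius**2 - (z - cz) ** 2
            if r2 <= 0:
                continue
            r = np.sqrt(r2)
            xs = cx + r * np.cos(theta)
            ys = cy + r * np.sin(theta)
            contour = Dataset()
            contour.ContourGeometricType = "CLOSED_PLANAR"
            contour.NumberOfContourPoints = theta.size
            contour.ContourData = [
                float(v) for xyz in zip(xs, ys) for v in (*xyz, z)
            ]
            rc.ContourSequence.append(contour)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# array fixture container
# ---------------------------------------------------------------------------

def save_dose_fixture(
    dose: DoseGrid, masks: dict[str, StructureMask], path: str | Path
) -> None:
    """Save dose + masks to a compressed ``.npz`` array container."""
    arrays = {
        "dose": dose.values,
        "spacing_mm": np.asarray(dose.spacing_mm),
        "origin_mm": np.asarray(dose.origin_mm),
    }
    for name, m in masks.items():
        arrays[f"mask__{name}"] = m.mask
    np.savez_compressed(path, **arrays)


def load_dose_fixture(path: str | Path) -> tuple[DoseGrid, dict[str, StructureMask]]:
    """Load a dose + mask bundle written by :func:`save_dose_fixture`."""
    with np.load(path) as data:
        dose = DoseGrid(
            data["dose"],
            tuple(float(v) for v in data["spacing_mm"]),
            tuple(float(v) for v in data["origin_mm"]),
        )
        masks = {
            key[len("mask__"):]: StructureMask(key[len("mask__"):], data[key])
            for key in data.files
            if key.startswith("mask__")
        }
    return dose, masks
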