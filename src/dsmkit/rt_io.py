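"""Reading and writing radiotherapy data.

Two input routes are supported: standard DICOM-RT Structure Set / Dose files
(generic attributes only, no planning-system dialects), and a plain-text
fixture layout used for synthetic cohorts::

    cohort_dir/
      cohort.json                 {"prescription_gy", "n_fractions", "patients"}
      <patient_id>/
        planning/                 fraction_index 0
          contours.json           [{"structure", "slices": [{"z", "xy": [[x, y], ...]}]}]
          dose.txt                header lines (# origin/spacing/shape) + flat values
          meta.json               {"isocentre_mm", "fraction_index", "truth"}
        fraction_001/ ...         fraction_index 1..N

All coordinates are DICOM patient-frame mm, head-first supine.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from shapely.geometry import Polygon

from .core import (
    CohortData,
    ContourStack,
    DDM,
    DoseGrid,
    DSM,
    FractionRecord,
    Patient,
    warn_geometry,
)

RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


# ---------------------------------------------------------------------------
# DICOM-RT
# ---------------------------------------------------------------------------

def read_rtstruct(path, structure_names: list[str]) -> list[ContourStack]:
    """Extract the requested structures (case-insensitive) from an RTSTRUCT.

    Slices are sorted ascending in z.  Multiple polygons on one z plane keep
    the largest-area polygon with a warning (the rectum is a single lumen).
    """
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "SOPClassUID", None) != RTSTRUCT_SOP_CLASS:
        raise ValueError(f"{path} is not a DICOM-RT Structure Set")
    roi_names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    by_lower = {name.lower(): num for num, name in roi_names.items()}
    contours_by_number: dict[int, list[tuple[float, np.ndarray]]] = {}
    for rc in ds.ROIContourSequence:
        num = int(rc.ReferencedROINumber)
        slices: dict[float, list[np.ndarray]] = {}
        for c in getattr(rc, "ContourSequence", []):
            data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            z = round(float(np.mean(data[:, 2])), 3)
            slices.setdefault(z, []).append(data[:, :2])
        merged: list[tuple[float, np.ndarray]] = []
        for z, polys in slices.items():
            if len(polys) > 1:
                warn_geometry(
                    f"{roi_names.get(num, num)}: {len(polys)} polygons at z={z}; "
                    "keeping the largest"
                )
                polys = [max(polys, key=lambda p: Polygon(p).area)]
            merged.append((z, polys[0]))
        contours_by_number[num] = merged
    out = []
    for requested in structure_names:
        num = by_lower.get(requested.lower())
        if num is None or num not in contours_by_number:
            available = ", ".join(sorted(roi_names.values()))
            raise KeyError(
                f"structure {requested!r} not found; available: {available}"
            )
        out.append(ContourStack(roi_names[num], contours_by_number[num]))
    return out


def read_rtdose(path) -> DoseGrid:
    """Read a DICOM-RT Dose file into a DoseGrid (values in Gy)."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "SOPClassUID", None) != RTDOSE_SOP_CLASS:
        raise ValueError(f"{path} is not a DICOM-RT Dose file")
    if "DoseGridScaling" not in ds:
        raise ValueError(f"{path}: missing DoseGridScaling tag")
    scaling = float(ds.DoseGridScaling)
    # pixel_array is (frames, rows, cols) = (z, y, x); reorder to (x, y, z)
    values = ds.pixel_array.astype(float).transpose(2, 1, 0) * scaling
    origin = np.asarray(ds.ImagePositionPatient, dtype=float)
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(np.mean(np.diff(offsets)))
    return DoseGrid(
        origin_mm=origin,
        spacing_mm=np.array([col_spacing, row_spacing, dz]),
        values=values,
    )


def _file_meta(sop_class: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def write_rtstruct(stacks: list[ContourStack], path) -> None:
    """Write contour stacks as a minimal standard RTSTRUCT file."""
    meta = _file_meta(RTSTRUCT_SOP_CLASS)
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientName = ds.PatientID = "synthetic"
    ds.StructureSetLabel = "dsmkit"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for i, stack in enumerate(stacks, start=1):
        roi = Dataset()
        roi.ROINumber = i
        roi.ROIName = stack.structure_name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = i
        rc.ContourSequence = []
        for z, verts in stack.slices:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(verts)
            xyz = np.column_stack([verts, np.full(len(verts), z)])
            c.ContourData = [float(v) for v in xyz.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)


def write_rtdose(grid: DoseGrid, path) -> None:
    """Write a DoseGrid as a minimal standard RTDOSE file (16-bit scaled)."""
    meta = _file_meta(RTDOSE_SOP_CLASS)
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.PatientName = ds.PatientID = "synthetic"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    nx, ny, nz = grid.values.shape
    max_dose = float(grid.values.max())
    scaling = max(max_dose, 1e-6) / 65000.0
    stored = np.round(grid.values / scaling).astype(np.uint16)
    ds.DoseGridScaling = scaling
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = ny, nx
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.ImagePositionPatient = [float(v) for v in grid.origin_mm]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [float(grid.spacing_mm[1]), float(grid.spacing_mm[0])]
    ds.GridFrameOffsetVector = [float(grid.spacing_mm[2] * k) for k in range(nz)]
    ds.PixelData = stored.transpose(2, 1, 0).tobytes()  # (z, y, x) frame order
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Fixture format
# ---------------------------------------------------------------------------

def _write_contours(stacks: list[ContourStack], path: Path) -> None:
    payload = [
        {
            "structure": s.structure_name,
            "slices": [
                {"z": z, "xy": np.asarray(v).tolist()} for z, v in s.slices
            ],
        }
        for s in stacks
    ]
    path.write_text(json.dumps(payload))


def _read_contours(path: Path) -> list[ContourStack]:
    payload = json.loads(path.read_text())
    return [
        ContourStack(
            entry["structure"],
            [(float(s["z"]), np.asarray(s["xy"], dtype=float)) for s in entry["slices"]],
        )
        for entry in payload
    ]


def _write_dose(grid: DoseGrid, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# origin_mm: %.9g %.9g %.9g\n" % tuple(float(v) for v in grid.origin_mm))
        fh.write("# spacing_mm: %.9g %.9g %.9g\n" % tuple(float(v) for v in grid.spacing_mm))
        fh.write("# shape: %d %d %d\n" % grid.values.shape)
        np.savetxt(fh, grid.values.reshape(-1, grid.values.shape[-1]), fmt="%.6g")


def _read_dose(path: Path) -> DoseGrid:
    with open(path) as fh:
        origin = np.array(fh.readline().split(":")[1].split(), dtype=float)
        spacing = np.array(fh.readline().split(":")[1].split(), dtype=float)
        shape = tuple(int(v) for v in fh.readline().split(":")[1].split())
        values = np.loadtxt(fh).reshape(shape)
    return DoseGrid(origin, spacing, values)


def _record_dir(base: Path, fraction_index: int) -> Path:
    return base / ("planning" if fraction_index == 0 else f"fraction_{fraction_index:03d}")


def _write_record(rec: FractionRecord, base: Path) -> None:
    d = _record_dir(base, rec.fraction_index)
    d.mkdir(parents=True, exist_ok=True)
    _write_contours([rec.rectum, rec.ptv], d / "contours.json")
    _write_dose(rec.dose, d / "dose.txt")
    meta = {
        "isocentre_mm": [float(v) for v in rec.isocentre_mm],
        "fraction_index": rec.fraction_index,
        "truth": rec.truth,
    }
    (d / "meta.json").write_text(json.dumps(meta))


def _read_record(d: Path) -> FractionRecord:
    if not (d / "dose.txt").exists():
        raise FileNotFoundError(f"{d}: fraction with no dose grid")
    meta = json.loads((d / "meta.json").read_text())
    stacks = {s.structure_name: s for s in _read_contours(d / "contours.json")}
    return FractionRecord(
        rectum=stacks["Rectum"],
        ptv=stacks["PTV"],
        isocentre_mm=np.asarray(meta["isocentre_mm"], dtype=float),
        dose=_read_dose(d / "dose.txt"),
        fraction_index=int(meta["fraction_index"]),
        truth=meta.get("truth"),
    )


def write_fixture_cohort(cohort: CohortData, path) -> None:
    """Persist a cohort in the documented plain-text fixture layout."""
    base = Path(path)
    base.mkdir(parents=True, exist_ok=True)
    (base / "cohort.json").write_text(
        json.dumps(
            {
                "prescription_gy": cohort.prescription_gy,
                "n_fractions": cohort.n_fractions,
                "patients": [p.patient_id for p in cohort.patients],
            }
        )
    )
    for pt in cohort.patients:
        pdir = base / pt.patient_id
        _write_record(pt.planning, pdir)
        for fr in pt.fractions:
            _write_record(fr, pdir)


def read_fixture_cohort(path) -> CohortData:
    """Load a fixture cohort; ordering is by patient_id then fraction_index."""
    base = Path(path)
    manifest = base / "cohort.json"
    if not manifest.exists():
        raise FileNotFoundError(f"{base}: no cohort.json manifest found")
    info = json.loads(manifest.read_text())
    patients = []
    for pid in sorted(info["patients"]):
        pdir = base / pid
        plan_dir = pdir / "planning"
        if not plan_dir.exists():
            raise FileNotFoundError(f"{pdir}: missing planning record")
        planning = _read_record(plan_dir)
        frac_dirs = sorted(d for d in pdir.iterdir() if d.name.startswith("fraction_"))
        fractions = [_read_record(d) for d in frac_dirs]
        fractions.sort(key=lambda r: r.fraction_index)
        patients.append(Patient(pid, planning, fractions))
    return CohortData(
        patients, float(info["prescription_gy"]), int(info["n_fractions"])
    )


# ---------------------------------------------------------------------------
# Map CSV
# ---------------------------------------------------------------------------

def write_map_csv(map2d: DSM | DDM, path) -> None:
    """Write a DSM or DDM as CSV, one row per axial level from the inferior border."""
    values = map2d.dose if isinstance(map2d, DSM) else map2d.values
    if values.shape[0] < 1 or values.size == 0:
        raise ValueError("cannot write an empty map")
    with open(path, "w") as fh:
        fh.write(f"# row_spacing_mm: {map2d.row_spacing_mm}\n")
        fh.write(f"# angular_count: {map2d.angular_count}\n")
        np.savetxt(fh, values, fmt="%.6f", delimiter=",")


def read_map_csv(path) -> tuple[np.ndarray, float, int]:
    """Read a map CSV back: (values, row_spacing_mm, angular_count)."""
    with open(path) as fh:
        row_spacing = float(fh.readline().split(":")[1])
        angular = int(fh.readline().split(":")[1])
        values = np.loadtxt(fh, delimiter=",", ndmin=2)
    return values, row_spacing, angular
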