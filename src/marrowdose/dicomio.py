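"""DICOM-RT reading/writing and the record-completeness filter.

Readers assemble the CT series, RT-dose grid and RT-plan prescription
into the package's raster/plan types (geometry in the DICOM patient
frame, LPS mm, voxel = voxel center). Writers produce minimal but
standard-conformant CT / RTDOSE / RTPLAN objects for the synthetic
fixtures; all UIDs are derived deterministically from caller-supplied
entropy so that a fixture tree is reproducible byte for byte.

The completeness filter compares the summed per-beam prescribed dose in
the RT-plan against the delivered dose recorded in the cohort database
and rejects a record when they disagree by more than 0.1 Gy (strict
inequality), reporting the direction of the mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grids import CTVolume, DoseGrid
from .phantom import PatientCharacteristics

__all__ = [
    "Beam",
    "PlanSummary",
    "ConsistencyResult",
    "read_ct_series",
    "read_rt_dose",
    "read_rt_plan",
    "write_ct_series",
    "write_rt_dose",
    "write_rt_plan",
    "check_dose_consistency",
    "categorize_treatment_region",
    "DOSE_MISMATCH_LIMIT_GY",
    "DEFAULT_REGION_KEYWORDS",
    "DEFAULT_Z_BANDS",
]

CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
RTDOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"
RTPLAN_STORAGE = "1.2.840.10008.5.1.4.1.1.481.5"

DOSE_MISMATCH_LIMIT_GY = 0.1

AXIAL_ORIENTATION = [1, 0, 0, 0, 1, 0]


@dataclass
class Beam:
    label: str
    prescribed_dose_gy: float
    isocenter_mm: np.ndarray | None = None


@dataclass
class PlanSummary:
    """Per-beam prescribed doses extracted from an RT-plan."""

    beams: list[Beam]
    plan_label: str = ""
    fallback_used: bool = False  # dose taken from the plan-level prescription

    @property
    def total_prescribed_gy(self) -> float:
        return float(sum(b.prescribed_dose_gy for b in self.beams))

    @property
    def isocenter_mm(self) -> np.ndarray | None:
        for b in self.beams:
            if b.isocenter_mm is not None:
                return b.isocenter_mm
        return None


def _uid(entropy: str) -> str:
    return generate_uid(entropy_srcs=[entropy])


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = _uid("marrowdose-implementation")
    return meta


def _common(ds: Dataset, patient_id: str, uid_seed: str) -> None:
    ds.PatientName = patient_id
    ds.PatientID = patient_id
    ds.StudyInstanceUID = _uid(f"{uid_seed}/study")
    ds.FrameOfReferenceUID = _uid(f"{uid_seed}/frame")
    ds.PositionReferenceIndicator = ""
    ds.StudyID = "1"
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.StudyDate = ""
    ds.StudyTime = ""


# ---------------------------------------------------------------- CT series


def read_ct_series(directory: str | Path) -> CTVolume:
    """Assemble one CT series into an HU volume, sorted by slice position.

    Slices are ordered by their z position (not filename); the rescale
    slope/intercept is applied. A directory holding more than one series
    or a non-uniform z grid (missing slices) is rejected.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    slices = [pydicom.dcmread(f) for f in files]
    slices = [s for s in slices if getattr(s, "Modality", "") == "CT"]
    if not slices:
        raise ValueError(f"no CT slices found in {directory}")
    series = {s.SeriesInstanceUID for s in slices}
    if len(series) > 1:
        raise ValueError(f"multiple CT series in one directory: {sorted(series)}")
    for s in slices:
        if list(map(float, s.ImageOrientationPatient)) != AXIAL_ORIENTATION:
            raise ValueError("only axis-aligned axial CT series are supported")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    z = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(z) > 1:
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise ValueError("duplicate slice positions in CT series")
        if not np.allclose(dz, dz[0], atol=1e-3):
            raise ValueError("non-uniform slice spacing (missing slices?) in CT series")
        z_spacing = float(dz[0])
    else:
        z_spacing = float(getattr(slices[0], "SliceThickness", 1.0))
    first = slices[0]
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    hu_slices = []
    for s in slices:
        arr = s.pixel_array.astype(float)
        arr = arr * float(getattr(s, "RescaleSlope", 1.0)) + float(
            getattr(s, "RescaleIntercept", 0.0)
        )
        hu_slices.append(arr.T)  # (rows, cols) = (y, x) -> (x, y)
    hu = np.stack(hu_slices, axis=2)
    return CTVolume(
        values=hu,
        spacing=np.array([col_sp, row_sp, z_spacing]),
        origin=np.array([float(v) for v in first.ImagePositionPatient]),
    )


def write_ct_series(
    ct: CTVolume, directory: str | Path, patient_id: str = "SYN", uid_seed: str = "ct"
) -> list[Path]:
    """Write an HU volume as a CT DICOM series, one file per slice."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = _uid(f"{uid_seed}/series")
    stored = np.round(ct.hu).astype(np.int64) + 1024  # intercept -1024
    if stored.min() < 0 or stored.max() > 32767:
        raise ValueError("HU values outside the storable range")
    paths = []
    nx, ny, nz = ct.shape
    for k in range(nz):
        sop_uid = _uid(f"{uid_seed}/slice/{k}")
        ds = Dataset()
        ds.file_meta = _file_meta(CT_STORAGE, sop_uid)
        _common(ds, patient_id, uid_seed)
        ds.SOPClassUID = CT_STORAGE
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            float(ct.origin[0]), float(ct.origin[1]),
            float(ct.origin[2] + k * ct.spacing[2]),
        ]
        ds.ImageOrientationPatient = AXIAL_ORIENTATION
        ds.PixelSpacing = [float(ct.spacing[1]), float(ct.spacing[0])]  # [row, col]
        ds.SliceThickness = float(ct.spacing[2])
        ds.Rows, ds.Columns = ny, nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T.astype(np.int16)).tobytes()
        path = directory / f"ct_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ----------------------------------------------------------------- RT-dose


def read_rt_dose(path: str | Path) -> DoseGrid:
    """Read an RTDOSE object; values are scaled to Gy at read time."""
    ds = pydicom.dcmread(str(path))
    if "DoseGridScaling" not in ds:
        raise ValueError("RT-dose object has no DoseGridScaling attribute")
    raw = ds.pixel_array.astype(float)  # (frames, rows, cols)
    if raw.min() < 0:
        raise ValueError("negative stored dose values")
    dose = (raw * float(ds.DoseGridScaling)).transpose(2, 1, 0)  # -> (x, y, z)
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if len(dz) and not np.allclose(dz, dz[0], atol=1e-6):
        raise ValueError("non-uniform dose-grid frame offsets")
    z_spacing = float(dz[0]) if len(dz) else 1.0
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    origin = np.array([float(v) for v in ds.ImagePositionPatient])
    origin[2] += offsets[0]
    return DoseGrid(
        values=dose, spacing=np.array([col_sp, row_sp, z_spacing]), origin=origin
    )


def write_rt_dose(
    grid: DoseGrid, path: str | Path, patient_id: str = "SYN", uid_seed: str = "dose"
) -> Path:
    """Write a dose grid as a multi-frame RTDOSE object (32-bit, auto scaling)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    max_dose = float(grid.dose.max())
    scaling = max_dose / (2**31 - 1) if max_dose > 0 else 1.0
    stored = np.round(grid.dose / scaling).astype(np.uint32)
    sop_uid = _uid(f"{uid_seed}/dose")
    ds = Dataset()
    ds.file_meta = _file_meta(RTDOSE_STORAGE, sop_uid)
    _common(ds, patient_id, uid_seed)
    ds.SOPClassUID = RTDOSE_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = _uid(f"{uid_seed}/dose-series")
    ds.SeriesNumber = 2
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    nx, ny, nz = grid.shape
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.GridFrameOffsetVector = [float(k * grid.spacing[2]) for k in range(nz)]
    ds.DoseGridScaling = scaling
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.ImageOrientationPatient = AXIAL_ORIENTATION
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]
    ds.Rows, ds.Columns = ny, nx
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(stored.transpose(2, 1, 0)).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


# ----------------------------------------------------------------- RT-plan


def read_rt_plan(path: str | Path) -> PlanSummary:
    """Extract per-beam prescribed doses (and isocenters) from an RT-plan.

    The prescribed dose per beam is the fraction-group beam dose times
    the number of planned fractions. When no per-beam doses exist the
    plan-level target prescription is used instead and the summary is
    flagged (``fallback_used``).
    """
    ds = pydicom.dcmread(str(path))
    label = str(getattr(ds, "RTPlanLabel", ""))
    isocenters: dict[int, np.ndarray] = {}
    names: dict[int, str] = {}
    for beam in getattr(ds, "BeamSequence", []):
        num = int(beam.BeamNumber)
        names[num] = str(getattr(beam, "BeamName", f"beam{num}"))
        for cp in getattr(beam, "ControlPointSequence", []):
            if "IsocenterPosition" in cp:
                isocenters[num] = np.array([float(v) for v in cp.IsocenterPosition])
                break
    beams: list[Beam] = []
    for fg in getattr(ds, "FractionGroupSequence", []):
        n_fx = int(getattr(fg, "NumberOfFractionsPlanned", 1) or 1)
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if "BeamDose" not in rb:
                continue
            num = int(getattr(rb, "ReferencedBeamNumber", -1))
            beams.append(Beam(
                label=names.get(num, f"beam{num}"),
                prescribed_dose_gy=float(rb.BeamDose) * n_fx,
                isocenter_mm=isocenters.get(num),
            ))
    if beams:
        return PlanSummary(beams=beams, plan_label=label)
    for ref in getattr(ds, "DoseReferenceSequence", []):
        if "TargetPrescriptionDose" in ref:
            iso = next(iter(isocenters.values()), None)
            return PlanSummary(
                beams=[Beam("plan-prescription", float(ref.TargetPrescriptionDose), iso)],
                plan_label=label,
                fallback_used=True,
            )
    raise ValueError("RT-plan carries no prescribed-dose attributes")


def write_rt_plan(
    plan: PlanSummary, path: str | Path, patient_id: str = "SYN", uid_seed: str = "plan"
) -> Path:
    """Write a PlanSummary as a minimal RTPLAN object (one fraction group)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sop_uid = _uid(f"{uid_seed}/plan")
    ds = Dataset()
    ds.file_meta = _file_meta(RTPLAN_STORAGE, sop_uid)
    _common(ds, patient_id, uid_seed)
    ds.SOPClassUID = RTPLAN_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTPLAN"
    ds.SeriesInstanceUID = _uid(f"{uid_seed}/plan-series")
    ds.SeriesNumber = 3
    ds.RTPlanLabel = plan.plan_label
    ds.RTPlanGeometry = "TREATMENT_DEVICE"
    beam_seq = []
    ref_seq = []
    for i, beam in enumerate(plan.beams, start=1):
        b = Dataset()
        b.BeamNumber = i
        b.BeamName = beam.label
        b.TreatmentMachineName = "SYNTH"
        b.RadiationType = "PHOTON"
        b.TreatmentDeliveryType = "TREATMENT"
        b.NumberOfControlPoints = 1
        cp = Dataset()
        cp.ControlPointIndex = 0
        if beam.isocenter_mm is not None:
            cp.IsocenterPosition = [float(v) for v in beam.isocenter_mm]
        b.ControlPointSequence = [cp]
        beam_seq.append(b)
        rb = Dataset()
        rb.ReferencedBeamNumber = i
        rb.BeamDose = float(beam.prescribed_dose_gy)
        ref_seq.append(rb)
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.ReferencedBeamSequence = ref_seq
    ds.FractionGroupSequence = [fg]
    ds.BeamSequence = beam_seq
    ds.save_as(path, enforce_file_format=True)
    return path


# --------------------------------------------- completeness / categorization


@dataclass
class ConsistencyResult:
    accepted: bool
    mismatch_gy: float | None
    direction: str  # "match" | "plan-low" | "plan-high" | "missing"


def check_dose_consistency(
    plan: PlanSummary, chars: PatientCharacteristics
) -> ConsistencyResult:
    """Compare the plan's summed prescription with the recorded delivered dose.

    The record is rejected when |planned - recorded| exceeds 0.1 Gy
    (strict inequality) or when no delivered dose was recorded.
    """
    recorded = chars.recorded_delivered_dose_gy
    if recorded is None:
        return ConsistencyResult(accepted=False, mismatch_gy=None, direction="missing")
    total = plan.total_prescribed_gy
    mismatch = abs(total - recorded)
    if total < recorded:
        direction = "plan-low"
    elif total > recorded:
        direction = "plan-high"
    else:
        direction = "match"
    # small epsilon so a mismatch of exactly 0.1 Gy passes despite binary rounding
    return ConsistencyResult(
        accepted=mismatch <= DOSE_MISMATCH_LIMIT_GY + 1e-9,
        mismatch_gy=mismatch,
        direction=direction,
    )


# Keyword map applied to the RT-plan label, first hit wins (configurable stub;
# order matters: more specific phrases come first).
DEFAULT_REGION_KEYWORDS: dict[str, str] = {
    "pelvic bone": "bone-pelvic",
    "thoracic bone": "bone-thoracic",
    "brain": "intracranial",
    "cranial": "intracranial",
    "head": "head-and-neck",
    "neck": "head-and-neck",
    "breast": "breast",
    "spine": "spine",
    "pelvis": "pelvic",
    "prostate": "pelvic",
    "lung": "thoracic",
    "chest": "thoracic",
    "thorax": "thoracic",
    "abdomen": "abdominal",
    "liver": "abdominal",
    "arm": "extremities",
    "leg": "extremities",
    "limb": "extremities",
}

# Fallback bands of the isocenter z position, as fractions of the matched
# phantom's cranio-caudal extent measured from the feet (0) to the vertex (1).
DEFAULT_Z_BANDS: dict[str, tuple[float, float]] = {
    "intracranial": (0.92, 1.0),
    "head-and-neck": (0.80, 0.92),
    "thoracic": (0.55, 0.80),
    "abdominal": (0.45, 0.55),
    "pelvic": (0.30, 0.45),
    "extremities": (0.0, 0.30),
}


def categorize_treatment_region(
    plan: PlanSummary,
    isocenter_mm: np.ndarray | None = None,
    keyword_map: dict[str, str] | None = None,
    phantom_z_extent_mm: tuple[float, float] | None = None,
    z_bands: dict[str, tuple[float, float]] | None = None,
) -> str:
    """Categorize the treated body region from the plan label, else the isocenter.

    A configurable keyword map is applied to the plan label first; when
    no keyword matches, the isocenter's z position is located within
    bands of the matched phantom's cranio-caudal extent. Returns
    ``"uncategorized"`` when neither rule applies.
    """
    keyword_map = DEFAULT_REGION_KEYWORDS if keyword_map is None else keyword_map
    label = plan.plan_label.lower()
    for keyword, region in keyword_map.items():
        if keyword.lower() in label:
            return region
    iso = isocenter_mm if isocenter_mm is not None else plan.isocenter_mm
    if iso is not None and phantom_z_extent_mm is not None:
        lo, hi = phantom_z_extent_mm
        if hi > lo:
            frac = (float(iso[2]) - lo) / (hi - lo)
            if 0.0 <= frac <= 1.0:
                bands = DEFAULT_Z_BANDS if z_bands is None else z_bands
                for region, (b_lo, b_hi) in bands.items():
                    if b_lo <= frac <= b_hi:
                        return region
    return "uncategorized"
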