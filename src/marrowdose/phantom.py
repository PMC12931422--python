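"""Whole-body computational phantom model and habitus-based phantom selection.

A phantom is a labeled voxel raster: each bone voxel carries a bone-site
id (one of the 34 named skeletal sites, or a declared subset for
miniature phantoms) and a tissue subtype (cortical bone, trabecular
spongiosa, or medullary cavity). Alongside the rasters, the phantom
carries the reference-individual body metadata (age, sex, height,
weight) used to pick the closest-matching phantom for a patient.

Container format on disk: ``<name>.labels.nrrd`` + ``<name>.tissue.nrrd``
(written via SimpleITK, x-fastest axis order) + ``<name>.meta.json`` with
keys ``age_years``, ``sex``, ``height_cm``, ``weight_kg`` and
``site_name_map`` (site id -> Table-style site name).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .abm_fractions import BONE_SITE_NAMES, canonical_site_name

__all__ = [
    "TISSUE_NONE",
    "TISSUE_CORTICAL",
    "TISSUE_SPONGIOSA",
    "TISSUE_MEDULLARY",
    "PhantomMeta",
    "PatientCharacteristics",
    "Phantom",
    "load_phantom",
    "save_phantom",
    "select_phantom",
    "bone_site_voxels",
]

# Tissue subtype codes used in Phantom.tissue_volume.
TISSUE_NONE = 0
TISSUE_CORTICAL = 1
TISSUE_SPONGIOSA = 2
TISSUE_MEDULLARY = 3


@dataclass
class PhantomMeta:
    """Reference-individual body metadata of a phantom."""

    id: str
    age_years: float
    sex: str
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")


@dataclass
class PatientCharacteristics:
    """Patient habitus and the recorded delivered dose from the cohort database."""

    age_years: float
    sex: str
    height_cm: float | None = None
    weight_kg: float | None = None
    recorded_delivered_dose_gy: float | None = None

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age must be non-negative")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        for name in ("height_cm", "weight_kg"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")

    @property
    def missing_habitus(self) -> bool:
        return self.height_cm is None or self.weight_kg is None


@dataclass
class Phantom:
    """A labeled voxel phantom: bone-site ids + tissue subtypes + geometry + metadata."""

    label_volume: np.ndarray  # voxel -> bone-site id, 0 = non-bone
    tissue_volume: np.ndarray  # voxel -> tissue subtype code
    spacing: np.ndarray  # mm per axis
    origin: np.ndarray  # mm, phantom frame, center of voxel (0,0,0)
    meta: PhantomMeta
    site_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        self.tissue_volume = np.asarray(self.tissue_volume)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.label_volume.shape != self.tissue_volume.shape:
            raise ValueError(
                "label and tissue rasters must have the same shape, got "
                f"{self.label_volume.shape} vs {self.tissue_volume.shape}"
            )
        if self.label_volume.ndim != 3:
            raise ValueError("phantom rasters must be 3D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        bone = self.label_volume > 0
        tissue = self.tissue_volume != TISSUE_NONE
        if not np.array_equal(bone, tissue):
            raise ValueError("bone-site labels and tissue subtypes must cover the same voxels")
        for site_id, name in self.site_names.items():
            if canonical_site_name(name) not in BONE_SITE_NAMES:
                raise ValueError(f"unknown bone-site name: {name!r}")
        present = set(np.unique(self.label_volume)) - {0}
        unnamed = present - set(self.site_names)
        if unnamed:
            raise ValueError(f"bone-site ids without names: {sorted(unnamed)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_volume.shape  # type: ignore[return-value]

    @property
    def site_ids(self) -> list[int]:
        return sorted(set(np.unique(self.label_volume)) - {0})

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + idx * self.spacing

    @property
    def craniocaudal_extent_mm(self) -> tuple[float, float]:
        """(low, high) z range spanned by bone voxel centers, phantom frame."""
        idx = np.argwhere(self.label_volume > 0)
        z = self.origin[2] + idx[:, 2] * self.spacing[2]
        return float(z.min()), float(z.max())


def bone_site_voxels(phantom: Phantom, site_id: int, exclude_cortical: bool = False) -> np.ndarray:
    """``(N, 3)`` voxel indices of one bone site, optionally marrow-bearing tissue only.

    With ``exclude_cortical`` set, only trabecular-spongiosa and
    medullary-cavity voxels are returned — the voxels to which active
    marrow is assigned.
    """
    if site_id not in phantom.site_ids:
        raise KeyError(f"bone site {site_id} not present in phantom {phantom.meta.id}")
    mask = phantom.label_volume == site_id
    if exclude_cortical:
        mask &= phantom.tissue_volume != TISSUE_CORTICAL
    return np.argwhere(mask)


def _write_raster(array: np.ndarray, spacing: np.ndarray, origin: np.ndarray, path: Path) -> None:
    # our arrays are (x, y, z); SimpleITK's numpy bridge is (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def _read_raster(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    img = sitk.ReadImage(str(path))
    array = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return array, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin())


def save_phantom(phantom: Phantom, directory: str | Path, name: str | None = None) -> Path:
    """Write the three-file phantom container; returns the metadata path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or phantom.meta.id
    _write_raster(
        phantom.label_volume.astype(np.int16), phantom.spacing, phantom.origin,
        directory / f"{name}.labels.nrrd",
    )
    _write_raster(
        phantom.tissue_volume.astype(np.int16), phantom.spacing, phantom.origin,
        directory / f"{name}.tissue.nrrd",
    )
    meta_path = directory / f"{name}.meta.json"
    meta_path.write_text(json.dumps({
        "id": phantom.meta.id,
        "age_years": phantom.meta.age_years,
        "sex": phantom.meta.sex,
        "height_cm": phantom.meta.height_cm,
        "weight_kg": phantom.meta.weight_kg,
        "site_name_map": {str(k): v for k, v in phantom.site_names.items()},
    }, indent=2))
    return meta_path


def load_phantom(path: str | Path) -> Phantom:
    """Load a phantom container given its ``.meta.json`` path (or basename)."""
    path = Path(path)
    if path.name.endswith(".meta.json"):
        base = path.name[: -len(".meta.json")]
        directory = path.parent
    else:
        base = path.name
        directory = path.parent
        path = directory / f"{base}.meta.json"
    if not path.exists():
        raise FileNotFoundError(f"phantom metadata not found: {path}")
    meta_raw = json.loads(path.read_text())
    for key in ("id", "age_years", "sex", "height_cm", "weight_kg", "site_name_map"):
        if key not in meta_raw:
            raise ValueError(f"phantom metadata missing field {key!r}")
    labels, spacing, origin = _read_raster(directory / f"{base}.labels.nrrd")
    tissue, t_spacing, t_origin = _read_raster(directory / f"{base}.tissue.nrrd")
    if labels.shape != tissue.shape:
        raise ValueError(
            f"raster shape mismatch: labels {labels.shape} vs tissue {tissue.shape}"
        )
    if not (np.allclose(spacing, t_spacing) and np.allclose(origin, t_origin)):
        raise ValueError("label and tissue rasters disagree on geometry")
    meta = PhantomMeta(
        id=meta_raw["id"],
        age_years=float(meta_raw["age_years"]),
        sex=meta_raw["sex"],
        height_cm=float(meta_raw["height_cm"]),
        weight_kg=float(meta_raw["weight_kg"]),
    )
    site_names = {int(k): v for k, v in meta_raw["site_name_map"].items()}
    return Phantom(
        label_volume=labels, tissue_volume=tissue,
        spacing=spacing, origin=origin, meta=meta, site_names=site_names,
    )


def select_phantom(
    chars: PatientCharacteristics, library: list[PhantomMeta]
) -> tuple[str, bool]:
    """Pick the closest-matching phantom by strict lexicographic priority.

    Priority order is age > sex > height > weight: candidates minimizing
    the absolute age difference are kept; among those, same-sex
    candidates are required if any exists (otherwise selection proceeds
    with the opposite sex and the returned flag is True); then the
    height difference is minimized, then the weight difference; a
    remaining tie goes to the smallest phantom id. Missing patient
    height/weight skips that comparison level.

    Returns ``(phantom_id, sex_mismatch_flag)``.
    """
    if not library:
        raise ValueError("phantom library is empty")
    pool = list(library)

    age_delta = [abs(m.age_years - chars.age_years) for m in pool]
    best = min(age_delta)
    pool = [m for m, d in zip(pool, age_delta) if d == best]

    sex_mismatch = not any(m.sex == chars.sex for m in pool)
    if not sex_mismatch:
        pool = [m for m in pool if m.sex == chars.sex]

    if chars.height_cm is not None:
        hd = [abs(m.height_cm - chars.height_cm) for m in pool]
        best = min(hd)
        pool = [m for m, d in zip(pool, hd) if d == best]
    if chars.weight_kg is not None:
        wd = [abs(m.weight_kg - chars.weight_kg) for m in pool]
        best = min(wd)
        pool = [m for m, d in zip(pool, wd) if d == best]

    chosen = min(pool, key=lambda m: m.id)
    return chosen.id, sex_mismatch
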