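"""Synthetic fixtures: miniature phantoms, CT series, dose grids, plans, cohorts.

Everything the reconstruction pipeline consumes can be generated here
without any external data: labeled mini-phantoms with a handful of real
bone-site names, CT volumes in which the phantom skeleton is embedded
at bone-range HU under a known rigid displacement, uniform-box or
Gaussian-beam dose grids, plan summaries, and whole cohort directory
trees with deliberately planted record mismatches and misalignments to
exercise every exclusion path. All randomness is seeded; the same spec
and seed reproduce a fixture byte for byte.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dicomio import Beam, PlanSummary, write_ct_series, write_rt_dose, write_rt_plan
from .grids import CTVolume, DoseGrid
from .phantom import (
    TISSUE_CORTICAL,
    TISSUE_MEDULLARY,
    TISSUE_SPONGIOSA,
    Phantom,
    PhantomMeta,
    save_phantom,
)
from .registration import RigidTransform

__all__ = [
    "SiteSpec",
    "FixtureSpec",
    "DEFAULT_SITES",
    "make_phantom",
    "make_library",
    "make_ct_from_phantom",
    "make_dose_grid",
    "make_plan",
    "make_cohort",
    "rotation_about_axis",
]


@dataclass
class SiteSpec:
    """One bone site of a miniature phantom: name, voxel count, tissue split."""

    name: str
    count: int
    cortical_fraction: float = 0.25
    medullary_fraction: float = 0.0


# A six-site miniature skeleton spanning cranium to proximal femora; the
# lateral stagger makes the cloud asymmetric so rigid registration has a
# unique optimum.
DEFAULT_SITES: tuple[SiteSpec, ...] = (
    SiteSpec("Craniofacial bones", 600, 0.30),
    SiteSpec("Ribs", 400, 0.20),
    SiteSpec("Lumbar vertebrae", 300, 0.20),
    SiteSpec("Sacrum", 150, 0.20),
    SiteSpec("Os coxae", 500, 0.25),
    SiteSpec("Femora, proximal head", 200, 0.30, medullary_fraction=0.15),
)

_LATERAL_OFFSETS = ((0, 0), (-5, 3), (4, -2), (-2, -4), (3, 2), (-6, -1))


@dataclass
class FixtureSpec:
    """Full description of a synthetic patient fixture."""

    sites: tuple[SiteSpec, ...] = DEFAULT_SITES
    grid_shape: tuple[int, int, int] = (44, 44, 80)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    true_transform: RigidTransform = field(default_factory=RigidTransform.identity)
    hu_bone: float = 1000.0
    hu_soft: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0


def skeleton_centroid(phantom: Phantom) -> np.ndarray:
    """Centroid (mm) of the phantom's bone voxel centers — the natural anchor
    for fixture rotations that must keep the skeleton on the CT grid."""
    idx = np.argwhere(phantom.label_volume > 0)
    return phantom.voxel_centers(idx).mean(axis=0)


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _blob_indices(count: int, center: np.ndarray) -> np.ndarray:
    """A compact connected blob of exactly ``count`` voxels around ``center``.

    Voxels of a bounding cube are ranked by distance from the center
    (ties broken lexicographically for determinism) and the nearest
    ``count`` are kept — a digital ball, always connected.
    """
    r = int(np.ceil((count * 3 / (4 * np.pi)) ** (1 / 3))) + 2
    grid = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].reshape(3, -1).T
    d2 = (grid**2).sum(axis=1)
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0], d2))
    chosen = grid[order[:count]]
    return chosen + np.asarray(center, dtype=int)


def make_phantom(
    spec: FixtureSpec | None = None,
    phantom_id: str = "mini30M",
    age_years: float = 30.0,
    sex: str = "M",
    height_cm: float = 176.0,
    weight_kg: float = 73.0,
) -> Phantom:
    """Build a miniature labeled phantom from a fixture spec.

    Sites are stacked cranio-caudally with lateral stagger; within each
    site the outermost voxels (per the cortical fraction) are cortical
    shell, an innermost core (per the medullary fraction) is medullary
    cavity, and the remainder is trabecular spongiosa. Per-site voxel
    counts match the spec exactly.
    """
    spec = spec or FixtureSpec()
    shape = spec.grid_shape
    labels = np.zeros(shape, dtype=np.int16)
    tissue = np.zeros(shape, dtype=np.int16)
    site_names: dict[int, str] = {}
    cx, cy = shape[0] // 2, shape[1] // 2
    z_cursor = shape[2] - 6
    for i, site in enumerate(spec.sites):
        radius = int(np.ceil((site.count * 3 / (4 * np.pi)) ** (1 / 3)))
        z_cursor -= radius
        ox, oy = _LATERAL_OFFSETS[i % len(_LATERAL_OFFSETS)]
        center = np.array([cx + ox, cy + oy, z_cursor])
        idx = _blob_indices(site.count, center)
        if np.any(idx < 0) or np.any(idx >= np.array(shape)):
            raise ValueError(f"site {site.name!r} does not fit the phantom grid")
        if np.any(labels[idx[:, 0], idx[:, 1], idx[:, 2]] != 0):
            raise ValueError(f"site {site.name!r} overlaps a previously placed site")
        site_id = i + 1
        labels[idx[:, 0], idx[:, 1], idx[:, 2]] = site_id
        site_names[site_id] = site.name
        # rank voxels by distance from the blob center: shell -> cortical,
        # core -> medullary, middle -> spongiosa
        d2 = ((idx - center) ** 2).sum(axis=1)
        order = np.argsort(d2, kind="stable")
        n_cort = int(round(site.cortical_fraction * site.count))
        n_med = int(round(site.medullary_fraction * site.count))
        codes = np.full(site.count, TISSUE_SPONGIOSA, dtype=np.int16)
        if n_med:
            codes[order[:n_med]] = TISSUE_MEDULLARY
        if n_cort:
            codes[order[site.count - n_cort :]] = TISSUE_CORTICAL
        tissue[idx[:, 0], idx[:, 1], idx[:, 2]] = codes
        z_cursor -= radius + 2
    return Phantom(
        label_volume=labels,
        tissue_volume=tissue,
        spacing=np.asarray(spec.spacing_mm),
        origin=np.asarray(spec.origin_mm),
        meta=PhantomMeta(id=phantom_id, age_years=age_years, sex=sex,
                         height_cm=height_cm, weight_kg=weight_kg),
        site_names=site_names,
    )


def make_library(directory: str | Path | None = None) -> list[Phantom]:
    """A small reference library of mini phantoms differing in age/sex/habitus."""
    spec = FixtureSpec()
    phantoms = [
        make_phantom(spec, "mini30M", 30, "M", 176, 73),
        make_phantom(spec, "mini30F", 30, "F", 163, 60),
        make_phantom(spec, "mini15M", 15, "M", 170, 58),
        make_phantom(spec, "mini15F", 15, "F", 162, 53),
    ]
    if directory is not None:
        for p in phantoms:
            save_phantom(p, directory)
    return phantoms


def make_ct_from_phantom(
    phantom: Phantom,
    true_transform: RigidTransform | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    spacing_mm: np.ndarray | None = None,
    origin_mm: np.ndarray | None = None,
    hu_bone: float = 1000.0,
    hu_soft: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CTVolume:
    """Render the phantom skeleton into a CT volume under a known rigid transform.

    Bone voxels land at ``hu_bone`` (plus optional Gaussian texture
    noise) at their transformed nearest-voxel positions; everything else
    is ``hu_soft``. By default the CT grid shares the phantom geometry,
    so the identity transform reproduces the skeleton voxel for voxel.
    Raises if the transformed skeleton falls outside the CT grid.
    """
    true_transform = true_transform or RigidTransform.identity()
    shape = grid_shape or phantom.shape
    spacing = np.asarray(spacing_mm if spacing_mm is not None else phantom.spacing, dtype=float)
    origin = np.asarray(origin_mm if origin_mm is not None else phantom.origin, dtype=float)
    hu = np.full(shape, hu_soft, dtype=float)
    bone_idx = np.argwhere(phantom.label_volume > 0)
    moved = true_transform.apply(phantom.voxel_centers(bone_idx))
    ct_idx = np.round((moved - origin) / spacing).astype(int)
    if np.any(ct_idx < 0) or np.any(ct_idx >= np.array(shape)):
        raise ValueError("transformed skeleton is clipped by the CT grid")
    hu[ct_idx[:, 0], ct_idx[:, 1], ct_idx[:, 2]] = hu_bone
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=len(ct_idx))
        hu[ct_idx[:, 0], ct_idx[:, 1], ct_idx[:, 2]] += noise
    return CTVolume(values=hu, spacing=spacing, origin=origin)


def make_dose_grid(
    grid_shape: tuple[int, int, int],
    spacing_mm,
    origin_mm,
    uniform_box: tuple[float, np.ndarray, np.ndarray] | None = None,
    gaussian_beam: tuple[float, float, int, np.ndarray] | None = None,
) -> DoseGrid:
    """A synthetic dose field: uniform box and/or axis-aligned Gaussian beam.

    ``uniform_box`` is (dose_gy, lower_mm, upper_mm): voxel centers
    within the closed box receive the dose. ``gaussian_beam`` is
    (peak_gy, sigma_mm, axis, center_mm): dose falls off with radial
    distance from a beam line along the given axis.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    origin = np.asarray(origin_mm, dtype=float)
    dose = np.zeros(grid_shape, dtype=float)
    axes = [origin[a] + np.arange(grid_shape[a]) * spacing[a] for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    if uniform_box is not None:
        level, lo, hi = uniform_box
        if level < 0:
            raise ValueError("dose must be non-negative")
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        inside = (
            (xx >= lo[0]) & (xx <= hi[0])
            & (yy >= lo[1]) & (yy <= hi[1])
            & (zz >= lo[2]) & (zz <= hi[2])
        )
        dose[inside] += level
    if gaussian_beam is not None:
        peak, sigma, axis, center = gaussian_beam
        if peak < 0:
            raise ValueError("dose must be non-negative")
        center = np.asarray(center, dtype=float)
        coords = [xx, yy, zz]
        r2 = np.zeros(grid_shape)
        for a in range(3):
            if a != axis:
                r2 += (coords[a] - center[a]) ** 2
        dose += peak * np.exp(-r2 / (2.0 * sigma**2))
    return DoseGrid(values=dose, spacing=spacing, origin=origin)


def make_plan(
    beams: list[tuple[str, float]],
    isocenter_mm=None,
    plan_label: str = "SYNTH PLAN",
) -> PlanSummary:
    """A plan summary whose per-beam prescriptions sum to the intended Rx."""
    iso = None if isocenter_mm is None else np.asarray(isocenter_mm, dtype=float)
    return PlanSummary(
        beams=[Beam(label, float(d), iso) for label, d in beams],
        plan_label=plan_label,
    )


# ------------------------------------------------------------------ cohorts

_REGION_TEMPLATES = (
    # (plan label, covered z band as fraction of skeleton extent)
    ("PELVIS IMRT", (0.05, 0.40)),
    ("BRAIN 3DCRT", (0.75, 1.00)),
    ("CHEST VMAT", (0.45, 0.75)),
)


def make_cohort(
    n_patients: int,
    out_dir: str | Path,
    seed: int = 0,
    mismatch_patients: int = 0,
    misaligned_patients: int = 0,
    multi_session_patients: int = 0,
    rx_gy: float = 50.0,
) -> Path:
    """Write a synthetic patient cohort as a DICOM-RT directory tree.

    The first ``mismatch_patients`` patients get a recorded delivered
    dose that disagrees with the plan by well over 0.1 Gy (alternating
    plan-low / plan-high); the next ``misaligned_patients`` get sessions
    whose planted review flags mark a rejected alignment (emulating the
    posture failures a human evaluator would catch); the last
    ``multi_session_patients`` get two treatment sessions. Everything is
    reproducible from the seed. Returns the manifest path.

    Layout: ``<out>/phantoms/`` (library), ``<out>/patients/<pid>/<sid>/``
    (CT series + ``plan.dcm`` + ``dose.dcm``), ``<out>/cohort_manifest.csv``
    and ``<out>/review_flags.csv``.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    if mismatch_patients + misaligned_patients > n_patients:
        raise ValueError("more planted exclusions than patients")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    library = make_library(out_dir / "phantoms")
    phantom_by_sex = {"M": library[0], "F": library[1]}

    manifest_rows = []
    flag_rows = []
    for p in range(n_patients):
        pid = f"P{p:04d}"
        sex = "M" if rng.random() < 0.5 else "F"
        age = float(np.round(rng.uniform(40, 75), 1))
        height = float(np.round(rng.normal(176 if sex == "M" else 163, 6), 1))
        weight = float(np.round(rng.normal(78 if sex == "M" else 65, 9), 1))
        phantom = phantom_by_sex[sex]
        n_sessions = 2 if p >= n_patients - multi_session_patients else 1
        mismatched = p < mismatch_patients
        misaligned = mismatch_patients <= p < mismatch_patients + misaligned_patients
        for s in range(n_sessions):
            sid = f"{pid}_S{s}"
            sdir = out_dir / "patients" / pid / f"S{s}"
            label, z_band = _REGION_TEMPLATES[int(rng.integers(len(_REGION_TEMPLATES)))]
            angle = np.deg2rad(rng.uniform(-6, 6))
            shift = rng.uniform(-10, 10, size=3)
            transform = RigidTransform.about_point(
                rotation_about_axis([0, 0, 1], angle), shift,
                skeleton_centroid(phantom),
            )
            ct = make_ct_from_phantom(
                phantom, transform, noise_sd=30.0, seed=int(rng.integers(2**31))
            )
            write_ct_series(ct, sdir / "ct", patient_id=pid, uid_seed=f"{seed}/{sid}/ct")

            z_lo_ext, z_hi_ext = phantom.craniocaudal_extent_mm
            span = z_hi_ext - z_lo_ext
            box_lo = np.array([-1e4, -1e4, z_lo_ext + z_band[0] * span])
            box_hi = np.array([1e4, 1e4, z_lo_ext + z_band[1] * span])
            dose = make_dose_grid(
                phantom.shape, phantom.spacing, phantom.origin,
                uniform_box=(rx_gy, box_lo, box_hi),
            )
            write_rt_dose(dose, sdir / "dose.dcm", patient_id=pid,
                          uid_seed=f"{seed}/{sid}/dose")
            iso_z = z_lo_ext + span * (z_band[0] + z_band[1]) / 2
            plan = make_plan(
                [("AP", 0.6 * rx_gy), ("PA", 0.4 * rx_gy)],
                isocenter_mm=[phantom.origin[0], phantom.origin[1], iso_z],
                plan_label=label,
            )
            write_rt_plan(plan, sdir / "plan.dcm", patient_id=pid,
                          uid_seed=f"{seed}/{sid}/plan")

            recorded = rx_gy
            if mismatched:
                recorded = rx_gy + (0.5 if p % 2 else -0.5)
            manifest_rows.append({
                "patient_id": pid, "session_id": sid,
                "session_dir": str(sdir.relative_to(out_dir)),
                "age_years": age, "sex": sex,
                "height_cm": height, "weight_kg": weight,
                "recorded_dose_gy": recorded,
            })
            reject_this = misaligned and s == 0
            flag_rows.append({
                "session_id": sid,
                "evaluator_1": True,
                "evaluator_2": not reject_this,
            })

    manifest = out_dir / "cohort_manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest_rows[0].keys()))
        writer.writeheader()
        writer.writerows(manifest_rows)
    with open(out_dir / "review_flags.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["session_id", "evaluator_1", "evaluator_2"])
        writer.writeheader()
        writer.writerows(flag_rows)
    return manifest
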