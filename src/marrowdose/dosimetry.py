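"""Marrow-fraction-weighted dose and dose-volume metrics.

Each bone site's reference marrow fraction is spread homogeneously over
that site's marrow-bearing voxels (trabecular spongiosa and medullary
cavity; cortical bone carries no active marrow and is excluded). Doses
are sampled from the treatment-planning dose grid by trilinear
interpolation at the registered voxel-center positions, with exactly
zero dose assigned to skeletal voxels outside the dose-grid boundary.

The weighted voxel sample defines an exact discrete dose distribution:
no histogram binning is used. The cumulative dose-volume curve is
V(d) = 100 * P(dose >= d), V# metrics read it at fixed doses, and D#
metrics are weighted percentiles of the distribution (D# is the
(100-#)th percentile with the lower-boundary convention, so D50 is the
median marrow dose and is 0 when more than half the marrow is
unirradiated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .abm_fractions import ABMFractionTable, default_table
from .grids import DoseGrid
from .phantom import TISSUE_CORTICAL, Phantom, bone_site_voxels
from .registration import RigidTransform

__all__ = [
    "WeightedDoseSample",
    "DVH",
    "ABMDoseResult",
    "assign_voxel_weights",
    "sample_dose",
    "mean_abm_dose",
    "compute_dvh",
    "dose_metrics",
    "accumulate_sessions",
]


@dataclass
class WeightedDoseSample:
    """Registered marrow-bearing voxels with their marrow-fraction weights and doses.

    ``weights`` sum to the total marrow fraction of the sites present in
    the phantom (1.0 for a full 34-site phantom). ``doses`` is filled by
    :func:`sample_dose` and is all-zero until then.
    """

    points: np.ndarray  # (N, 3) mm, patient frame
    weights: np.ndarray  # (N,) fraction of total active marrow
    site_ids: np.ndarray  # (N,) bone-site id per voxel
    phantom_id: str
    voxel_indices: np.ndarray | None = None  # (N, 3) phantom voxel index
    doses: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.site_ids = np.asarray(self.site_ids)
        if self.doses is None:
            self.doses = np.zeros(len(self.weights))
        self.doses = np.asarray(self.doses, dtype=float)
        if not (len(self.points) == len(self.weights) == len(self.site_ids) == len(self.doses)):
            raise ValueError("points, weights, site_ids and doses must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")

    def __len__(self) -> int:
        return len(self.weights)

    def with_doses(self, doses: np.ndarray) -> "WeightedDoseSample":
        return WeightedDoseSample(
            points=self.points, weights=self.weights, site_ids=self.site_ids,
            phantom_id=self.phantom_id, voxel_indices=self.voxel_indices,
            doses=np.asarray(doses, dtype=float),
        )


def assign_voxel_weights(
    phantom: Phantom,
    transform: RigidTransform,
    age_years: float,
    sex: str,
    table: ABMFractionTable | None = None,
) -> WeightedDoseSample:
    """Distribute each site's marrow fraction over its non-cortical voxels.

    Every spongiosa/medullary voxel of a site receives weight
    ``site fraction / n_noncortical``; cortical voxels carry no marrow
    and are excluded, as are sites whose fraction is zero for this
    (age, sex). Voxel centers are mapped to the patient frame with the
    registration transform.
    """
    table = table or default_table()
    pts_list, w_list, id_list, idx_list = [], [], [], []
    for site_id in phantom.site_ids:
        name = phantom.site_names[site_id]
        frac = table.fraction(name, age_years, sex)
        if frac == 0.0:
            continue  # no active marrow at this site for this age/sex
        idx = bone_site_voxels(phantom, site_id, exclude_cortical=True)
        if len(idx) == 0:
            raise ValueError(
                f"site {name!r} has marrow fraction {frac} but no non-cortical voxels"
            )
        pts_list.append(phantom.voxel_centers(idx))
        w_list.append(np.full(len(idx), frac / len(idx)))
        id_list.append(np.full(len(idx), site_id))
        idx_list.append(idx)
    if not pts_list:
        raise ValueError("phantom holds no active marrow for this age/sex")
    return WeightedDoseSample(
        points=transform.apply(np.vstack(pts_list)),
        weights=np.concatenate(w_list),
        site_ids=np.concatenate(id_list),
        phantom_id=phantom.meta.id,
        voxel_indices=np.vstack(idx_list),
    )


def sample_dose(grid: DoseGrid, points: np.ndarray) -> np.ndarray:
    """Trilinear dose at each patient-frame point; exactly 0 outside the grid."""
    axes = [grid.origin[a] + np.arange(grid.shape[a]) * grid.spacing[a] for a in range(3)]
    interp = RegularGridInterpolator(
        axes, grid.dose, method="linear", bounds_error=False, fill_value=0.0
    )
    doses = interp(np.atleast_2d(np.asarray(points, dtype=float)))
    return np.maximum(doses, 0.0)


def mean_abm_dose(sample: WeightedDoseSample) -> float:
    """Marrow-fraction-weighted mean dose: sum(w*d) / sum(w)."""
    total_w = sample.weights.sum()
    if total_w <= 0:
        raise ValueError("sample has zero total weight")
    return float(np.dot(sample.weights, sample.doses) / total_w)


@dataclass
class DVH:
    """Exact cumulative dose-volume curve of a weighted discrete dose sample.

    ``atoms`` are the distinct dose values (ascending); ``v_percent[k]``
    is V(atoms[k]) = 100 * P(dose >= atoms[k]). Between atoms the curve
    is a right-continuous staircase.
    """

    atoms: np.ndarray
    v_percent: np.ndarray
    cdf: np.ndarray  # P(dose <= atoms[k])

    def volume_at_least(self, dose: float) -> float:
        """V(d): percent of marrow receiving at least ``dose`` Gy."""
        if dose <= self.atoms[0]:
            return 100.0
        k = np.searchsorted(self.atoms, dose, side="left")
        if k >= len(self.atoms):
            return 0.0
        return float(self.v_percent[k])

    def percentile_dose(self, p: float) -> float:
        """Lower weighted quantile: smallest atom d with P(dose <= d) >= p."""
        if not 0 < p <= 1:
            raise ValueError("p must be in (0, 1]")
        k = np.searchsorted(self.cdf, p - 1e-12, side="left")
        k = min(k, len(self.atoms) - 1)
        return float(self.atoms[k])

    def d_metric(self, percent: float) -> float:
        """D#: dose exceeded by #% of the marrow volume ((100-#)th percentile)."""
        return self.percentile_dose(1.0 - percent / 100.0)

    def curve(self) -> np.ndarray:
        """Staircase polyline (dose, V%) including both corners of every step.

        Trapezoidal integration of V/100 over this polyline reproduces
        the weighted mean dose exactly.
        """
        doses = [self.atoms[0]]
        vols = [self.v_percent[0]]
        for k in range(1, len(self.atoms)):
            # V drops immediately past each atom: on (a[k-1], a[k]] the curve
            # sits at V(a[k])
            doses.extend([self.atoms[k - 1], self.atoms[k]])
            vols.extend([self.v_percent[k], self.v_percent[k]])
        doses.append(self.atoms[-1])
        vols.append(0.0)
        return np.column_stack([doses, vols])

    def mean(self) -> float:
        """Mean dose recovered from the curve (integral of V(d)/100 over d)."""
        c = self.curve()
        return float(np.trapezoid(c[:, 1] / 100.0, c[:, 0]) + self.atoms[0])


def compute_dvh(sample: WeightedDoseSample) -> DVH:
    """Exact weighted empirical cumulative DVH (no binning)."""
    total_w = sample.weights.sum()
    if total_w <= 0:
        raise ValueError("sample has zero total weight")
    order = np.argsort(sample.doses, kind="stable")
    d_sorted = sample.doses[order]
    w_sorted = sample.weights[order] / total_w
    atoms, start = np.unique(d_sorted, return_index=True)
    cum = np.concatenate([[0.0], np.cumsum(w_sorted)])
    # weight strictly below each atom, and at-or-below each atom
    below = cum[start]
    bounds = np.append(start[1:], len(d_sorted))
    at_or_below = cum[bounds]
    v = 100.0 * (1.0 - below)
    return DVH(atoms=atoms, v_percent=v, cdf=at_or_below)


@dataclass
class ABMDoseResult:
    """Dose and dose-volume summary of one session (or a cumulative sum of sessions)."""

    mean_gy: float
    mean_per_rx: float | None  # Gy per Gy of prescribed dose
    d50: float
    d10: float
    d1: float
    v5: float
    v10: float
    v20: float
    dvh: DVH
    sessions_included: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "mean_gy": self.mean_gy, "mean_per_rx": self.mean_per_rx,
            "d50": self.d50, "d10": self.d10, "d1": self.d1,
            "v5": self.v5, "v10": self.v10, "v20": self.v20,
        }


def dose_metrics(
    sample: WeightedDoseSample,
    total_prescribed_gy: float | None = None,
    sessions: list[str] | None = None,
) -> ABMDoseResult:
    """Mean, D50/D10/D1 and V5/V10/V20 of a weighted dose sample."""
    dvh = compute_dvh(sample)
    mean = mean_abm_dose(sample)
    if total_prescribed_gy is None or total_prescribed_gy == 0:
        mean_per_rx = None
    else:
        mean_per_rx = mean / total_prescribed_gy
    return ABMDoseResult(
        mean_gy=mean,
        mean_per_rx=mean_per_rx,
        d50=dvh.d_metric(50), d10=dvh.d_metric(10), d1=dvh.d_metric(1),
        v5=dvh.volume_at_least(5.0), v10=dvh.volume_at_least(10.0),
        v20=dvh.volume_at_least(20.0),
        dvh=dvh,
        sessions_included=sessions or [],
    )


def accumulate_sessions(samples: list[WeightedDoseSample]) -> WeightedDoseSample:
    """Per-voxel dose sum across sessions delivered on one shared phantom.

    All sessions must use the same phantom (same voxel identity space);
    weights are taken once, doses are summed voxelwise.
    """
    if not samples:
        raise ValueError("no sessions to accumulate")
    first = samples[0]
    for s in samples[1:]:
        if s.phantom_id != first.phantom_id:
            raise ValueError(
                f"sessions use different phantoms: {first.phantom_id!r} vs {s.phantom_id!r}"
            )
        if len(s) != len(first):
            raise ValueError("sessions disagree on phantom voxel count")
    total = np.sum([s.doses for s in samples], axis=0)
    return first.with_doses(total)
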