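"""Registration quality assurance: overlap scoring, overlays, review bookkeeping.

Registration quality is scored with the volume overlap fraction

    VOF = |S_patient ∩ S_phantom| / |S_patient| × 100 %

where both S sets are voxel-index sets on the patient CT grid (the
registered phantom points are snapped to their nearest patient voxel).
The VOF is asymmetric — its denominator is always the patient skeleton —
and it is reported for cohort comparison only, never applied as an
automatic acceptance cutoff: a thin-boned but well-aligned skeleton can
score low while its dose estimate is accurate. Acceptance is a human
decision, recorded as two independent evaluator flags that must both be
positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from scipy import stats

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "QARecord",
    "compute_vof",
    "render_overlay",
    "record_review",
    "vof_association",
    "session_acceptance_rollup",
]

PATIENT_COLOR = "purple"
PHANTOM_COLOR = "green"


@dataclass
class QARecord:
    """Per-session QA outcome: VOF score plus the two-evaluator review."""

    vof_percent: float
    evaluator_1: bool
    evaluator_2: bool
    overlay_path: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vof_percent <= 100.0:
            raise ValueError("VOF must be within [0, 100] percent")

    @property
    def accepted(self) -> bool:
        return self.evaluator_1 and self.evaluator_2


def _as_index_set(indices: np.ndarray) -> set[tuple[int, int, int]]:
    idx = np.atleast_2d(np.asarray(indices, dtype=np.int64))
    return set(map(tuple, idx))


def compute_vof(
    patient_voxels: np.ndarray,
    phantom_points: np.ndarray,
    grid,
) -> float:
    """Volume overlap fraction of the registered phantom over the patient skeleton.

    ``patient_voxels`` are integer voxel indices on the patient CT grid;
    ``phantom_points`` are mm positions already mapped into the patient
    frame and are discretized to their nearest patient voxel. Duplicate
    hits collapse: both sides are treated as sets.
    """
    patient = _as_index_set(patient_voxels)
    if not patient:
        raise ValueError("patient voxel set is empty")
    phantom = _as_index_set(grid.nearest_voxel(phantom_points))
    return 100.0 * len(patient & phantom) / len(patient)


def render_overlay(
    patient_points: np.ndarray,
    phantom_points: np.ndarray,
    out_path: str | Path,
) -> Path:
    """Write a three-view scatter overlay (patient purple, phantom green).

    Output is deterministic for fixed input: fixed canvas, no
    timestamps, points drawn in input order.
    """
    patient = np.atleast_2d(np.asarray(patient_points, dtype=float))
    phantom = np.atleast_2d(np.asarray(phantom_points, dtype=float))
    if patient.size == 0 or phantom.size == 0:
        raise ValueError("both point sets must be non-empty")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    views = [((0, 2), "x (mm)", "z (mm)"), ((1, 2), "y (mm)", "z (mm)"), ((0, 1), "x (mm)", "y (mm)")]
    fig, axes = plt.subplots(1, 3, figsize=(10.5, 4.0), dpi=100)
    for ax, ((a, b), xl, yl) in zip(axes, views):
        ax.scatter(patient[:, a], patient[:, b], s=1, c=PATIENT_COLOR, label="patient")
        ax.scatter(phantom[:, a], phantom[:, b], s=1, c=PHANTOM_COLOR, label="phantom")
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        ax.set_aspect("equal")
    axes[0].legend(loc="upper right", markerscale=6)
    fig.tight_layout()
    fig.savefig(out_path, metadata={"Software": None})
    plt.close(fig)
    return out_path


def record_review(vof_percent: float, evaluator_1: bool, evaluator_2: bool,
                  overlay_path: str | None = None) -> QARecord:
    """Record the two-evaluator visual review; accepted only if both agree."""
    return QARecord(
        vof_percent=float(vof_percent),
        evaluator_1=bool(evaluator_1),
        evaluator_2=bool(evaluator_2),
        overlay_path=overlay_path,
    )


def vof_association(
    vof_scores: np.ndarray, characteristics: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rank correlation of VOF against each patient characteristic.

    Sex is expected binary-coded (0/1); rank correlation handles ties by
    average ranks and is robust to skew. A constant characteristic has
    no defined correlation and is reported as missing (NaN), not zero.
    Returns a frame with columns characteristic, rho, p, n.
    """
    vof = np.asarray(vof_scores, dtype=float)
    if len(vof) < 3:
        raise ValueError("need at least 3 records for an association analysis")
    if len(vof) != len(characteristics):
        raise ValueError("vof_scores and characteristics disagree on length")
    rows = []
    for col in characteristics.columns:
        x = pd.to_numeric(characteristics[col], errors="coerce").to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(vof)
        n = int(mask.sum())
        if n < 3 or np.all(x[mask] == x[mask][0]):
            rows.append({"characteristic": col, "rho": np.nan, "p": np.nan, "n": n})
            continue
        rho, p = stats.spearmanr(x[mask], vof[mask])
        rows.append({"characteristic": col, "rho": float(rho), "p": float(p), "n": n})
    return pd.DataFrame(rows)


def session_acceptance_rollup(
    sessions_by_patient: dict[str, list[QARecord]]
) -> dict[str, bool]:
    """Patient-level inclusion: a patient is included iff ALL sessions are accepted.

    A patient with any rejected session is excluded entirely, dropping
    even that patient's otherwise-acceptable sessions.
    """
    return {
        patient: all(rec.accepted for rec in records)
        for patient, records in sessions_by_patient.items()
    }
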