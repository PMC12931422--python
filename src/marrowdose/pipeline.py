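"""Per-session and per-cohort orchestration of the dose-reconstruction workflow.

Stage order per treatment session: read the DICOM-RT set -> record
completeness check (plan vs recorded delivered dose) -> phantom
selection -> skeletal extraction -> rigid registration -> VOF / review
-> marrow-fraction weighting -> dose sampling -> dose and dose-volume
metrics. A failure at any stage yields a rejected session record with
the stage and reason — never an exception escaping the run.

At the cohort level the selection bookkeeping mirrors a study-population
flowchart: sessions excluded for dose mismatch (by direction), sessions
rejected at alignment review, accepted sessions, and the patient-level
rule that one rejected session excludes the whole patient (all of that
patient's sessions). Cumulative dosimetry for multi-session patients
sums voxelwise doses on a single shared phantom selected from the
patient's characteristics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dicomio import (
    check_dose_consistency,
    categorize_treatment_region,
    read_ct_series,
    read_rt_dose,
    read_rt_plan,
)
from .dosimetry import (
    ABMDoseResult,
    WeightedDoseSample,
    accumulate_sessions,
    assign_voxel_weights,
    dose_metrics,
    sample_dose,
)
from .phantom import PatientCharacteristics, Phantom, load_phantom, select_phantom
from .qa import QARecord, compute_vof, record_review, render_overlay, session_acceptance_rollup
from .registration import (
    DEFAULT_HU_THRESHOLD,
    ICPConfig,
    extract_skeleton,
    icp_register,
    phantom_skeleton_points,
)

__all__ = ["RunConfig", "SessionResult", "CohortReport", "run_session", "run_cohort"]


@dataclass
class RunConfig:
    """Configuration of a reconstruction run (serialized with the outputs)."""

    phantom_dir: str | Path | None = None
    output_dir: str | Path | None = None
    hu_threshold: float = DEFAULT_HU_THRESHOLD
    icp: ICPConfig = field(default_factory=ICPConfig)
    # "auto-accept" or "flags:<csv path>" with session_id,evaluator_1,evaluator_2
    acceptance_policy: str = "auto-accept"
    region_keywords: dict[str, str] | None = None
    render_overlays: bool = False
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["phantom_dir"] = str(d["phantom_dir"]) if d["phantom_dir"] else None
        d["output_dir"] = str(d["output_dir"]) if d["output_dir"] else None
        return json.dumps(d, indent=2)


@dataclass
class SessionResult:
    patient_id: str
    session_id: str
    status: str  # "accepted" | "rejected"
    stage: str  # last stage reached
    reason: str = ""
    mismatch_direction: str = ""
    mismatch_gy: float | None = None
    phantom_id: str = ""
    vof_percent: float | None = None
    region: str = ""
    total_prescribed_gy: float | None = None
    metrics: ABMDoseResult | None = None
    sample: WeightedDoseSample | None = None
    overlay_path: str | None = None
    qa: QARecord | None = None

    def as_row(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "session_id": self.session_id,
            "status": self.status,
            "stage": self.stage,
            "reason": self.reason,
            "mismatch_direction": self.mismatch_direction,
            "mismatch_gy": self.mismatch_gy,
            "phantom_id": self.phantom_id,
            "vof_percent": self.vof_percent,
            "region": self.region,
            "total_prescribed_gy": self.total_prescribed_gy,
        }
        if self.metrics is not None:
            row.update(self.metrics.as_row())
        return row


def _review_flags(policy: str, session_id: str) -> tuple[bool, bool]:
    if policy == "auto-accept":
        return True, True
    if policy.startswith("flags:"):
        flags_path = policy[len("flags:"):]
        table = pd.read_csv(flags_path, dtype={"session_id": str})
        row = table.loc[table["session_id"] == session_id]
        if row.empty:
            raise ValueError(f"no review flags recorded for session {session_id}")
        r = row.iloc[0]
        to_bool = lambda v: str(v).strip().lower() in ("true", "1", "yes")
        return to_bool(r["evaluator_1"]), to_bool(r["evaluator_2"])
    raise ValueError(f"unknown acceptance policy: {policy!r}")


def run_session(
    session_dir: str | Path,
    chars: PatientCharacteristics,
    phantom: Phantom,
    config: RunConfig | None = None,
    patient_id: str = "",
    session_id: str = "",
) -> SessionResult:
    """Run the full reconstruction workflow for one treatment session.

    ``session_dir`` must hold ``ct/`` (the CT series), ``plan.dcm`` and
    ``dose.dcm``. The phantom is passed in (selected once per patient)
    so multi-session dose accumulation shares a voxel identity space.
    """
    config = config or RunConfig()
    session_dir = Path(session_dir)
    result = SessionResult(
        patient_id=patient_id, session_id=session_id or session_dir.name,
        status="rejected", stage="read", phantom_id=phantom.meta.id,
    )
    try:
        plan = read_rt_plan(session_dir / "plan.dcm")
        dose_grid = read_rt_dose(session_dir / "dose.dcm")
        ct = read_ct_series(session_dir / "ct")
    except Exception as exc:  # incomplete record
        result.reason = f"unreadable DICOM set: {exc}"
        return result

    result.total_prescribed_gy = plan.total_prescribed_gy
    result.stage = "dose-consistency"
    consistency = check_dose_consistency(plan, chars)
    result.mismatch_direction = consistency.direction
    result.mismatch_gy = consistency.mismatch_gy
    if not consistency.accepted:
        result.reason = f"dose mismatch ({consistency.direction})"
        return result

    result.stage = "registration"
    try:
        patient_skel = extract_skeleton(ct, config.hu_threshold)
        phantom_skel = phantom_skeleton_points(phantom)
        icp = icp_register(phantom_skel, patient_skel, config.icp)
    except Exception as exc:
        result.reason = f"registration failed: {exc}"
        return result

    result.stage = "alignment-review"
    moved = icp.transform.apply(phantom_skel.points)
    vof = compute_vof(patient_skel.source_voxel_index, moved, ct)
    result.vof_percent = vof
    overlay = None
    if config.render_overlays and config.output_dir is not None:
        overlay = str(
            render_overlay(
                patient_skel.points, moved,
                Path(config.output_dir) / "overlays" / f"{result.session_id}.png",
            )
        )
        result.overlay_path = overlay
    try:
        flags = _review_flags(config.acceptance_policy, result.session_id)
    except Exception as exc:
        result.reason = f"review flags unavailable: {exc}"
        return result
    qa = record_review(vof, *flags, overlay_path=overlay)
    result.qa = qa
    if not qa.accepted:
        result.reason = "alignment rejected by review"
        return result

    result.stage = "dosimetry"
    try:
        sample = assign_voxel_weights(
            phantom, icp.transform, chars.age_years, chars.sex
        )
        sample = sample.with_doses(sample_dose(dose_grid, sample.points))
        result.sample = sample
        result.metrics = dose_metrics(
            sample, plan.total_prescribed_gy, sessions=[result.session_id]
        )
    except Exception as exc:
        result.reason = f"dosimetry failed: {exc}"
        return result

    z_lo, z_hi = phantom.craniocaudal_extent_mm
    result.region = categorize_treatment_region(
        plan, keyword_map=config.region_keywords, phantom_z_extent_mm=(z_lo, z_hi)
    )
    result.status = "accepted"
    result.stage = "complete"
    return result


@dataclass
class CohortReport:
    sessions: pd.DataFrame
    patients: pd.DataFrame
    flowchart: dict
    region_summary: pd.DataFrame

    def write(self, out_dir: str | Path, config: RunConfig | None = None) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.sessions.to_csv(out_dir / "sessions.csv", index=False)
        self.patients.to_csv(out_dir / "patients.csv", index=False)
        self.region_summary.to_csv(out_dir / "region_summary.csv", index=False)
        (out_dir / "flowchart.json").write_text(json.dumps(self.flowchart, indent=2))
        if config is not None:
            (out_dir / "run_config.json").write_text(config.to_json())


_SESSION_COLUMNS = [
    "patient_id", "session_id", "status", "stage", "reason", "mismatch_direction",
    "mismatch_gy", "phantom_id", "vof_percent", "region", "total_prescribed_gy",
    "mean_gy", "mean_per_rx", "d50", "d10", "d1", "v5", "v10", "v20",
]


def run_cohort(
    manifest_path: str | Path, config: RunConfig
) -> CohortReport:
    """Run every session in a cohort manifest and assemble the selection report.

    The manifest CSV needs columns patient_id, session_id, session_dir
    (relative to the manifest), age_years, sex, height_cm, weight_kg,
    recorded_dose_gy. An empty manifest produces empty reports.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path, dtype={"patient_id": str, "session_id": str})
    library_dir = Path(config.phantom_dir) if config.phantom_dir else root / "phantoms"
    phantoms = {
        (p := load_phantom(meta_file)).meta.id: p
        for meta_file in sorted(library_dir.glob("*.meta.json"))
    }
    if manifest.empty:
        empty = pd.DataFrame(columns=_SESSION_COLUMNS)
        return CohortReport(
            sessions=empty,
            patients=pd.DataFrame(columns=["patient_id", "included"]),
            flowchart=_flowchart([], {}),
            region_summary=pd.DataFrame(columns=["region", "n", "q1", "median", "q3"]),
        )
    if not phantoms:
        raise FileNotFoundError(f"no phantom containers in {library_dir}")
    library_meta = [p.meta for p in phantoms.values()]

    results: list[SessionResult] = []
    per_patient: dict[str, list[SessionResult]] = {}
    for pid, group in manifest.groupby("patient_id", sort=True):
        first = group.iloc[0]
        chars = PatientCharacteristics(
            age_years=float(first["age_years"]), sex=str(first["sex"]),
            height_cm=float(first["height_cm"]), weight_kg=float(first["weight_kg"]),
            recorded_delivered_dose_gy=None,
        )
        phantom_id, _ = select_phantom(chars, library_meta)
        phantom = phantoms[phantom_id]
        records = []
        for _, row in group.iterrows():
            chars_s = dataclasses.replace(
                chars,
                recorded_delivered_dose_gy=(
                    None if pd.isna(row["recorded_dose_gy"])
                    else float(row["recorded_dose_gy"])
                ),
            )
            rec = run_session(
                root / row["session_dir"], chars_s, phantom, config,
                patient_id=str(pid), session_id=str(row["session_id"]),
            )
            records.append(rec)
        results.extend(records)
        per_patient[str(pid)] = records

    inclusion = session_acceptance_rollup({
        pid: [
            QARecord(vof_percent=r.vof_percent or 0.0,
                     evaluator_1=r.status == "accepted", evaluator_2=True)
            for r in recs
        ]
        for pid, recs in per_patient.items()
    })

    sessions_df = pd.DataFrame([r.as_row() for r in results], columns=_SESSION_COLUMNS)

    patient_rows = []
    for pid, recs in per_patient.items():
        included = inclusion[pid]
        row = {"patient_id": pid, "included": included, "n_sessions": len(recs)}
        if included:
            samples = [r.sample for r in recs if r.sample is not None]
            total_rx = sum(r.total_prescribed_gy or 0.0 for r in recs)
            cumulative = accumulate_sessions(samples)
            metrics = dose_metrics(
                cumulative, total_rx or None,
                sessions=[r.session_id for r in recs],
            )
            row.update(metrics.as_row())
        patient_rows.append(row)
    patients_df = pd.DataFrame(patient_rows)

    region_summary = _region_summary(sessions_df)
    return CohortReport(
        sessions=sessions_df,
        patients=patients_df,
        flowchart=_flowchart(results, inclusion),
        region_summary=region_summary,
    )


def _flowchart(results: list[SessionResult], inclusion: dict[str, bool]) -> dict:
    mismatch = [r for r in results if r.stage == "dose-consistency" and r.status == "rejected"]
    alignment = [
        r for r in results
        if r.status == "rejected" and r.stage in ("read", "registration", "alignment-review", "dosimetry")
    ]
    accepted = [r for r in results if r.status == "accepted"]
    return {
        "total_sessions": len(results),
        "excluded_dose_mismatch": len(mismatch),
        "excluded_dose_mismatch_plan_low": sum(
            1 for r in mismatch if r.mismatch_direction == "plan-low"),
        "excluded_dose_mismatch_plan_high": sum(
            1 for r in mismatch if r.mismatch_direction == "plan-high"),
        "excluded_dose_mismatch_missing": sum(
            1 for r in mismatch if r.mismatch_direction == "missing"),
        "rejected_alignment": len(alignment),
        "accepted_sessions": len(accepted),
        "total_patients": len(inclusion),
        "patients_included": sum(inclusion.values()),
        "patients_excluded": sum(not v for v in inclusion.values()),
        "sessions_in_final_population": sum(
            1 for r in accepted if inclusion.get(r.patient_id, False)
        ),
    }


def _region_summary(sessions: pd.DataFrame) -> pd.DataFrame:
    """Quartiles of mean dose per prescribed dose, by treated region (accepted sessions)."""
    acc = sessions[(sessions["status"] == "accepted") & sessions["mean_per_rx"].notna()]
    rows = []
    for region, grp in acc.groupby("region"):
        q1, med, q3 = np.percentile(grp["mean_per_rx"], [25, 50, 75])
        rows.append({"region": region, "n": len(grp), "q1": q1, "median": med, "q3": q3})
    return pd.DataFrame(rows, columns=["region", "n", "q1", "median", "q3"])
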