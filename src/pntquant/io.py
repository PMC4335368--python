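"""NIfTI / CSV / JSON serialization of phantom subjects and results.

Cine stacks and label volumes are written as 4D NIfTI (row, col, slice,
phase ordering on disk), velocity series as 3D+time NIfTI, and the geometry
that NIfTI headers cannot carry faithfully (slice thickness vs gap, phase
duration) in a JSON sidecar per subject.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import CineStack, GroundTruth, SubjectRecord, VelocitySeries


def _affine(pixel_spacing: float, slice_spacing: float) -> np.ndarray:
    return np.diag([pixel_spacing, pixel_spacing, slice_spacing, 1.0])


def save_subject(outdir: str | Path, record: SubjectRecord) -> dict:
    """Write one subject's series and ground truth; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = record.subject_id
    cine, truth, vel = record.cine, record.truth, record.velocity
    spacing = cine.slice_spacing

    files = {
        "cine": outdir / f"{sid}_cine.nii.gz",
        "labels": outdir / f"{sid}_labels.nii.gz",
        "velocity": outdir / f"{sid}_velocity.nii.gz",
        "meta": outdir / f"{sid}_meta.json",
    }
    # [phase, slice, row, col] -> [row, col, slice, phase]
    cine_disk = np.transpose(cine.intensities, (2, 3, 1, 0)).astype(np.float32)
    nib.save(nib.Nifti1Image(cine_disk, _affine(cine.pixel_spacing, spacing)), files["cine"])
    labels_disk = np.transpose(truth.labels, (2, 3, 1, 0)).astype(np.uint8)
    nib.save(nib.Nifti1Image(labels_disk, _affine(cine.pixel_spacing, spacing)), files["labels"])
    vel_disk = np.transpose(vel.velocities, (1, 2, 0)).astype(np.float32)
    nib.save(
        nib.Nifti1Image(vel_disk, _affine(vel.pixel_spacing, vel.pixel_spacing)),
        files["velocity"],
    )

    meta = {
        "subject_id": sid,
        "group": record.group,
        "height_cm": record.height,
        "weight_kg": record.weight,
        "seed": record.seed,
        "pixel_spacing_mm": cine.pixel_spacing,
        "slice_thickness_mm": cine.slice_thickness,
        "slice_gap_mm": cine.slice_gap,
        "phase_duration_ms": cine.phase_duration,
        "velocity_pixel_spacing_mm": vel.pixel_spacing,
        "vessel_mask_true": vel.vessel_mask_true.astype(int).tolist(),
        "ground_truth": ground_truth_summary(truth),
    }
    files["meta"].write_text(json.dumps(meta, indent=1, sort_keys=True))
    return {k: str(v) for k, v in files.items()}


def ground_truth_summary(truth: GroundTruth) -> dict:
    return {
        "cavity_volume_per_phase_ml": [round(float(v), 4) for v in truth.cavity_volume_per_phase],
        "pnt_volume_per_phase_ml": [round(float(v), 4) for v in truth.pnt_volume_per_phase],
        "wall_volume_ml": round(float(truth.wall_volume), 4),
        "total_lvm_true_g": round(float(truth.total_lvm_true), 4),
        "true_sv_ml": round(float(truth.true_sv), 4),
        "true_pnt_mass_fraction": round(float(truth.true_pnt_mass_fraction), 6),
        "ed_phase": int(truth.ed_phase),
        "es_phase": int(truth.es_phase),
    }


def load_subject(outdir: str | Path, subject_id: str) -> SubjectRecord:
    """Re-assemble a SubjectRecord written by :func:`save_subject`."""
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{subject_id}_meta.json").read_text())
    cine_disk = np.asarray(nib.load(outdir / f"{subject_id}_cine.nii.gz").dataobj)
    labels_disk = np.asarray(nib.load(outdir / f"{subject_id}_labels.nii.gz").dataobj)
    vel_disk = np.asarray(nib.load(outdir / f"{subject_id}_velocity.nii.gz").dataobj)

    cine = CineStack(
        intensities=np.transpose(cine_disk, (3, 2, 0, 1)).astype(float),
        pixel_spacing=meta["pixel_spacing_mm"],
        slice_thickness=meta["slice_thickness_mm"],
        slice_gap=meta["slice_gap_mm"],
        phase_duration=meta["phase_duration_ms"],
    )
    gts = meta["ground_truth"]
    truth = GroundTruth(
        labels=np.transpose(labels_disk, (3, 2, 0, 1)).astype(np.uint8),
        cavity_volume_per_phase=np.array(gts["cavity_volume_per_phase_ml"]),
        pnt_volume_per_phase=np.array(gts["pnt_volume_per_phase_ml"]),
        wall_volume=gts["wall_volume_ml"],
        total_lvm_true=gts["total_lvm_true_g"],
        true_sv=gts["true_sv_ml"],
        true_pnt_mass_fraction=gts["true_pnt_mass_fraction"],
        ed_phase=gts["ed_phase"],
    )
    velocity = VelocitySeries(
        velocities=np.transpose(vel_disk, (2, 0, 1)).astype(float),
        pixel_spacing=meta["velocity_pixel_spacing_mm"],
        phase_duration=meta["phase_duration_ms"],
        vessel_mask_true=np.array(meta["vessel_mask_true"], dtype=bool),
    )
    return SubjectRecord(
        subject_id=meta["subject_id"],
        group=meta["group"],
        height=meta["height_cm"],
        weight=meta["weight_kg"],
        cine=cine,
        velocity=velocity,
        truth=truth,
        seed=meta["seed"],
    )


def save_cohort(outdir: str | Path, records: list[SubjectRecord]) -> Path:
    """Write every subject plus a cohort manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    rows = []
    for rec in records:
        files = save_subject(outdir, rec)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "height_cm": rec.height,
                "weight_kg": rec.weight,
                "seed": rec.seed,
                "true_sv_ml": rec.truth.true_sv,
                "total_lvm_true_g": rec.truth.total_lvm_true,
                "true_pnt_mass_fraction": rec.truth.true_pnt_mass_fraction,
                **{k: Path(v).name for k, v in files.items()},
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format="%.6f")
    return manifest
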