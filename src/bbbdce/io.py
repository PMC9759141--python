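"""NIfTI / CSV / JSON persistence for subjects, maps and cohort outputs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams
from .aif import AifParams
from .drift import DriftCurve
from .patlak import PkMaps
from .synthetic import SubjectDataset

__all__ = [
    "save_subject",
    "load_subject",
    "save_maps",
    "save_drift_curve",
    "write_manifest",
    "read_manifest",
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def _save_nifti(arr: np.ndarray, affine: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr), affine), str(path))


def save_subject(ds: SubjectDataset, out_dir: str | Path) -> Path:
    """Write one subject's volumes and a JSON sidecar under ``out_dir``."""
    out = Path(out_dir) / ds.subject_id
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(ds.voxel_size_mm)
    _save_nifti(ds.signal.astype(np.float32), aff, out / "dce.nii.gz")
    _save_nifti(ds.t1_map_ms.astype(np.float32), aff, out / "t1_map.nii.gz")
    _save_nifti(ds.b1_map.astype(np.float32), aff, out / "b1_map.nii.gz")
    _save_nifti(ds.roi_labels.astype(np.int16), aff, out / "roi_labels.nii.gz")
    _save_nifti(ds.phantom_labels.astype(np.int16), aff, out / "phantom_labels.nii.gz")
    _save_nifti(ds.brain_mask.astype(np.uint8), aff, out / "brain_mask.nii.gz")
    _save_nifti(ds.truth_ktrans.astype(np.float32), aff, out / "truth_ktrans.nii.gz")
    _save_nifti(ds.truth_vp.astype(np.float32), aff, out / "truth_vp.nii.gz")
    sidecar = {
        "subject_id": ds.subject_id,
        "seed": ds.seed,
        "group": ds.group,
        "voxel_size_mm": list(ds.voxel_size_mm),
        "acquisition": ds.acq.to_dict(),
        "aif": ds.aif_params.to_dict(),
        "truth_summary": {
            "mean_ktrans_brain": float(ds.truth_ktrans[ds.brain_mask].mean()),
            "vp": float(ds.truth_vp[ds.brain_mask].mean()),
        },
    }
    (out / "subject.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_subject(subject_dir: str | Path) -> SubjectDataset:
    """Read a subject previously written by :func:`save_subject`."""
    d = Path(subject_dir)
    sidecar = json.loads((d / "subject.json").read_text())

    def _load(name: str) -> np.ndarray:
        return np.asarray(nib.load(str(d / name)).dataobj)

    return SubjectDataset(
        subject_id=sidecar["subject_id"],
        signal=_load("dce.nii.gz").astype(float),
        t1_map_ms=_load("t1_map.nii.gz").astype(float),
        b1_map=_load("b1_map.nii.gz").astype(float),
        roi_labels=_load("roi_labels.nii.gz").astype(np.int16),
        phantom_labels=_load("phantom_labels.nii.gz").astype(np.int16),
        brain_mask=_load("brain_mask.nii.gz").astype(bool),
        truth_ktrans=_load("truth_ktrans.nii.gz").astype(float),
        truth_vp=_load("truth_vp.nii.gz").astype(float),
        acq=AcquisitionParams.from_dict(sidecar["acquisition"]),
        aif_params=AifParams.from_dict(sidecar["aif"]),
        voxel_size_mm=tuple(sidecar["voxel_size_mm"]),
        seed=int(sidecar["seed"]),
        group=sidecar.get("group"),
    )


def save_maps(maps: PkMaps, voxel_size_mm, out_dir: str | Path) -> Path:
    """Write ktrans/vp/r2 maps and a small fit log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(voxel_size_mm)
    _save_nifti(maps.ktrans.astype(np.float32), aff, out / "ktrans.nii.gz")
    _save_nifti(maps.vp.astype(np.float32), aff, out / "vp.nii.gz")
    _save_nifti(maps.fit_quality.astype(np.float32), aff, out / "r2.nii.gz")
    _save_nifti(maps.fit_mask.astype(np.uint8), aff, out / "fit_mask.nii.gz")
    log = {"n_fitted": int(maps.fit_mask.sum()), "n_excluded": int(maps.n_excluded)}
    (out / "fit_log.json").write_text(json.dumps(log, indent=2))
    return out


def save_drift_curve(
    drift: DriftCurve, times_min: np.ndarray, path: str | Path
) -> None:
    """QC export: one row per frame with time and gain multiplier."""
    pd.DataFrame(
        {
            "frame": np.arange(drift.multipliers.size),
            "time_s": np.asarray(times_min) * 60.0,
            "multiplier": drift.multipliers,
        }
    ).to_csv(path, index=False)


def write_manifest(records: list[dict], path: str | Path) -> None:
    """Cohort manifest CSV: subject_id, group, path."""
    pd.DataFrame(records, columns=["subject_id", "group", "path"]).to_csv(
        path, index=False
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
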