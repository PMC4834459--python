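"""File formats: NIfTI volumes, cohort tables, event tables, feature matrices."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .ppi import FeatureIndex
from .synthetic import EventSchedule
from .volume import VolumeGrid


def read_nifti(path) -> VolumeGrid:
    """Load a 3D or 4D NIfTI-1 image (.nii or .nii.gz) as a VolumeGrid."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises format-specific errors
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3D or 4D image, got {data.ndim}D")
    return VolumeGrid(np.asarray(data, dtype=float), np.asarray(img.affine, dtype=float))


def write_nifti(grid: VolumeGrid, path) -> Path:
    """Write a VolumeGrid as NIfTI-1.

    The affine is snapped to float32 precision before writing (the NIfTI-1
    header stores transforms as float32), so write-then-read round-trips are
    exactly idempotent.
    """
    path = Path(path)
    affine = np.asarray(np.asarray(grid.affine, dtype=np.float32), dtype=np.float64)
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.float64), affine)
    nib.save(img, str(path))
    return path


_COHORT_REQUIRED = ("subject_id", "group")
_GROUP_CODES = {"patient": 1, "control": 0, "1": 1, "0": 0}


def read_cohort_table(path) -> pd.DataFrame:
    """Delimited subject table with mandatory ``subject_id`` and ``group``
    columns (group in {patient, control} or {1, 0}); extra covariate columns
    are preserved untouched.  Adds a numeric ``label`` column (1 = patient)."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in _COHORT_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"cohort table {path} is missing mandatory column '{col}'")
    labels = []
    for g in df["group"].astype(str).str.strip().str.lower():
        if g not in _GROUP_CODES:
            raise ValueError(f"unrecognised group value {g!r} (expect patient/control)")
        labels.append(_GROUP_CODES[g])
    df["label"] = labels
    return df


def write_cohort_table(
    subject_ids: list[str], labels: np.ndarray, path, covariates: pd.DataFrame | None = None
) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": ["patient" if int(l) == 1 else "control" for l in labels],
        }
    )
    if covariates is not None:
        df = pd.concat([df, covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events(path) -> EventSchedule:
    """Tab-separated events table with columns onset, duration, trial_type."""
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"events table {path} is missing mandatory column '{col}'")
    return EventSchedule(
        df["onset"].to_numpy(float),
        df["duration"].to_numpy(float),
        df["trial_type"].astype(str).tolist(),
    )


def write_events(events: EventSchedule, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "onset": events.onsets_s,
            "duration": events.durations_s,
            "trial_type": events.conditions,
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def write_features(X: np.ndarray, index: FeatureIndex, stem) -> tuple[Path, Path]:
    """Feature matrix as ``<stem>.npy`` plus a JSON voxel-index sidecar."""
    stem = Path(stem)
    npy = stem.with_suffix(".npy")
    np.save(npy, np.asarray(X, dtype=float))
    sidecar = stem.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "flat_idx_fortran": index.flat_idx.tolist(),
                "shape": list(index.shape),
                "affine": np.asarray(index.affine).tolist(),
                "ordering": "ascending linear index, x fastest (Fortran ravel)",
            }
        )
    )
    return npy, sidecar


def read_features(stem) -> tuple[np.ndarray, FeatureIndex]:
    stem = Path(stem)
    X = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    index = FeatureIndex(
        np.asarray(meta["flat_idx_fortran"], dtype=int),
        tuple(meta["shape"]),
        np.asarray(meta["affine"], dtype=float),
    )
    return X, index
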