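"""Reading and writing subjects, tensors and maps.

Subjects are stored BIDS-style: a 4D NIfTI time series (runs concatenated),
a 3D mask NIfTI, an events TSV (onset, duration, run, trial_type) and a JSON
sidecar carrying the repetition time, run length and group label. Maps are
written both as NIfTI and as a sparse voxel-list TSV for diff-friendly
inspection.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import TrialWindowTensor, validate_trial_table
from .simulate import SubjectDataset

logger = logging.getLogger(__name__)

_AFFINE = np.eye(4)

EXTRA_COLUMN_LOGGED = ("onset", "duration", "run", "trial_type")


def write_subject(ds: SubjectDataset, out_dir, subject_id: str | None = None) -> Path:
    """Write one subject's files under ``out_dir``; returns the directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = subject_id or f"sub-{ds.subject_index + 1:02d}"
    nib.save(
        nib.Nifti1Image(ds.timeseries.astype(np.float32), _AFFINE),
        out_dir / f"{sid}_bold.nii.gz",
    )
    nib.save(
        nib.Nifti1Image(ds.mask.astype(np.uint8), _AFFINE),
        out_dir / f"{sid}_mask.nii.gz",
    )
    nib.save(
        nib.Nifti1Image(ds.true_informative_mask.astype(np.uint8), _AFFINE),
        out_dir / f"{sid}_truthmask.nii.gz",
    )
    ds.trials.to_csv(out_dir / f"{sid}_events.tsv", sep="\t", index=False)
    meta = {
        "tr": ds.tr,
        "run_length_trs": ds.run_length_trs,
        "group": ds.group,
        "true_latency": ds.true_latency,
        "subject_index": ds.subject_index,
    }
    (out_dir / f"{sid}_meta.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def read_events(path) -> pd.DataFrame:
    """Read and validate a BIDS-style events TSV."""
    # trial_type read as string: pandas would otherwise coerce the literal
    # values "true"/"false" to booleans
    trials = pd.read_csv(path, sep="\t", dtype={"trial_type": str})
    extra = [c for c in trials.columns if c not in EXTRA_COLUMN_LOGGED]
    if extra:
        logger.info("events %s: ignoring extra columns %s", path, extra)
    try:
        validate_trial_table(trials)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None
    return trials


def read_subject(
    bold_path, mask_path, events_path, meta_path=None
) -> SubjectDataset:
    """Load a subject from disk, validating grids and the trial table."""
    bold = nib.load(str(bold_path))
    mask_img = nib.load(str(mask_path))
    timeseries = np.asanyarray(bold.dataobj, dtype=np.float32)
    mask = np.asanyarray(mask_img.dataobj).astype(bool)
    if timeseries.shape[:3] != mask.shape:
        raise ValueError(
            f"{bold_path}: grid {timeseries.shape[:3]} does not match mask "
            f"grid {mask.shape}"
        )
    trials = read_events(events_path)
    if meta_path is None:
        meta_path = str(bold_path).replace("_bold.nii.gz", "_meta.json")
    meta = json.loads(Path(meta_path).read_text())
    truth_path = str(bold_path).replace("_bold.nii.gz", "_truthmask.nii.gz")
    truth = (
        np.asanyarray(nib.load(truth_path).dataobj).astype(bool)
        if Path(truth_path).exists()
        else np.zeros(mask.shape, dtype=bool)
    )
    return SubjectDataset(
        timeseries=timeseries,
        mask=mask,
        trials=trials,
        group=meta.get("group", "unknown"),
        true_informative_mask=truth,
        true_latency=float(meta.get("true_latency", float("nan"))),
        tr=float(meta["tr"]),
        run_length_trs=int(meta["run_length_trs"]),
        subject_index=int(meta.get("subject_index", 0)),
    )


def read_subject_dir(subject_dir, subject_id: str) -> SubjectDataset:
    d = Path(subject_dir)
    return read_subject(
        d / f"{subject_id}_bold.nii.gz",
        d / f"{subject_id}_mask.nii.gz",
        d / f"{subject_id}_events.tsv",
        d / f"{subject_id}_meta.json",
    )


def save_tensor(tensor: TrialWindowTensor, path) -> None:
    """Write the tensor as a .npy array with a JSON sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), tensor.values)
    sidecar = {
        "window_times": list(tensor.window_times),
        "voxel_coords": tensor.voxel_coords.tolist(),
        "grid_shape": list(tensor.grid_shape),
        "labels": tensor.labels.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_tensor(path) -> TrialWindowTensor:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return TrialWindowTensor(
        values=values,
        window_times=tuple(sidecar["window_times"]),
        voxel_coords=np.asarray(sidecar["voxel_coords"], dtype=int),
        grid_shape=tuple(sidecar["grid_shape"]),
        labels=np.asarray(sidecar["labels"], dtype=str),
    )


def write_map(volume: np.ndarray, path_stem) -> None:
    """Write a map as NIfTI plus a sparse voxel-list TSV (x, y, z, value)."""
    path_stem = Path(path_stem)
    vol = np.asarray(volume)
    nib.save(
        nib.Nifti1Image(vol.astype(np.float32), _AFFINE),
        path_stem.with_suffix(".nii.gz"),
    )
    coords = np.argwhere(vol != 0)
    values = vol[coords[:, 0], coords[:, 1], coords[:, 2]]
    pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "value": values,
        }
    ).to_csv(path_stem.with_suffix(".tsv"), sep="\t", index=False)


def load_map(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj)
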