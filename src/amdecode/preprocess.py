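"""From normalized voxel time series to the trials x voxels x 7-window tensor.

The decoder consumes, per trial, seven overlapping temporal windows centered
2-14 s after sentence onset. Each window is a 3-point central moving average
of the TR-grid samples taken 0-16 s post-onset (nine samples at TR = 2 s),
computed on signal that has been z-scored per voxel within each run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Window centers in seconds post sentence onset.
WINDOW_TIMES = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0)
N_WINDOWS = 7
N_RAW_SAMPLES = 9  # samples at 0, 2, ..., 16 s post-onset (TR = 2 s)

REQUIRED_EVENT_COLUMNS = ("onset", "run", "trial_type")
TRIAL_TYPES = ("true", "false")


@dataclass
class TrialWindowTensor:
    """Smoothed, normalized per-trial signal ready for decoding.

    Attributes
    ----------
    values : ndarray, shape (n_trials, n_voxels, 7)
        Signal in z-units; the last axis indexes the temporal windows.
    window_times : tuple of float
        Window centers in seconds post-onset, always ``(2, 4, ..., 14)``.
    voxel_coords : ndarray of int, shape (n_voxels, 3)
        Grid coordinate of each tensor column (0-based).
    grid_shape : tuple of int
        Shape of the originating 3D voxel grid.
    labels : ndarray of str, shape (n_trials,)
        Trial labels, ``"true"`` or ``"false"``.
    """

    values: np.ndarray
    window_times: tuple[float, ...]
    voxel_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    labels: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def window_index(self, seconds: float) -> int:
        times = np.asarray(self.window_times)
        hits = np.flatnonzero(np.isclose(times, seconds))
        if hits.size == 0:
            raise ValueError(f"no window centered at {seconds} s")
        return int(hits[0])


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, label values, and per-run onset monotonicity."""
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad = ~trials["trial_type"].isin(TRIAL_TYPES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"trial table row {row}: unknown trial_type "
            f"{trials['trial_type'].iloc[row]!r} (expected one of {TRIAL_TYPES})"
        )
    for run, sub in trials.groupby("run"):
        onsets = sub["onset"].to_numpy(float)
        if not np.all(np.diff(onsets) > 0):
            raise ValueError(f"onsets not strictly increasing within run {run}")
    return trials


def normalize_voxels(
    timeseries: np.ndarray,
    mask: np.ndarray,
    run_length_trs: int,
) -> np.ndarray:
    """Z-score each in-mask voxel over time, separately within each run.

    Voxels with zero temporal variance in a run are set to all-zero for that
    run and reported through a logged warning; out-of-mask voxels are zeroed.
    """
    timeseries = np.asarray(timeseries, dtype=np.float64)
    if timeseries.shape[:3] != mask.shape:
        raise ValueError(
            f"timeseries grid {timeseries.shape[:3]} does not match mask "
            f"{mask.shape}"
        )
    n_time = timeseries.shape[3]
    if n_time % run_length_trs:
        raise ValueError(
            f"time axis length {n_time} is not a multiple of the run length "
            f"{run_length_trs}"
        )
    out = np.zeros_like(timeseries)
    flat = timeseries.reshape(-1, n_time)
    out_flat = out.reshape(-1, n_time)
    mask_idx = np.flatnonzero(mask.ravel())
    n_zero_var = 0
    for start in range(0, n_time, run_length_trs):
        sl = slice(start, start + run_length_trs)
        seg = flat[mask_idx, sl]
        mu = seg.mean(axis=1, keepdims=True)
        sd = seg.std(axis=1, keepdims=True)
        zero = (sd == 0).ravel()
        n_zero_var += int(zero.sum())
        sd[sd == 0] = 1.0
        z = (seg - mu) / sd
        z[zero] = 0.0
        out_flat[mask_idx, sl] = z
    if n_zero_var:
        logger.warning(
            "%d zero-variance voxel/run segments set to zero during "
            "normalization", n_zero_var,
        )
    return out


def extract_trial_windows(
    timeseries: np.ndarray,
    mask: np.ndarray,
    trials: pd.DataFrame,
    tr: float,
    run_length_trs: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the nine raw TR samples 0-16 s post-onset for every trial.

    Returns ``(raw, voxel_coords)`` with ``raw`` of shape
    ``(n_trials, n_voxels, 9)`` over in-mask voxels. Onsets not aligned to
    the TR grid are rounded to the nearest TR with a logged warning. A trial
    whose 16 s sample falls outside its run raises an error naming the trial
    and run.
    """
    validate_trial_table(trials)
    n_time = timeseries.shape[3]
    voxel_coords = np.argwhere(mask)
    mask_idx = np.flatnonzero(mask.ravel())
    flat = timeseries.reshape(-1, n_time)[mask_idx]

    raw = np.empty((len(trials), mask_idx.size, N_RAW_SAMPLES))
    for k, (_, row) in enumerate(trials.iterrows()):
        run = int(row["run"])
        onset_tr_f = float(row["onset"]) / tr
        onset_tr = int(round(onset_tr_f))
        if abs(onset_tr_f - onset_tr) > 1e-9:
            logger.warning(
                "trial %d: onset %.3f s not TR-aligned, rounded to TR %d",
                k, row["onset"], onset_tr,
            )
        start = run * run_length_trs + onset_tr
        stop = start + N_RAW_SAMPLES
        if onset_tr < 0 or onset_tr + N_RAW_SAMPLES > run_length_trs:
            raise ValueError(
                f"trial {k} (onset {row['onset']} s, run {run}): the 0-16 s "
                f"window exceeds the run bounds"
            )
        if stop > n_time:
            raise ValueError(
                f"trial {k} (run {run}): window exceeds the time series"
            )
        raw[k] = flat[:, start:stop]
    return raw, voxel_coords


def temporal_smooth(raw: np.ndarray) -> np.ndarray:
    """3-point central moving average: 9 raw samples -> 7 windows (2-14 s).

    Window ``k`` (center ``2(k+1)`` s, ``k = 0..6``) averages the samples at
    the center time and one TR on either side. Linear and shift-equivariant.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.shape[-1] != N_RAW_SAMPLES:
        raise ValueError(
            f"expected {N_RAW_SAMPLES} raw samples per trial/voxel, got "
            f"{raw.shape[-1]}"
        )
    return (raw[..., :-2] + raw[..., 1:-1] + raw[..., 2:]) / 3.0


def build_tensor(
    timeseries: np.ndarray,
    mask: np.ndarray,
    trials: pd.DataFrame,
    tr: float,
    run_length_trs: int,
    normalize: bool = True,
) -> TrialWindowTensor:
    """Full preprocessing chain: normalize, extract, smooth.

    Normalization precedes extraction, so each trial's samples are z-units
    relative to its whole run.
    """
    if normalize:
        timeseries = normalize_voxels(timeseries, mask, run_length_trs)
    raw, voxel_coords = extract_trial_windows(
        timeseries, mask, trials, tr, run_length_trs
    )
    values = temporal_smooth(raw)
    return TrialWindowTensor(
        values=values,
        window_times=WINDOW_TIMES,
        voxel_coords=voxel_coords,
        grid_shape=tuple(mask.shape),
        labels=trials["trial_type"].to_numpy(str),
    )
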