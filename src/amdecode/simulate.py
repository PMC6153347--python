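"""Seeded synthetic fMRI cohorts for the true/false memory decoding pipeline.

The generator emulates the event-related design the decoder expects: per
subject, a 4D voxel time series over several runs, a gray-matter mask, and a
trial table of sentence onsets answered "true" or "false". A true-vs-false
amplitude difference is planted in a spatially clustered subset of voxels and
expressed at a subject-specific latency after sentence onset; everything else
is temporally autocorrelated Gaussian noise. The signal is generated directly
as trial-locked normalized response (no hemodynamic convolution): the decoding
analysis operates on residualized, z-scored signal, so only the latency and
amplitude structure matter to its contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

logger = logging.getLogger(__name__)

#: Allowed centers (seconds post-onset) of the informative latency window.
LATENCIES = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0)

#: Minimum onset-to-onset spacing (s) so 0-16 s trial windows never overlap.
MIN_TRIAL_SPACING_S = 18.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated cohort.

    Defaults reproduce the study design: 14 subjects (8 recalling a wedding,
    6 a funeral), 48 trials each (24 true / 24 false) over 3 runs at
    TR = 2 s, with 2,000 spatially clustered informative voxels.

    Parameters
    ----------
    n_subjects : int
        Number of subjects in the cohort.
    group_sizes : tuple of int
        Subjects per valence group; the first ``group_sizes[0]`` subjects are
        labeled ``"wedding"``, the remainder ``"funeral"``. Must sum to
        ``n_subjects``.
    n_trials : int
        Trials per subject (even; half true, half false).
    n_runs : int
        Scanning runs per subject; trials are split evenly across runs.
    tr : float
        Repetition time in seconds.
    grid_shape : tuple of int
        3D voxel grid dimensions.
    mask_fraction : float
        Fraction of grid voxels inside the gray-matter mask (a centered
        quasi-spherical region).
    n_informative_voxels : int
        Number of planted discriminative voxels, laid out as a few contiguous
        blobs inside the mask so the decoder's cluster filter has structure
        to act on.
    informative_latency : float or None
        Seconds post-onset at which the planted effect peaks, one of
        ``LATENCIES``. ``None`` draws a latency per subject.
    effect_size : float
        Standardized mean difference (in noise-SD units) between true and
        false response amplitude in informative voxels.
    noise_ar1 : float
        Lag-1 autocorrelation of the AR(1) voxel noise (unit stationary
        variance), i.i.d. across voxels.
    noise_shared_sd : float
        Stationary SD of an additional AR(1) regional fluctuation added
        identically to every in-mask voxel. Trial-level BOLD variability is
        spatially correlated; without this component a multivoxel effect of
        any realistic per-voxel size decodes perfectly at every window it
        touches, so neither graded accuracies nor the latency structure the
        analysis is built around would exist.
    seed : int
        Base RNG seed; per-subject streams are derived from it.
    """

    n_subjects: int = 14
    group_sizes: tuple[int, ...] = (8, 6)
    n_trials: int = 48
    n_runs: int = 3
    tr: float = 2.0
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    mask_fraction: float = 0.5
    n_informative_voxels: int = 2000
    informative_latency: float | None = None
    effect_size: float = 2.0
    noise_ar1: float = 0.3
    noise_shared_sd: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if sum(self.group_sizes) != self.n_subjects:
            raise ValueError(
                f"group_sizes {self.group_sizes} must sum to n_subjects "
                f"({self.n_subjects})"
            )
        if self.n_trials < 2 or self.n_trials % 2:
            raise ValueError("n_trials must be even and >= 2")
        if self.n_trials % self.n_runs:
            raise ValueError("n_trials must divide evenly across n_runs")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not (0 < self.mask_fraction <= 1):
            raise ValueError("mask_fraction must be in (0, 1]")
        n_grid = int(np.prod(self.grid_shape))
        n_mask = int(round(self.mask_fraction * n_grid))
        if self.n_informative_voxels > n_mask:
            raise ValueError(
                f"grid too small: {self.n_informative_voxels} informative "
                f"voxels requested but the mask holds only {n_mask}"
            )
        if self.informative_latency is not None and (
            self.informative_latency not in LATENCIES
        ):
            raise ValueError(
                f"informative_latency must be one of {LATENCIES}"
            )
        if not (0 <= self.noise_ar1 < 1):
            raise ValueError("noise_ar1 must be in [0, 1)")
        if self.noise_shared_sd < 0:
            raise ValueError("noise_shared_sd must be non-negative")

    @property
    def trials_per_run(self) -> int:
        return self.n_trials // self.n_runs

    @property
    def group_labels(self) -> list[str]:
        names = ("wedding", "funeral")
        out: list[str] = []
        for k, size in enumerate(self.group_sizes):
            label = names[k] if k < len(names) else f"group{k}"
            out.extend([label] * size)
        return out


@dataclass
class SubjectDataset:
    """One simulated subject: signal, masks, trials, and the ground truth.

    ``true_informative_mask`` and ``true_latency`` are simulation ground
    truth, exposed for parameter-recovery tests only — the analysis modules
    never read them.
    """

    timeseries: np.ndarray  # (x, y, z, t) float32, runs concatenated
    mask: np.ndarray  # (x, y, z) bool
    trials: pd.DataFrame  # onset, duration, run, trial_type
    group: str
    true_informative_mask: np.ndarray  # (x, y, z) bool
    true_latency: float  # seconds post-onset
    tr: float
    run_length_trs: int
    subject_index: int = 0

    @property
    def n_runs(self) -> int:
        return self.timeseries.shape[3] // self.run_length_trs


def _gray_matter_mask(grid_shape: Sequence[int], fraction: float) -> np.ndarray:
    """Centered quasi-spherical mask covering ``fraction`` of the grid."""
    shape = tuple(grid_shape)
    n_keep = int(round(fraction * np.prod(shape)))
    center = (np.array(shape) - 1) / 2.0
    coords = np.indices(shape).reshape(3, -1).T
    # normalized squared distance so anisotropic grids still give a blob
    d2 = (((coords - center) / np.maximum(center, 1.0)) ** 2).sum(axis=1)
    order = np.lexsort((np.arange(d2.size), d2))
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    mask[order[:n_keep]] = True
    return mask.reshape(shape)


def _grow_blobs(
    mask: np.ndarray, n_voxels: int, rng: np.random.Generator
) -> np.ndarray:
    """Plant ``n_voxels`` informative voxels as contiguous blobs in the mask.

    Blobs are grown by randomized breadth-first accretion (6-connectivity)
    from random in-mask seeds; each blob targets >= 21 voxels where the
    total allows, so the decoder's cluster-size filter can retain them.
    """
    shape = mask.shape
    target_blob = 500
    n_blobs = max(1, n_voxels // target_blob)
    sizes = np.full(n_blobs, n_voxels // n_blobs)
    sizes[: n_voxels % n_blobs] += 1

    informative = np.zeros(shape, dtype=bool)
    available = mask.copy()
    offsets = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    for size in sizes:
        placed = 0
        while placed < size:
            free = np.argwhere(available)
            if free.size == 0:
                raise ValueError(
                    "grid too small to host the requested informative "
                    "voxels as contiguous blobs"
                )
            seed_vox = free[rng.integers(len(free))]
            frontier = [tuple(seed_vox)]
            while frontier and placed < size:
                pick = rng.integers(len(frontier))
                vox = frontier.pop(pick)
                if not available[vox]:
                    continue
                available[vox] = False
                informative[vox] = True
                placed += 1
                for off in offsets:
                    nb = tuple(np.array(vox) + off)
                    if all(0 <= nb[d] < shape[d] for d in range(3)) and available[nb]:
                        frontier.append(nb)
    return informative


def _ar1_noise(
    n_time: int, n_vox: int, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1) noise with unit stationary variance, shape (n_time, n_vox)."""
    innov_sd = np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=(n_time, n_vox))
    x0 = rng.normal(0.0, 1.0, size=(1, n_vox))
    if phi == 0.0:
        out = eps
        out[0] = x0[0]
        return out
    zi = phi * x0  # filter state so x[0] = eps[0] + phi*x0 is stationary
    out, _ = _signal.lfilter([1.0], [1.0, -phi], eps, axis=0, zi=zi)
    return out


def _trial_schedule(spec: CohortSpec) -> tuple[pd.DataFrame, int]:
    """Fixed onset grid: >= 18 s spacing so 0-16 s windows never overlap."""
    spacing_trs = max(int(np.ceil(MIN_TRIAL_SPACING_S / spec.tr)) + 1, 10)
    lead_trs, tail_trs = 2, 3
    k = spec.trials_per_run
    run_len = lead_trs + spacing_trs * (k - 1) + 9 + tail_trs
    rows = []
    for run in range(spec.n_runs):
        for i in range(k):
            onset_tr = lead_trs + spacing_trs * i
            rows.append(
                {
                    "onset": onset_tr * spec.tr,
                    "duration": 5.5,
                    "run": run,
                }
            )
    return pd.DataFrame(rows), run_len


def generate_subject(spec: CohortSpec, subject_index: int) -> SubjectDataset:
    """Simulate one subject's dataset.

    Deterministic given ``(spec.seed, subject_index)``. The gray-matter mask
    and the informative-voxel blobs are cohort-level (drawn from ``spec.seed``
    alone) so that subjects share informative anatomy, as the group-level
    analyses presuppose; latency, trial labels and noise are per-subject.
    """
    spec.validate()
    if subject_index < 0 or subject_index >= spec.n_subjects:
        raise ValueError(
            f"subject_index {subject_index} out of range for "
            f"{spec.n_subjects} subjects"
        )

    cohort_rng = np.random.default_rng([spec.seed, 0xC0])
    mask = _gray_matter_mask(spec.grid_shape, spec.mask_fraction)
    informative = _grow_blobs(mask, spec.n_informative_voxels, cohort_rng)

    rng = np.random.default_rng([spec.seed, 1 + subject_index])
    if spec.informative_latency is None:
        latency = float(LATENCIES[rng.integers(len(LATENCIES))])
    else:
        latency = float(spec.informative_latency)

    trials, run_len = _trial_schedule(spec)
    half = spec.n_trials // 2
    labels = np.array(["true"] * half + ["false"] * half)
    trials = trials.copy()
    trials["trial_type"] = rng.permutation(labels)

    n_time = run_len * spec.n_runs
    mask_idx = np.flatnonzero(mask.ravel())
    n_vox = mask_idx.size
    ts_flat = np.zeros((int(np.prod(spec.grid_shape)), n_time), dtype=np.float32)

    noise = np.empty((n_time, n_vox))
    for run in range(spec.n_runs):
        sl = slice(run * run_len, (run + 1) * run_len)
        noise[sl] = _ar1_noise(run_len, n_vox, spec.noise_ar1, rng)
        if spec.noise_shared_sd > 0:
            shared = _ar1_noise(run_len, 1, spec.noise_ar1, rng)
            noise[sl] += spec.noise_shared_sd * shared  # regional fluctuation

    # Plant the effect: +/- effect_size/2 at the 3 TRs whose 3-point moving
    # average is centered on the subject's informative latency.
    inf_cols = np.flatnonzero(informative.ravel()[mask_idx])
    lat_tr = int(round(latency / spec.tr))
    for run in range(spec.n_runs):
        sub = trials[trials["run"] == run]
        for _, row in sub.iterrows():
            onset_tr = run * run_len + int(round(row["onset"] / spec.tr))
            amp = spec.effect_size / 2.0
            if row["trial_type"] == "false":
                amp = -amp
            for dt in (-1, 0, 1):
                t_idx = onset_tr + lat_tr + dt
                noise[t_idx, inf_cols] += amp

    ts_flat[mask_idx] = noise.T.astype(np.float32)
    timeseries = ts_flat.reshape(spec.grid_shape + (n_time,))

    return SubjectDataset(
        timeseries=timeseries,
        mask=mask,
        trials=trials,
        group=spec.group_labels[subject_index],
        true_informative_mask=informative,
        true_latency=latency,
        tr=spec.tr,
        run_length_trs=run_len,
        subject_index=subject_index,
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectDataset]:
    """Simulate all subjects of a cohort (see :func:`generate_subject`)."""
    spec.validate()
    return [generate_subject(spec, i) for i in range(spec.n_subjects)]
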