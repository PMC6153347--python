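"""Group posterior probability maps, cluster thresholding, sparseness test.

Single-subject decoding maps (each subject's voxel selection at their
best-accuracy window) are combined into a posterior probability map: the
per-voxel fraction of subjects whose map includes the voxel. The map is
thresholded at p > 0.33 — with 14 subjects, the probability of a voxel being
informative in at least 5 of them — with a minimum cluster size of 20.

Because subjects may engage the same regions at different times, the map's
reliability is tested through a sparseness permutation test: combining maps
at random windows across subjects should scatter the overlap, so the
observed combination (best window per subject) should contain fewer
suprathreshold voxels than the null at every probability threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .decode import connectivity_structure

logger = logging.getLogger(__name__)

P_THRESH_DEFAULT = 0.33
MIN_CLUSTER_GROUP = 20  # group-level rule: clusters of at least 20 voxels


@dataclass
class ProbabilityMap:
    """Per-voxel fraction of subjects whose decoding map includes the voxel."""

    prob: np.ndarray  # 3D grid of fractions in [0, 1]
    n_subjects: int
    contributing_windows: np.ndarray | None = None  # per-subject window used


def build_probability_map(
    subject_maps, contributing_windows=None
) -> ProbabilityMap:
    """Average binary subject maps into a posterior probability map."""
    maps = [np.asarray(m, dtype=bool) for m in subject_maps]
    shape = maps[0].shape
    for k, m in enumerate(maps):
        if m.shape != shape:
            raise ValueError(
                f"subject map {k} has grid {m.shape}, expected {shape}"
            )
    stack = np.stack(maps)
    return ProbabilityMap(
        prob=stack.mean(axis=0),
        n_subjects=len(maps),
        contributing_windows=(
            None
            if contributing_windows is None
            else np.asarray(contributing_windows)
        ),
    )


def threshold_map(
    pmap: ProbabilityMap,
    p_thresh: float = P_THRESH_DEFAULT,
    min_cluster: int = MIN_CLUSTER_GROUP,
    connectivity: int = 6,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold the probability map and tabulate the surviving clusters.

    Voxels with probability strictly above ``p_thresh`` are kept; connected
    clusters of at least ``min_cluster`` voxels survive. The cluster table
    (size, center of mass, peak-probability voxel) is sorted by size
    descending, ties by the cluster's smallest linear voxel index.
    """
    if not (0 < p_thresh < 1):
        raise ValueError("p_thresh must be in (0, 1)")
    prob = pmap.prob
    supra = prob > p_thresh
    structure = connectivity_structure(connectivity)
    lab, n_lab = ndimage.label(supra, structure=structure)
    sizes = np.bincount(lab.ravel(), minlength=n_lab + 1)
    rows = []
    thresholded = np.zeros_like(supra)
    for label_id in range(1, n_lab + 1):
        if sizes[label_id] < min_cluster:
            continue
        in_cluster = lab == label_id
        thresholded |= in_cluster
        coords = np.argwhere(in_cluster)
        lin = np.ravel_multi_index(coords.T, prob.shape)
        cm = coords.mean(axis=0)
        cluster_probs = prob[in_cluster]
        peak_order = np.lexsort((lin, -cluster_probs))
        peak = coords[peak_order[0]]
        rows.append(
            {
                "size": int(sizes[label_id]),
                "cm_x": cm[0], "cm_y": cm[1], "cm_z": cm[2],
                "peak_x": int(peak[0]), "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
                "peak_prob": float(cluster_probs.max()),
                "_min_lin": int(lin.min()),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "size", "cm_x", "cm_y", "cm_z",
            "peak_x", "peak_y", "peak_z", "peak_prob", "_min_lin",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["size", "_min_lin"], ascending=[False, True]
        ).reset_index(drop=True)
    table = table.drop(columns="_min_lin")
    return thresholded, table


@dataclass
class SparsenessTestResult:
    """Outcome of the random-window sparseness permutation test."""

    thresholds: np.ndarray  # probability thresholds swept
    observed_counts: np.ndarray  # suprathreshold voxel count per threshold
    null_counts: np.ndarray  # (n_iter, n_thresholds)
    fixed_window_counts: np.ndarray  # (n_windows, n_thresholds)
    p_per_threshold: np.ndarray  # add-one one-sided (low count = overlap)
    n_iter: int


def _counts_at_thresholds(
    subject_count: np.ndarray, n_subjects: int, thresholds: np.ndarray
) -> np.ndarray:
    """#voxels with fraction strictly above each threshold, via a histogram."""
    hist = np.bincount(subject_count, minlength=n_subjects + 1)
    tail = np.cumsum(hist[::-1])[::-1]  # tail[k] = #voxels with count >= k
    min_count = np.floor(thresholds * n_subjects + 1e-9).astype(int) + 1
    min_count = np.clip(min_count, 0, n_subjects + 1)
    out = np.zeros(thresholds.size, dtype=int)
    inside = min_count <= n_subjects
    out[inside] = tail[min_count[inside]]
    return out


def sparseness_test(
    maps_by_subject_window: np.ndarray,
    observed_windows,
    thresholds=None,
    n_iter: int = 10000,
    seed: int | None = None,
) -> SparsenessTestResult:
    """Permutation test of group-map sparseness against random window draws.

    Parameters
    ----------
    maps_by_subject_window : array (n_subjects, n_windows, *grid) of bool
        Every subject's decoding map at every temporal window.
    observed_windows : sequence of int
        The window index each subject contributes to the observed group map
        (their best-accuracy window).
    thresholds : array or None
        Probability thresholds to sweep; default ``k / n_subjects`` for
        ``k = 1..n_subjects`` (strict >, so threshold ``k/n`` counts voxels
        shared by more than ``k`` subjects).
    n_iter : int
        Null iterations (one random window per subject each).
    seed : int or None
        RNG seed.

    Notes
    -----
    The observed combination is one possible null draw, so the add-one
    p-values are bounded below by ``1/(n_iter + 1)``; if all maps are
    identical across windows the test degenerates to p = 1. The seven
    fixed-window combinations are evaluated against the same null.
    """
    maps = np.asarray(maps_by_subject_window, dtype=bool)
    n_subjects, n_windows = maps.shape[:2]
    flat = maps.reshape(n_subjects, n_windows, -1).astype(np.uint8)
    observed_windows = np.asarray(observed_windows, dtype=int)
    if observed_windows.size != n_subjects:
        raise ValueError("one observed window per subject required")
    if thresholds is None:
        thresholds = np.arange(1, n_subjects + 1) / n_subjects
    thresholds = np.asarray(thresholds, dtype=float)

    subj = np.arange(n_subjects)
    obs_count = flat[subj, observed_windows].sum(axis=0)
    observed_counts = _counts_at_thresholds(obs_count, n_subjects, thresholds)

    fixed = np.empty((n_windows, thresholds.size), dtype=int)
    for w in range(n_windows):
        fixed[w] = _counts_at_thresholds(
            flat[:, w].sum(axis=0), n_subjects, thresholds
        )

    rng = np.random.default_rng(seed)
    null_counts = np.empty((n_iter, thresholds.size), dtype=int)
    for it in range(n_iter):
        draw = rng.integers(0, n_windows, size=n_subjects)
        null_counts[it] = _counts_at_thresholds(
            flat[subj, draw].sum(axis=0), n_subjects, thresholds
        )

    p = (1 + (null_counts <= observed_counts).sum(axis=0)) / (1 + n_iter)
    return SparsenessTestResult(
        thresholds=thresholds,
        observed_counts=observed_counts,
        null_counts=null_counts,
        fixed_window_counts=fixed,
        p_per_threshold=p,
        n_iter=n_iter,
    )
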