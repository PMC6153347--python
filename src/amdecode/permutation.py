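"""Label-shuffling null distribution and one-sided rank-test p-values.

Because false sentences still require retrieval of the true event, the
chance level of the pair-match accuracy need not sit at 50%; significance is
therefore assessed against an empirical null built by re-running the entire
decoding procedure with the behavioral vector shuffled during the training
phase. 100 shuffles per temporal window, pooled over the 7 windows, give a
700-value null and a common significance threshold across the time window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .decode import (
    MIN_CLUSTER_SELECT,
    N_TOP_DEFAULT,
    _decode_window_core,
    connectivity_structure,
)
from .preprocess import TrialWindowTensor

logger = logging.getLogger(__name__)

N_PER_WINDOW_DEFAULT = 100


@dataclass
class NullDistribution:
    """Pooled permutation null of decoding accuracies.

    ``per_window_values[w]`` holds the replicate accuracies for window ``w``;
    ``values`` is their concatenation (the pooled null every observed
    accuracy is tested against).
    """

    per_window_values: dict[int, np.ndarray]
    seed: int | None = None

    @property
    def values(self) -> np.ndarray:
        return np.concatenate(
            [self.per_window_values[w] for w in sorted(self.per_window_values)]
        )


def permuted_accuracy(
    tensor: TrialWindowTensor,
    window: int,
    rng: np.random.Generator,
    n_top: int = N_TOP_DEFAULT,
    min_cluster: int = MIN_CLUSTER_SELECT,
    connectivity: int = 6,
) -> float:
    """Accuracy of one null replicate at one window.

    One permutation of the behavioral vector is drawn and reused as the
    training labels across all folds of the replicate (shuffle-then-CV);
    fold enumeration and the left-out test patterns keep the actual labels.
    """
    shuffled = rng.permutation(np.asarray(tensor.labels))
    outcomes = _decode_window_core(
        tensor.values[:, :, int(window)],
        tensor.labels,
        tensor.voxel_coords,
        tensor.grid_shape,
        n_top,
        min_cluster,
        connectivity_structure(connectivity),
        train_labels=shuffled,
    )
    return float(outcomes.mean())


def build_null(
    tensor: TrialWindowTensor,
    n_per_window: int = N_PER_WINDOW_DEFAULT,
    seed: int | None = None,
    n_top: int = N_TOP_DEFAULT,
    min_cluster: int = MIN_CLUSTER_SELECT,
    connectivity: int = 6,
) -> NullDistribution:
    """Permutation null over every window: ``n_per_window`` x 7 accuracies.

    Permutation draws are taken from a single seeded stream, window by
    window, so the whole null is reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_windows = tensor.values.shape[2]
    per_window: dict[int, np.ndarray] = {}
    for w in range(n_windows):
        per_window[w] = np.array(
            [
                permuted_accuracy(
                    tensor, w, rng,
                    n_top=n_top, min_cluster=min_cluster,
                    connectivity=connectivity,
                )
                for _ in range(n_per_window)
            ]
        )
    logger.info(
        "built null distribution: %d windows x %d replicates",
        n_windows, n_per_window,
    )
    return NullDistribution(per_window_values=per_window, seed=seed)


def rank_test(observed: float, null: NullDistribution | np.ndarray) -> float:
    """One-sided add-one rank test of an accuracy against the pooled null.

    p = (1 + #{null >= observed}) / (1 + N); the permutation p can never be
    exactly zero, and an observation above all 700 nulls gives 1/701.
    """
    values = null.values if isinstance(null, NullDistribution) else np.asarray(null)
    if values.size == 0:
        raise ValueError("null distribution is empty")
    return float((1 + (values >= observed).sum()) / (1 + values.size))
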