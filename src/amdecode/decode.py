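"""Single-subject encoding-model decoding with leave-two-stimuli-out CV.

Per temporal window, a per-voxel linear encoding model regresses the z-scored
signal on the condition regressor (true = +1, false = -1, with intercept).
In every cross-validation fold one true and one false trial are left out, the
model is fitted on the remaining trials, the 2,000 voxels with the highest
coefficient of determination R^2 are retained (after removing clusters of 20
or fewer face-connected voxels), the held-out activation patterns are
predicted over that subset, and the fold is scored correct if pairing each
predicted pattern with its own observed pattern yields a higher summed cosine
similarity than the swapped pairing. All true x false pairs are tested
(24 x 24 trials -> 576 folds, each trained on 46 stimuli).

The estimator-shaped surface (:class:`EncodingModelDecoder` with the
:class:`LeaveTrueFalsePairOut` splitter) composes with scikit-learn's model
selection; :func:`decode_window` / :func:`decode_subject` run the same
procedure on a vectorized fast path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.model_selection import BaseCrossValidator

from .preprocess import WINDOW_TIMES, TrialWindowTensor

logger = logging.getLogger(__name__)

N_TOP_DEFAULT = 2000
MIN_CLUSTER_SELECT = 21  # retain clusters strictly larger than 20 voxels


def _as_true_bool(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    return labels.astype(str) == "true"


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D neighborhood footprint for cluster labeling (6, 18 or 26)."""
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, rank)


# ---------------------------------------------------------------------------
# fold enumeration

def enumerate_folds(labels) -> list[tuple[int, int]]:
    """All (true trial, false trial) leave-two-out pairs, ascending indices.

    With 24 true and 24 false trials this yields the full 576-fold schedule;
    each fold trains on the remaining 46 stimuli (23 per class).
    """
    is_true = _as_true_bool(labels)
    true_idx = np.flatnonzero(is_true)
    false_idx = np.flatnonzero(~is_true)
    if true_idx.size < 2 or false_idx.size < 2:
        raise ValueError(
            "need at least 2 trials of each class for leave-two-out CV "
            f"(got {true_idx.size} true, {false_idx.size} false)"
        )
    return [(int(i), int(j)) for i in true_idx for j in false_idx]


class LeaveTrueFalsePairOut(BaseCrossValidator):
    """CV splitter leaving out one true and one false trial per fold.

    Compatible with scikit-learn model selection: ``split(X, y)`` yields
    ``(train_indices, [true_index, false_index])`` for every ordered
    true x false pair, in ascending trial order.
    """

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        is_true = _as_true_bool(y)
        return int(is_true.sum() * (~is_true).sum())

    def split(self, X=None, y=None, groups=None):
        # overridden (not _iter_test_indices) to keep the test pair ordered
        # as (true trial, false trial)
        n = len(y)
        for i, j in enumerate_folds(y):
            train = np.setdiff1d(np.arange(n), [i, j])
            yield train, np.array([i, j])

    def _iter_test_indices(self, X=None, y=None, groups=None):
        for i, j in enumerate_folds(y):
            yield np.array([i, j])


# ---------------------------------------------------------------------------
# encoding model

@dataclass
class EncodingModel:
    """Per-voxel linear model of signal on the true/false regressor."""

    weights: np.ndarray  # slope, z-units per condition unit
    intercepts: np.ndarray
    r2: np.ndarray  # coefficient of determination in [0, 1]


def fit_encoding(X: np.ndarray, labels) -> EncodingModel:
    """OLS fit of each voxel's signal on x = +1 (true) / -1 (false).

    With a two-level regressor and intercept the fitted values are the class
    means, so the slope is half the class-mean difference and
    R^2 = 1 - SS_within / SS_total. Voxels with zero total variance get
    weight 0 and R^2 = 0.
    """
    X = np.asarray(X, dtype=np.float64)
    is_true = _as_true_bool(labels)
    if is_true.all() or (~is_true).all():
        raise ValueError("training set must contain both classes")
    m1 = X[is_true].mean(axis=0)
    m0 = X[~is_true].mean(axis=0)
    ss_res = ((X[is_true] - m1) ** 2).sum(axis=0) + (
        (X[~is_true] - m0) ** 2
    ).sum(axis=0)
    ss_tot = ((X - X.mean(axis=0)) ** 2).sum(axis=0)
    weights = (m1 - m0) / 2.0
    intercepts = (m1 + m0) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    degenerate = ss_tot <= 1e-300
    r2[degenerate] = 0.0
    weights[degenerate] = 0.0
    return EncodingModel(weights, intercepts, np.clip(r2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# voxel selection

@dataclass
class VoxelSelection:
    """R^2-ranked, cluster-filtered voxel subset (a decoding map)."""

    selected: np.ndarray  # 3D bool grid
    n_selected: int
    clusters: list[tuple[np.ndarray, int]]  # (voxel coord array, size)
    columns: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    # tensor-column indices of the selected voxels


def _top_columns(r2: np.ndarray, n_top: int) -> np.ndarray:
    """Indices of the n_top highest-R^2 columns, ties by ascending index."""
    if n_top >= r2.size:
        return np.arange(r2.size)
    part = np.argpartition(-r2, n_top - 1)
    thr = r2[part[n_top - 1]]
    above = np.flatnonzero(r2 > thr)
    ties = np.flatnonzero(r2 == thr)  # ascending index by construction
    return np.concatenate([above, ties[: n_top - above.size]])


def _cluster_filter(
    cols: np.ndarray,
    voxel_coords: np.ndarray,
    grid_shape: tuple[int, int, int],
    min_cluster: int,
    structure: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop candidate voxels in connected clusters smaller than min_cluster.

    Returns (kept columns, label volume, cluster sizes by label).
    """
    vol = np.zeros(grid_shape, dtype=bool)
    pts = voxel_coords[cols]
    vol[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    lab, n_lab = ndimage.label(vol, structure=structure)
    if n_lab == 0:
        return cols[:0], lab, np.zeros(1, int)
    sizes = np.bincount(lab.ravel())
    keep_label = sizes >= min_cluster
    keep_label[0] = False
    keep = keep_label[lab[pts[:, 0], pts[:, 1], pts[:, 2]]]
    return cols[keep], lab, sizes


def select_voxels(
    model: EncodingModel,
    voxel_coords: np.ndarray,
    grid_shape: tuple[int, int, int],
    n_top: int = N_TOP_DEFAULT,
    min_cluster: int = MIN_CLUSTER_SELECT,
    connectivity: int = 6,
) -> VoxelSelection:
    """Take the top ``n_top`` voxels by R^2, then remove small clusters.

    Ranking ties are broken by ascending linear voxel index so the selection
    is deterministic. If fewer than ``n_top`` voxels are available, all are
    ranked (logged). Clusters are connected components at the requested grid
    connectivity; only clusters of at least ``min_cluster`` voxels survive
    (the default keeps clusters strictly larger than 20).
    """
    r2 = np.asarray(model.r2)
    if r2.size < n_top:
        logger.info(
            "mask holds %d voxels (< n_top=%d); ranking all", r2.size, n_top
        )
    structure = connectivity_structure(connectivity)
    cols = _top_columns(r2, n_top)
    kept, lab, sizes = _cluster_filter(
        cols, voxel_coords, grid_shape, min_cluster, structure
    )
    selected = np.zeros(grid_shape, dtype=bool)
    clusters: list[tuple[np.ndarray, int]] = []
    if kept.size:
        pts = voxel_coords[kept]
        selected[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        for label_id in np.flatnonzero(sizes >= min_cluster):
            if label_id == 0:
                continue
            coords = np.argwhere(lab == label_id)
            clusters.append((coords, int(sizes[label_id])))
    return VoxelSelection(
        selected=selected,
        n_selected=int(kept.size),
        clusters=clusters,
        columns=np.sort(kept),
    )


# ---------------------------------------------------------------------------
# prediction and pair matching

def predict_pattern(
    model: EncodingModel, columns: np.ndarray, label: str | bool
) -> np.ndarray:
    """Predicted activation over the selected voxels for one condition."""
    x = 1.0 if (label is True or str(label) == "true") else -1.0
    return model.intercepts[columns] + model.weights[columns] * x


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        logger.warning("zero-norm vector in cosine match; similarity set to 0")
        return 0.0
    return float(a @ b) / (na * nb)


def match_pair(
    pred_true: np.ndarray,
    pred_false: np.ndarray,
    obs_true: np.ndarray,
    obs_false: np.ndarray,
) -> bool:
    """Cosine-similarity assignment of the two left-out patterns.

    Correct iff matching each prediction with its own observation beats the
    swapped assignment; an exact tie scores incorrect (conservative).
    """
    same = _cosine(pred_true, obs_true) + _cosine(pred_false, obs_false)
    swapped = _cosine(pred_true, obs_false) + _cosine(pred_false, obs_true)
    return same > swapped


# ---------------------------------------------------------------------------
# fast whole-window decoding

def _decode_window_core(
    X: np.ndarray,
    labels,
    voxel_coords: np.ndarray,
    grid_shape: tuple[int, int, int],
    n_top: int,
    min_cluster: int,
    structure: np.ndarray,
    train_labels=None,
) -> np.ndarray:
    """Fold outcomes for one window; training labels may be overridden.

    ``train_labels`` (if given) replaces the behavioral vector during model
    fitting only — fold enumeration and the left-out observed patterns always
    follow the actual labels, which is how the permutation null shuffles the
    training phase. Class sums are downdated per fold rather than recomputed.
    """
    X = np.asarray(X, dtype=np.float64)
    is_true = _as_true_bool(labels)
    t = is_true if train_labels is None else _as_true_bool(train_labels)
    folds = enumerate_folds(is_true)

    Xsq = X**2
    S1 = X[t].sum(axis=0)
    Q1 = Xsq[t].sum(axis=0)
    S0 = X[~t].sum(axis=0)
    Q0 = Xsq[~t].sum(axis=0)
    n1 = int(t.sum())
    n0 = int((~t).sum())
    n_train = X.shape[0] - 2

    outcomes = np.zeros(len(folds), dtype=bool)
    for k, (i, j) in enumerate(folds):
        ai = 1.0 if t[i] else 0.0
        aj = 1.0 if t[j] else 0.0
        s1 = S1 - ai * X[i] - aj * X[j]
        q1 = Q1 - ai * Xsq[i] - aj * Xsq[j]
        s0 = S0 - (1 - ai) * X[i] - (1 - aj) * X[j]
        q0 = Q0 - (1 - ai) * Xsq[i] - (1 - aj) * Xsq[j]
        m1f = n1 - ai - aj
        m0f = n0 - (1 - ai) - (1 - aj)
        if m1f < 1 or m0f < 1:
            continue  # a shuffled fold emptied one class: scored incorrect
        mu1 = s1 / m1f
        mu0 = s0 / m0f
        w = (mu1 - mu0) / 2.0
        b = (mu1 + mu0) / 2.0
        ss_res = (q1 - s1 * mu1) + (q0 - s0 * mu0)
        s_all = s1 + s0
        ss_tot = (q1 + q0) - s_all * s_all / n_train
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - ss_res / ss_tot
        r2[ss_tot <= 1e-12] = 0.0
        np.clip(r2, 0.0, 1.0, out=r2)

        cols = _top_columns(r2, n_top)
        kept, _, _ = _cluster_filter(
            cols, voxel_coords, grid_shape, min_cluster, structure
        )
        if kept.size == 0:
            logger.debug("fold %d: empty selection, scored incorrect", k)
            continue
        outcomes[k] = match_pair(
            b[kept] + w[kept],
            b[kept] - w[kept],
            X[i, kept],
            X[j, kept],
        )
    return outcomes


def decode_window(
    tensor: TrialWindowTensor,
    window: int | float,
    n_top: int = N_TOP_DEFAULT,
    min_cluster: int = MIN_CLUSTER_SELECT,
    connectivity: int = 6,
    train_labels=None,
) -> tuple[float, np.ndarray, VoxelSelection]:
    """Run the full leave-two-out procedure at one temporal window.

    ``window`` is either a window index (int) or a center time in seconds
    (float). Returns ``(accuracy, fold_outcomes, decoding_map)`` where the
    decoding map is the voxel selection from a model fitted on all trials at
    this window.
    """
    w = (
        int(window)
        if isinstance(window, (int, np.integer))
        else tensor.window_index(float(window))
    )
    X = tensor.values[:, :, w]
    structure = connectivity_structure(connectivity)
    outcomes = _decode_window_core(
        X,
        tensor.labels,
        tensor.voxel_coords,
        tensor.grid_shape,
        n_top,
        min_cluster,
        structure,
        train_labels=train_labels,
    )
    full_model = fit_encoding(X, tensor.labels)
    decoding_map = select_voxels(
        full_model,
        tensor.voxel_coords,
        tensor.grid_shape,
        n_top=n_top,
        min_cluster=min_cluster,
        connectivity=connectivity,
    )
    return float(outcomes.mean()), outcomes, decoding_map


# ---------------------------------------------------------------------------
# per-subject aggregation

def bootstrap_se(
    fold_outcomes: np.ndarray, n_boot: int = 1000, seed=None
) -> float:
    """Bootstrap SE of the accuracy: resample fold outcomes with replacement."""
    fold_outcomes = np.asarray(fold_outcomes, dtype=np.float64)
    n = fold_outcomes.size
    if n < 2:
        raise ValueError("need at least 2 fold outcomes")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    return float(fold_outcomes[idx].mean(axis=1).std())


def best_window(
    accuracy_by_window: np.ndarray, window_times=WINDOW_TIMES
) -> float:
    """Window center (s) with the highest accuracy; ties go to the earliest."""
    acc = np.asarray(accuracy_by_window, dtype=np.float64)
    return float(np.asarray(window_times)[int(np.argmax(acc))])


@dataclass
class DecodingResult:
    """All per-window outputs of the single-subject decoding analysis."""

    window_times: tuple[float, ...]
    accuracy_by_window: np.ndarray  # 7 fractions in [0, 1]
    se_by_window: np.ndarray  # bootstrap SEs
    fold_outcomes: np.ndarray  # (7, n_folds) correctness flags
    decoding_maps: list[VoxelSelection]  # per window, full-data selection
    p_by_window: np.ndarray | None = None  # filled by the permutation module

    @property
    def best_window(self) -> float:
        return best_window(self.accuracy_by_window, self.window_times)

    @property
    def best_window_index(self) -> int:
        return int(np.argmax(self.accuracy_by_window))

    @property
    def best_map(self) -> VoxelSelection:
        return self.decoding_maps[self.best_window_index]


def decode_subject(
    tensor: TrialWindowTensor,
    n_top: int = N_TOP_DEFAULT,
    min_cluster: int = MIN_CLUSTER_SELECT,
    connectivity: int = 6,
    n_boot: int = 1000,
    seed=None,
) -> DecodingResult:
    """Decode every temporal window and bootstrap the accuracy SEs."""
    n_windows = tensor.values.shape[2]
    accuracies = np.empty(n_windows)
    ses = np.empty(n_windows)
    all_outcomes = []
    maps = []
    rng = np.random.default_rng(seed)
    for w in range(n_windows):
        acc, outcomes, dmap = decode_window(
            tensor, w, n_top=n_top, min_cluster=min_cluster,
            connectivity=connectivity,
        )
        accuracies[w] = acc
        ses[w] = bootstrap_se(outcomes, n_boot=n_boot, seed=rng)
        all_outcomes.append(outcomes)
        maps.append(dmap)
    return DecodingResult(
        window_times=tuple(tensor.window_times),
        accuracy_by_window=accuracies,
        se_by_window=ses,
        fold_outcomes=np.array(all_outcomes),
        decoding_maps=maps,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator surface

class EncodingModelDecoder(BaseEstimator):
    """Per-window encoding model as a scikit-learn style estimator.

    ``fit(X, y)`` takes ``X`` of shape (n_trials, n_voxels) — the tensor at
    one temporal window — and labels ``y`` in {"true", "false"}; it fits the
    per-voxel linear model and performs the R^2 ranking / cluster-filter
    voxel selection. ``score(X_pair, y_pair)`` scores one left-out
    true/false pair by the cosine-similarity match, so
    ``cross_val_score(est, X, y, cv=LeaveTrueFalsePairOut())`` reproduces the
    leave-two-stimuli-out accuracy fold by fold.

    Parameters
    ----------
    n_top : int
        Number of voxels retained by the R^2 ranking.
    min_cluster : int
        Minimum connected-cluster size retained after ranking (21 keeps
        clusters strictly larger than 20 voxels).
    connectivity : int
        Cluster connectivity, 6 (faces), 18 or 26.
    voxel_coords : ndarray of shape (n_voxels, 3) or None
        Grid coordinate of each column; ``None`` disables the cluster filter
        (columns are treated as isolated and min_cluster is ignored).
    grid_shape : tuple or None
        3D grid shape matching ``voxel_coords``.
    """

    def __init__(
        self,
        n_top: int = N_TOP_DEFAULT,
        min_cluster: int = MIN_CLUSTER_SELECT,
        connectivity: int = 6,
        voxel_coords=None,
        grid_shape=None,
    ):
        self.n_top = n_top
        self.min_cluster = min_cluster
        self.connectivity = connectivity
        self.voxel_coords = voxel_coords
        self.grid_shape = grid_shape

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_trials, n_voxels)")
        model = fit_encoding(X, y)
        self.model_ = model
        self.weights_ = model.weights
        self.intercepts_ = model.intercepts
        self.r2_ = model.r2
        if self.voxel_coords is not None:
            sel = select_voxels(
                model,
                np.asarray(self.voxel_coords),
                tuple(self.grid_shape),
                n_top=self.n_top,
                min_cluster=self.min_cluster,
                connectivity=self.connectivity,
            )
            self.selection_ = sel
            self.columns_ = sel.columns
        else:
            self.selection_ = None
            self.columns_ = _top_columns(model.r2, self.n_top)
        return self

    def predict_pattern(self, label) -> np.ndarray:
        """Predicted activation over the selected voxels for one label."""
        return predict_pattern(self.model_, self.columns_, label)

    def score(self, X, y) -> float:
        """Cosine-match correctness of one left-out true/false pair (0 or 1)."""
        X = np.asarray(X, dtype=np.float64)
        is_true = _as_true_bool(y)
        if X.shape[0] != 2 or is_true.sum() != 1:
            raise ValueError(
                "score expects exactly one true and one false trial"
            )
        if self.columns_.size == 0:
            logger.warning("empty voxel selection: pair scored incorrect")
            return 0.0
        obs_true = X[int(np.flatnonzero(is_true)[0]), self.columns_]
        obs_false = X[int(np.flatnonzero(~is_true)[0]), self.columns_]
        return float(
            match_pair(
                self.predict_pattern("true"),
                self.predict_pattern("false"),
                obs_true,
                obs_false,
            )
        )
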