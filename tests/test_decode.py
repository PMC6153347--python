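"""Encoding model, voxel selection, cosine matching and the CV schedule."""

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import cross_val_score

import amdecode as am
from amdecode.decode import (
    EncodingModel,
    _cluster_filter,
    _top_columns,
    connectivity_structure,
)


def _full_grid_coords(shape):
    return np.indices(shape).reshape(3, -1).T


class TestFoldEnumeration:
    def test_24_24_gives_576_folds_training_on_46(self):
        labels = np.array(["true"] * 24 + ["false"] * 24)
        folds = am.enumerate_folds(labels)
        assert len(folds) == 576
        for i, j in folds[:: 97]:
            train = np.delete(labels, [i, j])
            assert len(train) == 46
            assert (train == "true").sum() == 23

    def test_2_2_gives_4_folds(self):
        assert len(am.enumerate_folds(["true", "false", "true", "false"])) == 4

    @pytest.mark.parametrize("n_true,n_false", [(2, 3), (4, 4), (6, 5), (6, 6)])
    def test_matches_brute_force_double_loop(self, n_true, n_false, rng):
        labels = rng.permutation(
            np.array(["true"] * n_true + ["false"] * n_false)
        )
        oracle = [
            (i, j)
            for i in range(len(labels))
            if labels[i] == "true"
            for j in range(len(labels))
            if labels[j] == "false"
        ]
        assert am.enumerate_folds(labels) == oracle

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            am.enumerate_folds(["true", "true", "false"])

    def test_splitter_agrees_with_enumeration(self, rng):
        labels = rng.permutation(np.array(["true"] * 4 + ["false"] * 3))
        cv = am.LeaveTrueFalsePairOut()
        X = rng.normal(size=(7, 5))
        splits = list(cv.split(X, labels))
        assert cv.get_n_splits(X, labels) == 12 == len(splits)
        for (train, test), (i, j) in zip(splits, am.enumerate_folds(labels)):
            assert list(test) == [i, j]
            assert set(train) == set(range(7)) - {i, j}


class TestEncodingModel:
    def test_perfect_separation(self):
        labels = ["true"] * 4 + ["false"] * 4
        d = 0.7
        X = np.where(
            np.array([1] * 4 + [0] * 4)[:, None], d, -d
        ) + np.zeros((8, 3))
        m = am.fit_encoding(X, labels)
        np.testing.assert_allclose(m.weights, d)
        np.testing.assert_allclose(m.intercepts, 0.0, atol=1e-12)
        np.testing.assert_allclose(m.r2, 1.0)

    def test_constant_voxel_gets_zero_weight_and_r2(self):
        X = np.full((6, 2), 3.0)
        m = am.fit_encoding(X, ["true"] * 3 + ["false"] * 3)
        np.testing.assert_array_equal(m.weights, 0.0)
        np.testing.assert_array_equal(m.r2, 0.0)

    def test_agrees_with_lstsq(self, rng):
        labels = rng.permutation(np.array(["true"] * 5 + ["false"] * 7))
        X = rng.normal(size=(12, 6))
        m = am.fit_encoding(X, labels)
        x = np.where(labels == "true", 1.0, -1.0)
        design = np.column_stack([np.ones(12), x])
        coef, _, _, _ = np.linalg.lstsq(design, X, rcond=None)
        np.testing.assert_allclose(m.intercepts, coef[0], atol=1e-10)
        np.testing.assert_allclose(m.weights, coef[1], atol=1e-10)

    def test_null_r2_follows_beta(self, rng):
        """On pure noise R^2 ~ Beta(1/2, (n-2)/2): one-regressor OLS null."""
        n = 20
        labels = ["true"] * (n // 2) + ["false"] * (n // 2)
        X = rng.normal(size=(n, 4000))
        m = am.fit_encoding(X, labels)
        _, p = stats.kstest(m.r2, stats.beta(0.5, (n - 2) / 2).cdf)
        assert p > 0.01

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            am.fit_encoding(np.zeros((3, 2)), ["true"] * 3)


class TestVoxelSelection:
    def test_large_blob_keeps_exactly_n_top(self, rng):
        shape = (20, 20, 20)
        r2 = rng.uniform(0, 0.1, size=8000)
        blob = np.zeros(shape, dtype=bool)
        blob[2:18, 2:18, 4:14] = True  # 2560-voxel contiguous block
        r2[blob.ravel()] += 0.5
        model = EncodingModel(np.zeros(8000), np.zeros(8000), r2)
        sel = am.select_voxels(model, _full_grid_coords(shape), shape, n_top=2000)
        assert sel.n_selected == 2000
        assert len(sel.clusters) == 1

    def test_scattered_singletons_filtered_out(self):
        shape = (10, 10, 10)
        r2 = np.zeros(1000)
        r2[::7] = 0.9  # stride-7 singleton voxels, never face-adjacent
        model = EncodingModel(np.zeros(1000), np.zeros(1000), r2)
        sel = am.select_voxels(
            model, _full_grid_coords(shape), shape, n_top=100, min_cluster=21
        )
        assert sel.n_selected == 0
        assert sel.clusters == []

    def test_cluster_size_rule_30_kept_15_dropped(self):
        shape = (10, 10, 10)
        vol = np.zeros(shape, dtype=bool)
        vol[0, 0:6, 0:5] = True  # 30-voxel sheet
        vol[5, 0:3, 0:5] = True  # 15-voxel sheet, far away
        r2 = np.where(vol.ravel(), 0.9, 0.0)
        model = EncodingModel(np.zeros(1000), np.zeros(1000), r2)
        sel = am.select_voxels(
            model, _full_grid_coords(shape), shape, n_top=45, min_cluster=21
        )
        assert sel.n_selected == 30
        assert [size for _, size in sel.clusters] == [30]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cluster_filter_matches_bfs_oracle(self, seed):
        shape = (5, 5, 4)
        r = np.random.default_rng(seed)
        coords = _full_grid_coords(shape)
        cols = np.flatnonzero(r.random(100) < 0.4)

        def bfs_components(points):
            points = {tuple(p) for p in points}
            seen, comps = set(), []
            for p in points:
                if p in seen:
                    continue
                comp, stack = [], [p]
                seen.add(p)
                while stack:
                    q = stack.pop()
                    comp.append(q)
                    for d in range(3):
                        for s in (-1, 1):
                            nb = list(q)
                            nb[d] += s
                            nb = tuple(nb)
                            if nb in points and nb not in seen:
                                seen.add(nb)
                                stack.append(nb)
                comps.append(comp)
            return comps

        min_cluster = 4
        oracle_keep = set()
        for comp in bfs_components(coords[cols]):
            if len(comp) >= min_cluster:
                oracle_keep |= set(comp)
        kept, _, _ = _cluster_filter(
            cols, coords, shape, min_cluster, connectivity_structure(6)
        )
        assert {tuple(coords[c]) for c in kept} == oracle_keep

    def test_rank_ties_broken_by_ascending_index(self):
        r2 = np.array([0.5, 0.9, 0.5, 0.5, 0.1])
        top = _top_columns(r2, 2)
        assert set(top) == {1, 0}  # index 0 wins the three-way tie at 0.5

    def test_mask_smaller_than_n_top_selects_all(self, caplog):
        shape = (3, 3, 3)
        model = EncodingModel(np.zeros(27), np.zeros(27), np.linspace(0, 1, 27))
        sel = am.select_voxels(
            model, _full_grid_coords(shape), shape, n_top=2000, min_cluster=1
        )
        assert sel.n_selected == 27


class TestMatchPair:
    def test_identity_match_correct(self):
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        assert am.match_pair(a, b, a, b)

    def test_swapped_match_incorrect(self):
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        assert not am.match_pair(a, b, b, a)

    def test_tie_scored_incorrect(self):
        p = np.array([1.0, 1.0])
        assert not am.match_pair(p, p, np.array([1.0, 0.0]), np.array([0.0, 1.0]))

    def test_zero_norm_vector_counts_as_zero_similarity(self, caplog):
        z = np.zeros(2)
        a = np.array([1.0, 0.0])
        with caplog.at_level("WARNING"):
            assert not am.match_pair(z, z, a, a)

    def test_prediction_difference_is_twice_the_weight(self):
        m = EncodingModel(
            np.array([0.3, -0.2]), np.array([1.0, 2.0]), np.array([0.5, 0.5])
        )
        cols = np.array([0, 1])
        diff = am.predict_pattern(m, cols, "true") - am.predict_pattern(
            m, cols, "false"
        )
        np.testing.assert_allclose(diff, 2 * m.weights)


class TestDecodeWindow:
    def test_fold_count_and_accuracy_range(self, tiny_tensor):
        acc, outcomes, dmap = am.decode_window(
            tiny_tensor, 3, n_top=40, min_cluster=5
        )
        assert outcomes.shape == (36,)  # 6 true x 6 false
        assert acc == outcomes.mean()
        assert 0.0 <= acc <= 1.0
        assert dmap.n_selected <= 40

    def test_scale_invariance(self, tiny_tensor):
        acc1, out1, _ = am.decode_window(tiny_tensor, 3, n_top=40, min_cluster=5)
        scaled = am.TrialWindowTensor(
            values=tiny_tensor.values * 7.3,
            window_times=tiny_tensor.window_times,
            voxel_coords=tiny_tensor.voxel_coords,
            grid_shape=tiny_tensor.grid_shape,
            labels=tiny_tensor.labels,
        )
        acc2, out2, _ = am.decode_window(scaled, 3, n_top=40, min_cluster=5)
        assert np.array_equal(out1, out2)

    def test_label_swap_maps_accuracy_to_complement(self, tiny_tensor):
        """Flipping all training labels swaps each fold's assignment."""
        acc, out, _ = am.decode_window(tiny_tensor, 3, n_top=40, min_cluster=5)
        flipped = np.where(tiny_tensor.labels == "true", "false", "true")
        acc_f, out_f, _ = am.decode_window(
            tiny_tensor, 3, n_top=40, min_cluster=5, train_labels=flipped
        )
        # ties (scored incorrect both ways) can only reduce the complement
        assert acc_f <= 1 - acc + 1e-12
        assert np.mean(out & out_f) == 0.0

    def test_planted_window_beats_distant_window(self, tiny_tensor, tiny_subject):
        acc_at = {}
        for w in (0, 3):
            acc_at[w], _, _ = am.decode_window(
                tiny_tensor, w, n_top=40, min_cluster=5
            )
        assert acc_at[3] > acc_at[0]  # latency was planted at 8 s

    def test_decoding_map_recovers_planted_blobs(self, tiny_tensor, tiny_subject):
        _, _, dmap = am.decode_window(tiny_tensor, 3, n_top=40, min_cluster=5)
        truth = tiny_subject.true_informative_mask
        jaccard = (dmap.selected & truth).sum() / (dmap.selected | truth).sum()
        assert jaccard > 0.5


class TestSubjectLevel:
    def test_decode_subject_outputs(self, tiny_tensor):
        res = am.decode_subject(tiny_tensor, n_top=40, min_cluster=5, n_boot=100, seed=0)
        assert res.accuracy_by_window.shape == (7,)
        assert res.fold_outcomes.shape == (7, 36)
        np.testing.assert_allclose(
            res.accuracy_by_window, res.fold_outcomes.mean(axis=1)
        )
        assert res.best_window in am.WINDOW_TIMES
        assert all(s >= 0 for s in res.se_by_window)

    def test_bootstrap_se_closed_form(self, rng):
        """576 iid Bernoulli(1/2) outcomes: SE ~ sqrt(0.25/576) ~ 0.0208."""
        outcomes = rng.random(576) < 0.5
        se = am.bootstrap_se(outcomes, n_boot=2000, seed=1)
        assert se == pytest.approx(np.sqrt(0.25 / 576), rel=0.2)

    def test_bootstrap_se_constant_outcomes_zero(self):
        assert am.bootstrap_se(np.ones(50), n_boot=100, seed=0) == 0.0

    def test_bootstrap_se_deterministic_under_seed(self, rng):
        outcomes = rng.random(100) < 0.6
        assert am.bootstrap_se(outcomes, seed=7) == am.bootstrap_se(outcomes, seed=7)

    def test_best_window_argmax_and_tie_rule(self):
        acc = np.array([0.5, 0.5, 0.6, 0.9, 0.9, 0.5, 0.5])
        assert am.best_window(acc) == 8.0
        assert am.best_window(np.full(7, 0.5)) == 2.0


class TestSklearnSurface:
    def test_cross_val_score_matches_fast_path(self, tiny_tensor):
        """The estimator + splitter route reproduces the fast path fold by fold."""
        X = tiny_tensor.values[:, :, 3]
        y = tiny_tensor.labels
        est = am.EncodingModelDecoder(
            n_top=40,
            min_cluster=5,
            voxel_coords=tiny_tensor.voxel_coords,
            grid_shape=tiny_tensor.grid_shape,
        )
        scores = cross_val_score(est, X, y, cv=am.LeaveTrueFalsePairOut())
        acc, outcomes, _ = am.decode_window(tiny_tensor, 3, n_top=40, min_cluster=5)
        np.testing.assert_array_equal(scores.astype(bool), outcomes)
        assert scores.mean() == pytest.approx(acc)

    def test_estimator_is_cloneable_with_fitted_attributes(self, tiny_tensor):
        est = am.EncodingModelDecoder(n_top=10)
        est2 = clone(est)
        assert est2.get_params()["n_top"] == 10
        X = tiny_tensor.values[:, :, 3]
        est2.fit(X, tiny_tensor.labels)
        assert est2.r2_.shape == (X.shape[1],)
        assert est2.columns_.shape == (10,)
        assert est2.predict_pattern("true").shape == (10,)

    def test_score_requires_one_trial_per_class(self, tiny_tensor):
        X = tiny_tensor.values[:, :, 3]
        est = am.EncodingModelDecoder(n_top=10).fit(X, tiny_tensor.labels)
        with pytest.raises(ValueError, match="exactly one true"):
            est.score(X[:2], ["true", "true"])
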