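"""Ensemble SDM engine: filtering, Moran's I, splits, base learners,
evaluation metrics, binarization and map stacking."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speleosdm import esdm_engine as ee
from speleosdm.microclimate import NM


def _occ_set(n, species="sp", counts=None):
    counts = counts if counts is not None else np.ones(n, int)
    df = pd.DataFrame(
        {
            "site_id": "s",
            "level_index": 1,
            "x": np.linspace(1, 50, n),
            "y": 1.0,
            "count": counts,
        }
    )
    return ee.OccurrenceSet(species, NM, df)


class TestFilterOccurrences:
    @pytest.mark.parametrize("n,kept", [(24, False), (25, True), (26, True)])
    def test_threshold_inclusive(self, n, kept):
        retained, excluded = ee.filter_occurrences([_occ_set(n)])
        assert bool(retained) is kept
        if not kept:
            assert excluded[0]["n"] == n

    def test_counts_sum_toward_threshold(self):
        # 5 records x 5 individuals = 25 occurrences -> retained
        retained, _ = ee.filter_occurrences([_occ_set(5, counts=np.full(5, 5))])
        assert retained

    def test_empty_set_excluded(self):
        retained, excluded = ee.filter_occurrences([])
        assert retained == [] and excluded == []


@pytest.fixture(scope="module")
def wide_grid():
    """Wide corridor so aggregation cells form a 2-D patch, not a chain."""
    import networkx as nx
    from shapely.geometry import Polygon

    from speleosdm import cave_geometry as cg

    level = cg.LevelGeometry(
        1, Polygon([(0, 0), (100, 0), (100, 4), (0, 4)]), nx.Graph()
    )
    return cg.rasterize_boundary(level, 0.5)


class TestMoransI:
    def test_checkerboard_rook_weights(self):
        # 2x2 checkerboard {1,0;0,1}, rook adjacency: hand computation -> -1
        W = np.array(
            [[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]], float
        )
        rep = ee.morans_i_from_weights(np.array([1.0, 0.0, 0.0, 1.0]), W)
        assert rep.morans_I == pytest.approx(-1.0)
        assert rep.expected_I == pytest.approx(-1 / 3)

    def test_permuted_counts_near_null_expectation(self, corridor_grid):
        rng = np.random.default_rng(3)
        xs = rng.uniform(1, 99, 200)
        ys = rng.uniform(0.3, 1.7, 200)
        counts = rng.permutation(np.r_[np.ones(150), rng.integers(2, 9, 50)])
        rep = ee.morans_i(
            np.column_stack([xs, ys]), corridor_grid, counts=counts.astype(float)
        )
        # under random permutation |z| should be unremarkable
        assert abs(rep.z_score) < 3.0
        assert rep.morans_I == pytest.approx(rep.expected_I, abs=0.15)

    def test_single_tight_cluster_strongly_positive(self, wide_grid):
        rng = np.random.default_rng(0)
        pts = rng.normal([50, 2], [4.0, 0.8], size=(2000, 2))
        rep = ee.morans_i(pts, wide_grid)
        # a lone density dome: adjacent-cell tally noise caps I well below
        # the multi-colony regime, but the clustering signal is unambiguous
        assert rep.morans_I > 0.2
        assert rep.z_score > 3.0

    def test_multiple_colonies_heavily_clustered(self, wide_grid):
        # colonies with distinct tally scales: the regime the diagnostic
        # is meant to flag; I rises well above 0.5
        rng = np.random.default_rng(0)
        pts, cts = [], []
        for cx, scale in [(20, 12), (55, 3), (85, 30)]:
            pts.append(rng.normal([cx, 2], [3.0, 0.7], size=(120, 2)))
            cts.append(np.maximum(1, rng.poisson(scale, 120)))
        rep = ee.morans_i(
            np.vstack(pts), wide_grid, counts=np.concatenate(cts).astype(float)
        )
        assert rep.morans_I > 0.5
        assert rep.z_score > 3.0

    def test_degenerate_variance(self):
        W = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="degenerate variance"):
            ee.morans_i_from_weights(np.full(4, 2.0), W)


class TestBackgroundSampling:
    def test_inside_and_deterministic(self, corridor_grid):
        a = ee.sample_background(corridor_grid, 200, seed=5)
        b = ee.sample_background(corridor_grid, 200, seed=5)
        np.testing.assert_array_equal(a, b)
        for x, y in a:
            r, c = corridor_grid.xy_to_rc(x, y)
            assert corridor_grid.inside_mask[r, c]

    def test_oversampling_warns_and_replaces(self, corridor_grid):
        with pytest.warns(UserWarning, match="with replacement"):
            pts = ee.sample_background(corridor_grid, corridor_grid.n_inside + 100, seed=1)
        assert len(pts) == corridor_grid.n_inside + 100


class TestSplit:
    def test_75_25(self):
        tr, te = ee.split_train_test(np.arange(100), ee.SplitSpec(seed=0))
        assert len(tr) == 75 and len(te) == 25

    def test_minimum_size(self):
        tr, te = ee.split_train_test(np.arange(4), ee.SplitSpec(seed=0))
        assert len(tr) == 3 and len(te) == 1
        with pytest.raises(ValueError, match="too few records"):
            ee.split_train_test(np.arange(3), ee.SplitSpec(seed=0))

    def test_partition_disjoint_exhaustive(self):
        tr, te = ee.split_train_test(np.arange(37), ee.SplitSpec(seed=7))
        assert not set(tr) & set(te)
        assert sorted(np.concatenate([tr, te])) == list(range(37))


def _separable_data(rng, n=60):
    xp = np.column_stack([rng.normal(10, 0.1, n)] * 5)
    xb = np.column_stack([rng.normal(2, 0.1, n)] * 5)
    X = np.vstack([xp, xb])
    y = np.r_[np.ones(n, int), np.zeros(n, int)]
    return X, y


class TestBaseLearners:
    @pytest.mark.parametrize("family", ee.LEARNER_FAMILIES)
    def test_separable_data_perfect_training_auc(self, family):
        rng = np.random.default_rng(0)
        X, y = _separable_data(rng)
        m = ee.fit_base_learner(ee.BaseLearnerSpec(family), X, y, seed=0)
        assert m.training_auc == pytest.approx(1.0)
        s = m.predict(X)
        assert np.all((s >= 0) & (s <= 1))

    @pytest.mark.parametrize("family", ee.LEARNER_FAMILIES)
    def test_deterministic_given_seed(self, family):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 5))
        y = (X[:, 0] + rng.normal(0, 0.5, 80) > 0).astype(int)
        s1 = ee.fit_base_learner(ee.BaseLearnerSpec(family), X, y, seed=9).predict(X)
        s2 = ee.fit_base_learner(ee.BaseLearnerSpec(family), X, y, seed=9).predict(X)
        np.testing.assert_array_equal(s1, s2)

    def test_glm_shuffled_labels_chance_auc(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 5))
            y = rng.permutation(np.r_[np.ones(250, int), np.zeros(250, int)])
            m = ee.fit_base_learner(ee.BaseLearnerSpec("GLM"), X, y, seed=seed)
            aucs.append(m.training_auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_maxent_strong_regularization_collapses_to_prevalence(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3))
        y = (rng.random(200) < 0.3).astype(int)
        spec = ee.BaseLearnerSpec("MAXENT_LIKE", {"C": 1e-8})
        m = ee.fit_base_learner(spec, X, y, seed=0)
        s = m.predict(X)
        assert np.std(s) < 0.01
        assert np.mean(s) == pytest.approx(np.mean(y), abs=0.05)

    def test_degenerate_labels_and_unknown_family(self):
        X = np.zeros((10, 5))
        with pytest.raises(ValueError, match="degenerate labels"):
            ee.fit_base_learner(ee.BaseLearnerSpec("GLM"), X, np.ones(10), seed=0)
        with pytest.raises(ValueError, match="unknown learner"):
            ee.BaseLearnerSpec("RANDOM_FOREST")


class TestAuc:
    def test_examples(self):
        assert ee.compute_auc([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert ee.compute_auc([0.9, 0.8], [0.7, 0.85]) == 0.75  # 3 of 4 concordant
        assert ee.compute_auc([0.5, 0.5], [0.5, 0.5]) == 0.5

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        sp=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=25),
        sb=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=25),
    )
    def test_matches_brute_force_pair_counting(self, sp, sb):
        brute = np.mean(
            [
                1.0 if p > b else (0.5 if p == b else 0.0)
                for p in sp
                for b in sb
            ]
        )
        assert ee.compute_auc(sp, sb) == pytest.approx(brute, abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty class"):
            ee.compute_auc([], [0.5])


class TestKappa:
    def test_perfect_agreement(self):
        assert ee.cohens_kappa([1, 0, 1], [1, 0, 1]) == 1.0

    def test_worked_confusion_matrix(self):
        # TP 40, FP 10, FN 10, TN 40: p_o = 0.8, p_e = 0.5 -> kappa 0.6
        pred = [1] * 40 + [1] * 10 + [0] * 10 + [0] * 40
        truth = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        assert ee.cohens_kappa(pred, truth) == pytest.approx(0.6)

    def test_constant_prediction_is_chance(self):
        assert ee.cohens_kappa([1] * 10, [1] * 7 + [0] * 3) == pytest.approx(0.0)


class TestOmission:
    def test_examples(self):
        assert ee.ten_percentile_omission([0.5, 0.6], [0.7, 0.8]) == 0.0
        train = np.arange(1, 11) / 10  # 10th percentile = 0.19
        assert np.percentile(train, 10) == pytest.approx(0.19)
        assert ee.ten_percentile_omission(train, [0.05, 0.5]) == 0.5

    def test_self_omission_bounded(self):
        rng = np.random.default_rng(0)
        s = rng.random(40)
        assert ee.ten_percentile_omission(s, s) <= 0.10 + 1 / len(s)


class TestEnsemble:
    def test_identical_predictions_unchanged(self):
        models = [
            ee.FittedLearner("GLM", lambda X: np.full(len(X), 0.4), 0.7),
            ee.FittedLearner("CTA", lambda X: np.full(len(X), 0.4), 0.9),
        ]
        ens = ee.build_ensemble(models)
        assert ens.predict(np.zeros((5, 5))) == pytest.approx(np.full(5, 0.4))

    def test_auc_weighted_mean(self):
        models = [
            ee.FittedLearner("GLM", lambda X: np.zeros(len(X)), 0.6),
            ee.FittedLearner("CTA", lambda X: np.ones(len(X)), 0.9),
        ]
        ens = ee.build_ensemble(models)
        assert ens.predict(np.zeros((1, 5)))[0] == pytest.approx(0.9 / 1.5)
        assert ens.weights.sum() == pytest.approx(1.0)

    def test_floor_drops_models(self):
        models = [
            ee.FittedLearner("GLM", lambda X: np.zeros(len(X)), 0.45),
            ee.FittedLearner("CTA", lambda X: np.ones(len(X)), 0.8),
        ]
        ens = ee.build_ensemble(models, auc_floor=0.5)
        assert len(ens.models) == 1 and len(ens.dropped) == 1
        with pytest.raises(ValueError, match="ensemble empty"):
            ee.build_ensemble(models, auc_floor=0.95)


class TestVariableContribution:
    def test_single_feature_model_gets_everything(self):
        ens = ee.build_ensemble(
            [ee.FittedLearner("GLM", lambda X: np.asarray(X)[:, 0], 0.8)]
        )
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        contrib = ee.variable_contribution(ens, X, seed=0, feature_names=list("abc"))
        assert contrib["a"] == pytest.approx(100.0, abs=1e-6)
        assert contrib["b"] == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_two_feature_model(self):
        ens = ee.build_ensemble(
            [ee.FittedLearner("GLM", lambda X: np.asarray(X)[:, :2].mean(axis=1), 0.8)]
        )
        shares = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(500, 2))
            contrib = ee.variable_contribution(ens, X, seed=seed, feature_names=["a", "b"])
            shares.append(contrib["a"])
        assert np.mean(shares) == pytest.approx(50.0, abs=5.0)

    def test_contributions_sum_to_100(self):
        ens = ee.build_ensemble(
            [ee.FittedLearner("GLM", lambda X: np.asarray(X).sum(axis=1), 0.8)]
        )
        X = np.random.default_rng(1).normal(size=(100, 5))
        contrib = ee.variable_contribution(ens, X, seed=1)
        assert sum(contrib.values()) == pytest.approx(100.0)


class TestBinarize:
    def test_tss_threshold_separates_training_data(self, corridor_grid):
        sp = np.array([0.8, 0.9])
        sb = np.array([0.1, 0.2])
        thr = ee.find_threshold(sp, sb, "tss")
        assert 0.2 < thr <= 0.8
        assert np.all(sp >= thr) and np.all(sb < thr)

    def test_binary_values_only(self, corridor_grid):
        field = corridor_grid.empty_field()
        field[corridor_grid.inside_mask] = np.linspace(0, 1, corridor_grid.n_inside)
        bmap = ee.binarize(field, corridor_grid, [0.8, 0.9], [0.1, 0.2])
        vals = bmap.values[corridor_grid.inside_mask]
        assert set(np.unique(vals)) <= {0.0, 1.0}
        assert np.all(np.isnan(bmap.values[~corridor_grid.inside_mask]))
        assert bmap.provenance["threshold"] == bmap.threshold

    def test_methods(self):
        sp, sb = np.array([0.6, 0.7, 0.9]), np.array([0.1, 0.3, 0.5])
        assert ee.find_threshold(sp, sb, "tenth_percentile") == pytest.approx(
            np.percentile(sp, 10)
        )
        with pytest.raises(ValueError, match="unknown binarization"):
            ee.find_threshold(sp, sb, "magic")


class TestSumBinaryMaps:
    def _bmap(self, grid, cells_on):
        v = np.where(grid.inside_mask, 0.0, np.nan)
        for r, c in cells_on:
            v[r, c] = 1.0
        return ee.BinaryMap(grid, v, 0.5, "tss")

    def test_empty_list_zero_map(self, corridor_grid):
        rmap = ee.sum_binary_maps([], corridor_grid)
        assert np.nansum(rmap.values) == 0

    def test_overlap_counts(self, corridor_grid):
        r, c = corridor_grid.xy_to_rc(10.0, 1.0)
        maps = [self._bmap(corridor_grid, [(r, c)]), self._bmap(corridor_grid, [(r, c)])]
        rmap = ee.sum_binary_maps(maps)
        assert rmap.values[r, c] == 2.0
        assert np.nanmax(rmap.values) <= len(maps)
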