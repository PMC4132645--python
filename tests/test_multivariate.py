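"""Linear-SVM inference: design assembly, C search, weight maps."""

import numpy as np
import pytest

import lesionmap as lm
from lesionmap.ground_truth import GroundTruthSpec, LabelVector
from lesionmap.multivariate import (
    build_design,
    c_search,
    compare_localization,
    evaluate_noiseless,
    fit_weight_map,
    threshold_weights_topk,
)

from conftest import masks_from_columns


def _design_from_columns(cols, labels):
    ds = masks_from_columns(np.asarray(cols, dtype=np.uint8))
    return build_design(ds, LabelVector(labels=np.asarray(labels)), min_hits=1)


@pytest.fixture(scope="module")
def toy_design(toy):
    ds, parc = toy
    spec = GroundTruthSpec(kind="area-set", target=(1,), damage_fraction=0.05,
                           deficit_probability=1.0)
    labels = lm.label_area_model(ds, parc, spec)
    return build_design(ds, labels)


class TestBuildDesign:
    def test_row_sums_are_lesion_sizes(self, toy_dataset):
        labels = lm.label_single_voxel(toy_dataset, (2, 6, 6))
        design = build_design(toy_dataset, labels, min_hits=1)
        stack = toy_dataset.stack()
        tested = lm.tested_voxels(toy_dataset, 1)
        expect = stack[:, tested[:, 0], tested[:, 1], tested[:, 2]].sum(axis=1)
        assert np.array_equal(design.X.sum(axis=1), expect)

    def test_column_sums_are_hit_counts(self, toy_dataset):
        labels = lm.label_single_voxel(toy_dataset, (2, 6, 6))
        design = build_design(toy_dataset, labels)
        hits = toy_dataset.hit_count[tuple(design.tested.T)]
        assert np.array_equal(design.X.sum(axis=0), hits)

    def test_identical_masks_identical_rows(self):
        cols = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        design = _design_from_columns(cols, [1, 1, 0])
        assert np.array_equal(design.X[0], design.X[1])

    def test_single_class_target_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            build_design(toy_dataset,
                         LabelVector(labels=np.ones(len(toy_dataset), dtype=int)))


class TestCSearch:
    def test_candidate_count_default_grid(self, toy_design):
        res = c_search(toy_design, n_splits=3, seed=0)
        assert res.table["C"].nunique() == 41
        assert res.exponents == (-20, 20)

    def test_separable_design_reaches_perfect_accuracy(self, toy_design):
        res = c_search(toy_design, c_exponents=(-4, 4), n_splits=5, seed=1)
        assert res.per_c()["accuracy"].max() == pytest.approx(1.0)

    def test_determinism(self, toy_design):
        r1 = c_search(toy_design, c_exponents=(-2, 2), n_splits=4, seed=7)
        r2 = c_search(toy_design, c_exponents=(-2, 2), n_splits=4, seed=7)
        assert r1.chosen_C == r2.chosen_C
        assert r1.table.equals(r2.table)

    def test_chosen_c_in_searched_grid(self, toy_design):
        res = c_search(toy_design, c_exponents=(-3, 3), n_splits=3, seed=2)
        assert res.chosen_C in {2.0 ** e for e in range(-3, 4)}

    def test_degenerate_inputs_rejected(self, toy_design):
        with pytest.raises(ValueError):
            c_search(toy_design, n_splits=1)
        with pytest.raises(ValueError):
            c_search(toy_design, test_size=10**6)


class TestWeightMap:
    def test_informative_column_gets_largest_weight(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 10)
        cols = rng.integers(0, 2, size=(20, 6)).astype(np.uint8)
        cols[:, 2] = y  # one perfectly separating feature
        design = _design_from_columns(cols, y)
        wmap = fit_weight_map(design, C=10.0)
        assert np.argmax(np.abs(wmap.w)) == 2
        assert wmap.w[2] > 0  # positive weight pushes toward 'affected'

    def test_label_flip_negates_weights(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 8)
        cols = rng.integers(0, 2, size=(16, 5)).astype(np.uint8)
        cols[:, 0] = y
        d1 = _design_from_columns(cols, y)
        d2 = _design_from_columns(cols, 1 - y)
        w1 = fit_weight_map(d1, C=1.0)
        w2 = fit_weight_map(d2, C=1.0)
        assert np.allclose(w1.w, -w2.w, atol=1e-6)

    def test_duplicate_subject_leaves_decision_unchanged(self):
        rng = np.random.default_rng(2)
        y = np.array([0, 1] * 8)
        cols = rng.integers(0, 2, size=(16, 5)).astype(np.uint8)
        cols[:, 0] = y
        d1 = _design_from_columns(cols, y)
        dup_cols = np.vstack([cols, cols[:1]])
        d2 = _design_from_columns(dup_cols, np.concatenate([y, y[:1]]))
        w1 = fit_weight_map(d1, C=1000.0)
        w2 = fit_weight_map(d2, C=1000.0)
        scores1 = cols @ w1.w + w1.bias
        scores2 = cols @ w2.w + w2.bias
        assert np.allclose(scores1, scores2, atol=1e-4)

    def test_volume_roundtrip_identity(self, toy_design):
        wmap = fit_weight_map(toy_design, C=1.0)
        back = lm.WeightMap.from_volume(wmap.volume(), wmap.grid, wmap.tested,
                                        wmap.bias, wmap.chosen_C)
        assert np.array_equal(back.w, wmap.w)

    def test_column_permutation_consistency(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 8)
        cols = rng.integers(0, 2, size=(16, 6)).astype(np.uint8)
        cols[:, 1] = y
        d1 = _design_from_columns(cols, y)
        perm = rng.permutation(6)
        d2 = _design_from_columns(cols[:, perm], y)
        w1 = fit_weight_map(d1, C=1.0)
        w2 = fit_weight_map(d2, C=1.0)
        assert np.allclose(w1.w[perm], w2.w, atol=1e-6)
        assert w1.bias == pytest.approx(w2.bias, abs=1e-6)


class TestTopK:
    @pytest.fixture()
    def wmap(self, toy_design):
        return fit_weight_map(toy_design, C=1.0)

    def test_full_and_single(self, wmap):
        assert len(threshold_weights_topk(wmap, len(wmap.w))) == len(wmap.w)
        top1 = threshold_weights_topk(wmap, 1)
        assert tuple(top1[0]) == tuple(wmap.tested[np.argmax(wmap.w)])

    def test_nesting(self, wmap):
        sets = [
            {tuple(v) for v in threshold_weights_topk(wmap, k)}
            for k in (5, 20, 60)
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_out_of_range_rejected(self, wmap):
        with pytest.raises(ValueError):
            threshold_weights_topk(wmap, 0)


class TestEvaluateNoiseless:
    def test_separable_cohort_perfect_scores(self, toy):
        ds, parc = toy
        spec = GroundTruthSpec(kind="area-set", target=(1,), damage_fraction=0.05,
                               deficit_probability=1.0)
        labels = lm.label_area_model(ds, parc, spec)
        design = build_design(ds, labels)
        stats = evaluate_noiseless(design, ds, parc, spec, C=10.0,
                                   n_splits=6, seed=0)
        assert stats.sensitivity_mean == pytest.approx(1.0)
        assert stats.specificity_mean == pytest.approx(1.0)
        assert stats.sensitivity_sd == 0.0 and stats.specificity_sd == 0.0

    def test_subject_order_invariance(self, toy):
        ds, parc = toy
        spec = GroundTruthSpec(kind="area-set", target=(1,), damage_fraction=0.05,
                               deficit_probability=1.0)
        labels = lm.label_area_model(ds, parc, spec)
        design = build_design(ds, labels)
        s1 = evaluate_noiseless(design, ds, parc, spec, C=1.0, n_splits=5, seed=3)
        s2 = evaluate_noiseless(design, ds, parc, spec, C=1.0, n_splits=5, seed=3)
        assert s1.per_split.equals(s2.per_split)


class TestCompareLocalization:
    grid = lm.VoxelGrid(dims=(8, 8, 8))

    def test_identical_sets_dice_one(self):
        truth = np.array([(1, 1, 1), (2, 2, 2)])
        res = compare_localization(truth, truth, truth, self.grid)
        assert res.dice_univariate == 1.0 and res.dice_multivariate == 1.0
        assert np.allclose(res.com_offset_multivariate_mm, 0)

    def test_disjoint_sets_dice_zero(self):
        truth = np.array([(1, 1, 1)])
        other = np.array([(5, 5, 5)])
        res = compare_localization(other, truth, truth, self.grid)
        assert res.dice_univariate == 0.0 and res.dice_multivariate == 1.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            compare_localization(np.array([(1, 1, 1)]), np.array([(1, 1, 1)]),
                                 np.empty((0, 3)), self.grid)


class TestModelInterface:
    def test_fixed_c_skips_search(self, toy_design):
        res = lm.LesionSVM(toy_design).fit(C=1.0)
        assert res.search is None and res.weight_map.chosen_C == 1.0
        assert "linear SVM" in res.summary()

    def test_search_then_fit_deterministic(self, toy_design):
        r1 = lm.LesionSVM(toy_design).fit(seed=5, c_exponents=(-2, 2), n_splits=3)
        r2 = lm.LesionSVM(toy_design).fit(seed=5, c_exponents=(-2, 2), n_splits=3)
        assert r1.weight_map.chosen_C == r2.weight_map.chosen_C
        assert np.array_equal(r1.weight_map.w, r2.weight_map.w)
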