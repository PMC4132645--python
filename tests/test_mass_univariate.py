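"""Fisher exact machinery, thresholding, localization summaries."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import lesionmap as lm
from lesionmap.mass_univariate import (
    ContingencyTable,
    fisher_p_vector,
    significance,
    top_k_voxels,
)
from lesionmap.ground_truth import LabelVector

from conftest import fisher_oracle, masks_from_columns


class TestContingency:
    def _dataset_one_voxel(self, damaged_subjects, n=6):
        cols = np.zeros((n, 1), dtype=np.uint8)
        cols[list(damaged_subjects), 0] = 1
        return masks_from_columns(cols)

    def test_perfect_association(self):
        ds = self._dataset_one_voxel({1, 2})
        labels = LabelVector(labels=np.array([0, 1, 1, 0, 0, 0]))
        t = lm.contingency(ds, labels, (0, 0, 0))
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 4)

    def test_partial_association(self):
        ds = self._dataset_one_voxel({1, 2})
        labels = LabelVector(labels=np.array([0, 0, 0, 1, 0, 0]))
        t = lm.contingency(ds, labels, (0, 0, 0))
        assert (t.a, t.b, t.c, t.d) == (0, 2, 1, 3)

    @given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1))
    def test_margin_identities(self, dam_bits, lab_bits):
        n = 12
        dam = [(dam_bits >> i) & 1 for i in range(n)]
        lab = [(lab_bits >> i) & 1 for i in range(n)]
        ds = self._dataset_one_voxel({i for i in range(n) if dam[i]}, n=n)
        labels = LabelVector(labels=np.array(lab))
        t = lm.contingency(ds, labels, (0, 0, 0))
        assert t.a + t.b == ds.hit_count[0, 0, 0]
        assert t.a + t.c == labels.n_affected
        assert t.n == n

    def test_misaligned_labels_rejected(self):
        ds = self._dataset_one_voxel({0})
        with pytest.raises(ValueError):
            lm.contingency(ds, LabelVector(labels=np.array([1, 0])), (0, 0, 0))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((4, 0, 0, 6), 1 / 210),  # only the observed table is as extreme
            ((1, 1, 1, 1), 1.0),  # no association
            ((3, 0, 0, 5), 1 / 56),
        ],
    )
    def test_frozen_enumeration_values(self, table, expected):
        p = lm.fisher_exact_p(ContingencyTable(*table))
        assert p == pytest.approx(expected, rel=1e-9)
        assert fisher_oracle(*table) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_oracle_small_tables(self):
        for n in range(1, 9):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        got = lm.fisher_exact_p(ContingencyTable(a, b, c, d))
                        want = fisher_oracle(a, b, c, d)
                        assert got == pytest.approx(want, rel=1e-9, abs=1e-15)

    def test_matches_scipy_two_sided(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            ours = lm.fisher_exact_p(ContingencyTable(int(a), int(b), int(c), int(d)))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-7)

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, size=4))
            if a + b + c + d == 0:
                continue
            p1 = lm.fisher_exact_p(ContingencyTable(a, b, c, d))
            p2 = lm.fisher_exact_p(ContingencyTable(b, a, d, c))
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_concordant_table_attains_minimal_p(self):
        # with equal margins m = k, the fully aligned table (b = c = 0) is
        # the most extreme outcome
        for n in range(2, 13):
            for m in range(1, n):
                ps = [
                    lm.fisher_exact_p(
                        ContingencyTable(a, m - a, m - a, n - 2 * m + a)
                    )
                    for a in range(max(0, 2 * m - n), m + 1)
                ]
                assert ps[-1] == pytest.approx(min(ps), rel=1e-12)

    def test_degenerate_margins_return_one(self):
        assert lm.fisher_exact_p(ContingencyTable(0, 0, 3, 5)) == 1.0
        assert lm.fisher_exact_p(ContingencyTable(2, 3, 0, 0)) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    def test_asymptotic_matches_chi2_contingency(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 20, size=4))
            ours = lm.fisher_exact_p(ContingencyTable(a, b, c, d), mode="asymptotic")
            ref = scipy.stats.chi2_contingency([[a, b], [c, d]], correction=False)[1]
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_vectorised_path_equals_scalar_path(self):
        rng = np.random.default_rng(6)
        n, k = 40, 13
        m = rng.integers(0, n + 1, size=30)
        a = np.array([rng.integers(max(0, mv + k - n), min(mv, k) + 1) for mv in m])
        vec = fisher_p_vector(a, m, k, n)
        for i in range(len(m)):
            t = ContingencyTable(int(a[i]), int(m[i] - a[i]), int(k - a[i]),
                                 int(n - m[i] - k + a[i]))
            assert vec[i] == pytest.approx(lm.fisher_exact_p(t), rel=1e-12)


class TestBonferroni:
    def test_printed_scale_example(self):
        # alpha 0.01 over 90469 simultaneous voxel tests
        assert lm.bonferroni_threshold(0.01, 90469) == pytest.approx(1.1054e-7, rel=1e-4)

    def test_single_test_identity(self):
        assert lm.bonferroni_threshold(0.01, 1) == 0.01

    def test_strictly_decreasing_in_n_tests(self):
        ts = [lm.bonferroni_threshold(0.05, n) for n in (1, 2, 10, 1000)]
        assert all(x > y for x, y in zip(ts, ts[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lm.bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            lm.bonferroni_threshold(0.01, 0)


class TestSignificance:
    grid = lm.VoxelGrid(dims=(6, 6, 6))

    def _pmap(self, voxels, ps):
        return lm.PMap(grid=self.grid, voxels=np.array(voxels), p=np.array(ps))

    def test_com_is_midpoint(self):
        pmap = self._pmap([(0, 0, 0), (2, 0, 0), (5, 5, 5)], [1e-6, 1e-6, 0.5])
        res = significance(pmap, 1e-3)
        assert np.allclose(res.com_mm, (2.0, 0.0, 0.0))

    def test_empty_result_flagged(self):
        pmap = self._pmap([(0, 0, 0)], [0.5])
        res = significance(pmap, 1e-3)
        assert res.empty and res.com_mm is None and res.peak_mm is None

    def test_threshold_extremes(self):
        pmap = self._pmap([(0, 0, 0), (1, 1, 1)], [0.2, 0.9])
        assert significance(pmap, 1.0).n_significant == 2
        assert significance(pmap, 0.0).n_significant == 0

    def test_peak_tie_broken_by_com_of_ties(self):
        pmap = self._pmap([(0, 0, 0), (4, 0, 0), (1, 1, 1)], [1e-8, 1e-8, 1e-5])
        res = significance(pmap, 1e-3)
        assert np.allclose(res.peak_mm, (4.0, 0.0, 0.0))

    def test_strict_inequality_at_threshold(self):
        pmap = self._pmap([(0, 0, 0)], [0.01])
        assert significance(pmap, 0.01).empty

    def test_top_k_ordering_and_ties(self):
        pmap = self._pmap([(0, 0, 0), (1, 0, 0), (2, 0, 0)], [0.5, 0.1, 0.1])
        top2 = top_k_voxels(pmap, 2)
        assert [tuple(v) for v in top2] == [(1, 0, 0), (2, 0, 0)]
        with pytest.raises(ValueError):
            top_k_voxels(pmap, 4)


class TestDisplacement:
    def test_three_four_five(self):
        vec, mag = lm.displacement((10, 10, 10), (13, 14, 10))
        assert np.allclose(vec, (3, 4, 0)) and mag == pytest.approx(5.0)

    def test_identity(self):
        vec, mag = lm.displacement((1, 2, 3), (1, 2, 3))
        assert mag == 0.0 and np.allclose(vec, 0)

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=9, max_size=9))
    def test_translation_invariance(self, xs):
        a, b, t = np.array(xs[:3]), np.array(xs[3:6]), np.array(xs[6:])
        _, m1 = lm.displacement(a, b)
        _, m2 = lm.displacement(a + t, b + t)
        assert m1 == pytest.approx(m2, rel=1e-9, abs=1e-9)

    def test_undefined_locus_propagates(self):
        with pytest.raises(ValueError):
            lm.displacement((0, 0, 0), None)


class TestModelInterface:
    def test_pmap_agrees_with_scalar_route(self, toy_dataset):
        labels = lm.label_single_voxel(toy_dataset, (2, 6, 6))
        res = lm.MassUnivariateVLSM(toy_dataset, labels).fit()
        rng = np.random.default_rng(0)
        for i in rng.choice(res.pmap.n_tested, size=20, replace=False):
            t = lm.contingency(toy_dataset, labels, res.pmap.voxels[i])
            assert res.pmap.p[i] == pytest.approx(lm.fisher_exact_p(t), rel=1e-12)
            ref = scipy.stats.fisher_exact([[t.a, t.b], [t.c, t.d]])[1]
            assert res.pmap.p[i] == pytest.approx(ref, rel=1e-7)

    def test_modes_agree_qualitatively_on_toy(self, toy_dataset):
        # the strongly associated voxels are extreme under either test
        labels = lm.label_single_voxel(toy_dataset, (2, 6, 6))
        model = lm.MassUnivariateVLSM(toy_dataset, labels)
        exact = model.fit(mode="exact")
        asym = model.fit(mode="asymptotic")
        thr = lm.bonferroni_threshold(0.01, exact.pmap.n_tested)
        sig_e = {tuple(v) for v in significance(exact.pmap, thr).voxels}
        sig_a = {tuple(v) for v in significance(asym.pmap, thr).voxels}
        assert sig_e and sig_a
        # the exact-mode significant core survives in asymptotic mode
        assert len(sig_e & sig_a) >= 0.8 * len(sig_e)

    def test_summary_mentions_key_quantities(self, toy_dataset):
        labels = lm.label_single_voxel(toy_dataset, (2, 6, 6))
        res = lm.MassUnivariateVLSM(toy_dataset, labels).fit()
        text = res.summary()
        assert "tested voxels" in text and "Bonferroni" in text
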