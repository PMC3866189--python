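from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from braingraph.stats import (
    cohens_d,
    duration_association,
    edgewise_tstats,
    fisher_exact_2x2,
    nbs,
    permutation_test,
    two_sample_t,
)


class TestPermutationTest:
    def test_matches_exhaustive_enumeration(self):
        # oracle: all C(6,3)=20 relabelings of {1..6}; only the observed
        # split and its mirror reach |diff| = 3, so exact p = 2/20 = 0.1
        case, control = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        pooled = case + control
        observed = np.mean(case) - np.mean(control)
        null = []
        for idx in combinations(range(6), 3):
            a = [pooled[i] for i in idx]
            b = [pooled[i] for i in range(6) if i not in idx]
            null.append(np.mean(a) - np.mean(b))
        exact_p = np.mean(np.abs(null) >= abs(observed))
        assert exact_p == pytest.approx(0.1)
        res = permutation_test(case, control, n_perm=20_000, seed=0)
        assert res.p_two_tailed == pytest.approx(exact_p, abs=0.01)

    def test_identical_groups_not_significant(self):
        vals = np.arange(10.0)
        res = permutation_test(vals, vals, n_perm=500, seed=1)
        assert res.observed_diff == 0.0
        assert res.p_two_tailed > 0.5

    def test_label_swap_flips_sign_but_not_p(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
        r1 = permutation_test(a, b, n_perm=2000, seed=3)
        r2 = permutation_test(b, a, n_perm=2000, seed=3)
        assert r1.observed_diff == pytest.approx(-r2.observed_diff)
        assert abs(r1.p_two_tailed - r2.p_two_tailed) < 0.02

    def test_p_never_zero(self):
        res = permutation_test([0.0, 0.1], [100.0, 100.1], n_perm=200, seed=4)
        assert res.p_two_tailed >= 1 / 201

    def test_tiny_n_perm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test([1.0, 2.0], [3.0, 4.0], n_perm=50, seed=0)


class TestCohensD:
    def test_raw_equals_summary_form(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=17), rng.normal(0.5, 1.2, size=15)
        d_raw = cohens_d(a, b).d
        d_sum = cohens_d(
            (a.mean(), a.std(ddof=1), 17), (b.mean(), b.std(ddof=1), 15)
        ).d
        assert d_raw == pytest.approx(d_sum, abs=1e-12)

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=10)
        assert cohens_d(a, b).d == pytest.approx(
            cohens_d(5 * a + 3, 5 * b + 3).d, abs=1e-10
        )

    def test_zero_for_identical_summaries(self):
        assert cohens_d((5.0, 1.0, 10), (5.0, 1.0, 12)).d == 0.0

    def test_magnitude_labels(self):
        assert cohens_d((1.0, 1.0, 10), (0.1, 1.0, 10)).magnitude_label == "large"
        assert cohens_d((0.55, 1.0, 10), (0.0, 1.0, 10)).magnitude_label == "medium"

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d((1.0, 0.0, 5), (2.0, 0.0, 5))


class TestTwoSampleT:
    def test_identical_samples(self):
        x = np.arange(5.0)
        t, p = two_sample_t(x, x)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=14), rng.normal(0.3, 1.0, size=11)
        t, p = two_sample_t(a, b)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)


class TestFisherExact:
    def test_direct_hypergeometric_sum_on_diagonal_table(self):
        # [[5,0],[0,5]]: only the two extreme tables are as unlikely as
        # the observed one, each with probability 1/C(10,5)
        p = fisher_exact_2x2([[5, 0], [0, 5]])
        from math import comb

        assert p == pytest.approx(2 / comb(10, 5), abs=1e-12)
        assert p <= 0.01

    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_2x2([[4, 8], [3, 6]]) == pytest.approx(1.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 6]])


class TestEdgewiseT:
    def test_identical_stacks_give_zero(self):
        rng = np.random.default_rng(8)
        base = rng.random((4, 6, 6))
        stack = 0.5 * (base + base.transpose(0, 2, 1))
        t = edgewise_tstats(stack, stack.copy())
        assert np.abs(t).max() < 1e-8

    def test_single_perturbed_edge_dominates(self):
        rng = np.random.default_rng(9)
        def sym(x):
            s = 0.5 * (x + x.transpose(0, 2, 1))
            for m in s:
                np.fill_diagonal(m, 0)
            return s
        case = sym(rng.normal(0.5, 0.01, size=(8, 10, 10)))
        ctrl = sym(rng.normal(0.5, 0.01, size=(8, 10, 10)))
        case[:, 2, 7] += 1.0
        case[:, 7, 2] += 1.0
        t = edgewise_tstats(case, ctrl)
        i, j = np.unravel_index(np.abs(t).argmax(), t.shape)
        assert {i, j} == {2, 7}

    def test_matches_scalar_t_test_loop(self):
        rng = np.random.default_rng(10)
        def sym(x):
            return 0.5 * (x + x.transpose(0, 2, 1))
        case = sym(rng.normal(size=(6, 5, 5)))
        ctrl = sym(rng.normal(size=(7, 5, 5)))
        t = edgewise_tstats(case, ctrl)
        for i in range(5):
            for j in range(i + 1, 5):
                ref = sps.ttest_ind(
                    case[:, i, j], ctrl[:, i, j], equal_var=True
                ).statistic
                assert t[i, j] == pytest.approx(ref, abs=1e-10)


class TestNBS:
    def _noise_stacks(self, seed, n1=6, n2=6, n=12, scale=0.05):
        rng = np.random.default_rng(seed)
        def draw(k):
            x = rng.normal(0.3, scale, size=(k, n, n))
            x = 0.5 * (x + x.transpose(0, 2, 1))
            for m in x:
                np.fill_diagonal(m, 0)
            return x
        return draw(n1), draw(n2)

    def test_degenerate_threshold_joins_all_edges(self):
        case, ctrl = self._noise_stacks(0)
        res = nbs(case, ctrl, primary_p=1.0, n_perm=50, seed=0)
        n = case.shape[1]
        assert len(res.components) == 1
        assert res.components[0].size == n * (n - 1) // 2

    def test_null_stacks_yield_no_significant_component(self):
        case, ctrl = self._noise_stacks(1)
        res = nbs(case, ctrl, primary_p=0.001, n_perm=200, seed=1)
        assert res.min_corrected_p() > 0.05

    def test_implanted_component_recovered(self):
        case, ctrl = self._noise_stacks(2, n1=10, n2=10)
        implant = [(0, 1), (1, 2), (2, 3), (3, 4)]
        for i, j in implant:
            case[:, i, j] += 0.4
            case[:, j, i] += 0.4
        res = nbs(case, ctrl, primary_p=0.001, n_perm=500, seed=2)
        assert res.components
        top = res.components[0]
        assert top.corrected_p < 0.05
        assert set(map(tuple, top.edges)) >= set(implant)

    def test_empty_suprathreshold_graph_is_not_an_error(self):
        case, ctrl = self._noise_stacks(3)
        res = nbs(case, ctrl, primary_p=1e-12, n_perm=50, seed=3)
        assert res.components == []
        assert res.suprathreshold_edges == []
        assert res.min_corrected_p() == 1.0


class TestDurationAssociation:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(11)
        dur = rng.uniform(1, 19, size=12)
        age = rng.uniform(25, 50, size=12)
        res = duration_association(2 * dur, dur, age)
        assert res.slope == pytest.approx(2.0, abs=1e-10)
        assert res.partial_r == pytest.approx(1.0, abs=1e-6)
        assert res.p_two_tailed < 1e-10

    def test_age_confound_removed(self):
        # value depends only on age; duration slope should be null
        rng = np.random.default_rng(12)
        age = rng.uniform(25, 50, size=40)
        dur = 0.3 * age + rng.uniform(1, 10, size=40)  # correlated with age
        value = 1.5 * age + rng.normal(0, 0.1, size=40)
        res = duration_association(value, dur, age)
        assert abs(res.partial_r) < 0.4
        assert res.p_two_tailed > 0.01

    def test_collinear_covariates_rejected(self):
        dur = np.linspace(1, 19, 10)
        with pytest.raises(ValueError, match="collinear"):
            duration_association(dur, dur, dur * 1.0001 + 0.01)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="four"):
            duration_association([1, 2, 3], [1, 2, 3], [4, 5, 6])
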