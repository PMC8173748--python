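"""Group-comparison and ROC machinery tests.

Oracles: exhaustive enumeration (rank-sum permutations, hypergeometric
tables, pair counting), an independent library AUC (scikit-learn),
bootstrap simulation for the paired DeLong test, and the Hanley-McNeil
closed-form AUC variance approximation.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from dwiresponse import (
    bonferroni_alpha,
    categorical_test,
    compare_groups,
    delong_compare,
    normality_screen,
    roc,
)
from dwiresponse.exceptions import (
    InsufficientDataError,
    PairingError,
    UndefinedRocError,
    UndefinedTableError,
    UnsupportedSampleError,
)
from dwiresponse.stats import pair_counting_auc, trapezoidal_auc


class TestNormalityScreen:
    def test_constant_sample_flagged_non_normal(self):
        assert normality_screen([2.0] * 10) == 0.0

    def test_sample_size_limits(self):
        with pytest.raises(UnsupportedSampleError):
            normality_screen([1.0, 2.0])

    def test_p_uniform_under_normal_null(self):
        # calibration: Shapiro-Wilk p-values on normal samples are uniform
        rng = np.random.default_rng(101)
        ps = [normality_screen(rng.normal(size=100)) for _ in range(1000)]
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_power_against_exponential(self):
        rng = np.random.default_rng(102)
        rejections = sum(
            normality_screen(rng.exponential(size=200)) < 0.05
            for _ in range(200)
        )
        assert rejections / 200 > 0.95


class TestCompareGroups:
    def test_identical_samples_t_branch(self):
        res = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.test == "t"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_forced_wilcoxon_matches_exhaustive_permutation(self):
        # all 20 arrangements of ranks for n = (3, 3) as the exact null
        a = [1.0, 2.0, 3.0]
        b = [11.0, 12.0, 13.0]
        res = compare_groups(a, b, force="wilcoxon")
        pooled = a + b
        observed = sum(pooled.index(v) + 1 for v in a)  # rank sum of group a
        null = [sum(c) for c in itertools.combinations(range(1, 7), 3)]
        lo = sum(s <= observed for s in null) / len(null)
        hi = sum(s >= observed for s in null) / len(null)
        exact_p = min(1.0, 2 * min(lo, hi))
        assert res.test == "wilcoxon"
        assert res.p_value == pytest.approx(exact_p)

    def test_power_on_separated_group_means(self):
        # two normal groups with a ~1.3 SD mean gap at n = (37, 64)
        rng = np.random.default_rng(103)
        hits = 0
        for _ in range(200):
            a = rng.normal(0.50, 0.26, 37)
            b = rng.normal(0.19, 0.22, 64)
            if compare_groups(a, b).p_value < 0.001:
                hits += 1
        assert hits / 200 > 0.99

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(104)
        n_sim = 10_000
        rejections = 0
        for _ in range(n_sim):
            if compare_groups(rng.normal(size=30), rng.normal(size=30)).p_value < 0.05:
                rejections += 1
        assert 0.04 <= rejections / n_sim <= 0.06

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0], [1.0, 2.0])


class TestCategoricalTest:
    def test_er_table_highly_significant(self):
        res = categorical_test([[35, 19], [18, 72]])
        assert res.test == "chi-square"
        assert res.p_value < 0.001

    def test_perfect_independence(self):
        res = categorical_test([[10, 10], [10, 10]])
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = np.array([[2, 8], [7, 3]])
        res = categorical_test(table)
        assert res.test == "fisher"  # min expected count 4.5 < 5
        # enumerate all tables with the observed margins
        r1, r2 = table.sum(axis=1)
        c1 = table[:, 0].sum()
        n = table.sum()
        p_obs = sps.hypergeom.pmf(table[0, 0], n, r1, c1)
        p_exact = sum(
            sps.hypergeom.pmf(k, n, r1, c1)
            for k in range(max(0, c1 - r2), min(r1, c1) + 1)
            if sps.hypergeom.pmf(k, n, r1, c1) <= p_obs * (1 + 1e-9)
        )
        assert res.p_value == pytest.approx(p_exact)

    def test_zero_margin_rejected(self):
        with pytest.raises(UndefinedTableError):
            categorical_test([[0, 0], [3, 4]])


class TestBonferroni:
    @pytest.mark.parametrize(
        "m, display", [(21, 0.0024), (6, 0.0083), (1, 0.05)]
    )
    def test_adjusted_levels(self, m, display):
        adj = bonferroni_alpha(0.05, m)
        assert adj.display == display
        assert adj.exact == pytest.approx(0.05 / m)


class TestRoc:
    def test_perfect_separation(self):
        res = roc([3.0, 4.0, 1.0, 2.0], [True, True, False, False])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 2.0 <= res.threshold < 3.0

    def test_pair_counting_example(self):
        # 3 of 4 (positive, negative) pairs concordant
        values = [0.9, 0.4, 0.6, 0.2]
        labels = [True, True, False, False]
        res = roc(values, labels)
        assert res.auc == pytest.approx(0.75)

    def test_trapezoid_equals_pair_counting_with_ties(self, rng):
        for _ in range(50):
            n = rng.integers(4, 40)
            values = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            t = trapezoidal_auc(values, labels)
            p = pair_counting_auc(values, labels)
            assert t == pytest.approx(p, abs=1e-12)
            assert t == pytest.approx(roc_auc_score(labels, values), abs=1e-12)

    def test_label_flip_maps_auc(self, rng):
        values = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        labels[0], labels[1] = True, False
        a = trapezoidal_auc(values, labels)
        b = trapezoidal_auc(values, ~labels)
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedRocError):
            roc([1.0, 2.0], [True, True])

    def test_orientation_auto_keeps_auc_above_half(self, rng):
        values = rng.normal(size=80)
        labels = np.r_[np.ones(30, bool), np.zeros(50, bool)]
        values[labels] -= 1.0  # smaller value predicts positive
        res = roc(values, labels)
        assert res.orientation == "less"
        assert res.auc >= 0.5

    def test_youden_threshold_and_rates(self):
        values = [1, 2, 3, 4, 5, 6]
        labels = [False, False, True, False, True, True]
        res = roc(values, labels)
        # J maximal (sens 1, spec 2/3) at threshold 2 under rule "> t"
        assert res.threshold == 2
        assert res.sensitivity == pytest.approx(1.0)
        assert res.specificity == pytest.approx(2 / 3)

    def test_delong_variance_approaches_hanley_mcneil(self, rng):
        pos = rng.normal(1.0, 1.0, 500)
        neg = rng.normal(0.0, 1.0, 500)
        values = np.r_[pos, neg]
        labels = np.r_[np.ones(500, bool), np.zeros(500, bool)]
        res = roc(values, labels)
        a = res.auc
        m = n = 500
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        hm = (a * (1 - a) + (m - 1) * (q1 - a * a) + (n - 1) * (q2 - a * a)) / (m * n)
        assert res.variance == pytest.approx(hm, rel=0.10)

    def test_ci_contains_auc_and_is_clipped(self, rng):
        values = rng.normal(size=40)
        labels = np.r_[np.ones(15, bool), np.zeros(25, bool)]
        res = roc(values, labels)
        assert res.ci[0] <= res.auc <= res.ci[1]
        assert 0.0 <= res.ci[0] and res.ci[1] <= 1.0


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    values=st.lists(st.integers(-1000, 1000), min_size=4, max_size=25),
    n_pos=st.integers(1, 10),
    shift=st.floats(-10, 10),
)
def test_auc_invariant_under_increasing_transform(values, n_pos, shift):
    values = np.asarray(values, dtype=float)
    n_pos = min(n_pos, len(values) - 1)
    labels = np.zeros(len(values), bool)
    labels[:n_pos] = True
    before = trapezoidal_auc(values, labels)
    after = trapezoidal_auc(np.exp(values / 300.0) + shift, labels)
    assert before == pytest.approx(after, abs=1e-9)


class TestDelongCompare:
    def test_identical_scores(self):
        scores = [0.1, 0.9, 0.4, 0.7, 0.2, 0.8]
        labels = [False, True, False, True, False, True]
        assert delong_compare(scores, scores, labels) == 1.0

    def test_monotone_transform_has_equal_auc(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(15, bool), np.zeros(25, bool)]
        p = delong_compare(scores, np.exp(scores), labels)
        assert p == pytest.approx(1.0)

    def test_against_bootstrap_oracle(self):
        # small paired dataset; a label-preserving (stratified) bootstrap
        # of the AUC difference estimates its sampling variance, and the
        # resulting normal p must agree with the DeLong p
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0], bool)
        a = np.array([0.9, 0.8, 0.35, 0.6, 0.52, 0.4, 0.45, 0.2, 0.55, 0.3, 0.1, 0.42])
        b = np.array([0.7, 0.9, 0.3, 0.4, 0.65, 0.6, 0.3, 0.25, 0.5, 0.2, 0.15, 0.48])
        p = delong_compare(a, b, labels)

        rng = np.random.default_rng(7)
        pos_idx = np.nonzero(labels)[0]
        neg_idx = np.nonzero(~labels)[0]
        B = 100_000
        pos_draw = rng.choice(pos_idx, size=(B, pos_idx.size))
        neg_draw = rng.choice(neg_idx, size=(B, neg_idx.size))

        def auc_batch(scores):
            p_s = scores[pos_draw][:, :, None]
            n_s = scores[neg_draw][:, None, :]
            return ((p_s > n_s) + 0.5 * (p_s == n_s)).mean(axis=(1, 2))

        def auc_obs(scores):
            p_s = scores[labels][:, None]
            n_s = scores[~labels][None, :]
            return ((p_s > n_s) + 0.5 * (p_s == n_s)).mean()

        diff = auc_batch(a) - auc_batch(b)
        diff_obs = auc_obs(a) - auc_obs(b)
        p_boot = 2 * sps.norm.sf(abs(diff_obs) / diff.std(ddof=1))
        assert p == pytest.approx(p_boot, abs=0.02)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(PairingError):
            delong_compare([1, 2, 3], [1, 2], [True, False, True])
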