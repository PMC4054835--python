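"""The shrinkage-entropy MI machinery against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scquant.mide import (
    BinSpec,
    ContingencyTable,
    contingency,
    de_scan,
    entropy,
    fd_binspec,
    js_shrink,
    mutual_information,
    wilcoxon_rank,
)


def oracle_lambda(counts):
    """Brute-force shrinkage intensity, coded independently of js_shrink."""
    counts = [float(c) for c in counts]
    n = sum(counts)
    theta = [c / n for c in counts]
    t = 1.0 / len(counts)
    num = 1.0 - sum(th * th for th in theta)
    den = (n - 1.0) * sum((t - th) ** 2 for th in theta)
    if den == 0:
        return 1.0
    return min(max(num / den, 0.0), 1.0)


def oracle_mi_bits(joint):
    """MI from explicit marginal/joint entropy sums (base 2)."""
    joint = np.asarray(joint, dtype=float)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)

    def h(p):
        return -sum(v * math.log2(v) for v in np.ravel(p) if v > 0)

    return h(px) + h(py) - h(joint)


class TestFdBinspec:
    def test_textbook_case(self):
        spec = fd_binspec(np.arange(1, 9))
        assert spec.K == 2
        np.testing.assert_allclose(spec.bin_edges, [1, 4.5, 8])

    def test_zero_range_single_bin(self):
        spec = fd_binspec([3.0, 3.0, 3.0])
        assert spec.K == 1
        assert spec.bin_edges[0] <= 3.0 <= spec.bin_edges[-1]

    def test_zero_iqr_fallback(self):
        # IQR 0 but nonzero range -> ceil(log2 n) + 1 bins
        values = [5.0] * 14 + [0.0, 10.0]
        spec = fd_binspec(values)
        assert spec.K == math.ceil(math.log2(16)) + 1

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            fd_binspec([1.0])


class TestContingency:
    def test_two_bin_split(self):
        spec = BinSpec(np.array([0.0, 5.0, 10.0]))
        table = contingency([0, 0, 10, 10], ["A", "A", "B", "B"], spec)
        np.testing.assert_array_equal(table.counts, [[2, 0], [0, 2]])
        assert table.n == 4

    def test_single_state_single_column(self):
        spec = BinSpec(np.array([0.0, 5.0, 10.0]))
        table = contingency([1, 2, 8], ["A", "A", "A"], spec)
        assert table.counts.shape == (2, 1)
        assert table.counts.sum() == 3

    def test_out_of_range_value_raises(self):
        spec = BinSpec(np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="outside"):
            contingency([2.0], ["A"], spec)


class TestJsShrink:
    @pytest.mark.parametrize(
        "counts, expect_lambda, expect_probs",
        [
            ([3, 1], 1.0, [0.5, 0.5]),
            ([8, 2], 0.32 / 1.62, [0.32 / 1.62 * 0.5 + (1 - 0.32 / 1.62) * 0.8,
                                   0.32 / 1.62 * 0.5 + (1 - 0.32 / 1.62) * 0.2]),
        ],
    )
    def test_hand_derived_intensities(self, counts, expect_lambda, expect_probs):
        table = ContingencyTable(np.array([counts]), (0,), (0, 1))
        dist = js_shrink(table)
        assert dist.lambda_star == pytest.approx(expect_lambda, abs=1e-12)
        np.testing.assert_allclose(dist.probabilities.ravel(), expect_probs, atol=1e-12)

    def test_uniform_counts_fixed_point(self):
        table = ContingencyTable(np.full((2, 2), 5), (0, 1), ("a", "b"))
        dist = js_shrink(table)
        np.testing.assert_allclose(dist.probabilities, 0.25, atol=1e-15)

    def test_matches_oracle_on_random_tables(self):
        """lambda* equals the independently coded formula to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = rng.integers(2, 9)
            counts = rng.integers(0, 20, size=k)
            if counts.sum() == 0:
                counts[0] = 1
            table = ContingencyTable(counts[None, :], (0,), tuple(range(k)))
            dist = js_shrink(table)
            assert dist.lambda_star == pytest.approx(oracle_lambda(counts), abs=1e-12)

    def test_small_sample_mse_improvement(self):
        """Shrunk frequencies beat ML in MSE on K=8 multinomials at n=10."""
        rng = np.random.default_rng(5)
        p_true = rng.dirichlet(np.ones(8))
        mse_ml = mse_js = 0.0
        reps = 2000
        for _ in range(reps):
            counts = rng.multinomial(10, p_true)
            theta = counts / 10
            dist = js_shrink(ContingencyTable(counts[None, :], (0,), tuple(range(8))))
            mse_ml += np.sum((theta - p_true) ** 2)
            mse_js += np.sum((dist.probabilities.ravel() - p_true) ** 2)
        assert mse_js <= mse_ml


class TestEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.5, 0.5], 1.0),
            ([1.0, 0.0], 0.0),
            ([0.75, 0.25], -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))),
        ],
    )
    def test_known_values(self, p, expected):
        assert entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            entropy([-0.1, 1.1])


class TestMutualInformation:
    def test_diagonal_table_one_bit(self):
        table = ContingencyTable(np.array([[5, 0], [0, 5]]), (0, 1), ("a", "b"))
        assert mutual_information(table, shrink=False).mi_bits == pytest.approx(1.0)

    def test_outer_product_independence_zero(self):
        for counts in ([[4, 4], [4, 4]], [[6, 2], [3, 1]]):
            table = ContingencyTable(np.array(counts), (0, 1), ("a", "b"))
            assert mutual_information(table, shrink=False).mi_bits == pytest.approx(0.0, abs=1e-12)
            assert mutual_information(table, shrink=True).mi_bits >= 0.0

    def test_hand_derived_skew_table(self):
        table = ContingencyTable(np.array([[4, 1], [1, 4]]), (0, 1), ("a", "b"))
        assert mutual_information(table, shrink=False).mi_bits == pytest.approx(
            2.0 - 1.7219280948873623, abs=1e-10
        )

    def test_single_cell_degenerate(self):
        table = ContingencyTable(np.array([[7]]), (0,), ("a",))
        res = mutual_information(table)
        assert res.degenerate and res.mi_bits == 0.0

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(0, 30), min_size=4, max_size=12).filter(lambda c: sum(c) >= 2)
    )
    def test_mi_laws_on_random_tables(self, flat):
        """Nonnegative, exactly symmetric under transposition, <= min marginal
        entropy, and matches the explicit entropy-sum oracle."""
        rows = 2
        cols = len(flat) // rows
        counts = np.array(flat[: rows * cols]).reshape(rows, cols)
        if counts.sum() < 2:
            counts[0, 0] += 2
        table = ContingencyTable(counts, tuple(range(rows)), tuple(range(cols)))
        for shrink in (False, True):
            res = mutual_information(table, shrink=shrink)
            res_t = mutual_information(table.transpose(), shrink=shrink)
            assert res.mi_bits >= 0.0
            assert res.mi_bits == res_t.mi_bits  # exact symmetry
            assert res.mi_bits <= min(res.h_x, res.h_y) + 1e-12
        ml = mutual_information(table, shrink=False)
        assert ml.mi_bits == pytest.approx(oracle_mi_bits(counts / counts.sum()), abs=1e-10)

    def test_shrink_converges_to_ml_at_large_n(self):
        """|MI_shrink - MI_ML| -> 0 as n grows (fixed proportions, n = 1e4)."""
        base = np.array([[4, 1], [1, 4]])
        table = ContingencyTable(base * 1000, (0, 1), ("a", "b"))
        on = mutual_information(table, shrink=True).mi_bits
        off = mutual_information(table, shrink=False).mi_bits
        assert abs(on - off) < 0.01


class TestWilcoxon:
    def test_exact_enumeration_example(self):
        # all C(6,3)=20 rank splits; the observed split is one of 2 extremes
        assert wilcoxon_rank([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert wilcoxon_rank([1.0, 2.0], [1.0, 2.0]) == 1.0
        assert wilcoxon_rank([3.0, 3.0], [3.0, 3.0]) == 1.0

    def test_exact_and_approximate_agree(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            exact = wilcoxon_rank(a, b)
            approx = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(exact - approx) < 0.02


class TestDeScan:
    def test_constant_gene_untested(self, two_type_experiment):
        truth, matrix, annotation = two_type_experiment
        values = matrix.values.copy()
        values.iloc[0, :] = 5.0  # constant across all samples
        from scquant.iohub import ExpressionMatrix

        de = de_scan(ExpressionMatrix(values), annotation, ("ES", "PrE"))
        row = de.iloc[0]
        assert not row["tested"] and np.isnan(row["mi_bits"])

    def test_missing_state_raises(self, two_type_experiment):
        _, matrix, annotation = two_type_experiment
        with pytest.raises(ValueError):
            de_scan(matrix, annotation, ("ES", "NoSuchType"))

    def test_planted_de_ranked_by_mi(self, two_type_experiment):
        """MI ranking separates strong planted effects from nulls."""
        from sklearn.metrics import roc_auc_score

        truth, matrix, annotation = two_type_experiment
        de = de_scan(matrix, annotation, ("ES", "PrE"))
        de = de[de["tested"] & de["gene_id"].str.startswith("gene_")].set_index("gene_id")
        labels = truth.gene_table.loc[de.index]
        strong = labels["log2_fold_change"].abs() >= 2
        keep = strong | ~labels["de_flag"]
        auroc = roc_auc_score(strong[keep], de.loc[keep.index[keep], "mi_bits"])
        assert auroc >= 0.85  # small fixture; the full-size design is checked elsewhere

    def test_bh_q_at_least_p(self, two_type_experiment):
        _, matrix, annotation = two_type_experiment
        de = de_scan(matrix, annotation, ("ES", "PrE"))
        tested = de[de["tested"]]
        assert (tested["q"] >= tested["p"] - 1e-12).all()
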