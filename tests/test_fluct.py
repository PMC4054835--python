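"""Fluctuation analysis: dispersion measures and F-test wiring."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from scquant.fluct import (
    cv_concordance,
    f_test_two_sided,
    fluctuation_reproducibility,
    fluctuation_vs_error,
    per_gene_dispersion,
)
from scquant.iohub import ExpressionMatrix
from scquant.synthdata import (
    DesignRow,
    GeneratorConfig,
    NoiseParams,
    make_truth,
    simulate_experiment,
)


def matrix_from(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
        )
    )


def oracle_f_cdf(f, d1, d2):
    """F CDF via the regularized incomplete beta function, coded directly."""
    x = d1 * f / (d1 * f + d2)
    return special.betainc(d1 / 2.0, d2 / 2.0, x)


class TestDispersion:
    def test_constant_gene_zero(self):
        m = matrix_from([[5.0, 5.0, 5.0]])
        assert per_gene_dispersion(m, m.sample_ids, "sd_log10").iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert per_gene_dispersion(m, m.sample_ids, "cv_linear").iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_cv_of_one_three(self):
        m = matrix_from([[1.0, 3.0]])
        cv = per_gene_dispersion(m, m.sample_ids, "cv_linear").iloc[0]
        assert cv == pytest.approx(np.sqrt(2) / 2)

    def test_cv_scale_invariant(self):
        rng = np.random.default_rng(0)
        arr = rng.gamma(3, 2, size=(20, 5))
        m1, m2 = matrix_from(arr), matrix_from(10 * arr)
        pd.testing.assert_series_equal(
            per_gene_dispersion(m1, m1.sample_ids, "cv_linear"),
            per_gene_dispersion(m2, m2.sample_ids, "cv_linear"),
        )

    def test_zero_mean_cv_undefined(self):
        m = matrix_from([[0.0, 0.0]])
        assert np.isnan(per_gene_dispersion(m, m.sample_ids, "cv_linear").iloc[0])

    def test_single_sample_group_rejected(self):
        m = matrix_from([[1.0, 2.0]])
        with pytest.raises(ValueError):
            per_gene_dispersion(m, ["s0"], "sd_log10")


class TestFluctuationReproducibility:
    def test_self_comparison(self):
        rng = np.random.default_rng(1)
        m = matrix_from(rng.gamma(2, 5, size=(50, 6)))
        pcc, table = fluctuation_reproducibility(m, m)
        assert pcc == pytest.approx(1.0)
        assert np.allclose(table["f_statistic"].dropna(), 1.0)
        assert np.allclose(table["p_two_sided"].dropna(), 1.0)
        assert table["reproducible_flag"].all()

    def test_f_p_matches_incomplete_beta_oracle(self):
        """Two-sided variance-ratio p agrees with a direct incomplete-beta
        evaluation to 1e-10 (variances 4 vs 1, n = 13 vs 13)."""
        f_stat, p = f_test_two_sided(4.0, 1.0, 13, 13)
        assert f_stat == 4.0
        cdf = oracle_f_cdf(4.0, 12, 12)
        expected = 2.0 * min(cdf, 1.0 - cdf)
        assert p == pytest.approx(expected, abs=1e-10)

    def test_null_type_one_error_calibrated(self):
        """Under equal variances (5,000 genes, n = 12 vs 8) the two-sided
        p < 0.05 rate sits within 3 binomial SEs of 0.05."""
        rng = np.random.default_rng(2)
        n_genes = 5000
        a = matrix_from(rng.lognormal(1.0, 0.5, size=(n_genes, 12)), prefix="a")
        b = matrix_from(rng.lognormal(1.0, 0.5, size=(n_genes, 8)), prefix="b")
        # pseudo_count 0: log-expression is exactly normal, so F calibration
        # is exact rather than approximate
        _, table = fluctuation_reproducibility(a, b, pseudo_count=0.0)
        rate = float((table["p_two_sided"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(rate - 0.05) < 3 * se

    def test_zero_variance_handling(self):
        a = matrix_from([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        b = matrix_from([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        _, table = fluctuation_reproducibility(a, b)
        assert table.iloc[0]["degenerate"] and table.iloc[0]["reproducible_flag"]
        assert not table.iloc[1]["reproducible_flag"]  # dispersion only in set a

    def test_reproducible_fraction_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        a = matrix_from(rng.lognormal(1, 0.5, size=(800, 10)), prefix="a")
        b = matrix_from(rng.lognormal(1, 0.5, size=(800, 10)), prefix="b")
        _, t_low = fluctuation_reproducibility(a, b, q_threshold=0.6)
        _, t_high = fluctuation_reproducibility(a, b, q_threshold=0.9)
        assert t_low["reproducible_flag"].sum() >= t_high["reproducible_flag"].sum()


class TestFluctuationVsError:
    def simulate_pair(self, sigma_bio, n_single=40, n_pooled=20, seed=5):
        config = GeneratorConfig(
            n_genes=200, n_de_up=0, n_de_down=0, dropout=False,
            sigma_bio_range=(sigma_bio, sigma_bio), noise=NoiseParams(sigma_tech=0.1),
        )
        truth = make_truth(config, seed=seed)
        matrix, ann = simulate_experiment(
            truth,
            [
                DesignRow("ES", "G1", "single_cell", n_single),
                DesignRow("ES", "G1", "pooled_equivalent", n_pooled),
            ],
            seed=seed + 1,
        )
        singles = matrix.subset_samples(ann.samples_where(sample_class="single_cell"))
        pooled = matrix.subset_samples(ann.samples_where(sample_class="pooled_equivalent"))
        return singles, pooled

    def test_identical_groups_p_half(self):
        rng = np.random.default_rng(6)
        m = matrix_from(rng.lognormal(1, 0.3, size=(30, 8)))
        pvals, _ = fluctuation_vs_error(m, m)
        assert np.allclose(pvals.dropna(), 0.5)

    def test_biological_fluctuation_detected(self):
        singles, pooled = self.simulate_pair(sigma_bio=0.4)
        genes = [g for g in singles.gene_ids if g.startswith("gene_")]
        pvals, n_sig = fluctuation_vs_error(
            ExpressionMatrix(singles.values.loc[genes]),
            ExpressionMatrix(pooled.values.loc[genes]),
        )
        assert pvals.median() < 0.001
        assert n_sig > 100

    def test_median_p_decreases_with_sigma_bio(self):
        medians = []
        for sigma in (0.0, 0.2, 0.5):
            singles, pooled = self.simulate_pair(sigma_bio=sigma)
            genes = [g for g in singles.gene_ids if g.startswith("gene_")]
            pvals, _ = fluctuation_vs_error(
                ExpressionMatrix(singles.values.loc[genes]),
                ExpressionMatrix(pooled.values.loc[genes]),
            )
            medians.append(float(pvals.median()))
        assert medians[0] > medians[1] > medians[2]

    def test_one_and_two_sided_consistency(self):
        """p_two = 2.min(p_one, 1 - p_one) for the same F."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            va, vb = rng.chisquare(5) / 5, rng.chisquare(7) / 7
            n_a, n_b = 9, 13
            _, p_two = f_test_two_sided(va, vb, n_a, n_b)
            p_one = float(stats.f(n_a - 1, n_b - 1).sf(va / vb))
            assert p_two == pytest.approx(2 * min(p_one, 1 - p_one), abs=1e-12)


class TestCvConcordance:
    def test_identical_vectors(self):
        cv = pd.Series([0.1, 0.5, 0.9, 0.3])
        assert cv_concordance(cv, cv) == pytest.approx(1.0)

    def test_anti_ordered_vectors(self):
        assert cv_concordance(pd.Series([1.0, 2.0, 3.0]),
                              pd.Series([3.0, 2.0, 1.0])) == pytest.approx(-1.0)

    def test_shared_truth_platforms_concordant(self):
        """Two platforms measuring the same per-gene biological fluctuation
        yield highly correlated CVs when the fluctuation spread dominates."""
        config = GeneratorConfig(
            n_genes=150, n_de_up=0, n_de_down=0, dropout=False,
            sigma_bio_range=(0.05, 0.6), noise=NoiseParams(sigma_tech=0.05),
        )
        truth = make_truth(config, seed=8)
        cvs = []
        for seed in (100, 200):  # independent measurements, shared truth
            matrix, ann = simulate_experiment(
                truth, [DesignRow("ES", "G1", "single_cell", 60)], seed=seed
            )
            genes = [g for g in matrix.gene_ids if g.startswith("gene_")]
            sub = ExpressionMatrix(matrix.values.loc[genes])
            cvs.append(per_gene_dispersion(sub, sub.sample_ids, "sd_log10"))
        assert cv_concordance(cvs[0], cvs[1]) >= 0.9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cv_concordance(pd.Series([1.0, 1.0, 1.0]), pd.Series([1.0, 2.0, 3.0]))
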