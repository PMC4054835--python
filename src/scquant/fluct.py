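"""Gene-expression fluctuation analysis.

Cell-to-cell variability of a gene mixes biological fluctuation with
measurement error. Two complementary questions are answered here:

* Is a gene's fluctuation *reproducible*? Compare its variance across two
  independently processed single-cell sets with a two-sided F-test; genes
  whose Benjamini-Hochberg-adjusted p exceeds a threshold (default 0.6)
  show no evidence of differing dispersion between the sets and are called
  reproducibly fluctuating.
* Is the fluctuation *biological*? Compare single-cell variance against the
  variance of pooled-equivalent samples (single-cell-sized aliquots of a
  pooled lysate, which carry experimental error only) with a one-sided
  F-test of var_single > var_pooled.

Dispersions are computed on log10(value + pseudo_count) with the n-1
denominator; the coefficient of variation (SD/mean on the linear scale) is
the scale-free alternative used for cross-platform concordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iohub import ExpressionMatrix


def per_gene_dispersion(
    matrix: ExpressionMatrix,
    samples: list[str],
    measure: str = "sd_log10",
    pseudo_count: float = 1.0,
) -> pd.Series:
    """Per-gene dispersion over a sample group.

    ``sd_log10``: sample SD (ddof=1) of log10(value + pseudo_count).
    ``cv_linear``: sample SD / mean on the linear scale; NaN where the mean
    is 0 (undefined).
    """
    if len(samples) < 2:
        raise ValueError(f"dispersion needs >= 2 samples, got {len(samples)}")
    data = matrix.values[samples].to_numpy(dtype=float)
    if measure == "sd_log10":
        out = np.log10(data + pseudo_count).std(axis=1, ddof=1)
    elif measure == "cv_linear":
        mean = data.mean(axis=1)
        sd = data.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(mean > 0, sd / mean, np.nan)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return pd.Series(out, index=matrix.values.index, name=measure)


def f_test_two_sided(var_a: float, var_b: float, n_a: int, n_b: int) -> tuple[float, float]:
    """Variance-ratio F statistic and two-sided p with (n_a-1, n_b-1) df.

    p = 2.min(P(F <= f), P(F >= f)), capped at 1.
    """
    f = var_a / var_b
    dist = stats.f(n_a - 1, n_b - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def fluctuation_reproducibility(
    set_a: ExpressionMatrix,
    set_b: ExpressionMatrix,
    q_threshold: float = 0.6,
    pseudo_count: float = 1.0,
) -> tuple[float, pd.DataFrame]:
    """Per-gene F-test of dispersion equality between two independent
    single-cell sets.

    Returns (Pearson correlation of the two per-gene SD vectors, table with
    columns ``gene_id, sd_set_a, sd_set_b, f_statistic, p_two_sided, q_bh,
    reproducible_flag, degenerate``). A gene with zero variance in both
    sets has an undefined F and is flagged degenerate-reproducible
    (identical dispersion); zero variance in exactly one set is called
    non-reproducible.
    """
    if not set_a.values.index.equals(set_b.values.index):
        raise ValueError("the two sets must share the same gene list")
    n_a, n_b = set_a.shape[1], set_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("both sets need >= 2 samples")
    log_a = np.log10(set_a.values.to_numpy(dtype=float) + pseudo_count)
    log_b = np.log10(set_b.values.to_numpy(dtype=float) + pseudo_count)
    var_a = log_a.var(axis=1, ddof=1)
    var_b = log_b.var(axis=1, ddof=1)
    sd_a, sd_b = np.sqrt(var_a), np.sqrt(var_b)

    both_zero = (var_a == 0) & (var_b == 0)
    one_zero = ((var_a == 0) | (var_b == 0)) & ~both_zero

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = var_a / var_b
    dist = stats.f(n_a - 1, n_b - 1)
    p = np.full(len(f_stat), np.nan)
    ok = ~both_zero & ~one_zero
    p[ok] = 2.0 * np.minimum(dist.cdf(f_stat[ok]), dist.sf(f_stat[ok]))
    p[ok] = np.minimum(p[ok], 1.0)
    p[one_zero] = 0.0  # infinitely discrepant dispersion

    q = np.full(len(p), np.nan)
    testable = ~both_zero
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]
    reproducible = np.where(both_zero, True, q > q_threshold)

    table = pd.DataFrame(
        {
            "gene_id": set_a.values.index,
            "sd_set_a": sd_a,
            "sd_set_b": sd_b,
            "f_statistic": f_stat,
            "p_two_sided": p,
            "q_bh": q,
            "reproducible_flag": reproducible.astype(bool),
            "degenerate": both_zero,
        }
    ).set_index("gene_id", drop=False)

    if np.ptp(sd_a) == 0 or np.ptp(sd_b) == 0:
        pcc = float("nan")
    else:
        pcc = float(stats.pearsonr(sd_a, sd_b).statistic)
    return pcc, table


def fluctuation_vs_error(
    single_cells: ExpressionMatrix,
    pooled: ExpressionMatrix,
    pseudo_count: float = 1.0,
    alpha: float = 0.05,
) -> tuple[pd.Series, int]:
    """One-sided per-gene F-test of var(single cells) > var(pooled).

    Returns (per-gene one-sided p-values, number of genes significant at
    ``alpha`` after Benjamini-Hochberg). Genes with zero variance in both
    groups get p = NaN.
    """
    if not single_cells.values.index.equals(pooled.values.index):
        raise ValueError("matrices must share the same gene list")
    n_s, n_p = single_cells.shape[1], pooled.shape[1]
    if n_s < 2 or n_p < 2:
        raise ValueError("both groups need >= 2 samples")
    log_s = np.log10(single_cells.values.to_numpy(dtype=float) + pseudo_count)
    log_p = np.log10(pooled.values.to_numpy(dtype=float) + pseudo_count)
    var_s = log_s.var(axis=1, ddof=1)
    var_p = log_p.var(axis=1, ddof=1)
    both_zero = (var_s == 0) & (var_p == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = var_s / var_p
    p = np.full(len(f_stat), np.nan)
    dist = stats.f(n_s - 1, n_p - 1)
    ok = ~both_zero & (var_p > 0)
    p[ok] = dist.sf(f_stat[ok])
    p[(var_p == 0) & ~both_zero] = 0.0
    pvals = pd.Series(p, index=single_cells.values.index, name="p_one_sided")
    testable = ~np.isnan(p)
    n_sig = 0
    if testable.any():
        q = multipletests(p[testable], method="fdr_bh")[1]
        n_sig = int((q < alpha).sum())
    return pvals, n_sig


def cv_concordance(cv_platform_1: pd.Series, cv_platform_2: pd.Series) -> float:
    """Pearson correlation between two platforms' per-gene CV vectors."""
    a = np.asarray(cv_platform_1, dtype=float)
    b = np.asarray(cv_platform_2, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("CV vectors must share a gene list of >= 3 genes")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("fewer than 3 genes with defined CV in both platforms")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a CV vector; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)
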