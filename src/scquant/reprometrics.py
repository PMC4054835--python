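"""Reproducibility and sensitivity metrics between expression profiles.

Two technical replicates of the same RNA pool should agree: the headline
summaries are (i) the Pearson correlation of log10-transformed expression,
(ii) the count of transcripts detected above a unit-scale threshold in both
profiles, and of those, the fraction whose linear-scale fold change stays
under a threshold ("reproducible"), and (iii) detection-vs-depth curves
obtained by downsampling read counts. Preset detection thresholds follow
the field's conventions: FPKM > 1.0, tpm > 1.0, RMA (log2) > 7.0, with
"less than two-fold change" as the default reproducibility rule; both
inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .iohub import ExpressionMatrix

#: Detection thresholds per unit scale (value must be strictly greater).
DETECTION_PRESETS = {"FPKM": 1.0, "tpm": 1.0, "RMA_log2": 7.0}


@dataclass(frozen=True)
class ReproReport:
    n_detected: int
    n_reproducible: int
    pcc: float
    slope: float
    intercept: float
    parameters: dict

    @property
    def fraction_reproducible(self) -> float:
        return self.n_reproducible / self.n_detected if self.n_detected else 0.0


def log_pcc(
    profile_a,
    profile_b,
    pseudo_count: float = 1.0,
) -> tuple[float, float, float]:
    """Pearson correlation and least-squares line of log10(x + pseudo)
    pairs.

    Returns (pcc, slope, intercept) of the regression of log(b) on log(a).
    Zero variance in either transformed vector is an undefined correlation
    and raises.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("expression values must be nonnegative")
    la = np.log10(a + pseudo_count)
    lb = np.log10(b + pseudo_count)
    if np.ptp(la) == 0 or np.ptp(lb) == 0:
        raise ValueError("zero variance after log transform; correlation undefined")
    res = stats.linregress(la, lb)
    return float(res.rvalue), float(res.slope), float(res.intercept)


def count_reproducible(
    profile_a,
    profile_b,
    min_expr: float | None = None,
    fold_threshold: float = 2.0,
    unit: str = "FPKM",
    pseudo_count: float = 1.0,
) -> ReproReport:
    """Count transcripts detected in both profiles and, of those, the ones
    with a fold change strictly below ``fold_threshold``.

    Detection = value strictly greater than ``min_expr`` in BOTH profiles
    (preset per unit when ``min_expr`` is None). The fold ratio is computed
    on the linear scale; RMA log2 values are exponentiated first.
    """
    if fold_threshold <= 1:
        raise ValueError(f"fold_threshold must exceed 1, got {fold_threshold}")
    if min_expr is None:
        if unit not in DETECTION_PRESETS:
            raise ValueError(f"no detection preset for unit {unit!r}; pass min_expr")
        min_expr = DETECTION_PRESETS[unit]
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal gene sets")
    detected = (a > min_expr) & (b > min_expr)
    if unit == "RMA_log2":
        lin_a, lin_b = 2.0**a, 2.0**b
    else:
        lin_a, lin_b = a, b
    hi = np.maximum(lin_a, lin_b)
    lo = np.minimum(lin_a, lin_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / lo, np.inf)
    reproducible = detected & (ratio < fold_threshold)
    n_det = int(detected.sum())
    if n_det >= 3 and np.ptp(np.log10(a + pseudo_count)) > 0 and np.ptp(
        np.log10(b + pseudo_count)
    ) > 0:
        pcc, slope, intercept = log_pcc(a, b, pseudo_count)
    else:
        pcc = slope = intercept = float("nan")
    return ReproReport(
        n_detected=n_det,
        n_reproducible=int(reproducible.sum()),
        pcc=pcc,
        slope=slope,
        intercept=intercept,
        parameters={
            "min_expr": float(min_expr),
            "fold_threshold": float(fold_threshold),
            "pseudo_count": float(pseudo_count),
            "unit": unit,
        },
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean of order statistics.

    After normalization each sample's sorted values equal the mean sorted
    vector; within-sample ranks are preserved, ties receive the average of
    the reference values over the tied ranks, and the operation is
    idempotent.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, arr.shape[0] + 1), reference)
    normalized = pd.DataFrame(out, index=values.index, columns=values.columns)
    return ExpressionMatrix(normalized, unit=matrix.unit, gene_meta=matrix.gene_meta)


def downsample_detection(
    counts,
    depths,
    seed: int,
    gene_lengths=None,
    min_fpkm: float = 1.0,
    min_count: int = 1,
    mode: str = "multinomial",
    pseudo_count: float = 1.0,
) -> pd.DataFrame:
    """Detection and correlation versus sequencing depth for one sample.

    Reads are drawn per target depth by multinomial sampling with
    probabilities proportional to ``counts`` (or exhaustively, without
    replacement, when ``mode='hypergeometric'`` — the depth = total case
    then reproduces the counts exactly). When ``gene_lengths`` (bp) is
    supplied, FPKM is recomputed at each depth and detection is
    FPKM > ``min_fpkm``; otherwise detection is count >= ``min_count``.
    The PCC column correlates each depth's log profile with the full-depth
    profile.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be a 1-d array of nonnegative integers")
    total = int(counts.sum())
    if total < 1:
        raise ValueError("counts sum to zero")
    depths = [int(d) for d in depths]
    if any(d > total for d in depths):
        too_big = [d for d in depths if d > total]
        raise ValueError(f"depths exceed total counts {total}: {too_big} (no upsampling)")
    if any(d < 1 for d in depths):
        raise ValueError("depths must be >= 1")
    if mode not in ("multinomial", "hypergeometric"):
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    probs = counts / total

    def profile(c, depth):
        if gene_lengths is not None:
            return c / (np.asarray(gene_lengths) / 1e3) / (depth / 1e6)
        return c.astype(float)

    full = profile(counts, total)
    rows = []
    for depth in depths:
        if mode == "multinomial":
            draw = rng.multinomial(depth, probs)
        else:
            draw = rng.multivariate_hypergeometric(counts, depth)
        prof = profile(draw, depth)
        if gene_lengths is not None:
            detected = int((prof > min_fpkm).sum())
        else:
            detected = int((draw >= min_count).sum())
        pcc, _, _ = log_pcc(prof, full, pseudo_count=pseudo_count)
        rows.append({"depth": depth, "n_detected": detected, "pcc_vs_full": pcc})
    return pd.DataFrame(rows)


def expected_detected_multinomial(counts, depth: int, min_count: int = 1) -> float:
    """Closed-form expected number of detected genes under multinomial
    downsampling with a min-count rule of 1: sum over genes of
    1 - (1 - p_g)^depth.

    Only ``min_count`` = 1 has this simple closed form; it serves as the
    analytic reference for the Monte-Carlo detection curve.
    """
    if min_count != 1:
        raise NotImplementedError("closed form implemented for min_count=1 only")
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    return float(np.sum(1.0 - (1.0 - p) ** depth))
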