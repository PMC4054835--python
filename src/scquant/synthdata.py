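"""Synthetic single-cell experiments with known ground truth.

The generator emulates the statistical structure a poly-A-tailing WTA
single-cell RNA-seq study produces, so that every downstream analysis in
this package can be scored against a planted truth:

* two cell types (ES-like and PrE-like) with differentially expressed
  marker genes at configurable log2 fold changes;
* three cell-cycle phases (G1/S/G2M) shifting expression per gene;
* per-gene biological fluctuation as a lognormal deviation on the log10
  scale, on top of lognormal technical measurement noise;
* dropout that is logistic in log expression, GC fraction and transcript
  length (low-expressed, GC-rich, short transcripts drop out more — the
  bias directions amplification-based protocols show);
* spike-in transcripts at fixed copy numbers per cell equivalent
  (Lys 1000, Dap 100, Phe 20, Thr 5 by default) carrying technical noise
  only;
* pooled-equivalent ("single-cell-sized aliquot of a pooled lysate")
  samples whose per-gene profile is the population mean, so their spread
  across replicates measures experimental error only; and
* FASTQ reads with the WTA suppression-primer adaptor planted at an exact
  rate, as a test bed for adaptor-contamination scanning.

Everything is deterministic given (config, seed); per-sample random streams
are spawned from the master seed so that adding samples to a design never
perturbs the values of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .iohub import ExpressionMatrix, ReadRecord, SampleAnnotation

#: WTA suppression-primer sequence whose carry-over into sequencing reads is
#: the adaptor contamination the scanner looks for.
SUPPRESSION_PRIMER = "GTATAGAATTCGCGGCCGCTCGCGAT"

#: Spike-in transcripts at copies per single-cell RNA equivalent (10 pg).
DEFAULT_SPIKE_COPIES = {"Lys": 1000, "Dap": 100, "Phe": 20, "Thr": 5}

DEFAULT_CELL_TYPES = ("ES", "PrE")
PHASES = ("G1", "S", "G2M")

IUPAC_CODES = set("ACGTRYSWKMBDHVN")

LOG10_2 = math.log10(2.0)


@dataclass
class NoiseParams:
    """Technical noise and dropout parameters.

    sigma_tech is the SD of the lognormal measurement error on the log10
    scale (a free parameter of the generator, not an estimate of any
    protocol's noise). The dropout probability of a gene with expected
    log10 expression e, GC fraction g and transcript length L bp is
    sigmoid(intercept - slope_expression.e + slope_gc.(g - 0.5)
    - slope_length.(log10 L - 3.25)); positive slopes make dropout monotone
    increasing in GC and decreasing in expression and length.
    """

    sigma_tech: float = 0.2
    dropout_intercept: float = -1.0
    dropout_slope_expression: float = 1.0
    dropout_slope_gc: float = 4.0
    dropout_slope_length: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_tech < 0:
            raise ValueError(f"sigma_tech must be >= 0, got {self.sigma_tech}")


@dataclass
class GeneratorConfig:
    """Settings for :func:`make_truth`.

    DE genes are split between up- and down-regulated (in the second cell
    type relative to the first); |log2FC| is drawn uniformly from
    ``lfc_range``. Per-gene biological fluctuation SDs (log10 scale) are
    uniform over ``sigma_bio_range``; setting both ends to 0 switches
    biological variability off. ``dropout`` toggles the dropout layer.
    """

    n_genes: int = 2000
    n_de_up: int = 100
    n_de_down: int = 100
    lfc_range: tuple[float, float] = (1.0, 4.0)
    baseline_mean: float = 1.0
    baseline_sd: float = 0.5
    sigma_bio_range: tuple[float, float] = (0.1, 0.5)
    cycle_sd: float = 0.1
    cell_types: tuple[str, str] = DEFAULT_CELL_TYPES
    noise: NoiseParams = field(default_factory=NoiseParams)
    dropout: bool = True
    spike_copies: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SPIKE_COPIES))
    adaptor_rate: float = 0.0768

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_de_up < 0 or self.n_de_down < 0:
            raise ValueError("n_de_up and n_de_down must be >= 0")
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise ValueError(
                f"DE gene count {self.n_de_up + self.n_de_down} exceeds n_genes {self.n_genes}"
            )
        if any(s < 0 for s in self.sigma_bio_range):
            raise ValueError(f"sigma_bio_range must be >= 0, got {self.sigma_bio_range}")
        if not 0.0 <= self.adaptor_rate <= 1.0:
            raise ValueError(f"adaptor_rate must be in [0, 1], got {self.adaptor_rate}")


@dataclass
class SyntheticTruth:
    """Generative ground truth for one synthetic experiment.

    gene_table columns: gene_id, transcript_length, gc_fraction, one
    ``mu_<cell type>`` baseline (log10 mean) per cell type, de_flag,
    log2_fold_change, sigma_bio, and one ``cycle_<phase>`` shift per phase.
    """

    gene_table: pd.DataFrame
    noise_params: NoiseParams
    spike_copies: dict[str, int]
    adaptor_rate: float
    seed: int
    cell_types: tuple[str, str]
    dropout: bool = True

    def __post_init__(self) -> None:
        gt = self.gene_table
        if (gt["sigma_bio"] < 0).any():
            raise ValueError("sigma_bio contains negative values")
        if ((gt["gc_fraction"] < 0) | (gt["gc_fraction"] > 1)).any():
            raise ValueError("gc_fraction outside [0, 1]")
        if (gt["transcript_length"] < 1).any():
            raise ValueError("transcript_length must be >= 1")
        mism = gt["de_flag"] != (gt["log2_fold_change"] != 0)
        if mism.any():
            raise ValueError("de_flag must be true exactly when log2_fold_change != 0")


def make_truth(config: GeneratorConfig, seed: int) -> SyntheticTruth:
    """Draw a fully populated :class:`SyntheticTruth`, deterministic in
    (config, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = config.n_genes
    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    lengths = np.round(10 ** rng.normal(3.25, 0.25, size=n)).astype(int)
    lengths = np.maximum(lengths, 200)
    gc = np.clip(rng.normal(0.5, 0.06, size=n), 0.25, 0.75)
    mu_a = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    sigma_bio = rng.uniform(*config.sigma_bio_range, size=n)
    cycle_s = rng.normal(0.0, config.cycle_sd, size=n)
    cycle_g2m = rng.normal(0.0, config.cycle_sd, size=n)

    lfc = np.zeros(n)
    n_de = config.n_de_up + config.n_de_down
    de_idx = rng.choice(n, size=n_de, replace=False)
    magnitudes = rng.uniform(*config.lfc_range, size=n_de)
    signs = np.concatenate(
        [np.ones(config.n_de_up), -np.ones(config.n_de_down)]
    )
    lfc[de_idx] = signs * magnitudes

    type_a, type_b = config.cell_types
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "transcript_length": lengths,
            "gc_fraction": gc,
            f"mu_{type_a}": mu_a,
            f"mu_{type_b}": mu_a + lfc * LOG10_2,
            "de_flag": lfc != 0,
            "log2_fold_change": lfc,
            "sigma_bio": sigma_bio,
            "cycle_G1": np.zeros(n),
            "cycle_S": cycle_s,
            "cycle_G2M": cycle_g2m,
        }
    ).set_index("gene_id", drop=False)
    return SyntheticTruth(
        gene_table=table,
        noise_params=config.noise,
        spike_copies=dict(config.spike_copies),
        adaptor_rate=config.adaptor_rate,
        seed=int(seed),
        cell_types=config.cell_types,
        dropout=config.dropout,
    )


@dataclass(frozen=True)
class DesignRow:
    """One block of samples: n samples of a cell type / phase / class."""

    cell_type: str
    phase: str
    sample_class: str
    n: int
    batch: str = "batch1"


def _dropout_probability(truth: SyntheticTruth, expected_log10: np.ndarray) -> np.ndarray:
    np_ = truth.noise_params
    gt = truth.gene_table
    z = (
        np_.dropout_intercept
        - np_.dropout_slope_expression * expected_log10
        + np_.dropout_slope_gc * (gt["gc_fraction"].to_numpy() - 0.5)
        - np_.dropout_slope_length * (np.log10(gt["transcript_length"].to_numpy()) - 3.25)
    )
    return 1.0 / (1.0 + np.exp(-z))


def expected_log10_expression(truth: SyntheticTruth, cell_type: str, phase: str) -> np.ndarray:
    """Per-gene expected log10 expression for a (cell type, phase) condition."""
    gt = truth.gene_table
    col = f"mu_{cell_type}"
    if col not in gt.columns:
        raise ValueError(f"unknown cell type {cell_type!r}")
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    return gt[col].to_numpy() + gt[f"cycle_{phase}"].to_numpy()


def simulate_experiment(
    truth: SyntheticTruth,
    design: Sequence[DesignRow],
    seed: int,
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Simulate an expression matrix plus annotation for a sample design.

    Single cells draw a per-gene biological deviation ~ N(0, sigma_bio) on
    the log10 scale around the condition mean, then lognormal technical
    noise, then dropout. Pooled-equivalent and bulk-reference samples use
    the condition-mean profile with technical noise only (no biological
    deviation, no dropout). Spike transcripts are appended at their
    configured copy numbers with technical noise only.

    Deterministic given (truth, design, seed); the random stream of sample i
    in the flattened design depends only on (seed, i), so appending design
    rows never changes existing samples.
    """
    if not design:
        raise ValueError("design must be non-empty")
    gt = truth.gene_table
    sigma_bio = gt["sigma_bio"].to_numpy()
    sigma_tech = truth.noise_params.sigma_tech
    n_genes = len(gt)
    spike_ids = [f"SPIKE_{name}" for name in truth.spike_copies]
    spike_copies = np.array(list(truth.spike_copies.values()), dtype=float)

    columns: dict[str, np.ndarray] = {}
    annot_rows = []
    sample_index = 0
    per_type_counter: dict[tuple, int] = {}
    for row in design:
        expected = expected_log10_expression(truth, row.cell_type, row.phase)
        if row.sample_class not in ("single_cell", "pooled_equivalent", "bulk_reference"):
            raise ValueError(f"unknown sample_class {row.sample_class!r}")
        for _ in range(row.n):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(sample_index,))
            )
            log_mu = expected.copy()
            if row.sample_class == "single_cell":
                log_mu = log_mu + rng.normal(0.0, 1.0, size=n_genes) * sigma_bio
            value = 10.0 ** (log_mu + rng.normal(0.0, sigma_tech, size=n_genes))
            if truth.dropout and row.sample_class == "single_cell":
                p_drop = _dropout_probability(truth, log_mu)
                value = np.where(rng.random(n_genes) < p_drop, 0.0, value)
            spikes = spike_copies * 10.0 ** rng.normal(0.0, sigma_tech, size=len(spike_copies))
            key = (row.cell_type, row.phase, row.sample_class, row.batch)
            per_type_counter[key] = per_type_counter.get(key, 0) + 1
            short = {"single_cell": "sc", "pooled_equivalent": "pool", "bulk_reference": "bulk"}[
                row.sample_class
            ]
            sample_id = (
                f"{row.cell_type}_{row.phase}_{short}_{row.batch}_{per_type_counter[key]:03d}"
            )
            columns[sample_id] = np.concatenate([value, spikes])
            annot_rows.append(
                {
                    "sample_id": sample_id,
                    "cell_type": row.cell_type,
                    "cycle_phase": row.phase,
                    "sample_class": row.sample_class,
                    "batch": row.batch,
                }
            )
            sample_index += 1

    index = list(gt["gene_id"]) + spike_ids
    values = pd.DataFrame(columns, index=index)
    gene_meta = pd.DataFrame(
        {
            "transcript_length": np.concatenate(
                [gt["transcript_length"].to_numpy(), np.full(len(spike_ids), 1000)]
            ),
            "gc_fraction": np.concatenate(
                [gt["gc_fraction"].to_numpy(), np.full(len(spike_ids), 0.5)]
            ),
        },
        index=index,
    )
    matrix = ExpressionMatrix(values, unit="FPKM", gene_meta=gene_meta)
    annotation = SampleAnnotation(pd.DataFrame(annot_rows))
    return matrix, annotation


# ---------------------------------------------------------------------------
# Read simulation

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_reads(
    n_reads: int,
    read_length: int = 50,
    adaptor: str = SUPPRESSION_PRIMER,
    adaptor_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
    quality: int = 30,
) -> Iterator[ReadRecord]:
    """Yield reads with the adaptor planted in exactly
    round(n_reads x adaptor_rate) of them.

    Planted reads carry the adaptor (forward or reverse complement, uniform
    position, optional per-base substitution error) inside an otherwise
    random read. Background reads are uniform random bases, resampled in the
    (rare) event that a random read would itself pass the default adaptor
    similarity scan — the planted count is the exact number of
    adaptor-bearing reads, which is the generator's contract.
    """
    from .seqqc import _read_hits_adaptor  # local import to avoid a cycle

    if not 0.0 <= adaptor_rate <= 1.0:
        raise ValueError(f"adaptor_rate must be in [0, 1], got {adaptor_rate}")
    bad = set(adaptor.upper()) - IUPAC_CODES
    if bad:
        raise ValueError(f"adaptor contains non-IUPAC characters: {sorted(bad)}")
    adaptor = adaptor.upper()
    if read_length < len(adaptor):
        raise ValueError(
            f"read_length {read_length} shorter than adaptor length {len(adaptor)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_planted = round(n_reads * adaptor_rate)
    planted_mask = np.zeros(n_reads, dtype=bool)
    if n_planted:
        planted_mask[rng.choice(n_reads, size=n_planted, replace=False)] = True
    bases = np.array(list("ACGT"))
    qual_str = chr(quality + 33) * read_length

    for i in range(n_reads):
        if planted_mask[i]:
            read = rng.choice(bases, size=read_length)
            insert = adaptor if rng.random() < 0.5 else reverse_complement(adaptor)
            insert_arr = np.array(list(insert))
            if error_rate > 0:
                err = rng.random(len(insert_arr)) < error_rate
                if err.any():
                    insert_arr = insert_arr.copy()
                    insert_arr[err] = bases[
                        (
                            np.searchsorted(bases, insert_arr[err])
                            + rng.integers(1, 4, size=int(err.sum()))
                        )
                        % 4
                    ]
            start = int(rng.integers(0, read_length - len(insert) + 1))
            read[start : start + len(insert)] = insert_arr
            seq = "".join(read)
        else:
            while True:
                seq = "".join(rng.choice(bases, size=read_length))
                if not _read_hits_adaptor(seq, adaptor):
                    break
        yield ReadRecord(read_id=f"read_{i:07d}", bases=seq, qualities=qual_str)
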