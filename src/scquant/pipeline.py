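"""Config-driven end-to-end orchestration.

One ``run(config)`` call simulates a synthetic experiment and pushes it
through every enabled analysis stage — technical-replicate reproducibility,
detection-vs-depth downsampling, MI differential expression, fluctuation
analysis, sequence QC, and sample-structure analysis — writing intermediate
TSV/FASTQ files and a single versioned JSON report under the output
directory. A master seed is split into fixed per-stage streams, so toggling
one stage never perturbs another's randomness and a rerun with the same
config and seed reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import fluct, mide, reprometrics, seqqc, structure, synthdata
from .iohub import write_annotation, write_fastq, write_matrix
from .synthdata import DesignRow, GeneratorConfig, SUPPRESSION_PRIMER

logger = logging.getLogger("scquant.pipeline")

REPORT_SCHEMA_VERSION = 1

STAGES = ("simulate", "repro", "downsample", "mide", "fluct", "seqqc", "structure")
# fixed stage -> seed-stream index, independent of which stages are enabled
_STAGE_STREAM = {name: i for i, name in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    """Validated settings for :func:`run`."""

    out_dir: str = "scquant_out"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {name: True for name in STAGES}
    )
    n_genes: int = 2000
    n_de_up: int = 100
    n_de_down: int = 100
    n_cells_per_type: int = 12
    n_fluct_set_a: int = 12
    n_fluct_set_b: int = 8
    n_pooled: int = 8
    n_reads: int = 2000
    read_length: int = 50
    adaptor: str = SUPPRESSION_PRIMER
    min_expr: float = 1.0
    fold_threshold: float = 2.0
    q_threshold_fluct: float = 0.6
    de_q_alpha: float = 0.05
    downsample_depths: tuple[int, ...] = (1_000, 5_000, 20_000, 50_000)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        for name in STAGES:
            self.stages.setdefault(name, True)
        if not self.stages["simulate"]:
            raise ValueError("the simulate stage is required; all others consume its output")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "downsample_depths" in raw:
            raw["downsample_depths"] = tuple(int(d) for d in raw["downsample_depths"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        return out


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(_STAGE_STREAM[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def run(config: PipelineConfig) -> dict:
    """Execute all enabled stages in dependency order and return the report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "INCOMPLETE"
    marker.write_text("pipeline in progress\n")

    # hash the scientific settings only: where the output lands is not part
    # of the analysis identity
    config_dict = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    config_json = json.dumps(config_dict, sort_keys=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "stages": {},
    }

    current = "simulate"
    try:
        # ------------------------------------------------------------------
        logger.info("stage simulate")
        gen_config = GeneratorConfig(
            n_genes=config.n_genes,
            n_de_up=config.n_de_up,
            n_de_down=config.n_de_down,
        )
        truth = synthdata.make_truth(gen_config, seed=_stage_seed(config, "simulate"))
        n = config.n_cells_per_type
        design = [
            DesignRow("ES", "G1", "single_cell", config.n_fluct_set_a, batch="set1"),
            DesignRow("ES", "G1", "single_cell", config.n_fluct_set_b, batch="set2"),
            DesignRow("PrE", "G1", "single_cell", n, batch="set1"),
            DesignRow("ES", "G1", "pooled_equivalent", config.n_pooled, batch="pool"),
        ]
        matrix, annotation = synthdata.simulate_experiment(
            truth, design, seed=_stage_seed(config, "simulate")
        )
        write_matrix(matrix, out_dir / "expression.tsv")
        write_annotation(annotation, out_dir / "annotation.tsv")
        truth.gene_table.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        report["stages"]["simulate"] = {
            "n_genes": config.n_genes,
            "n_samples": matrix.shape[1],
            "n_de_planted": int(truth.gene_table["de_flag"].sum()),
        }

        es_set1 = annotation.samples_where(cell_type="ES", batch="set1",
                                           sample_class="single_cell")
        es_set2 = annotation.samples_where(cell_type="ES", batch="set2",
                                           sample_class="single_cell")
        pooled_ids = annotation.samples_where(sample_class="pooled_equivalent")

        # ------------------------------------------------------------------
        if config.stages["repro"]:
            current = "repro"
            logger.info("stage repro")
            a = matrix.values[pooled_ids[0]].to_numpy()
            b = matrix.values[pooled_ids[1]].to_numpy()
            rep = reprometrics.count_reproducible(
                a, b, min_expr=config.min_expr, fold_threshold=config.fold_threshold
            )
            report["stages"]["repro"] = {
                "n_detected": rep.n_detected,
                "n_reproducible": rep.n_reproducible,
                "fraction_reproducible": rep.fraction_reproducible,
                "pcc_log10": rep.pcc,
                "parameters": rep.parameters,
            }

        # ------------------------------------------------------------------
        if config.stages["downsample"]:
            current = "downsample"
            logger.info("stage downsample")
            rng = np.random.default_rng(_stage_seed(config, "downsample"))
            expr = matrix.values[es_set1[0]].to_numpy()
            probs = expr / expr.sum()
            total = max(config.downsample_depths)
            counts = rng.multinomial(total, probs)
            curve = reprometrics.downsample_detection(
                counts,
                depths=list(config.downsample_depths),
                seed=_stage_seed(config, "downsample"),
            )
            curve.to_csv(out_dir / "downsample.tsv", sep="\t", index=False)
            report["stages"]["downsample"] = {
                "depths": list(map(int, curve["depth"])),
                "n_detected": list(map(int, curve["n_detected"])),
                "pcc_vs_full": [round(float(x), 6) for x in curve["pcc_vs_full"]],
            }

        # ------------------------------------------------------------------
        if config.stages["mide"]:
            current = "mide"
            logger.info("stage mide")
            de = mide.de_scan(matrix, annotation, ("ES", "PrE"))
            de.to_csv(out_dir / "de.tsv", sep="\t", index=False)
            tested = de[de["tested"]]
            called = tested[tested["q"] < config.de_q_alpha]
            report["stages"]["mide"] = {
                "n_tested": int(len(tested)),
                "n_de_q_lt_alpha": int(len(called)),
                "n_up": int((called["direction"] > 0).sum()),
                "n_down": int((called["direction"] < 0).sum()),
                "median_mi_bits": round(float(tested["mi_bits"].median()), 6),
            }

        # ------------------------------------------------------------------
        if config.stages["fluct"]:
            current = "fluct"
            logger.info("stage fluct")
            pcc_sds, table = fluct.fluctuation_reproducibility(
                matrix.subset_samples(es_set1),
                matrix.subset_samples(es_set2),
                q_threshold=config.q_threshold_fluct,
            )
            table.to_csv(out_dir / "fluct.tsv", sep="\t", index=False)
            pvals, n_sig = fluct.fluctuation_vs_error(
                matrix.subset_samples(es_set1 + es_set2),
                matrix.subset_samples(pooled_ids),
            )
            report["stages"]["fluct"] = {
                "pcc_of_sds": round(float(pcc_sds), 6),
                "n_reproducible": int(table["reproducible_flag"].sum()),
                "n_genes": int(len(table)),
                "n_fluct_gt_error_bh": n_sig,
            }

        # ------------------------------------------------------------------
        if config.stages["seqqc"]:
            current = "seqqc"
            logger.info("stage seqqc")
            reads = list(
                synthdata.simulate_reads(
                    n_reads=config.n_reads,
                    read_length=config.read_length,
                    adaptor=config.adaptor,
                    adaptor_rate=truth.adaptor_rate,
                    seed=_stage_seed(config, "seqqc"),
                )
            )
            write_fastq(reads, out_dir / "reads.fastq")
            scan = seqqc.adaptor_scan(reads, adaptor=config.adaptor)
            detected = (matrix.values[es_set1] > config.min_expr).any(axis=1)
            profile = seqqc.gc_length_profile(matrix.gene_meta, detected.to_numpy())
            report["stages"]["seqqc"] = {
                "adaptor_rate_planted": truth.adaptor_rate,
                "adaptor_fraction_observed": round(scan.fraction_hits, 6),
                "n_reads": scan.n_reads,
                "gc_length_profile": {
                    k: (round(v, 6) if isinstance(v, float) else v)
                    for k, v in profile.items()
                },
            }

        # ------------------------------------------------------------------
        if config.stages["structure"]:
            current = "structure"
            logger.info("stage structure")
            singles = annotation.samples_where(sample_class="single_cell")
            sub = matrix.subset_samples(singles)
            scores, loadings, var_frac = structure.pca_embed(sub, n_components=3)
            scores.to_csv(out_dir / "pca_scores.tsv", sep="\t")
            newick = structure.ward_cluster(sub)
            (out_dir / "ward.nwk").write_text(newick + "\n")
            universe = set(truth.gene_table["gene_id"])
            gene_sets = {
                "planted_up": set(
                    truth.gene_table.loc[truth.gene_table["log2_fold_change"] > 0, "gene_id"]
                ),
                "planted_down": set(
                    truth.gene_table.loc[truth.gene_table["log2_fold_change"] < 0, "gene_id"]
                ),
            }
            selected = structure.top_loading_genes(loadings, "PC1", m=200) & universe
            records = structure.ora_hypergeom(selected, gene_sets, universe)
            clusters = structure.cut_two_clusters(sub)
            report["stages"]["structure"] = {
                "variance_explained": [round(float(v), 6) for v in var_frac],
                "ora_pc1": {
                    r.set_name: {"overlap": r.overlap, "p": float(f"{r.p_hyper:.6g}")}
                    for r in records
                },
                "two_cluster_sizes": sorted(
                    int(np.sum(np.array(list(clusters.values())) == c)) for c in (1, 2)
                ),
            }
    except Exception as exc:
        raise StageError(f"stage {current!r} failed: {exc}") from exc

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    marker.unlink()
    return report
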