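# scquant

A quantification toolkit for benchmarking single-cell RNA-seq protocols and
analyzing the data they produce. It is aimed at method developers and
analysts who need to answer, with numbers: how reproducible is an
amplification-based protocol; which genes are differentially expressed
between two cell states when only a dozen cells per state are available;
which gene-expression fluctuations are biological rather than technical;
and how contaminated are the reads with whole-transcript-amplification
(WTA) adaptor sequence.

Every analysis is paired with a synthetic-data generator that plants a
known ground truth (DE labels, fold changes, per-gene fluctuation SDs,
dropout biases, adaptor contamination rate), so the entire pipeline is
testable end-to-end without any external dataset.

## What it computes

**Reproducibility and sensitivity** (`scquant.reprometrics`). For two
expression profiles: the Pearson correlation of log10(FPKM + c); the number
of transcripts detected above a unit-scale threshold in both profiles
(FPKM > 1, tpm > 1, or RMA > 7); and of those, the fraction with less than
two-fold change — the "reproducible" fraction. Plus quantile normalization
and multinomial read-downsampling detection curves.

**Mutual-information differential expression** (`scquant.mide`). The core
statistic for two-state DE with small n. Per gene, expression values of
both states are pooled and discretized by the Freedman–Diaconis rule
(bin width 2·IQR·n^(−1/3)); the K×2 contingency table of (expression bin,
cell state) is estimated with the James–Stein empirical-Bayes shrinkage
estimator

    p̂_k = λ*·t_k + (1 − λ*)·θ̂_k,
    λ* = (1 − Σ_k θ̂_k²) / ((n − 1)·Σ_k (t_k − θ̂_k)²)  clipped to [0, 1],

where θ̂_k are the maximum-likelihood cell frequencies and t_k the uniform
target; and the mutual information is the entropy decomposition
MI = H(X) + H(Y) − H(X,Y) in bits, with marginals derived from the shrunk
joint so MI ≥ 0 holds structurally. A two-sided Wilcoxon rank-sum p-value
(exact for small groups without ties) and Benjamini–Hochberg q accompany
the MI score.

**Fluctuation analysis** (`scquant.fluct`). Per-gene SD (log10 scale) and
CV (linear scale); a two-sided F-test of dispersion equality between two
independently processed single-cell sets with BH adjustment (genes with
adjusted p above a threshold, default 0.6, are "reproducibly fluctuating");
and a one-sided F-test of single-cell variance against pooled-equivalent
samples, which carry experimental error only.

**Sequence QC** (`scquant.seqqc`). An ungapped-identity adaptor scan
(default: the WTA suppression primer `GTATAGAATTCGCGGCCGCTCGCGAT`, both
strands, identity ≥ 0.8 over ≥ 16 bp overlap including end overhangs);
GC/length profiling of detected vs undetected isoforms; and transcript
coverage breadth (median over transcripts with expression ≥ 10).

**Sample structure** (`scquant.structure`). PCA of cells on centered
log10(x+1) profiles, Ward hierarchical clustering (Newick output), and
hypergeometric over-representation of gene sets (GMT input).

**Pipeline** (`scquant.pipeline` and the `scquant` CLI). A config-driven
end-to-end run over synthetic data emitting one versioned JSON report,
deterministic to the byte under a fixed master seed.

## Worked example

Simulate a two-cell-type experiment (1,000 genes, 100 planted DE, 12 cells
per type) and scan for differential expression:

```python
from scquant import mide, synthdata
from scquant.synthdata import DesignRow, GeneratorConfig

config = GeneratorConfig(n_genes=1000, n_de_up=50, n_de_down=50)
truth = synthdata.make_truth(config, seed=7)
matrix, annotation = synthdata.simulate_experiment(
    truth,
    [DesignRow("ES", "G1", "single_cell", 12),
     DesignRow("PrE", "G1", "single_cell", 12)],
    seed=8,
)
de = mide.de_scan(matrix, annotation, ("ES", "PrE"))
top = de[de["tested"]].sort_values("mi_bits", ascending=False).head(5)
print(top[["gene_id", "K", "mi_bits", "lambda_star", "p", "q", "direction"]]
      .to_string(index=False))
print("genes at q < 0.05:", int((de["q"] < 0.05).sum()))
```

prints

```
   gene_id  K  mi_bits  lambda_star            p        q  direction
gene_00992  4 0.691560     0.100686 7.396023e-07 0.000248         -1
gene_00804  5 0.660392     0.146886 3.644203e-05 0.003049         -1
gene_00649  4 0.511616     0.163249 1.479205e-06 0.000371         -1
gene_00119  4 0.487757     0.230435 3.644203e-05 0.003049         -1
gene_00738  4 0.465315     0.244851 7.396023e-07 0.000248          1
genes at q < 0.05: 35
```

Each row is one gene: `K` is the Freedman–Diaconis bin count for its pooled
expression values, `mi_bits` the shrinkage-estimated mutual information
between expression bin and cell state (higher = stronger separation of the
two states), `lambda_star` the shrinkage intensity actually applied, `p`/`q`
the Wilcoxon rank-sum p-value and its BH adjustment, and `direction` the
sign of median(ES) − median(PrE). All five top-ranked genes are planted DE
genes with |log2FC| ≈ 3.5–3.9, and the sign of `direction` matches the
planted fold-change direction.

The same experiment can be driven from the shell:

```sh
scquant simulate --seed 7 --n-genes 1000 --n-de 100 --n-cells 12 --out-prefix demo
scquant mide --matrix demo.expr.tsv --annot demo.annot.tsv --states ES,PrE --out de.tsv
scquant run --seed 7 --out-dir demo_run     # full pipeline, JSON report
```

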