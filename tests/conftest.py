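import numpy as np
import pandas as pd
import pytest

from scquant.iohub import ExpressionMatrix, SampleAnnotation
from scquant.synthdata import DesignRow, GeneratorConfig, make_truth, simulate_experiment


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.gamma(2.0, 5.0, size=(30, 6)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(6)],
    )
    return ExpressionMatrix(values, unit="FPKM")


@pytest.fixture
def two_type_experiment():
    """Small two-cell-type experiment with planted truth (fast)."""
    config = GeneratorConfig(n_genes=400, n_de_up=20, n_de_down=20)
    truth = make_truth(config, seed=11)
    design = [
        DesignRow("ES", "G1", "single_cell", 8, batch="set1"),
        DesignRow("PrE", "G1", "single_cell", 8, batch="set1"),
        DesignRow("ES", "G1", "pooled_equivalent", 6, batch="pool"),
    ]
    matrix, annotation = simulate_experiment(truth, design, seed=12)
    return truth, matrix, annotation
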