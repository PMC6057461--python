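import numpy as np
import pandas as pd
import pytest

from radtx import (
    ExpressionMatrix,
    SimulationConfig,
    default_design,
    filter_detection,
    filter_intensity,
    generate_expression_study,
    normalize_to_control,
)

STUDY_SEED = 11


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def study(design):
    """Default-condition synthetic study: 2,000 genes, 6 arms x 3 replicates."""
    return generate_expression_study(design, SimulationConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def fold_changes(study):
    matrix, _ = study
    filtered = filter_intensity(filter_detection(matrix))
    return normalize_to_control(filtered, "control")


def make_matrix(values, arms=None, genes=None):
    """Small hand-built expression matrix for unit tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    arms = arms or ["control"] * n_samples
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    return ExpressionMatrix(frame, pd.Series(arms, index=samples, name="arm"))
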