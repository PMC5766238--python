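import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.exceptions import ConvergenceWarning

from seqexpr.features import build_feature_matrix
from seqexpr.regions import build_catalog
from seqexpr.synthetic import SimulationConfig, generate_annotation, simulate_expression

warnings.filterwarnings("ignore", category=ConvergenceWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """A shared 80-gene simulation with TADs and one planted variable."""
    config = SimulationConfig(
        n_genes=80,
        n_samples=2,
        tad_count=2,
        genes_per_tad=15,
        planted_support=[("CpG_CORE", 1.0)],
        noise_sd=0.5,
        seed=7,
    )
    annotation = generate_annotation(config)
    catalog = build_catalog(annotation.genes, annotation.genome, tss_choice="second")
    X = build_feature_matrix(catalog)
    expression, truth = simulate_expression(X, config, annotation.tad_assignments)
    return {
        "config": config,
        "annotation": annotation,
        "catalog": catalog,
        "X": X,
        "expression": expression,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def random_feature_frame():
    """A 300 x 12 i.i.d. normal feature matrix for model-level tests."""
    gen = np.random.default_rng(42)
    X = pd.DataFrame(
        gen.normal(size=(300, 12)),
        columns=[f"V{i}" for i in range(12)],
        index=[f"G{i:04d}" for i in range(300)],
    )
    return X
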