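import numpy as np
import pandas as pd
import pytest

import tmecomm as tc
from tmecomm.subpop import expression_phenotype_scores
from tmecomm.synthetic import benchmark_cohort_config


@pytest.fixture(scope="session")
def small_cohort():
    """A 5v5-patient null cohort shared across read-only tests."""
    cfg = benchmark_cohort_config(n_patients_per_group=5, n_cells_per_sample=150, seed=42)
    dataset, truth = tc.simulate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def small_tensor(small_cohort):
    """Standardized communication tensor for the shared cohort."""
    cfg, dataset, _ = small_cohort
    embeddings = {
        ct: tc.embed_phenotypes(
            expression_phenotype_scores(dataset, ct), ct, out_dims=2, seed=0, method="pca"
        )
        for ct in sorted(dataset.obs["cell_type"].unique())
    }
    partition = tc.partition_cohort(embeddings, dataset.obs["sample"])
    tensor = tc.standardize_and_summarize(
        tc.compute_communication_tensor(dataset, partition, cfg.lr_database())
    )
    return partition, tensor


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
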