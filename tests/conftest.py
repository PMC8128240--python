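import numpy as np
import pandas as pd
import pytest

from sepsismeta import (
    ExpressionSet,
    SimulationConfig,
    consolidate_labels,
    generate_meta_expression,
    merge_series,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small but structured collection: 3 studies, ~60 samples each."""
    return SimulationConfig(
        n_studies=3,
        samples_per_study=60,
        n_genes_per_platform=150,
        common_gene_fraction=0.8,
        n_de_genes=30,
        de_logfc=2.0,
        n_weak_genes=15,
        weak_logfc=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_collection(small_config):
    return generate_meta_expression(small_config)


@pytest.fixture(scope="session")
def small_merged(small_collection):
    sets, _truth = small_collection
    return merge_series(sets)


@pytest.fixture(scope="session")
def small_labels(small_merged):
    return consolidate_labels(small_merged.metadata)


def make_eset(values: np.ndarray, classes=None, study="s1", platform="p1"):
    """Minimal ExpressionSet around a genes-x-samples array."""
    values = np.asarray(values, dtype=float)
    G, N = values.shape
    genes = [f"g{i:03d}" for i in range(G)]
    samples = [f"{study}_x{j:03d}" for j in range(N)]
    if classes is None:
        classes = ["sepsis" if j < N // 2 else "healthy" for j in range(N)]
    meta = pd.DataFrame(
        {"class": classes, "study": study, "platform": platform},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionSet(pd.DataFrame(values, index=genes, columns=samples), meta)
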