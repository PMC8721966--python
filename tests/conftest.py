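import numpy as np
import pandas as pd
import pytest

from coexbench.corpus_io import Corpus, Dataset
from coexbench.synthdata import SynthConfig, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts(rng):
    """8 genes x 5 samples of modest negative-binomial-ish counts."""
    counts = rng.poisson(50, size=(8, 5)).astype(float)
    return pd.DataFrame(
        counts,
        index=[f"G{i}" for i in range(1, 9)],
        columns=[f"S{j}" for j in range(1, 6)],
    )


def make_dataset(rng, dataset_id, n_genes=10, n_samples=6, tissue="t1", lam=40):
    counts = pd.DataFrame(
        rng.poisson(lam, size=(n_genes, n_samples)).astype(float),
        index=[f"G{i}" for i in range(1, n_genes + 1)],
        columns=[f"{dataset_id}.S{j}" for j in range(1, n_samples + 1)],
    )
    return Dataset(dataset_id, counts, tissue=tissue)


@pytest.fixture
def small_corpus(rng):
    return Corpus({
        ds.dataset_id: ds
        for ds in (
            make_dataset(rng, "d1", tissue="t1"),
            make_dataset(rng, "d2", tissue="t2"),
            make_dataset(rng, "d3", tissue="t1"),
        )
    })


@pytest.fixture(scope="session")
def high_signal_bundle():
    """Strongly modular synthetic corpus used by end-to-end checks."""
    cfg = SynthConfig(
        n_genes=120, n_modules=6, module_size=10, n_samples=100,
        beta=1.5, dispersion=0.2, seed=1234,
    )
    return generate_corpus(cfg, n_datasets=3, n_tissues=3)
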