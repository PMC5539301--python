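import warnings

import numpy as np
import pytest

from malani.data import ExpressionDataset, normalize_per_sample, stratified_folds
from malani.simulate import SimConfig, generate_expression

warnings.filterwarnings("ignore", message=".*does not have valid feature names.*")


@pytest.fixture
def tiny_ds() -> ExpressionDataset:
    """3 genes x 4 samples with forced-arithmetic values."""
    return ExpressionDataset(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [[1.0, 2.0, 4.0, 1.0], [3.0, 4.0, 2.0, 1.0], [5.0, 6.0, 3.0, 2.0]]
        ),
        labels=np.array(["cancer", "cancer", "normal", "normal"], dtype=object),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study shared across tests: 60 genes, 12+12 samples."""
    cfg = SimConfig(
        G=60, n_cancer=12, n_normal=12, n_up=3, n_down=3, n_pairs=2, seed=7
    )
    ds, truth = generate_expression(cfg)
    return cfg, normalize_per_sample(ds), truth


@pytest.fixture(scope="session")
def small_folds(small_sim):
    _, ds, _ = small_sim
    return stratified_folds(ds.labels, 5, seed=3)
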