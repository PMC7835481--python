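import numpy as np
import pytest

from perfilt import MockDesign, TaxaTable, geometric_proportions


@pytest.fixture
def tiny_table() -> TaxaTable:
    """3 samples x 4 taxa with easily hand-checked counts."""
    counts = np.array([[5, 0, 2, 0],
                       [3, 1, 0, 0],
                       [8, 0, 4, 1]])
    return TaxaTable(counts, ["s1", "s2", "s3"], ["tA", "tB", "tC", "tD"])


@pytest.fixture
def random_table():
    """Factory for random sparse Poisson tables with a fixed seed."""

    def make(n_samples: int, n_taxa: int, seed: int, density: float = 0.6,
             lam: float = 4.0) -> TaxaTable:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam, size=(n_samples, n_taxa))
        counts = counts * (rng.random((n_samples, n_taxa)) < density)
        # guarantee at least one nonzero entry
        if counts.sum() == 0:
            counts[0, 0] = 1
        return TaxaTable(counts,
                         [f"s{i:03d}" for i in range(n_samples)],
                         [f"t{j:03d}" for j in range(n_taxa)])

    return make


def small_mock_design(seed: int) -> MockDesign:
    """20 samples x 40 taxa mock (8 signal, 2 labs x 16 noise taxa)."""
    return MockDesign(n_signal=8, signal_props=geometric_proportions(8),
                      labs=("L1", "L2"), samples_per_lab=10, n_noise_per_lab=16,
                      noise_prevalence=0.1, noise_mean_count=5.0,
                      library_size_mean=20_000, seed=seed)
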