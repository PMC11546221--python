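import numpy as np
import pytest

import codonlens as cl


@pytest.fixture(scope="session")
def code():
    return cl.standard_code()


@pytest.fixture(scope="session")
def planted():
    """Moderate-noise planted-effect dataset at the study scale (K=1000)."""
    return cl.generate_dataset(cl.SyntheticConfig(n_genes=1000, seed=11))


@pytest.fixture(scope="session")
def planted_matrices(planted):
    ds, _ = planted
    counts = cl.build_count_matrix(ds.genes)
    return counts, cl.to_frequencies(counts)


@pytest.fixture(scope="session")
def noiseless():
    """Zero-noise dataset: log(e+1) is exactly affine in the gene's mean
    planted weight."""
    return cl.generate_dataset(cl.SyntheticConfig(n_genes=1000, noise_sd=0.0, seed=7))


def tau_a_brute(x, y):
    """O(K^2) sign-product oracle for Kendall's tau-a."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    K = len(x)
    return np.triu(sx * sy, 1).sum() * 2.0 / (K * (K - 1))
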