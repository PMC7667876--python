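import numpy as np
import pandas as pd
import pytest

from coldclock import pasquant


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_catalog():
    """A mixed-species polyA-site catalog on three chromosomes."""
    sites = [
        pasquant.PasSite(f"chr{(i % 3) + 1}", "+" if i % 2 == 0 else "-",
                         10_000 + 1_500 * i, f"HG{i:03d}", "human")
        for i in range(20)
    ]
    sites += [
        pasquant.PasSite("chr2L", "+", 5_000 + 1_500 * i, f"FG{i:03d}", "fly")
        for i in range(5)
    ]
    return sites


def nb_counts(rng, mean, dispersion, size):
    """Gamma-Poisson draw used as an independent NB generator in tests."""
    if dispersion == 0:
        return rng.poisson(np.broadcast_to(mean, size))
    lam = rng.gamma(1.0 / dispersion, dispersion * np.broadcast_to(mean, size))
    return rng.poisson(lam)


@pytest.fixture
def nb_table():
    def make(rng, n_genes, n_samples, mean_range=(20, 2000), dispersion=0.1):
        means = rng.uniform(*mean_range, n_genes)
        mat = nb_counts(rng, means[:, None], dispersion, (n_genes, n_samples))
        return pd.DataFrame(
            mat,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )

    return make
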