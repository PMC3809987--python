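import numpy as np
import pytest

from chronopl import (
    CladeSpec,
    RateModel,
    SubstitutionModel,
    assign_rates,
    simulate_alignment,
    simulate_chronogram,
    to_phylogram,
)


@pytest.fixture
def jc_model():
    """Jukes-Cantor: equal frequencies and exchangeabilities, no rate mix."""
    return SubstitutionModel(n_rate_categories=1)


@pytest.fixture
def gtr_model():
    """An asymmetric GTR+Gamma+I typical of mitochondrial data."""
    return SubstitutionModel(
        exchangeabilities=(2.0, 10.0, 2.0, 1.0, 20.0, 1.0),
        base_freqs=(0.35, 0.30, 0.10, 0.25),
        gamma_shape=0.5,
        n_rate_categories=4,
        p_inv=0.2,
    )


@pytest.fixture
def small_chronogram():
    return simulate_chronogram(8, 50.0, seed=42)


@pytest.fixture
def strict_phylogram(small_chronogram):
    rates = assign_rates(small_chronogram, RateModel("strict", 0.01), seed=0)
    return to_phylogram(small_chronogram, rates)


def random_tree_and_alignment(seed, n_taxa=5, n_sites=200, model=None, rate=0.02):
    """A simulated (phylogram, alignment) pair for likelihood tests."""
    rng = np.random.default_rng(seed)
    chron = simulate_chronogram(n_taxa, 10.0, rng)
    rates = assign_rates(chron, RateModel("iid_lognormal", rate, 0.3), rng)
    phylo = to_phylogram(chron, rates)
    model = model or SubstitutionModel(n_rate_categories=1)
    aln = simulate_alignment(phylo, model, n_sites, rng)
    return phylo, aln
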