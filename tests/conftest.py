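import numpy as np
import pytest

from ratelink.models import MorphModelParams, NucModelParams
from ratelink.synthetic import (
    ScenarioSpec,
    generate_scenario_pair,
    simulate_alignment,
    simulate_characters,
)
from ratelink.trees import load_chronogram, load_phylogram, simulate_chronogram

# Jukes-Cantor: equal rates/freqs, no invariant sites, (near-)homogeneous
# site rates (huge gamma shape, one category)
JC_LIKE = NucModelParams(
    exchangeabilities=(1.0,) * 6,
    base_freqs=(0.25,) * 4,
    gamma_shape=1e9,
    p_inv=0.0,
    n_categories=1,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def four_taxon_phylogram():
    return load_phylogram("((A:0.12,B:0.3):0.08,(C:0.5,D:0.02):0.2);")


@pytest.fixture
def five_taxon_phylogram():
    return load_phylogram("(((A:0.1,B:0.2):0.05,C:0.4):0.07,(D:0.3,E:0.15):0.1);")


@pytest.fixture
def small_chronogram():
    return simulate_chronogram(8, root_age=139.40, seed=7)


@pytest.fixture
def coupled_pair():
    return generate_scenario_pair(
        ScenarioSpec(n_taxa=18, n_chars=100, sigma=1.25, coupled=True, master_seed=99)
    )


@pytest.fixture
def coupled_data(coupled_pair):
    aln = simulate_alignment(coupled_pair["mol_phylogram"], L=500, seed=11)
    chars = simulate_characters(
        coupled_pair["morph_phylogram"], MorphModelParams(2), 100, seed=12
    )
    return coupled_pair, aln, chars
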