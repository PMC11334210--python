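import numpy as np
import pandas as pd
import pytest

from karyorate import chrom_markov as cm
from karyorate import synthetic_data as sd
from karyorate.phylo_io import scale_to_unit_height


@pytest.fixture(scope="session")
def small_space():
    return cm.build_state_space(2, 4)  # 6 combined states


@pytest.fixture(scope="session")
def generic_params():
    return cm.RateParams(delta_S=0.8, delta_L=0.3, gamma_S=1.1, gamma_L=0.4,
                         q_SL=0.9, q_LS=0.6)


@pytest.fixture(scope="session")
def sim_dataset():
    """A 40-tip unit-height tree with simulated counts and hyperstates."""
    phy = scale_to_unit_height(sd.simulate_tree(40, seed=11))
    cfg = sd.SimConfig(n_tips=40, params=cm.RateParams(1.0, 0.5, 1.0, 0.5, 2.0, 2.0),
                       seed=11)
    data = sd.simulate_chromosomes(phy, cfg, np.random.default_rng(11))
    return phy, data


def make_traits(labels, counts, states):
    return pd.DataFrame(dict(species=labels, haploid_n=counts, state=states))
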