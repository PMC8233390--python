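import numpy as np
import pandas as pd
import pytest

import flocklearn as fl
from flocklearn.association_network import AssociationMatrix


@pytest.fixture(scope="session")
def small_cfg():
    return fl.SimConfig(n_birds=12, n_days=3, n_days_pretraining=3, seed=7)


@pytest.fixture(scope="session")
def population(small_cfg):
    roster, true_net = fl.simulate_population(small_cfg)
    return roster, true_net


@pytest.fixture(scope="session")
def pretraining(population, small_cfg):
    roster, _ = population
    return fl.simulate_pretraining_stream(roster, small_cfg)


@pytest.fixture(scope="session")
def avoidance(population, small_cfg):
    roster, true_net = population
    return fl.simulate_avoidance_stream(roster, true_net, small_cfg)


@pytest.fixture(scope="session")
def true_matrix(population):
    roster, true_net = population
    return AssociationMatrix(birds=list(roster["bird_id"]), weights=true_net)


@pytest.fixture(scope="session")
def choice_table(avoidance, true_matrix, population):
    roster, _ = population
    visits, _ = avoidance
    return fl.build_choice_table(visits, true_matrix, roster)


def toy_roster(n, species=None, age=None):
    """Tiny hand-specified roster for fixture-based tests."""
    ids = [f"b{k}" for k in range(1, n + 1)]
    return pd.DataFrame({
        "bird_id": ids,
        "species": species or ["A"] * n,
        "age": age or ["adult"] * n,
        "activity": np.ones(n),
    })
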