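import numpy as np
import pytest

import fluxdose as fd


@pytest.fixture(scope="session")
def chain():
    return fd.fixture("chain")


@pytest.fixture(scope="session")
def diamond():
    return fd.fixture("diamond")


@pytest.fixture(scope="session")
def superfluous():
    return fd.fixture("superfluous")


@pytest.fixture(scope="session")
def activation():
    return fd.fixture("activation")


@pytest.fixture(scope="session")
def all_fixtures(chain, diamond, superfluous, activation):
    return [chain, diamond, superfluous, activation]


def make_synthetic_case(seed, n_metabolites=4, n_reactions=8, n_drugs=2, targets_per_drug=2):
    """Canonical synthetic instance: (net, ref, catalog)."""
    net, catalog = fd.generate_synthetic(n_metabolites, n_reactions, n_drugs, targets_per_drug, seed)
    canon = fd.make_irreversible(net)
    ref = fd.fba_reference(canon)
    return canon, ref, catalog


@pytest.fixture()
def synthetic_case():
    return make_synthetic_case


def random_grid_h(rng, catalog, precision):
    enc = fd.InhibitionEncoding.for_catalog(catalog, precision)
    return np.array(
        [rng.choice(enc.achievable_levels(did)) for did in catalog.drug_ids]
    )
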