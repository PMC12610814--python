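import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from plastcub import DEFAULT_CODE, filter_cds, profile_genes
from plastcub.simulate import UsageRegime, generate_cds_set


@pytest.fixture(scope="session")
def code():
    return DEFAULT_CODE


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


def _regime_set(name, seed, n_genes=55, **kw):
    seqs, meta = generate_cds_set(
        UsageRegime(name=name, n_genes=n_genes, seed=seed, **kw))
    return seqs, meta


@pytest.fixture(scope="session")
def uniform_set():
    return _regime_set("uniform", seed=101)[0]


@pytest.fixture(scope="session")
def at_biased_set():
    return _regime_set("at_biased", seed=102)[0]


@pytest.fixture(scope="session")
def mutation_set():
    return _regime_set("mutation_gradient", seed=103, n_genes=100)[0]


@pytest.fixture(scope="session")
def selection_set():
    return _regime_set("selection_regime", seed=104, n_genes=100)[0]


@pytest.fixture(scope="session")
def uniform_profiles(uniform_set):
    retained, _ = filter_cds(uniform_set)
    return profile_genes(retained)


@pytest.fixture(scope="session")
def mutation_profiles(mutation_set):
    retained, _ = filter_cds(mutation_set)
    return profile_genes(retained)


@pytest.fixture(scope="session")
def selection_profiles(selection_set):
    retained, _ = filter_cds(selection_set)
    return profile_genes(retained)
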