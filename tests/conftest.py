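from importlib import resources

import pytest

from cobalance import default_reactions, default_registry, read_bottles_csv
from cobalance.synthetic_data import SimConfig, simulate_bottle


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def reactions(registry):
    """Packaged microcosm ledger, keyed by reaction name."""
    return {r.name: r for r in default_reactions(registry)}


@pytest.fixture(scope="session")
def table2_path():
    with resources.as_file(
        resources.files("cobalance.data").joinpath("table2_bottles.csv")
    ) as p:
        yield p


@pytest.fixture(scope="session")
def table2_bottles(table2_path, registry):
    return {b.treatment: b for b in read_bottles_csv(table2_path, registry)}


@pytest.fixture(scope="session")
def clean_sim():
    """One noise-free default bottle run to completion, shared read-only."""
    return simulate_bottle(SimConfig(noise_sd=0.0))
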