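import pytest

from ampbench import CopiesModel, SimConfig, simulate_library
from ampbench.library_io import tag_pairs


def make_library(**kwargs):
    """Simulate a library with test-friendly defaults (overridable)."""
    defaults = dict(
        n_molecules=200,
        copies=CopiesModel.fixed(5),
        sub_rate_fwd=0.0,
        sub_rate_rev=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        seed=7,
    )
    defaults.update(kwargs)
    return simulate_library(SimConfig(**defaults))


def make_pairs(**kwargs):
    """Simulated, tagged in-memory read pairs."""
    lib = make_library(**kwargs)
    return tag_pairs(lib.pairs, lib.config.layout), lib


@pytest.fixture(scope="session")
def zero_error_pairs():
    """1000 molecules, 5 exact copies each, no errors: the ideal-retention case."""
    pairs, lib = make_pairs(n_molecules=1000)
    return pairs


@pytest.fixture(scope="session")
def noisy_pairs():
    """Default-model noisy library shared across read-only tests."""
    pairs, lib = make_pairs(
        n_molecules=500,
        copies=CopiesModel.poisson(5.0),
        sub_rate_fwd=1e-3,
        sub_rate_rev=3e-3,
        ins_rate=5e-5,
        del_rate=1e-4,
        seed=13,
    )
    return pairs
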