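"""Shared fixtures: the liver network and expensive protocol states are
built once per session."""

import pytest

from nashflux.pipeline import PerfusionModel


@pytest.fixture(scope="session")
def model() -> PerfusionModel:
    return PerfusionModel()


@pytest.fixture(scope="session")
def network(model):
    return model.network


@pytest.fixture(scope="session")
def scs_result(model):
    """UW flush + 6 h static cold storage at 4 C."""
    return model.run_scs()


@pytest.fixture(scope="session")
def post_scs(scs_result):
    return scs_result.final_state


@pytest.fixture(scope="session")
def baseline_mp(model, post_scs):
    """Conventional mid-thermic perfusion: constant 16 C for 8 h."""
    return model.run_mp(post_scs)
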