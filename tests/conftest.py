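import pytest

from prediabetes_bia import build_strategy, load_country, simulate


@pytest.fixture(scope="session")
def poland():
    return load_country("poland")


@pytest.fixture(scope="session")
def saudi_arabia():
    return load_country("saudi_arabia")


@pytest.fixture(scope="session")
def vietnam():
    return load_country("vietnam")


@pytest.fixture(scope="session")
def countries(poland, saudi_arabia, vietnam):
    return {"poland": poland, "saudi_arabia": saudi_arabia, "vietnam": vietnam}


@pytest.fixture(scope="session")
def poland_trajectories(poland):
    """15-year runs for all five strategies, shared across tests."""
    return {
        kind: simulate(poland, build_strategy(kind), 15)
        for kind in ("inaction", "metformin", "ilc", "combination", "titration")
    }
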