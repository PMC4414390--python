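import pytest

import taxoprov as tp


@pytest.fixture(scope="session")
def curated():
    return tp.curated_fixture()


@pytest.fixture(scope="session")
def curated_merged(curated):
    graph, _report = tp.merge(list(curated.sources), curated.alignment)
    return graph


@pytest.fixture(scope="session")
def small_bundle():
    """One default-sized random fixture, shared where the seed is irrelevant."""
    return tp.generate_fixture(tp.FixtureParams(seed=11))
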