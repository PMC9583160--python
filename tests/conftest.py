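import pytest

import ncycle as nc


@pytest.fixture(scope="session")
def catalog():
    return nc.load_catalog()


@pytest.fixture(scope="session")
def micro():
    """Bundled 8-sample / 6-KO hand-checkable dataset."""
    records, env = nc.fixture_small()
    return records, env


@pytest.fixture(scope="session")
def micro_metrics(micro, catalog):
    records, _ = micro
    return nc.compute_metrics(records, catalog)


@pytest.fixture(scope="session")
def synth32(catalog):
    """One default 32-sample synthetic dataset (seed 7)."""
    records, env, truth = nc.generate(nc.SimulationConfig(seed=7), catalog)
    return records, env, truth
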