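import numpy as np
import pytest

from chanfire import (IntegratorConfig, NeuronSimulator, build_model,
                      reduced_protocol)


@pytest.fixture(scope="session")
def proto():
    """Desk-scale protocol: 1 s steps, 50 coarse currents, dt 0.01 ms."""
    return reduced_protocol()


@pytest.fixture(scope="session")
def sim_cache():
    """Session-wide cache of settled simulators (settling is deterministic)."""
    cache = {}

    def get(model_id: str) -> NeuronSimulator:
        if model_id not in cache:
            sim = NeuronSimulator(build_model(model_id), IntegratorConfig())
            sim.settle()
            cache[model_id] = sim
        return cache[model_id]

    return get


@pytest.fixture(scope="session")
def metrics_cache(proto, sim_cache):
    """Session-wide cache of reduced-protocol firing characterizations."""
    from chanfire import characterize

    cache = {}

    def get(model_id: str, need=("rheobase", "auc")):
        key = (model_id, tuple(sorted(need)))
        if key not in cache:
            cache[key] = characterize(sim_cache(model_id), proto, need=need)
        return cache[key]

    return get
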