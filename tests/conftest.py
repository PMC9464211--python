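import numpy as np
import pytest

from refillsim import (ParameterRegistry, SessionProtocol, VirtualPatient,
                       build_model, run_session, scenario_protocols)


@pytest.fixture(scope="session")
def registry():
    return ParameterRegistry()


@pytest.fixture(scope="session")
def patient(registry):
    return VirtualPatient(registry)


@pytest.fixture(scope="session")
def flatline_model(patient):
    return build_model(patient, SessionProtocol.flatline(300.0))


@pytest.fixture(scope="session")
def trajectories(patient):
    """Lazily simulated named scenarios, shared across the whole suite."""
    cache = {}
    protocols = scenario_protocols()

    def get(name, protocol=None, **kwargs):
        if name not in cache:
            proto = protocol if protocol is not None else protocols[name]
            cache[name] = run_session(patient, proto, **kwargs)
        return cache[name]

    return get


@pytest.fixture(scope="session")
def basal(trajectories):
    return trajectories("basal")


@pytest.fixture(scope="session")
def flatline(trajectories):
    return trajectories("flatline", SessionProtocol.flatline(300.0))
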