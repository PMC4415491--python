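import numpy as np
import pytest

from pdresonance import (
    ChirpSpec,
    assemble_linear_circuit,
    chirp_response,
    control_params,
    find_equilibrium,
)


@pytest.fixture(scope="session")
def control():
    return control_params()


@pytest.fixture(scope="session")
def eq55(control):
    return find_equilibrium(control, -55.0)


@pytest.fixture(scope="session")
def circuit55(control, eq55):
    return assemble_linear_circuit(control, eq55)


@pytest.fixture(scope="session")
def chirp():
    return ChirpSpec()


class _ResponseCache:
    """Memoized chirp-response metrics so acceptance and experiment tests
    reuse identical simulations."""

    def __init__(self, params, chirp):
        self.params = params
        self.chirp = chirp
        self._cache = {}

    def profile(self, V, scale=None, model_kind="nonlinear", settle=0.0):
        key = (round(V, 6), tuple(sorted((scale or {}).items())), model_kind, settle)
        if key not in self._cache:
            p = self.params.scale_gbar(scale) if scale else self.params
            self._cache[key] = chirp_response(
                p, V, self.chirp, model_kind=model_kind, settle=settle
            )
        return self._cache[key]


@pytest.fixture(scope="session")
def responses(control, chirp):
    return _ResponseCache(control, chirp)
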