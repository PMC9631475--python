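import warnings

import pytest

from lvadloop.energetics import default_constants
from lvadloop.metrics import compute_beat_metrics
from lvadloop.model import CirculationModel
from lvadloop.parameters import seed_parameter_set
from lvadloop.scenarios import default_catalogue


@pytest.fixture(scope="session")
def catalogue():
    """The calibrated scenario catalogue shipped with the package."""
    return default_catalogue()


@pytest.fixture(scope="session")
def constants():
    return default_constants()


@pytest.fixture(scope="session")
def seed_params():
    return seed_parameter_set()


class _ScenarioRunner:
    """Session-wide cache: each catalogued scenario is simulated once."""

    def __init__(self, catalogue, constants):
        self.catalogue = catalogue
        self.constants = constants
        self._cache = {}

    def results(self, name: str, n_cycles: int = 10):
        key = (name, n_cycles)
        if key not in self._cache:
            params = self.catalogue.build(name)
            with warnings.catch_warnings():
                warnings.simplefilter("error")  # periodicity warning -> failure
                res = CirculationModel(params).simulate(n_cycles=n_cycles)
            metrics = compute_beat_metrics(res.waveforms, params, self.constants)
            self._cache[key] = (metrics, res)
        return self._cache[key]

    def metrics(self, name: str, n_cycles: int = 10):
        return self.results(name, n_cycles)[0]


@pytest.fixture(scope="session")
def runner(catalogue, constants):
    return _ScenarioRunner(catalogue, constants)
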