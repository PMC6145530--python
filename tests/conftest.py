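import numpy as np
import pytest

from pencildec import simulate
from pencildec.timeseries import components_to_poles


@pytest.fixture(scope="session")
def preset_components():
    return simulate.standard_preset()


@pytest.fixture(scope="session")
def true_poles(preset_components):
    """Analytic poles implied by the standard preset (hourly sampling)."""
    return components_to_poles(preset_components, dt=1.0)


@pytest.fixture(scope="session")
def noiseless_50(preset_components):
    return simulate.generate(simulate.SimulationSpec(
        components=preset_components, n_samples=50, noise_sd=0.0))


def match_poles(estimated, true):
    """Greedy nearest matching; returns max |estimated - true| over true poles."""
    est = np.asarray(estimated, dtype=complex).copy()
    worst = 0.0
    for lam in np.asarray(true, dtype=complex):
        i = int(np.argmin(np.abs(est - lam)))
        worst = max(worst, float(abs(est[i] - lam)))
        est[i] = 1e9  # consume
    return worst
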