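"""Shared fixtures: small, fast synthetic runs used across the suite."""

import numpy as np
import pytest

from qbead import (
    AcquisitionSettings,
    CircuitParams,
    DetectorParams,
    FrequencyPanel,
    SampleSpec,
    ShellMap,
    simulate_traces,
)

# Compact acquisition used by most tests: 2 kHz sampling keeps the transit
# resolvable (76 samples) while traces stay small.
FAST_RATE = 2000.0
TRANSIT = 0.038


def fast_settings(**overrides) -> AcquisitionSettings:
    base = dict(
        sampling_rate=FAST_RATE,
        duration=20.0,
        mean_transit_time=TRANSIT,
        arrival_rate=4.0,
        noise_sd=1e-5,
        drift_amplitude=2e-4,
        drift_timescale=5.0,
        seed=0,
    )
    base.update(overrides)
    return AcquisitionSettings(**base)


def duration_for(n_beads: int, arrival_rate: float = 4.0) -> float:
    """Trace length that comfortably fits n_beads thinned Poisson arrivals."""
    return float(np.ceil(1.6 * n_beads / arrival_rate + 1.0))


@pytest.fixture(scope="session")
def circuit() -> CircuitParams:
    return CircuitParams()


@pytest.fixture(scope="session")
def panel() -> FrequencyPanel:
    return FrequencyPanel()


@pytest.fixture(scope="session")
def shell_map() -> ShellMap:
    return ShellMap()


@pytest.fixture(scope="session")
def detector() -> DetectorParams:
    return DetectorParams.for_transit(TRANSIT)


@pytest.fixture(scope="session")
def bare_traces_50(circuit, panel, shell_map):
    """50 bare-bead transits on a noisy, drifting baseline."""
    spec = SampleSpec("bare", 0, 0.0, 50)
    acq = fast_settings(duration=duration_for(50), seed=11)
    return simulate_traces(spec, circuit, acq, panel, shell_map)


@pytest.fixture(scope="session")
def noisefree_traces_20(circuit, panel, shell_map):
    """20 DNA-bead transits with zero noise and zero drift."""
    spec = SampleSpec("dna", 300, 4.75e4, 20)
    acq = fast_settings(
        duration=duration_for(20), seed=7, noise_sd=0.0, drift_amplitude=0.0
    )
    return simulate_traces(spec, circuit, acq, panel, shell_map)
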