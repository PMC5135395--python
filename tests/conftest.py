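"""Shared simulated recordings.

Session-scoped so the heavier simulations run once.  The fluctuation-state
parameters emulate a neuron embedded in an active network: high synaptic
conductance (short effective membrane time constant), mean drive a few mV
below threshold, spikes triggered by noise transients.  The mean-driven
parameters use a strong suprathreshold drive with a shallow
after-hyperpolarization reset.
"""

import numpy as np
import pytest

import regimescope as rs


def fluct_params(**overrides) -> rs.NeuronModelParams:
    kw = dict(membrane_time_constant=6.0, mean_input_current=0.10,
              current_noise_sd=0.055, noise_correlation_tau=5.0,
              cycle_duty_fraction=1.0)
    kw.update(overrides)
    return rs.NeuronModelParams(**kw)


def mean_params(**overrides) -> rs.NeuronModelParams:
    kw = dict(mean_input_current=0.30, current_noise_sd=0.02,
              reset_potential=-50.0, resting_potential=-55.0,
              cycle_duty_fraction=1.0)
    kw.update(overrides)
    return rs.NeuronModelParams(**kw)


@pytest.fixture(scope="session")
def fluct_recording() -> rs.SimulatedRecording:
    return rs.simulate_two_regime_neuron(fluct_params(), duration=60.0,
                                         dt=0.05, seed=11)


@pytest.fixture(scope="session")
def mean_recording() -> rs.SimulatedRecording:
    return rs.simulate_two_regime_neuron(mean_params(), duration=20.0,
                                         dt=0.05, seed=7)


@pytest.fixture(scope="session")
def hazard_recording() -> rs.SimulatedRecording:
    # programmed exponential hazard nu(V) = c exp(0.5 V); c chosen for a
    # mean rate near 8 Hz at Vm ~ -57 mV
    return rs.simulate_hazard_neuron(c=6.2e12, beta=0.5, duration=300.0,
                                     dt=0.1, vm_mean=-57.0, vm_sd=3.0,
                                     vm_tau_ms=30.0, seed=3)


@pytest.fixture(scope="session")
def population_raster():
    spec = rs.PopulationSpec(n_units=200, log_rate_mean=2.0, log_rate_sd=1.0,
                             n_cycles=20, seed=5)
    return rs.generate_population_raster(spec)


@pytest.fixture(scope="session")
def fluct_spikes(fluct_recording):
    tr = rs.VmTrace(fluct_recording.vm, fluct_recording.sampling_rate)
    peaks = rs.detect_spike_peaks(tr)
    return tr, rs.estimate_thresholds_phase_plane(tr, peaks)
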