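"""Synthetic recordings with the statistical structure of rhythmically active
spinal networks.

This module generates ground-truth-labelled data for every downstream stage:

* single-neuron membrane-potential (Vm) traces from a leaky integrate-and-fire
  model driven by a cycle-modulated mean current plus Gaussian (OU) current
  noise, spanning the fluctuation-driven regime (mean drive subthreshold,
  spikes triggered by noise transients) and the mean-driven regime (mean drive
  suprathreshold, regular pacemaker-like spiking);
* gamma-renewal spike trains (shape 1 = Poisson, shape -> inf = clock-like);
* population rasters with lognormally distributed per-unit mean rates,
  phase-locked bursting on a fixed cycle, and per-unit irregularity;
* per-electrode spike-amplitude maps on a staggered multi-shank probe, with
  inverse-square distance decay.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class NeuronModelParams:
    """Leaky integrate-and-fire neuron with adaptive threshold and cycle drive.

    Units follow intracellular convention: MOhm x nA = mV.

    Attributes
    ----------
    membrane_resistance : float
        Input resistance Rm (MOhm).
    membrane_time_constant : float
        Effective membrane time constant tau_m (ms).
    mean_input_current : float
        Mean drive Im during the active phase (nA). The product
        Rm * Im is the asymptotic depolarization above rest.
    current_noise_sd : float
        Stationary SD of the synaptic noise current (nA), modelled as an
        Ornstein-Uhlenbeck process with correlation time
        ``noise_correlation_tau``.
    spike_threshold : float
        Baseline spike threshold V_thres (mV).
    reset_potential : float
        Post-spike reset (mV); also the leak reversal by default.
    refractory_period : float
        Absolute refractory period (ms); must cover the stylized spike shape.
    threshold_adaptation_increment : float
        Per-spike depolarizing shift of the threshold (mV); models Na+
        channel inactivation.
    threshold_recovery_tau : float
        Exponential recovery time constant of the threshold shift (ms).
    cycle_period : float
        Motor-cycle period (s).
    cycle_duty_fraction : float
        Fraction of each cycle occupied by the active (depolarized) phase.
    drive_modulation_depth : float
        Depth in [0, 1] of the half-sine modulation of Im within the active
        phase (0 = flat drive).
    """

    membrane_resistance: float = 100.0
    membrane_time_constant: float = 20.0
    mean_input_current: float = 0.10
    current_noise_sd: float = 0.04
    spike_threshold: float = -45.0
    reset_potential: float = -60.0
    refractory_period: float = 3.0
    threshold_adaptation_increment: float = 0.0
    threshold_recovery_tau: float = 50.0
    cycle_period: float = 1.0
    cycle_duty_fraction: float = 0.6
    drive_modulation_depth: float = 0.0
    resting_potential: float = -60.0
    noise_correlation_tau: float = 5.0
    interburst_hyperpolarization: float = 5.0
    interburst_noise_fraction: float = 0.2
    spike_peak: float = 20.0
    spike_rise_ms: float = 1.0
    spike_repolarization_tau: float = 0.6

    def __post_init__(self) -> None:
        if self.membrane_resistance <= 0:
            raise ValueError("membrane_resistance must be > 0")
        if self.membrane_time_constant <= 0:
            raise ValueError("membrane_time_constant must be > 0")
        if self.refractory_period < self.spike_rise_ms:
            raise ValueError("refractory_period must cover the spike rise")
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be > 0")
        if not (0.0 < self.cycle_duty_fraction <= 1.0):
            raise ValueError("cycle_duty_fraction must be in (0, 1]")
        if self.reset_potential >= self.spike_threshold:
            raise ValueError("reset_potential must lie below spike_threshold")
        if self.current_noise_sd < 0:
            raise ValueError("current_noise_sd must be >= 0")

    @property
    def is_fluctuation_driven(self) -> bool:
        """True when the peak mean drive stays below threshold (Rm Im <
        V_thres - V_rest), so that spikes require noise transients."""
        drive_mv = self.membrane_resistance * self.mean_input_current
        return drive_mv < (self.spike_threshold - self.resting_potential)


@dataclass
class SimulatedRecording:
    """Ground-truth container tying a simulated Vm trace to its spikes."""

    vm: np.ndarray                    # mV
    sampling_rate: float              # Hz
    true_spike_times: np.ndarray      # s, spike *peak* times
    true_onset_times: np.ndarray      # s, threshold-crossing times
    true_threshold_per_spike: np.ndarray  # mV, adaptive threshold at crossing
    regime_label: str                 # "fluctuation" | "mean"
    params: NeuronModelParams | None = None
    seed: int | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.vm.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.vm.size / self.sampling_rate


@dataclass
class PopulationSpec:
    """Parameters of a simulated population raster.

    Per-unit mean rates are drawn lognormally: rate_i = exp(N(log_rate_mean,
    log_rate_sd)) in Hz, averaged over the whole cycle.  Each unit fires in
    phase-locked bursts (raised-cosine intensity around its preferred phase
    inside the active window) as a gamma renewal process in rescaled time.
    """

    n_units: int = 50
    log_rate_mean: float = 2.0        # log Hz (natural log)
    log_rate_sd: float = 1.0          # log units
    gamma_shape: float | tuple[float, float] = 1.0
    cycle_period: float = 1.0         # s
    n_cycles: int = 20
    interburst_gap: float = 0.4       # s of quiescence per cycle
    phase_concentration: float = 1.0  # raised-cosine sharpness (0 = uniform)
    n_shanks: int = 8
    depth_range: tuple[float, float] = (300.0, 800.0)  # um below surface
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.log_rate_sd < 0:
            raise ValueError("log_rate_sd must be >= 0")
        shapes = np.atleast_1d(np.asarray(self.gamma_shape, dtype=float))
        if np.any(shapes <= 0):
            raise ValueError("gamma_shape must be > 0")
        if not (0 <= self.interburst_gap < self.cycle_period):
            raise ValueError("interburst_gap must be in [0, cycle_period)")


@dataclass
class ProbeGeometry:
    """Multi-shank silicon probe: 8 shanks x 8 staggered electrodes by default.

    ``y`` is measured upward from the deepest electrode of the shank;
    electrodes are spaced 30 um vertically with a small alternating lateral
    stagger.  ``insertion_depth_um[s]`` is the depth of the deepest electrode
    of shank ``s`` below the cord surface.
    """

    n_shanks: int = 8
    shank_pitch_um: float = 200.0
    n_electrodes_per_shank: int = 8
    electrode_spacing_um: float = 30.0
    stagger_um: float = 11.0
    insertion_depth_um: np.ndarray = field(
        default_factory=lambda: np.full(8, 800.0))

    def __post_init__(self) -> None:
        self.insertion_depth_um = np.asarray(self.insertion_depth_um, float)
        if self.insertion_depth_um.size != self.n_shanks:
            raise ValueError("need one insertion depth per shank")

    def electrode_positions(self, shank: int = 0) -> np.ndarray:
        """(n_electrodes, 2) array of (x, y) um in the shank plane."""
        ys = np.arange(self.n_electrodes_per_shank) * self.electrode_spacing_um
        xs = (shank * self.shank_pitch_um
              + self.stagger_um * np.where(
                  np.arange(self.n_electrodes_per_shank) % 2 == 0, -1.0, 1.0))
        pos = np.column_stack([xs, ys])
        if len({tuple(p) for p in pos}) != len(pos):
            raise ValueError("electrode positions must be unique per shank")
        return pos


@dataclass
class AmplitudeMap:
    """Mean spike amplitude (uV) of one unit on each electrode of a shank."""

    amplitudes_uV: np.ndarray
    shank: int = 0
    noise_sd_uV: float = 0.0
    true_position_um: tuple[float, float] | None = None
    true_strength: float | None = None    # uV * um^2

    def __post_init__(self) -> None:
        self.amplitudes_uV = np.asarray(self.amplitudes_uV, float)
        if np.any(self.amplitudes_uV < 0):
            raise ValueError("amplitudes must be rectified at 0")


# --------------------------------------------------------------------------
# single-neuron simulator
# --------------------------------------------------------------------------

def _cycle_drive(t: np.ndarray, p: NeuronModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Return (active mask, drive current in nA) for time vector t (s)."""
    phase = np.mod(t, p.cycle_period) / p.cycle_period
    active = phase < p.cycle_duty_fraction
    u = np.where(active, phase / p.cycle_duty_fraction, 0.0)
    env = (1.0 - p.drive_modulation_depth
           + p.drive_modulation_depth * np.sin(np.pi * u))
    return active, np.where(active, p.mean_input_current * env, 0.0)


def _ou_current(n: int, sd: float, tau_ms: float, dt_ms: float,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary OU process with SD `sd` and correlation time `tau_ms`."""
    if sd == 0:
        return np.zeros(n)
    a = np.exp(-dt_ms / tau_ms)
    b = sd * np.sqrt(1.0 - a * a)
    w = rng.standard_normal(n)
    # AR(1) recursion x[k] = a x[k-1] + b w[k], started from stationarity
    drive = np.concatenate([[sd * w[0]], b * w[1:]])
    return signal.lfilter([1.0], [1.0, -a], drive)


def simulate_two_regime_neuron(params: NeuronModelParams,
                               duration: float,
                               dt: float = 0.05,
                               seed: int = 0) -> SimulatedRecording:
    """Simulate a cycle-driven LIF neuron with threshold-reset spiking.

    Parameters
    ----------
    params : NeuronModelParams
    duration : float
        Total simulated time (s); must cover at least one cycle.
    dt : float
        Integration step (ms); must satisfy dt <= tau_m / 10.
    seed : int
        Seed for the noise generator; same seed + params reproduce the
        output bit-identically.

    Returns
    -------
    SimulatedRecording
        Vm trace with stylized spikes pasted in (1 ms linear rise from the
        instantaneous threshold to ``spike_peak``, exponential
        repolarization to reset), plus per-spike ground truth.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    if dt > 0.1 * params.membrane_time_constant:
        raise ValueError("dt must be <= membrane_time_constant / 10")
    if duration < params.cycle_period:
        raise ValueError("duration must cover at least one cycle")

    rng = np.random.default_rng(seed)
    dt_s = dt * 1e-3
    n = int(round(duration / dt_s))
    t = np.arange(n) * dt_s
    p = params

    active, i_drive = _cycle_drive(t, p)
    noise = _ou_current(n, p.current_noise_sd, p.noise_correlation_tau,
                        dt, rng)
    noise = np.where(active, noise, noise * p.interburst_noise_fraction)
    leak_target = np.where(
        active, p.resting_potential,
        p.resting_potential - p.interburst_hyperpolarization)

    rise_steps = max(1, int(round(p.spike_rise_ms / dt)))
    refr_steps = max(rise_steps + 1, int(round(p.refractory_period / dt)))
    rep_tau = p.spike_repolarization_tau

    vm = np.empty(n)
    v = p.resting_potential
    adapt = 0.0
    alpha = dt / p.membrane_time_constant
    decay_adapt = np.exp(-dt / p.threshold_recovery_tau)
    rm = p.membrane_resistance

    spike_peak_idx: list[int] = []
    onset_idx: list[int] = []
    thr_at_spike: list[float] = []

    i = 0
    while i < n:
        theta = p.spike_threshold + adapt
        v = v + alpha * (leak_target[i] - v + rm * (i_drive[i] + noise[i]))
        if v >= theta:
            # threshold crossing: paste stylized waveform; a spike whose
            # rise would be cut off by the trace end is not recorded
            end = min(n, i + refr_steps)
            record = i + rise_steps <= n
            if record:
                onset_idx.append(i)
                thr_at_spike.append(theta)
            k = np.arange(i, end) - i
            wave = np.where(
                k < rise_steps,
                theta + (p.spike_peak - theta) * (k + 1) / rise_steps,
                p.reset_potential + (p.spike_peak - p.reset_potential)
                * np.exp(-(k - rise_steps + 1) * dt / rep_tau))
            vm[i:end] = wave
            if record:
                spike_peak_idx.append(i + rise_steps - 1)
            adapt = (adapt + p.threshold_adaptation_increment) \
                * decay_adapt ** (end - i)
            v = vm[end - 1] if end > i else p.reset_potential
            v = max(v, p.reset_potential)
            i = end
        else:
            vm[i] = v
            adapt *= decay_adapt
            i += 1

    fs = 1.0 / dt_s
    label = "fluctuation" if p.is_fluctuation_driven else "mean"
    return SimulatedRecording(
        vm=vm, sampling_rate=fs,
        true_spike_times=np.asarray(spike_peak_idx) * dt_s,
        true_onset_times=np.asarray(onset_idx) * dt_s,
        true_threshold_per_spike=np.asarray(thr_at_spike),
        regime_label=label, params=p, seed=seed)


def simulate_hazard_neuron(c: float, beta: float, duration: float,
                           dt: float = 0.1, vm_mean: float = -60.0,
                           vm_sd: float = 3.0, vm_tau_ms: float = 30.0,
                           seed: int = 0) -> SimulatedRecording:
    """Inhomogeneous-Poisson neuron with a programmed exponential hazard.

    The subthreshold Vm is a stationary OU process (mean ``vm_mean``, SD
    ``vm_sd``, correlation time ``vm_tau_ms``); in each time step a spike is
    emitted with probability nu(Vm) * dt where nu(V) = c * exp(beta * V).
    Spikes are point events (the trace is left untouched), which makes the
    recording an exact test bed for the stochastic-intensity estimator.

    Parameters are (c in Hz, beta in 1/mV).
    """
    rng = np.random.default_rng(seed)
    dt_s = dt * 1e-3
    n = int(round(duration / dt_s))
    vm = vm_mean + _ou_current(n, vm_sd, vm_tau_ms, dt, rng)
    hazard = c * np.exp(beta * vm) * dt_s
    spikes = rng.random(n) < hazard
    times = np.nonzero(spikes)[0] * dt_s
    return SimulatedRecording(
        vm=vm, sampling_rate=1.0 / dt_s, true_spike_times=times,
        true_onset_times=times, true_threshold_per_spike=np.full(times.size,
                                                                 np.nan),
        regime_label="fluctuation", params=None, seed=seed)


# --------------------------------------------------------------------------
# renewal trains and population rasters
# --------------------------------------------------------------------------

def generate_renewal_train(rate: float, duration: float,
                           shape: float = 1.0,
                           seed: int = 0,
                           start: float = 0.0) -> np.ndarray:
    """Gamma renewal spike train.

    ISIs are gamma distributed with the given shape and mean 1/rate; shape 1
    is a Poisson process, ``np.inf`` the exactly periodic limit.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if shape <= 0:
        raise ValueError("shape must be > 0")
    mean_isi = 1.0 / rate
    if np.isinf(shape):
        times = start + np.arange(1, int(np.floor(duration * rate + 1e-9)) + 1
                                  ) * mean_isi
        if times.size == 0:
            warnings.warn("duration shorter than one ISI: empty train")
        return times
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    total = 0.0
    n_guess = max(16, int(duration * rate * 1.5) + 8)
    while total < duration:
        isis = rng.gamma(shape, scale=mean_isi / shape, size=n_guess)
        out.append(isis)
        total += isis.sum()
    times = start + np.cumsum(np.concatenate(out))
    times = times[times <= start + duration]
    if times.size == 0:
        warnings.warn("duration shorter than one ISI: empty train")
    return times


def _phase_locked_cycle_spikes(rate: float, shape: float, spec: PopulationSpec,
                               phase: float, rng: np.random.Generator
                               ) -> np.ndarray:
    """Spike times within [0, cycle_period) for one unit and one cycle.

    Uses time rescaling: a unit-rate gamma renewal process in operational
    time is mapped through the inverse cumulative intensity of a
    raised-cosine bump centred on the unit's preferred phase within the
    active window.
    """
    T = spec.cycle_period
    A = T - spec.interburst_gap
    mass = rate * T                       # expected spikes per cycle
    if mass <= 0:
        return np.empty(0)
    # raised-cosine intensity over the active window, normalized to `mass`
    m = 1000
    u = (np.arange(m) + 0.5) / m          # position within active window
    kappa = spec.phase_concentration
    dens = 1.0 + kappa * np.cos(2 * np.pi * u - phase)
    dens = np.clip(dens, 0.0, None)
    if dens.sum() == 0:
        dens[:] = 1.0
    cum = np.concatenate([[0.0], np.cumsum(dens)])
    cum *= mass / cum[-1]
    # unit-rate gamma renewal in operational time
    n_guess = max(8, int(mass * 2) + 8)
    ops: list[np.ndarray] = []
    tot = 0.0
    while tot < mass:
        isis = rng.gamma(shape, scale=1.0 / shape, size=n_guess)
        ops.append(isis)
        tot += isis.sum()
    op = np.cumsum(np.concatenate(ops))
    op = op[op <= mass]
    # invert the cumulative intensity onto the active window
    pos = np.interp(op, cum, np.arange(m + 1) / m)
    return np.sort(pos * A)


def generate_population_raster(spec: PopulationSpec
                               ) -> tuple[dict[int, np.ndarray], pd.DataFrame]:
    """Simulate a population raster with lognormal per-unit rates.

    Returns
    -------
    raster : dict unit_id -> spike-time array (s)
    units : DataFrame with ground truth per unit: drawn mean rate (Hz, over
        the whole recording), realized rate, preferred phase (rad), gamma
        shape, shank, depth_um.
    """
    rng = np.random.default_rng(spec.seed)
    rates = np.exp(rng.normal(spec.log_rate_mean, spec.log_rate_sd,
                              spec.n_units))
    phases = rng.uniform(0, 2 * np.pi, spec.n_units)
    shapes = np.atleast_1d(np.asarray(spec.gamma_shape, float))
    if shapes.size == 1:
        shapes = np.full(spec.n_units, shapes[0])
    elif shapes.size == 2:
        shapes = rng.choice(shapes, size=spec.n_units)
    elif shapes.size != spec.n_units:
        raise ValueError("gamma_shape must be scalar, a pair, or per-unit")
    shanks = rng.integers(0, spec.n_shanks, spec.n_units)
    depths = rng.uniform(*spec.depth_range, spec.n_units)

    duration = spec.n_cycles * spec.cycle_period
    raster: dict[int, np.ndarray] = {}
    realized = np.zeros(spec.n_units)
    for i in range(spec.n_units):
        parts = []
        for cyc in range(spec.n_cycles):
            s = _phase_locked_cycle_spikes(rates[i], shapes[i], spec,
                                           phases[i], rng)
            parts.append(s + cyc * spec.cycle_period)
        times = np.concatenate(parts) if parts else np.empty(0)
        raster[i] = times
        realized[i] = times.size / duration

    units = pd.DataFrame({
        "unit_id": np.arange(spec.n_units),
        "rate_hz": rates,
        "realized_rate_hz": realized,
        "phase_rad": phases,
        "gamma_shape": shapes,
        "shank": shanks,
        "depth_um": depths,
    })
    return raster, units


# --------------------------------------------------------------------------
# extracellular amplitude maps
# --------------------------------------------------------------------------

def generate_amplitude_map(source_xy_um: tuple[float, float],
                           strength: float,
                           geometry: ProbeGeometry,
                           shank: int = 0,
                           noise_sd_uV: float = 0.0,
                           seed: int = 0) -> AmplitudeMap:
    """Per-electrode mean spike amplitudes under inverse-square decay.

    Amplitude on electrode j is S / r_j^2 + Gaussian noise, rectified at 0;
    distances are clamped at 1 um so a source may sit on an electrode.
    """
    rng = np.random.default_rng(seed)
    pos = geometry.electrode_positions(shank)
    r = np.hypot(pos[:, 0] - source_xy_um[0], pos[:, 1] - source_xy_um[1])
    r = np.maximum(r, 1.0)
    amps = strength / r ** 2
    if noise_sd_uV > 0:
        amps = amps + rng.normal(0.0, noise_sd_uV, amps.size)
    amps = np.clip(amps, 0.0, None)
    return AmplitudeMap(amplitudes_uV=amps, shank=shank,
                        noise_sd_uV=noise_sd_uV,
                        true_position_um=tuple(source_xy_um),
                        true_strength=strength)


# --------------------------------------------------------------------------
# text I/O for simulated objects
# --------------------------------------------------------------------------

def write_recording(rec: SimulatedRecording, trace_path, truth_path=None
                    ) -> None:
    """Write a Vm trace as two-column text (time_s, vm_mV) and the ground
    truth as a JSON sidecar."""
    arr = np.column_stack([rec.times, rec.vm])
    np.savetxt(trace_path, arr, fmt="%.6f\t%.4f",
               header="time_s\tvm_mV", comments="")
    if truth_path is not None:
        truth = {
            "true_spike_times": rec.true_spike_times.tolist(),
            "true_onset_times": rec.true_onset_times.tolist(),
            "true_threshold_per_spike": rec.true_threshold_per_spike.tolist(),
            "regime_label": rec.regime_label,
            "sampling_rate": rec.sampling_rate,
            "seed": rec.seed,
            "params": asdict(rec.params) if rec.params else None,
        }
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)


def write_raster(raster: dict[int, np.ndarray], path) -> None:
    """Write spike times as two-column text (unit_id, time_s)."""
    rows = [(u, t) for u, times in raster.items() for t in times]
    df = pd.DataFrame(rows, columns=["unit_id", "time_s"])
    df.sort_values(["unit_id", "time_s"]).to_csv(path, sep="\t", index=False)


def read_raster(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path, sep=None, engine="python")
    return {int(u): np.sort(g["time_s"].to_numpy(float))
            for u, g in df.groupby("unit_id")}
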