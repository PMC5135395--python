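# regimescope

Analysis toolkit for classifying neuronal spiking into **fluctuation-driven**
and **mean-driven** regimes and quantifying how much of a recorded population
occupies each, aimed at electrophysiologists working with intracellular
membrane-potential (Vm) recordings and multi-electrode population rasters
from rhythmically active networks (e.g. spinal motor circuits).

## The two regimes

A neuron receiving mean input current $I_m$ through membrane resistance
$R_m$ is **mean-driven** when $R_m I_m > V_{thres} - V_{rest}$: the drive
alone carries Vm across threshold, spiking is paced by the
after-hyperpolarization, ISIs are regular and the firing-rate distribution
symmetric. It is **fluctuation-driven** when $R_m I_m < V_{thres} -
V_{rest}$: spikes are triggered by synaptic transients riding on a
subthreshold Gaussian Vm, ISIs are irregular and the rate distribution
skewed/lognormal. The package implements the metrics that separate the two
from data:

- **CV2** — local ISI irregularity, $CV_2(i) = 2|ISI_i - ISI_{i+1}| /
  (ISI_i + ISI_{i+1}) \in [0, 2]$; 0 for clock-like firing, 1 for Poisson.
- **Return map ratio (RMR)** — fraction of lagged inter-spike Vm pairs
  $(V_m(t), V_m(t+\Delta t))$, $\Delta t = 1.5$ ms, above the unity line;
  $\approx 0.5$ for a fluctuating path, $\to 1$ for a straight climb from
  reset to threshold; neurons with RMR < 0.7 classify as
  fluctuation-driven.
- **FV-curve (stochastic intensity)** — empirical firing rate as a function
  of Vm: pre-spike Vm counts divided by residence time per Vm bin, with
  exponential $\nu(V) = c\,e^{\beta V}$ and power-law
  $\nu(V) = k\,(V - E_a)^\alpha$ fits.
- **Phase-plane threshold** — per-spike threshold as the maximum of
  $d^2 f / dV_m^2$ along the trajectory $f = dV_m/dt$ vs $V_m$, after 5 kHz
  low-pass filtering.
- **TIF50 / SIF50** — population occupancy: the normalized time (or spike)
  fraction with $CV_2 > i_{crit}$ attained by at least half the units, read
  off the 50% crossing of the reverse cumulative distribution
  $F(t) = 1 - \int_0^t f(t')\,dt'$ (default $i_{crit} = 0.5$).
- **Lorenz/Gini** — participation inequality of firing rates,
  $Gini = 1 - 2b$ with $b$ the area under the Lorenz curve.
- **Trilateration** — 2D source localization from per-electrode spike
  amplitudes under inverse-square decay $A_j = S / r_j^2$.

A seedable synthetic-data module generates ground-truth-labelled Vm traces
(leaky integrate-and-fire with cycle-modulated drive and OU current noise,
stylized spike waveforms, adaptive threshold), gamma-renewal trains,
lognormal population rasters, and probe amplitude maps, so every analysis
stage is testable without recordings.

## Worked example

```python
import regimescope as rs

# a fluctuation-driven neuron: subthreshold drive + synaptic noise
p = rs.NeuronModelParams(membrane_time_constant=6.0, mean_input_current=0.10,
                         current_noise_sd=0.055, cycle_duty_fraction=1.0)
rec = rs.simulate_two_regime_neuron(p, duration=30.0, dt=0.05, seed=1)

trace = rs.VmTrace(rec.vm, rec.sampling_rate)
peaks = rs.detect_spike_peaks(trace)
spikes = rs.estimate_thresholds_phase_plane(trace, peaks)
rmr = rs.return_map_ratio(trace, spikes.peak_times)
seq = rs.cv2_sequence(spikes.peak_times)
tbt = rs.time_below_threshold(trace, spikes.most_hyperpolarized_threshold)

print(f"{peaks.size} spikes, regime: {rec.regime_label}")
print(f"mean threshold: {spikes.mean_threshold:.1f} mV (programmed -45.0)")
print(f"return map ratio: {rmr:.2f}  -> fluctuation-driven: {rmr < 0.7}")
print(f"mean CV2: {seq.mean():.2f}")
print(f"time below threshold: {tbt:.2f}")
```

Output:

```
337 spikes, regime: fluctuation
mean threshold: -45.3 mV (programmed -45.0)
return map ratio: 0.52  -> fluctuation-driven: True
mean CV2: 0.93
time below threshold: 0.96
```

The phase-plane estimator recovers the programmed -45 mV threshold to a
few tenths of a millivolt; the RMR near 0.5 and mean CV2 near 1 mark the
neuron as fluctuation-driven, and the smoothed Vm sits below threshold 96%
of the time — all consistent with the subthreshold drive it was built with.

There is also a CLI:

```bash
regimescope simulate neuron --seed 1 --duration 10 --out sim/
regimescope intracell --trace sim/trace.tsv --out results/
regimescope simulate raster --seed 2 --out pop/
regimescope population --raster pop/raster.tsv --meta pop/units.tsv --out report/
```

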