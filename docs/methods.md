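# Methods

## Scope

regimescope implements the analysis chain that classifies single-neuron
spiking into fluctuation- vs mean-driven regimes and quantifies population
occupancy of those regimes: intracellular Vm analytics (spike/threshold
detection, subthreshold distributions, return map ratio, time below
threshold, FV-curves), spike-train statistics (CV2, rate distributions,
kernel rates), population statistics (pooled lognormal rates, Lorenz/Gini,
TIF50/SIF50, time-resolved log-skewness, depth profiles), and
inverse-square trilateration of extracellular sources. A synthetic-data
module supplies ground-truth-labelled inputs for all of it.

## Synthetic data

### Two-regime neuron

A leaky integrate-and-fire neuron,

    tau_m dV/dt = -(V - V_rest) + R_m (I_drive(t) + I_noise(t)),

with threshold-reset spiking. `I_drive` is the mean current `Im` gated by a
motor-cycle envelope (period `cycle_period`, active fraction
`cycle_duty_fraction`, optional half-sine modulation); during the
interburst phase the leak target is hyperpolarized by
`interburst_hyperpolarization` (default 5 mV) and the noise attenuated,
emulating the quiescence between burst cycles. `I_noise` is an
Ornstein-Uhlenbeck current with stationary SD `current_noise_sd` and a 5 ms
correlation time. An OU process rather than white noise makes the voltage
variance well-defined independently of the integration step: synaptic
bombardment has a finite correlation time, and with white-noise current the
simulated sigma_V would change with dt. Gaussian current noise is the
appropriate model because summed synaptic input is Gaussian by the central
limit theorem; conductance-based E/I is deliberately not simulated —
disinhibition-type manipulations are emulated by raising `Im`.

The regime label is derived from the parameters: fluctuation-driven iff
`Rm * Im < spike_threshold - resting_potential` (peak mean drive stays
subthreshold).

Spikes are stylized: on crossing the (possibly adapted) threshold the
waveform rises linearly over 1 ms to +20 mV, then repolarizes
exponentially (tau = 0.6 ms) toward the reset for the remainder of the
refractory period. The linear rise gives the phase-plane threshold
estimator a realistic acceleration profile while keeping the programmed
threshold exactly known. A crossing whose rise would be cut off by the end
of the trace is not recorded as a spike. Threshold adaptation is
increment-and-decay: each spike adds `threshold_adaptation_increment`
(default 0, i.e. off) to the threshold, which recovers exponentially with
`threshold_recovery_tau`; this reproduces the rate-dependent threshold
depolarization attributed to Na+ channel inactivation.

Default integration step dt = 0.05 ms (20 kHz, intracellular-grade
sampling). The default membrane time constant is 20 ms; tests that probe
properties of the *active network state* (agreement of temporal and
spike-triggered Vm distributions, pre-spike sigma skewness) use 6 ms,
reflecting the high synaptic conductance of a neuron embedded in an active
network — that choice is what makes the Vm decorrelate over the 18 ms
pre-spike lag, as the sigma estimator assumes.

### Hazard neuron

For validating the FV estimator, `simulate_hazard_neuron` draws a
stationary OU voltage (no reset) and emits spikes as an inhomogeneous
Poisson process with programmed hazard nu(V) = c exp(beta V). Because the
trace is untouched by spiking, the estimator's output can be compared
bin-wise to the programmed hazard.

### Population rasters

Per-unit mean rates are drawn lognormally (defaults: log-mean 2 log Hz,
log-SD 1, matching a rate distribution spanning roughly two decades).
Within each cycle a unit fires as a gamma renewal process (shape 1 =
Poisson-like, large shape = regular) warped by time rescaling through a
raised-cosine intensity centred on the unit's preferred phase inside the
active window, giving phase-locked bursts separated by a configurable
interburst gap (default 0.4 s of a 1 s cycle). Ground truth (drawn rate,
phase, shape, shank, depth) is returned alongside.

### Amplitude maps

The probe is 8 shanks x 8 electrodes (200 um pitch, 30 um vertical
spacing, alternating 11 um lateral stagger). Amplitude on electrode j is
S / r_j^2 plus Gaussian noise, rectified at zero; distances are clamped at
1 um.

## Intracellular estimators

**Spike peaks** are local maxima above a height threshold (default -10 mV)
with a minimum separation (1 ms), via standard peak picking.

**Phase-plane threshold.** The trace is low-pass filtered at 5 kHz before
differentiation. A Bessel filter is used because its monotone step
response does not ring at the sharp spike onset; ringing would inject
spurious local minima exactly where the curvature maximum is sought. For
each spike, within a 10 ms pre-peak window, the trajectory is anchored at
the most hyperpolarized sample, resampled onto a strictly increasing Vm
grid with a 0.2 mV minimum spacing (regularizing the finite differences
where Vm hovers), and truncated just past the point of maximal dV/dt
(beyond it the phase-plane curvature reflects the spike apex, not its
onset). The threshold is the Vm at the maximum of d^2 f / dVm^2 along this
trajectory, f = dVm/dt. On simulated 20 kHz traces the estimator recovers
a programmed non-adaptive threshold to ~0.2 mV on average. Per-spike
summary statistics include the mean, the most hyperpolarized value, and
the 5% quantile Vthres,Q5.

**Subthreshold distributions.** The spike-triggered ("sigma") distribution
samples Vm exactly 18 ms before each spike peak, over spikes whose
preceding ISI lies in (20 ms, 300 ms). The temporal distribution pools all
inter-spike samples for ISIs in (6 ms, 300 ms) with ±6 ms excised around
each peak. Skewness uses the moment estimator
(1/N) sum(((x - mean)/sd)^3) with the sample SD; degenerate cases (n < 3
or zero SD) report 0 with a flag rather than erroring.

**Return map ratio.** Over retained inter-spike segments (±6 ms spike
excision; segments spanning ISIs > 300 ms removed as interburst), pairs
(Vm(t), Vm(t + 1.5 ms)) are counted above vs below the unity line; exact
ties are split evenly, which is unbiased for quantized Vm. The ratio is in
[0, 1], equals 1 exactly for monotone climbs, complements under time
reversal, and sits at 0.5 for stationary symmetric noise. Neurons with
RMR < 0.7 classify as fluctuation-driven.

**Time below threshold** smooths Vm with a 20 ms moving average (the
smoothing choice is free; a moving average is the simplest symmetric
kernel) and reports the fraction of samples strictly below the reference
threshold (by convention the most hyperpolarized per-spike threshold).

**FV-curve.** Pre-spike Vm is sampled one `pre_lag` before each peak
(default 1.7 ms; the definition admits 1.5–1.7 ms, so the lag is an
exposed parameter), over spikes with preceding ISI > 1.7 ms. Counts per
0.5 mV bin are divided by the total residence time of the trace in that
bin; this estimates the stochastic intensity nu(V) = P(V)/dt. Bins never
visited are excluded. Fits: exponential nu = c exp(beta V) and power law
nu = k (V - Ea)^alpha (bounds keep Ea below all fitted Vm and alpha in
[0.1, 12]), by unweighted nonlinear least squares. Only bins with at least
`min_residence_s` (default 0.05 s) of residence enter the fits: a bin
visited for a handful of samples has a rate estimate with unbounded
relative error and would otherwise dominate. A log-domain fit
(linear regression of log nu on V) is available and preferred when bin
errors are multiplicative, as they are for Poisson counts over widely
varying residence times; the hazard-recovery validation uses it. Recovery
of a programmed beta carries a small attenuation from the 1.7 ms lag
(the Vm autocorrelation over the lag multiplies the recovered exponent),
which stays well inside 20% for correlation times of tens of ms.

## Spike-train statistics

CV2 sequences follow the adjacent-pair formula; each value carries the
time span (ISI_i + ISI_{i+1})/2 it represents and a mask marking pairs
that touch an interburst ISI. Two interburst thresholds coexist by design:
0.5 s for cycle-restricted CV2 statistics and 0.3 s for Vm-linked rate
statistics. Instantaneous rates are 1/ISI with interburst ISIs excluded;
log statistics use natural logs (base only rescales the log-SD and leaves
skewness unchanged).

Kernel firing rates convolve spikes with a Gaussian kernel evaluated on a
grid at bandwidth/10, truncated at ±5 bandwidths, so the integral equals
the spike count to numerical precision. Automatic bandwidth selection
minimizes the cross-validated mean integrated squared error
(Shimazaki–Shinomoto fixed-kernel cost, closed form for Gaussians) over a
log grid from 1 ms to 1 s; above 3000 spikes the pairwise cost is
evaluated on a 3000-spike subsample for selection only. For a homogeneous
train the optimum correctly runs to the top of the range; strong
modulation pulls it down to the burst timescale.

## Population statistics

Regime occupancy weights each CV2 value by its span for the time fraction
and counts each value once (its middle spike) for the spike fraction;
span-weighting avoids the double counting that overlapping-ISI
alternatives would introduce. The reverse cumulative F(t) is the fraction
of units with occupancy >= t. Its 50% crossing (TIF50/SIF50) is obtained
by linear interpolation through the Hazen plotting positions
((n - k + 0.5)/n at the k-th ordered value), which makes the crossing
coincide exactly with the sample median — the stepwise empirical curve
would otherwise make the crossing non-unique. TIF50 is non-increasing in
icrit by construction; the icrit grid {0.4, 0.5, 0.6} brackets the
suggested 0.5.

Pooled rates are spike counts over episode windows divided by window
duration, with silent units excluded and counted. Lognormal fits use
moments of the log rates. The Lorenz curve sorts rates ascending and
cumulates shares; Gini = 1 - 2b with b by the trapezoidal rule (equal
rates give 0 to machine precision; the statistic is scale-invariant and
increases under poor-to-rich transfers).

Time-resolved log-skewness samples each unit's kernel rate on a 10 ms bin
grid, keeps bins with at least 10 units above a rate floor, and tracks the
across-unit log-rate mean, SD and skewness per bin; the Pearson
correlation between log-mean and log-skewness across bins is the summary.
With only tens of units the per-bin sample skewness of noisy kernel
estimates couples weakly to the sample mean even without modulation, so
null checks use bandwidths wide enough (~0.2 s) that per-unit estimates
average over many spikes.

Depth profiles bin units by corrected depth (insertion depth minus fitted
local y) and compare CV2 distributions between bins with two-sample
Kolmogorov–Smirnov tests; bins under 5 units are skipped. The null
calibration property is framed as a false-positive rate: across
depth-independent simulations, pairwise KS tests reject at no more than
the nominal level. (Requiring *every* pairwise p to exceed 0.05
simultaneously would fail by chance alone once many bins are tested.)

## Trilateration

The 2D fit minimizes sum_j (S / max(r_j^2, 1) - A_j)^2 over (x, y, log S),
multi-started around the three highest-amplitude electrodes and bounded to
±400 um around the shank (beyond that the signal is below noise and the
problem diverges). The fit is in the sagittal shank plane; out-of-plane
distance is absorbed into S, so S is an effective strength. Noiseless
inverse-square maps are recovered to well under 1 um; at 10% amplitude
noise the median position error is ~11 um over 100 draws. Absolute depth
is insertion depth minus fitted y (y = 0 at the deepest electrode).
Amplitude is taken as the trough-to-peak of the mean waveform; a unit is
localized on its single best shank.

## Pipeline

`AnalysisConfig` collects every tunable (lags, excision windows, ISI
filters, icrit grid, bin widths, smoothing, seeds) and round-trips
losslessly through JSON; a config hash enters the report provenance.
`run_pipeline` isolates stage failures (a corrupt trace yields a recorded
stage error, other stages complete) and is byte-deterministic given seeds.
Correlations are Pearson product-moment with two-sided p; constant columns
are flagged undefined rather than raised.

## Problem sizes

Validation simulations are sized for tight statistics at interactive
runtimes: 1000 s renewal trains for CV2 anchors (~10^4 ISI pairs), 10^5
retained pairs for the return-map noise anchor, 300 s hazard simulations
(~2300 spikes) for FV recovery, 60 s two-regime traces (>= 100 spikes)
for threshold recovery, 100-draw Monte Carlo for trilateration noise, and
rasters of 40–200 units over 20 cycles for population statistics.

## Known limitations

- The neuron model is a point LIF with pasted waveforms: no conductance
  dynamics, no dendritic filtering, no electrotonically distant initiation
  site. Passing tests show the estimators recover what the model programs,
  not that the model captures every feature of real recordings.
- The stylized spike onset is a sharp kink; real onsets are smoother, so
  real-data threshold estimates inherit more smoothing sensitivity than
  the simulations exhibit.
- The FV estimator assumes renewal (Poisson-like) spiking; adaptation or
  bursting distorts the recovered hazard.
- Trilateration is 2D per shank under an exact 1/r^2 decay; tissue
  anisotropy and waveform-shape variation across electrodes are not
  modelled.
- Population rasters draw units independently; common-input correlations
  between units are not emulated.
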