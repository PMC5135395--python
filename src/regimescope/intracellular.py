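"""Single-cell membrane-potential analytics.

Implements the intracellular half of the regime classification: spike peak
detection, phase-plane threshold estimation, subthreshold Vm distributions
(spike-triggered and temporal), the return-map ratio, time below threshold,
and the empirical FV-curve (stochastic intensity, firing rate as a function
of Vm) with exponential and power-law fits.

All ISI-based exclusion rules are pure filters: a result depends only on the
samples each rule retains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal
from scipy.ndimage import uniform_filter1d

from .spike_metrics import skewness

DEFAULT_RMR_LAG_MS = 1.5
DEFAULT_RMR_CUTOFF = 0.7
DEFAULT_EXCISION_MS = 6.0
DEFAULT_INTERBURST_MS = 300.0
DEFAULT_SIGMA_LAG_MS = 18.0
DEFAULT_PRESPIKE_LAG_MS = 1.7
DEFAULT_FV_BIN_MV = 0.5


@dataclass
class VmTrace:
    """Uniformly sampled membrane potential."""

    samples: np.ndarray          # mV
    sampling_rate: float         # Hz
    start_time: float = 0.0      # s

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Vm samples must be finite")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) * self.dt

    def index_of(self, t: float) -> int:
        return int(round((t - self.start_time) * self.sampling_rate))


@dataclass
class SpikeEvents:
    """Detected spikes with per-spike phase-plane threshold estimates."""

    peak_times: np.ndarray
    onset_times: np.ndarray
    threshold_mV: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, float)
        self.onset_times = np.asarray(self.onset_times, float)
        self.threshold_mV = np.asarray(self.threshold_mV, float)
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.peak_times.size

    @property
    def mean_threshold(self) -> float:
        return float(np.mean(self.threshold_mV)) if self.n else np.nan

    @property
    def most_hyperpolarized_threshold(self) -> float:
        return float(np.min(self.threshold_mV)) if self.n else np.nan

    @property
    def threshold_q5(self) -> float:
        """5%-quantile of the per-spike thresholds (Vthres,Q5)."""
        return float(np.quantile(self.threshold_mV, 0.05)) if self.n \
            else np.nan


@dataclass
class VmDistribution:
    """Histogram summary of subthreshold Vm samples."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    skewness: float
    estimator_kind: str          # "spike_triggered" | "temporal"
    n: int
    low_n: bool = False
    degenerate: bool = False


@dataclass
class FVCurve:
    """Empirical firing rate as a function of Vm (stochastic intensity)."""

    vm_bin_centers: np.ndarray
    residence_time_s: np.ndarray
    pre_spike_counts: np.ndarray
    rate_hz: np.ndarray
    sampling_interval_s: float
    exp_fit: dict | None = None        # {"c": Hz, "beta": 1/mV, "converged"}
    power_fit: dict | None = None      # {"k", "alpha", "Ea", "converged"}


@dataclass
class RegimeMetrics:
    """Intracellular regime indicators for one neuron."""

    return_map_ratio: float
    fraction_time_below_threshold: float
    rmr_cutoff: float = DEFAULT_RMR_CUTOFF

    @property
    def is_fluctuation_driven(self) -> bool:
        return self.return_map_ratio < self.rmr_cutoff


# --------------------------------------------------------------------------
# spike detection
# --------------------------------------------------------------------------

def detect_spike_peaks(trace: VmTrace, min_height: float = -10.0,
                       min_separation_ms: float = 1.0) -> np.ndarray:
    """Spike peak times: local maxima above ``min_height`` (mV) separated by
    at least ``min_separation_ms``; the larger peak wins a conflict."""
    dist = max(1, int(round(min_separation_ms * 1e-3 * trace.sampling_rate)))
    idx, _ = signal.find_peaks(trace.samples, height=min_height,
                               distance=dist)
    return trace.start_time + idx / trace.sampling_rate


# --------------------------------------------------------------------------
# phase-plane threshold estimation
# --------------------------------------------------------------------------

def _lowpass(v: np.ndarray, fs: float, cutoff_hz: float = 5000.0
             ) -> np.ndarray:
    if fs <= 2.0 * cutoff_hz:
        return v
    # Bessel: monotone step response, so the sharp spike onset does not ring
    b, a = signal.bessel(4, cutoff_hz / (fs / 2.0))
    return signal.filtfilt(b, a, v)


def estimate_thresholds_phase_plane(trace: VmTrace, peak_times: np.ndarray,
                                    search_window_ms: float = 10.0,
                                    lowpass_hz: float = 5000.0
                                    ) -> SpikeEvents:
    """Per-spike threshold from the Vm phase plane.

    The trace is low-pass filtered (5 kHz), the slope f = dVm/dt computed,
    and for each spike the threshold taken as the Vm of the largest peak of
    d2f/dVm2 along the final monotone upstroke before the peak — the point
    of strongest acceleration away from baseline.  Spikes whose search
    window falls off the start of the trace are dropped with a warning.
    """
    peak_times = np.asarray(peak_times, float)
    if peak_times.size == 0:
        raise ValueError("need at least one spike")
    fs = trace.sampling_rate
    v = _lowpass(trace.samples, fs, lowpass_hz)
    f = np.gradient(v) * fs * 1e-3          # mV/ms
    win = max(4, int(round(search_window_ms * 1e-3 * fs)))

    kept_peaks, onsets, thresholds = [], [], []
    for tp in peak_times:
        pk = trace.index_of(tp)
        if pk - win < 0:
            warnings.warn("spike too close to trace start; dropped")
            continue
        seg = slice(pk - win, pk + 1)
        vv, ff = v[seg], f[seg]
        # approach + upstroke: anchor at the most hyperpolarized point of
        # the window so the baseline ahead of the acceleration is part of
        # the trajectory; without it the curvature at the foot is one-sided
        i0 = int(np.argmin(vv[:-3]))
        vs, fsg = vv[i0:], ff[i0:]
        # increasing Vm grid with a minimum spacing: regularizes the
        # finite differences where Vm hovers during the approach
        dv_min = 0.2
        keep = [0]
        for j in range(1, vs.size):
            if vs[j] > vs[keep[-1]] + dv_min:
                keep.append(j)
        keep = np.asarray(keep)
        vk, fk = vs[keep], fsg[keep]
        # search only up to the point of maximal dVm/dt: beyond it the
        # phase-plane curvature reflects the spike apex, not its onset
        stop = min(int(np.argmax(fk)) + 2, fk.size)
        if stop < 4:
            warnings.warn("upstroke too short for phase-plane estimate; "
                          "spike dropped")
            continue
        vk, fk = vk[:stop], fk[:stop]
        d2f = np.gradient(np.gradient(fk, vk), vk)
        # exclude the trailing boundary point: its one-sided difference
        # duplicates the interior curvature and can tie with it
        j = int(np.argmax(d2f[:-1]))
        thresholds.append(float(vk[j]))
        onset_idx = pk - win + i0 + int(keep[j])
        onsets.append(trace.start_time + onset_idx / fs)
        kept_peaks.append(tp)

    if not kept_peaks:
        raise ValueError("no spike yielded a threshold estimate")
    return SpikeEvents(peak_times=np.asarray(kept_peaks),
                       onset_times=np.asarray(onsets),
                       threshold_mV=np.asarray(thresholds))


# --------------------------------------------------------------------------
# subthreshold distributions
# --------------------------------------------------------------------------

def _make_distribution(samples: np.ndarray, kind: str, bin_mv: float = 0.5,
                       low_n_at: int = 10) -> VmDistribution:
    samples = np.asarray(samples, float)
    n = samples.size
    if n == 0:
        raise ValueError("no retained samples")
    lo = np.floor(samples.min() / bin_mv) * bin_mv
    hi = np.ceil(samples.max() / bin_mv) * bin_mv
    nb = max(1, int(round((hi - lo) / bin_mv)))
    counts, edges = np.histogram(samples, bins=nb, range=(lo, hi + 1e-12))
    sd = float(np.std(samples, ddof=1)) if n > 1 else 0.0
    sk, degenerate = skewness(samples, flag_degenerate=True)
    return VmDistribution(bin_edges=edges, counts=counts,
                          mean=float(samples.mean()), sd=sd, skewness=sk,
                          estimator_kind=kind, n=n, low_n=n < low_n_at,
                          degenerate=degenerate)


def spike_triggered_distribution(trace: VmTrace, spikes: SpikeEvents,
                                 lag_ms: float = DEFAULT_SIGMA_LAG_MS,
                                 min_isi_ms: float = 20.0,
                                 max_isi_ms: float = DEFAULT_INTERBURST_MS,
                                 ) -> VmDistribution:
    """Distribution of Vm one fixed lag (default 18 ms) before each spike
    peak, over spikes whose preceding ISI lies in (min_isi, max_isi)."""
    pk = spikes.peak_times
    isi = np.diff(pk)
    ok = np.nonzero((isi > min_isi_ms * 1e-3) & (isi < max_isi_ms * 1e-3))[0] + 1
    samples = []
    for i in ok:
        j = trace.index_of(pk[i] - lag_ms * 1e-3)
        if 0 <= j < trace.samples.size:
            samples.append(trace.samples[j])
    return _make_distribution(np.asarray(samples), "spike_triggered")


def temporal_distribution(trace: VmTrace, spikes: SpikeEvents,
                          min_isi_ms: float = 6.0,
                          max_isi_ms: float = DEFAULT_INTERBURST_MS,
                          excision_ms: float = DEFAULT_EXCISION_MS
                          ) -> VmDistribution:
    """Distribution of inter-spike Vm over time.

    Only segments between consecutive spikes with min_isi < ISI < max_isi
    contribute, with ``excision_ms`` around each peak removed.
    """
    samples = []
    for seg in _retained_segments(trace, spikes.peak_times, excision_ms,
                                  max_isi_ms, min_isi_ms):
        samples.append(trace.samples[seg])
    if not samples:
        raise ValueError("no retained inter-spike samples")
    return _make_distribution(np.concatenate(samples), "temporal")


def _retained_segments(trace: VmTrace, peak_times: np.ndarray,
                       excision_ms: float, interburst_ms: float,
                       min_isi_ms: float = 0.0) -> list[slice]:
    """Inter-spike index slices after spike excision and interburst removal.

    With no spikes the whole trace is one segment.
    """
    n = trace.samples.size
    pk = np.asarray(peak_times, float)
    if pk.size == 0:
        return [slice(0, n)]
    exc = int(round(excision_ms * 1e-3 * trace.sampling_rate))
    out = []
    for a, b in zip(pk[:-1], pk[1:]):
        isi_ms = (b - a) * 1e3
        if isi_ms > interburst_ms or isi_ms <= min_isi_ms:
            continue
        i0 = trace.index_of(a) + exc + 1
        i1 = trace.index_of(b) - exc
        if i1 > i0:
            out.append(slice(max(0, i0), min(n, i1)))
    return out


# --------------------------------------------------------------------------
# return map ratio
# --------------------------------------------------------------------------

def return_map_ratio(trace: VmTrace,
                     peak_times: np.ndarray | None = None,
                     lag_ms: float = DEFAULT_RMR_LAG_MS,
                     excision_ms: float = DEFAULT_EXCISION_MS,
                     interburst_ms: float = DEFAULT_INTERBURST_MS) -> float:
    """Fraction of lagged Vm pairs above the unity line.

    Over every retained inter-spike segment, pairs (Vm(t), Vm(t+lag)) are
    classified as above (Vm rose) or below (Vm fell) the unity line; exact
    ties are split evenly.  A value near 1 means a straight climb from reset
    to threshold (mean-driven); near 0.5, a fluctuating path.
    """
    pk = np.empty(0) if peak_times is None else np.asarray(peak_times, float)
    L = max(1, int(round(lag_ms * 1e-3 * trace.sampling_rate)))
    above = below = ties = 0
    for seg in _retained_segments(trace, pk, excision_ms, interburst_ms):
        v = trace.samples[seg]
        if v.size <= L:
            continue
        d = v[L:] - v[:-L]
        above += int(np.sum(d > 0))
        below += int(np.sum(d < 0))
        ties += int(np.sum(d == 0))
    total = above + below + ties
    if total == 0:
        raise ValueError("no retained Vm pairs for the return map")
    return (above + 0.5 * ties) / total


# --------------------------------------------------------------------------
# time below threshold
# --------------------------------------------------------------------------

def time_below_threshold(trace: VmTrace, threshold_mV: float,
                         smoothing_window_ms: float = 20.0) -> float:
    """Fraction of time the smoothed Vm spends strictly below threshold."""
    if not np.isfinite(threshold_mV):
        raise ValueError("threshold must be finite")
    w = max(1, int(round(smoothing_window_ms * 1e-3 * trace.sampling_rate)))
    sm = uniform_filter1d(trace.samples, size=w, mode="nearest")
    return float(np.mean(sm < threshold_mV))


# --------------------------------------------------------------------------
# FV-curve (stochastic intensity)
# --------------------------------------------------------------------------

def estimate_fv_curve(trace: VmTrace, peak_times: np.ndarray,
                      pre_lag_ms: float = DEFAULT_PRESPIKE_LAG_MS,
                      bin_mv: float = DEFAULT_FV_BIN_MV,
                      min_isi_ms: float = 1.7) -> FVCurve:
    """Firing rate as a function of Vm.

    For each spike (preceding ISI > ``min_isi_ms``; the first spike always
    qualifies) the Vm one ``pre_lag_ms`` before the peak is collected; the
    count per Vm bin is divided by the total residence time of the trace in
    that bin, giving nu(V) in Hz.  Bins the trace never visits are excluded.
    """
    pk = np.asarray(peak_times, float)
    if pk.size == 0:
        raise ValueError("need at least one spike")
    isi_ok = np.concatenate([[True], np.diff(pk) > min_isi_ms * 1e-3])
    idx = np.asarray([trace.index_of(t - pre_lag_ms * 1e-3)
                      for t in pk[isi_ok]])
    idx = idx[(idx >= 0) & (idx < trace.samples.size)]
    pre_v = trace.samples[idx]

    v = trace.samples
    lo = np.floor(v.min() / bin_mv) * bin_mv
    hi = np.ceil(v.max() / bin_mv) * bin_mv
    nb = max(1, int(round((hi - lo) / bin_mv)))
    edges = lo + np.arange(nb + 1) * bin_mv
    res_counts, _ = np.histogram(v, bins=edges)
    spike_counts, _ = np.histogram(pre_v, bins=edges)

    keep = res_counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])[keep]
    res_t = res_counts[keep] * trace.dt
    s_counts = spike_counts[keep]
    return FVCurve(vm_bin_centers=centers, residence_time_s=res_t,
                   pre_spike_counts=s_counts, rate_hz=s_counts / res_t,
                   sampling_interval_s=trace.dt)


def _fit_bins(curve: FVCurve, min_residence_s: float
              ) -> tuple[np.ndarray, np.ndarray]:
    """Bins eligible for fitting: enough residence time that the rate
    estimate is meaningful.  Bins visited for only a handful of samples
    carry rate estimates with unbounded relative error and would otherwise
    dominate an unweighted fit."""
    ok = curve.residence_time_s >= min_residence_s
    return curve.vm_bin_centers[ok], curve.rate_hz[ok]


def fit_fv_exponential(curve: FVCurve, min_residence_s: float = 0.05,
                       log_domain: bool = False) -> dict:
    """Least-squares fit nu(V) = c * exp(beta V); beta in 1/mV, c in Hz.

    ``log_domain`` fits log nu against V by linear regression over the
    positive-rate bins instead.  Stores the result on ``curve.exp_fit``
    and returns it.
    """
    v, nu = _fit_bins(curve, min_residence_s)
    if v.size < 3 or (v.max() - v.min()) < 5.0:
        curve.exp_fit = {"converged": False}
        return curve.exp_fit
    if log_domain:
        pos = nu > 0
        if pos.sum() < 3:
            curve.exp_fit = {"converged": False}
            return curve.exp_fit
        beta, logc = np.polyfit(v[pos], np.log(nu[pos]), 1)
        curve.exp_fit = {"c": float(np.exp(logc)), "beta": float(beta),
                         "converged": True}
        return curve.exp_fit
    pos = nu > 0
    if pos.sum() >= 2:
        b0, loga = np.polyfit(v[pos], np.log(nu[pos]), 1)
        p0 = (float(np.exp(loga)), float(b0))
    else:
        p0 = (1.0, 0.1)
    try:
        popt, _ = optimize.curve_fit(
            lambda x, c, b: c * np.exp(b * x), v, nu, p0=p0, maxfev=20000)
        curve.exp_fit = {"c": float(popt[0]), "beta": float(popt[1]),
                         "converged": True}
    except RuntimeError:
        curve.exp_fit = {"converged": False}
    return curve.exp_fit


def fit_fv_powerlaw(curve: FVCurve, min_residence_s: float = 0.05) -> dict:
    """Least-squares fit nu(V) = k (V - Ea)^alpha with Ea below all fitted V."""
    v, nu = _fit_bins(curve, min_residence_s)
    if v.size < 3 or (v.max() - v.min()) < 5.0:
        curve.power_fit = {"converged": False}
        return curve.power_fit
    vmin = v.min()

    def model(x, k, alpha, ea):
        return k * np.power(np.clip(x - ea, 1e-9, None), alpha)

    best = None
    for ea0 in (vmin - 0.5, vmin - 2.0, vmin - 8.0):
        pos = nu > 0
        if pos.sum() >= 2:
            a0, logk = np.polyfit(np.log(v[pos] - ea0 + 1e-9),
                                  np.log(nu[pos]), 1)
            p0 = (float(np.exp(logk)), float(max(a0, 0.5)), ea0)
        else:
            p0 = (1.0, 2.0, ea0)
        try:
            popt, _ = optimize.curve_fit(
                model, v, nu, p0=p0,
                bounds=([0, 0.1, vmin - 60.0], [np.inf, 12.0, vmin - 1e-6]),
                maxfev=40000)
            resid = float(np.sum((model(v, *popt) - nu) ** 2))
            if best is None or resid < best[1]:
                best = (popt, resid)
        except (RuntimeError, ValueError):
            continue
    if best is None:
        curve.power_fit = {"converged": False}
    else:
        k, alpha, ea = best[0]
        curve.power_fit = {"k": float(k), "alpha": float(alpha),
                           "Ea": float(ea), "converged": True}
    return curve.power_fit


# --------------------------------------------------------------------------
# threshold distance
# --------------------------------------------------------------------------

def normalized_threshold_distance(vm_dist: VmDistribution,
                                  spikes: SpikeEvents) -> float:
    """(mean Vm - mean threshold) / sigma; negative below threshold."""
    if vm_dist.sd <= 0:
        raise ValueError("sigma must be > 0")
    return (vm_dist.mean - spikes.mean_threshold) / vm_dist.sd
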