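"""Spike-train statistics for single units.

CV2 irregularity sequences, instantaneous-rate distributions with linear and
log-axis skewness, lognormal fits, and Gaussian-kernel firing-rate estimation
with cross-validated bandwidth optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_CV2_INTERBURST_S = 0.5     # cycle-restricted CV2 statistics
DEFAULT_RATE_INTERBURST_S = 0.3    # Vm-linked rate statistics


def skewness(sample, flag_degenerate: bool = False):
    """Pearson moment coefficient of skewness.

    (1/N) sum(((x - mean)/sd)^3) with the sample SD (ddof=1).  Degenerate
    inputs (n < 3 or zero SD) yield 0; with ``flag_degenerate`` the flag is
    returned alongside.
    """
    x = np.asarray(sample, float)
    n = x.size
    if n < 3:
        return (0.0, True) if flag_degenerate else 0.0
    sd = np.std(x, ddof=1)
    if sd == 0:
        return (0.0, True) if flag_degenerate else 0.0
    val = float(np.mean(((x - x.mean()) / sd) ** 3))
    return (val, False) if flag_degenerate else val


@dataclass
class CV2Sequence:
    """Local irregularity per adjacent ISI pair.

    CV2(i) = 2 |ISI_i - ISI_{i+1}| / (ISI_i + ISI_{i+1}), in [0, 2]:
    0 for clock-like firing, 1 for a Poisson process.  ``spans`` holds the
    time each value represents, (ISI_i + ISI_{i+1}) / 2; ``interburst_mask``
    marks pairs touching an interburst ISI.
    """

    values: np.ndarray
    spans: np.ndarray
    interburst_mask: np.ndarray
    interburst_threshold_s: float = DEFAULT_CV2_INTERBURST_S

    @property
    def n(self) -> int:
        return self.values.size

    def mean(self, exclude_interburst: bool = True) -> float:
        if self.n == 0:
            return np.nan
        if exclude_interburst:
            keep = ~self.interburst_mask
            return float(self.values[keep].mean()) if keep.any() else np.nan
        return float(self.values.mean())


def cv2_sequence(spike_times,
                 interburst_threshold_s: float = DEFAULT_CV2_INTERBURST_S
                 ) -> CV2Sequence:
    """CV2 for every adjacent ISI pair of a spike train.

    Fewer than 3 spikes yield an empty sequence.
    """
    t = np.sort(np.asarray(spike_times, float))
    if t.size < 3:
        empty = np.empty(0)
        return CV2Sequence(empty, empty.copy(), np.empty(0, bool),
                           interburst_threshold_s)
    isi = np.diff(t)
    a, b = isi[:-1], isi[1:]
    values = 2.0 * np.abs(a - b) / (a + b)
    spans = 0.5 * (a + b)
    mask = (a >= interburst_threshold_s) | (b >= interburst_threshold_s)
    return CV2Sequence(values, spans, mask, interburst_threshold_s)


@dataclass
class RateDistribution:
    """Instantaneous (1/ISI) rates of one unit with skewness on both axes."""

    rates_hz: np.ndarray
    skewness_linear: float
    skewness_log: float
    log_mean: float              # natural-log Hz
    log_sd: float
    degenerate: bool = False


def rate_distribution(spike_times,
                      interburst_threshold_s: float = DEFAULT_RATE_INTERBURST_S
                      ) -> RateDistribution:
    """Distribution of instantaneous firing rates, interburst ISIs excluded.

    Rates are 1/ISI for ISIs below the interburst threshold; skewness is
    computed on the linear and natural-log axes, and a lognormal fit comes
    from the moments of the log rates.
    """
    t = np.sort(np.asarray(spike_times, float))
    isi = np.diff(t)
    isi = isi[(isi > 0) & (isi < interburst_threshold_s)]
    if isi.size < 3:
        raise ValueError("need >= 3 within-burst ISIs")
    rates = 1.0 / isi
    sk_lin, deg = skewness(rates, flag_degenerate=True)
    logr = np.log(rates)
    sk_log, deg_log = skewness(logr, flag_degenerate=True)
    return RateDistribution(
        rates_hz=rates, skewness_linear=sk_lin, skewness_log=sk_log,
        log_mean=float(logr.mean()),
        log_sd=float(np.std(logr, ddof=1)),
        degenerate=deg or deg_log)


@dataclass
class KernelRate:
    """Time-dependent firing rate from Gaussian-kernel smoothing."""

    times: np.ndarray
    rate_hz: np.ndarray
    bandwidth_s: float
    bandwidth_grid: np.ndarray = field(default_factory=lambda: np.empty(0))
    cost: np.ndarray = field(default_factory=lambda: np.empty(0))

    def integral(self) -> float:
        return float(np.trapezoid(self.rate_hz, self.times))


def _sskernel_cost(diffs: np.ndarray, n: int, w: float) -> float:
    """Cross-validated MISE cost of a Gaussian kernel of SD w.

    C(w) = sum_ij phi_{sqrt(2) w}(d_ij) - 2 sum_{i != j} phi_w(d_ij), using
    the closed form for the integral of the squared Gaussian estimate.
    ``diffs`` holds the positive pairwise spike-time differences.
    """
    def phi(d, s):
        return np.exp(-0.5 * (d / s) ** 2).sum() / (np.sqrt(2 * np.pi) * s)

    s2 = np.sqrt(2.0) * w
    term1 = n / (np.sqrt(2 * np.pi) * s2) + 2.0 * phi(diffs, s2)
    term2 = 4.0 * phi(diffs, w)
    return term1 - term2


def optimize_bandwidth(spike_times, w_min: float = 1e-3, w_max: float = 1.0,
                       n_grid: int = 40
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """Shimazaki-Shinomoto bandwidth selection by grid search.

    Minimizes the cross-validated mean integrated squared error of the
    Gaussian-kernel rate estimate over a log-spaced bandwidth grid
    (default 1 ms - 1 s).  Returns (best w, grid, cost).
    """
    t = np.sort(np.asarray(spike_times, float))
    n = t.size
    if n < 2:
        raise ValueError("need >= 2 spikes to optimize bandwidth")
    if n > 3000:   # pairwise cost is O(n^2); subsample for selection only
        rng = np.random.default_rng(0)
        t = np.sort(rng.choice(t, 3000, replace=False))
        n = 3000
    d = np.abs(t[:, None] - t[None, :])[np.triu_indices(n, 1)]
    grid = np.geomspace(w_min, w_max, n_grid)
    cost = np.asarray([_sskernel_cost(d, n, w) for w in grid])
    return float(grid[int(np.argmin(cost))]), grid, cost


def kernel_rate(spike_times, bandwidth: float | str = "auto",
                default_bandwidth_s: float = 0.05,
                grid_dt: float | None = None) -> KernelRate:
    """Firing rate nu(t) by convolving spikes with a Gaussian kernel.

    With ``bandwidth='auto'`` the width is optimized by cross-validation;
    a single spike falls back to ``default_bandwidth_s`` with a warning.
    The grid spans all spikes plus 5 bandwidths and steps at bandwidth/10,
    so the integral of nu equals the spike count.
    """
    t = np.sort(np.asarray(spike_times, float))
    if t.size == 0:
        raise ValueError("need >= 1 spike")
    grid_info = (np.empty(0), np.empty(0))
    if bandwidth == "auto":
        if t.size < 2:
            warnings.warn("single spike: falling back to default bandwidth")
            w = default_bandwidth_s
        else:
            w, g, c = optimize_bandwidth(t)
            grid_info = (g, c)
    else:
        w = float(bandwidth)
        if w <= 0:
            raise ValueError("bandwidth must be > 0")
    dt = grid_dt if grid_dt is not None else w / 10.0
    lo, hi = t[0] - 5 * w, t[-1] + 5 * w
    times = np.arange(lo, hi + dt, dt)
    rate = np.zeros_like(times)
    norm = 1.0 / (np.sqrt(2 * np.pi) * w)
    for tj in t:     # truncate each kernel at +-5 bandwidths
        i0 = np.searchsorted(times, tj - 5 * w)
        i1 = np.searchsorted(times, tj + 5 * w)
        rate[i0:i1] += norm * np.exp(-0.5 * ((times[i0:i1] - tj) / w) ** 2)
    return KernelRate(times=times, rate_hz=rate, bandwidth_s=w,
                      bandwidth_grid=grid_info[0], cost=grid_info[1])
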