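"""Ensemble statistics: lognormal participation, Lorenz/Gini, regime
occupancy (TIF50 / SIF50), time-resolved log-skewness, and depth profiles.

The central construct is the reverse cumulative distribution F(t): the
fraction of units that spend at least a normalized time (or spike) fraction t
in the fluctuation-driven regime, demarcated as CV2 > icrit.  Its 50%
crossing, TIF50 (time) or SIF50 (spikes), compresses population occupancy
into a single number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spike_metrics import (CV2Sequence, cv2_sequence, kernel_rate, skewness,
                            DEFAULT_CV2_INTERBURST_S)

DEFAULT_ICRIT = 0.5
ICRIT_GRID = (0.4, 0.5, 0.6)


# --------------------------------------------------------------------------
# pooled rates, Lorenz / Gini
# --------------------------------------------------------------------------

@dataclass
class PooledRates:
    rates_hz: np.ndarray           # one mean rate per active unit
    n_silent: int
    skewness_linear: float
    skewness_log: float
    log_mean: float
    log_sd: float
    degenerate: bool = False


def pooled_rate_distribution(raster: dict[int, np.ndarray],
                             episode_windows: list[tuple[float, float]]
                             ) -> PooledRates:
    """Per-unit spike-count rates over episode windows, pooled.

    Rate per unit = total spikes falling in the windows / total window
    duration.  Silent units are excluded and counted.  The lognormal fit is
    by moments of the natural-log rates.
    """
    windows = [(a, b) for a, b in episode_windows if b > a]
    if not windows:
        raise ValueError("need at least one non-empty episode window")
    total_t = sum(b - a for a, b in windows)
    rates = []
    n_silent = 0
    for u, t in raster.items():
        t = np.asarray(t, float)
        n = sum(int(np.sum((t >= a) & (t < b))) for a, b in windows)
        if n == 0:
            n_silent += 1
        else:
            rates.append(n / total_t)
    if len(rates) < 2:
        raise ValueError("need >= 2 units with spikes in the windows")
    rates = np.asarray(rates)
    sk_lin, deg = skewness(rates, flag_degenerate=True)
    logr = np.log(rates)
    sk_log = skewness(logr)
    return PooledRates(rates_hz=rates, n_silent=n_silent,
                       skewness_linear=sk_lin, skewness_log=sk_log,
                       log_mean=float(logr.mean()),
                       log_sd=float(np.std(logr, ddof=1)),
                       degenerate=deg)


@dataclass
class LorenzCurve:
    """Cumulative-share curve of sorted rates; Gini = 1 - 2 * area below."""

    population_share: np.ndarray   # x, starts at 0, ends at 1
    rate_share: np.ndarray         # y
    area_b: float
    gini: float


def lorenz_gini(rates) -> LorenzCurve:
    """Lorenz curve and Gini coefficient of a set of firing rates.

    Rates are sorted ascending, shares cumulated, and the area b under the
    Lorenz curve taken by the trapezoidal rule; Gini = 1 - 2b.  Equal rates
    give 0; the statistic is invariant under positive rescaling.
    """
    r = np.asarray(rates, float)
    if r.size == 0 or np.any(r < 0):
        raise ValueError("rates must be non-negative and non-empty")
    if r.sum() == 0:
        raise ValueError("all rates are zero")
    r = np.sort(r)
    x = np.arange(r.size + 1) / r.size
    y = np.concatenate([[0.0], np.cumsum(r) / r.sum()])
    b = float(np.trapezoid(y, x))
    return LorenzCurve(population_share=x, rate_share=y, area_b=b,
                       gini=1.0 - 2.0 * b)


# --------------------------------------------------------------------------
# regime occupancy
# --------------------------------------------------------------------------

def regime_fractions(seq: CV2Sequence, icrit: float = DEFAULT_ICRIT
                     ) -> tuple[float, float]:
    """(time fraction, spike fraction) a unit spends with CV2 > icrit.

    Time weights each CV2 value by the span (ISI_i + ISI_{i+1}) / 2 it
    covers; the spike fraction counts each value once (one middle spike per
    value).  Pairs touching an interburst ISI are excluded.
    """
    if seq.n == 0:
        raise ValueError("empty CV2 sequence")
    keep = ~seq.interburst_mask
    if not keep.any():
        raise ValueError("all CV2 pairs touch an interburst ISI")
    v, s = seq.values[keep], seq.spans[keep]
    above = v > icrit
    time_frac = float(np.sum(s[above]) / np.sum(s))
    spike_frac = float(np.mean(above))
    return time_frac, spike_frac


@dataclass
class ReverseCumulative:
    """Empirical reverse cumulative F(t) of per-unit fractions with its
    interpolated 50% crossing (TIF50 / SIF50)."""

    grid: np.ndarray
    fraction_of_units: np.ndarray     # F(t) = mean(fraction >= t)
    crossing_50: float

    @property
    def f50_percent(self) -> float:
        return 100.0 * self.crossing_50


def reverse_cumulative(unit_fractions, n_grid: int = 201) -> ReverseCumulative:
    """Reverse cumulative distribution of per-unit occupancy fractions.

    F(t) is the fraction of units whose occupancy is at least t.  The 50%
    crossing is read off by linear interpolation through the Hazen plotting
    positions of the ordered sample, which makes it coincide with the sample
    median.
    """
    x = np.asarray(unit_fractions, float)
    if x.size < 2:
        raise ValueError("need >= 2 units")
    grid = np.linspace(0.0, 1.0, n_grid)
    F = np.asarray([(x >= t).mean() for t in grid])
    xs = np.sort(x)
    n = xs.size
    pos = (n - np.arange(1, n + 1) + 0.5) / n    # F at each ordered sample
    # pos is decreasing in the sample index; invert for the 50% crossing
    crossing = float(np.interp(0.5, pos[::-1], xs[::-1]))
    if pos[0] < 0.5:          # more than half the units below the smallest t
        crossing = float(xs[0])
    elif pos[-1] > 0.5:       # more than half at the top
        crossing = float(xs[-1])
    return ReverseCumulative(grid=grid, fraction_of_units=F,
                             crossing_50=crossing)


def tif50_sif50(time_fractions, spike_fractions
                ) -> tuple[ReverseCumulative, ReverseCumulative]:
    """Reverse cumulative curves and 50% crossings for time- and
    spike-weighted fluctuation-regime occupancy."""
    return reverse_cumulative(time_fractions), \
        reverse_cumulative(spike_fractions)


def unit_summary_table(raster: dict[int, np.ndarray],
                       icrit: float = DEFAULT_ICRIT,
                       interburst_threshold_s: float =
                       DEFAULT_CV2_INTERBURST_S,
                       meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-unit ledger: mean rate, mean CV2, and regime fractions.

    Units with < 3 spikes are skipped.  ``meta`` (unit_id, shank, depth_um)
    is merged in when given.
    """
    rows = []
    for u, t in raster.items():
        t = np.asarray(t, float)
        if t.size < 3:
            continue
        seq = cv2_sequence(t, interburst_threshold_s)
        try:
            tf, sf = regime_fractions(seq, icrit)
        except ValueError:
            continue
        span = t[-1] - t[0]
        rows.append({"unit_id": u,
                     "mean_rate_hz": t.size / span if span > 0 else np.nan,
                     "mean_cv2": seq.mean(exclude_interburst=True),
                     "time_fraction_fluct": tf,
                     "spike_fraction_fluct": sf})
    df = pd.DataFrame(rows)
    if meta is not None and not df.empty:
        df = df.merge(meta, on="unit_id", how="left")
    return df


# --------------------------------------------------------------------------
# time-resolved log-skewness
# --------------------------------------------------------------------------

@dataclass
class TimeResolvedSkewness:
    bin_centers: np.ndarray
    log_mean: np.ndarray
    log_sd: np.ndarray
    skewness_log: np.ndarray
    correlation_r: float
    correlation_p: float
    n_bins_used: int


def time_resolved_log_skewness(raster: dict[int, np.ndarray],
                               t_start: float, t_stop: float,
                               bin_s: float = 0.010,
                               bandwidth: float | str = 0.05,
                               min_active_units: int = 10,
                               rate_floor_hz: float = 1e-3
                               ) -> TimeResolvedSkewness:
    """Across-unit log-rate distribution tracked in 10 ms bins.

    Each unit's kernel rate is sampled on the bin grid; per bin, units above
    ``rate_floor_hz`` contribute log rates whose mean, SD and skewness are
    recorded.  The Pearson correlation between the population log-mean and
    the log-skewness across bins tests whether high-activity epochs compress
    the top rates (negative correlation).
    """
    centers = np.arange(t_start + bin_s / 2, t_stop, bin_s)
    per_unit = []
    for u, t in raster.items():
        t = np.asarray(t, float)
        if t.size < 2:
            continue
        kr = kernel_rate(t, bandwidth=bandwidth)
        per_unit.append(np.interp(centers, kr.times, kr.rate_hz,
                                  left=0.0, right=0.0))
    if len(per_unit) < min_active_units:
        raise ValueError("too few units with spikes")
    R = np.vstack(per_unit)                     # units x bins

    lm = np.full(centers.size, np.nan)
    ls = np.full(centers.size, np.nan)
    sk = np.full(centers.size, np.nan)
    for j in range(centers.size):
        r = R[:, j]
        r = r[r > rate_floor_hz]
        if r.size < min_active_units:
            continue
        lr = np.log(r)
        lm[j] = lr.mean()
        ls[j] = np.std(lr, ddof=1)
        sk[j] = skewness(lr)
    used = np.isfinite(lm) & np.isfinite(sk)
    if used.sum() < 2:
        raise ValueError("too few populated time bins for a correlation")
    r_val, p_val = stats.pearsonr(lm[used], sk[used])
    return TimeResolvedSkewness(bin_centers=centers, log_mean=lm, log_sd=ls,
                                skewness_log=sk, correlation_r=float(r_val),
                                correlation_p=float(p_val),
                                n_bins_used=int(used.sum()))


# --------------------------------------------------------------------------
# depth profiles
# --------------------------------------------------------------------------

@dataclass
class DepthProfile:
    bin_edges_um: np.ndarray
    bin_mean_cv2: np.ndarray
    bin_counts: np.ndarray
    ks_table: pd.DataFrame        # pairwise KS statistics and p-values


def depth_profile(units: pd.DataFrame, bin_um: float = 100.0,
                  min_units_per_bin: int = 5,
                  cv2_column: str = "mean_cv2",
                  depth_column: str = "depth_um") -> DepthProfile:
    """Binned CV2-by-depth distributions with pairwise two-sample KS tests.

    Depths must already be corrected for per-shank insertion offsets.  Bins
    holding fewer than ``min_units_per_bin`` units are skipped.
    """
    d = units[depth_column].to_numpy(float)
    c = units[cv2_column].to_numpy(float)
    ok = np.isfinite(d) & np.isfinite(c)
    d, c = d[ok], c[ok]
    if d.size == 0:
        raise ValueError("no units with finite depth and CV2")
    lo = np.floor(d.min() / bin_um) * bin_um
    hi = np.ceil(d.max() / bin_um) * bin_um
    edges = np.arange(lo, hi + bin_um, bin_um)
    idx = np.clip(np.digitize(d, edges) - 1, 0, edges.size - 2)

    groups, means, counts = [], [], []
    for b in range(edges.size - 1):
        vals = c[idx == b]
        counts.append(vals.size)
        if vals.size >= min_units_per_bin:
            groups.append((b, vals))
            means.append(vals.mean())
        else:
            means.append(np.nan)

    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            bi, vi = groups[i]
            bj, vj = groups[j]
            ks = stats.ks_2samp(vi, vj)
            rows.append({"bin_i": bi, "bin_j": bj,
                         "ks_stat": float(ks.statistic),
                         "p_value": float(ks.pvalue)})
    return DepthProfile(bin_edges_um=edges,
                        bin_mean_cv2=np.asarray(means),
                        bin_counts=np.asarray(counts),
                        ks_table=pd.DataFrame(
                            rows, columns=["bin_i", "bin_j", "ks_stat",
                                           "p_value"]))
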