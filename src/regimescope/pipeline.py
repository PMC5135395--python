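"""Orchestration: configuration, file formats, and the end-to-end report.

The pipeline chains the intracellular, spike-metrics, population and
localization stages over simulated or loaded inputs and assembles a run
report with per-unit summaries, population scalars (Gini, TIF50, SIF50,
pooled skewness) and cross-metric Pearson correlations.  Every ISI filter
logs how much it discarded, since the exclusion rules materially change the
results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import intracellular as ic
from . import population as pop
from . import spike_metrics as sm
from .synthetic import read_raster

log = logging.getLogger("regimescope")


@dataclass
class AnalysisConfig:
    """All pipeline tunables with their defaults.

    Durations in ms unless suffixed otherwise; the icrit grid covers the
    sensitivity band around the suggested 0.5.
    """

    rmr_lag_ms: float = 1.5
    rmr_cutoff: float = 0.7
    spike_excision_ms: float = 6.0
    temporal_min_isi_ms: float = 6.0
    triggered_min_isi_ms: float = 20.0
    vm_interburst_ms: float = 300.0
    fv_min_isi_ms: float = 1.7
    pre_spike_lag_ms: float = 1.7
    sigma_lag_ms: float = 18.0
    cv2_interburst_s: float = 0.5
    rate_interburst_s: float = 0.3
    icrit: float = 0.5
    icrit_grid: tuple[float, ...] = (0.4, 0.5, 0.6)
    population_bin_ms: float = 10.0
    fv_bin_mv: float = 0.5
    smoothing_ms: float = 20.0
    depth_bin_um: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rmr_lag_ms", "spike_excision_ms", "vm_interburst_ms",
                     "fv_min_isi_ms", "pre_spike_lag_ms", "sigma_lag_ms",
                     "cv2_interburst_s", "rate_interburst_s",
                     "population_bin_ms", "fv_bin_mv", "smoothing_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for v in (self.icrit, *self.icrit_grid):
            if not (0.0 < v < 2.0):
                raise ValueError("icrit values must be in (0, 2)")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "icrit_grid" in d:
            d["icrit_grid"] = tuple(d["icrit_grid"])
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def correlate(x, y) -> tuple[float, float, int]:
    """Pearson product-moment correlation with two-sided p and n.

    Pairs with non-finite entries are dropped; a constant column yields
    (nan, nan, n) rather than an exception.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        log.warning("constant column: correlation undefined")
        return np.nan, np.nan, n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------

def read_vm_trace(path) -> ic.VmTrace:
    """Read a two-column (time_s, vm_mV) delimited text trace."""
    df = pd.read_csv(path, sep=None, engine="python")
    t = df.iloc[:, 0].to_numpy(float)
    v = df.iloc[:, 1].to_numpy(float)
    if t.size < 2:
        raise ValueError("trace needs >= 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-3):
        raise ValueError("trace must be uniformly sampled")
    return ic.VmTrace(samples=v, sampling_rate=1.0 / float(dt[0]),
                      start_time=float(t[0]))


# --------------------------------------------------------------------------
# per-neuron and population stages
# --------------------------------------------------------------------------

def analyze_neuron(trace: ic.VmTrace, config: AnalysisConfig | None = None,
                   peak_times: np.ndarray | None = None) -> dict:
    """Full intracellular + spike-metrics record for one neuron."""
    cfg = config or AnalysisConfig()
    if peak_times is None:
        peak_times = ic.detect_spike_peaks(trace)
    rec: dict = {"n_spikes": int(np.asarray(peak_times).size)}
    if rec["n_spikes"] == 0:
        rec["status"] = "no_spikes"
        return rec

    spikes = ic.estimate_thresholds_phase_plane(trace, peak_times)
    rec["n_thresholded"] = spikes.n
    rec["mean_threshold_mv"] = spikes.mean_threshold
    rec["min_threshold_mv"] = spikes.most_hyperpolarized_threshold
    rec["threshold_q5_mv"] = spikes.threshold_q5

    rec["rmr"] = ic.return_map_ratio(
        trace, spikes.peak_times, cfg.rmr_lag_ms, cfg.spike_excision_ms,
        cfg.vm_interburst_ms)
    rec["is_fluctuation_driven_rmr"] = bool(rec["rmr"] < cfg.rmr_cutoff)
    rec["time_below_threshold"] = ic.time_below_threshold(
        trace, spikes.most_hyperpolarized_threshold, cfg.smoothing_ms)

    try:
        tdist = ic.temporal_distribution(
            trace, spikes, cfg.temporal_min_isi_ms, cfg.vm_interburst_ms,
            cfg.spike_excision_ms)
        rec["vm_mean_mv"] = tdist.mean
        rec["vm_sd_mv"] = tdist.sd
        rec["vm_skewness"] = tdist.skewness
        if tdist.sd > 0:
            rec["threshold_distance_sigma"] = \
                ic.normalized_threshold_distance(tdist, spikes)
    except ValueError as err:
        log.warning("temporal distribution unavailable: %s", err)

    try:
        sdist = ic.spike_triggered_distribution(
            trace, spikes, cfg.sigma_lag_ms, cfg.triggered_min_isi_ms,
            cfg.vm_interburst_ms)
        rec["sigma_mv"] = sdist.sd
        rec["triggered_mean_mv"] = sdist.mean
        rec["triggered_skewness"] = sdist.skewness
        rec["triggered_low_n"] = sdist.low_n
    except ValueError as err:
        log.warning("spike-triggered distribution unavailable: %s", err)

    seq = sm.cv2_sequence(spikes.peak_times, cfg.cv2_interburst_s)
    rec["mean_cv2"] = seq.mean(exclude_interburst=True)
    if seq.n:
        tf, sf = pop.regime_fractions(seq, cfg.icrit)
        rec["time_fraction_fluct"] = tf
        rec["spike_fraction_fluct"] = sf

    curve = ic.estimate_fv_curve(trace, spikes.peak_times,
                                 cfg.pre_spike_lag_ms, cfg.fv_bin_mv,
                                 cfg.fv_min_isi_ms)
    rec["fv_exp_fit"] = ic.fit_fv_exponential(curve)
    rec["fv_power_fit"] = ic.fit_fv_powerlaw(curve)
    rec["status"] = "ok"
    return rec


@dataclass
class RunReport:
    unit_table: pd.DataFrame
    neuron_records: list[dict]
    population: dict
    correlations: dict
    provenance: dict
    stage_status: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "population": self.population,
            "correlations": self.correlations,
            "provenance": self.provenance,
            "stage_status": self.stage_status,
            "neuron_records": self.neuron_records,
            "unit_table": self.unit_table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: AnalysisConfig,
                 traces: list[ic.VmTrace] | None = None,
                 raster: dict[int, np.ndarray] | str | None = None,
                 unit_meta: pd.DataFrame | None = None,
                 episode_windows: list[tuple[float, float]] | None = None
                 ) -> RunReport:
    """Run every applicable stage and assemble the report.

    Stage failures are caught and recorded in ``stage_status``; the other
    stages still complete.
    """
    status: dict = {}
    neuron_records: list[dict] = []
    if traces:
        for k, tr in enumerate(traces):
            try:
                neuron_records.append(analyze_neuron(tr, config))
                status[f"neuron_{k}"] = "ok"
            except Exception as err:           # stage isolation by design
                status[f"neuron_{k}"] = f"error: {err}"
                neuron_records.append({"status": "error", "error": str(err)})

    if isinstance(raster, str):
        raster = read_raster(raster)

    unit_table = pd.DataFrame()
    population: dict = {}
    correlations: dict = {}
    if raster:
        try:
            unit_table = pop.unit_summary_table(
                raster, config.icrit, config.cv2_interburst_s, unit_meta)
            status["unit_summary"] = "ok"
        except Exception as err:
            status["unit_summary"] = f"error: {err}"
        if not unit_table.empty:
            try:
                for icrit in config.icrit_grid:
                    tfs = [pop.regime_fractions(
                        sm.cv2_sequence(raster[u], config.cv2_interburst_s),
                        icrit) for u in unit_table["unit_id"]]
                    rc_t, rc_s = pop.tif50_sif50([a for a, _ in tfs],
                                                 [b for _, b in tfs])
                    population[f"tif50_icrit_{icrit}"] = rc_t.crossing_50
                    population[f"sif50_icrit_{icrit}"] = rc_s.crossing_50
                population["tif50"] = population[
                    f"tif50_icrit_{config.icrit}"]
                population["sif50"] = population[
                    f"sif50_icrit_{config.icrit}"]
                status["occupancy"] = "ok"
            except Exception as err:
                status["occupancy"] = f"error: {err}"
            try:
                if episode_windows is None:
                    tmax = max(t[-1] for t in raster.values() if len(t))
                    episode_windows = [(0.0, float(tmax))]
                pooled = pop.pooled_rate_distribution(raster, episode_windows)
                population["gini"] = pop.lorenz_gini(pooled.rates_hz).gini
                population["pooled_skewness_linear"] = pooled.skewness_linear
                population["pooled_skewness_log"] = pooled.skewness_log
                population["pooled_log_sd"] = pooled.log_sd
                population["n_silent_units"] = pooled.n_silent
                status["pooled_rates"] = "ok"
            except Exception as err:
                status["pooled_rates"] = f"error: {err}"
            try:
                r, p, n = correlate(unit_table["mean_rate_hz"],
                                    unit_table["mean_cv2"])
                correlations["rate_vs_cv2"] = {"r": r, "p": p, "n": n}
            except ValueError as err:
                status["correlations"] = f"error: {err}"
            if "depth_um" in unit_table.columns:
                try:
                    prof = pop.depth_profile(unit_table, config.depth_bin_um)
                    population["depth_ks_table"] = prof.ks_table.to_dict(
                        orient="records")
                    status["depth_profile"] = "ok"
                except Exception as err:
                    status["depth_profile"] = f"error: {err}"

    if neuron_records:
        ok = [r for r in neuron_records if r.get("status") == "ok"]
        if len(ok) >= 3:
            try:
                r, p, n = correlate([r_["mean_cv2"] for r_ in ok],
                                    [r_["rmr"] for r_ in ok])
                correlations["cv2_vs_rmr"] = {"r": r, "p": p, "n": n}
            except ValueError:
                pass

    provenance = {"config_hash": config.hash(), "config": asdict(config),
                  "seed": config.seed}
    return RunReport(unit_table=unit_table, neuron_records=neuron_records,
                     population=population, correlations=correlations,
                     provenance=provenance, stage_status=status)
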