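"""Trilateration of extracellular sources from per-electrode amplitudes.

A unit's mean spike amplitude on electrode j is modelled as A_j = S / r_j^2
with r_j the distance from the source to the electrode; the 2D source
position (x along the probe, y dorsoventral in the shank plane) and the
strength S are recovered by least squares.  Out-of-plane distance is
absorbed into S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic import AmplitudeMap, ProbeGeometry

SEARCH_MARGIN_UM = 400.0     # bound the fit to +-400 um around the shank


@dataclass
class SourceFit:
    x_um: float
    y_um: float
    strength: float            # uV * um^2
    residual: float
    converged: bool


def _model(params: np.ndarray, pos: np.ndarray) -> np.ndarray:
    x, y, log_s = params
    r2 = (pos[:, 0] - x) ** 2 + (pos[:, 1] - y) ** 2
    return np.exp(log_s) / np.maximum(r2, 1.0)


def trilaterate(amp_map: AmplitudeMap, geometry: ProbeGeometry,
                min_amplitude_uV: float = 0.0) -> SourceFit:
    """Fit source position and strength to an inverse-square amplitude map.

    Electrodes at or below ``min_amplitude_uV`` (noise floor) are down-
    weighted by exclusion; at least 3 usable electrodes are required.  The
    fit is multi-started from offsets around the 3 highest-amplitude
    electrodes and the best residual kept.
    """
    pos = geometry.electrode_positions(amp_map.shank)
    amps = amp_map.amplitudes_uV
    use = amps > min_amplitude_uV
    if use.sum() < 3:
        raise ValueError("need >= 3 electrodes above the noise floor")
    p, a = pos[use], amps[use]

    x0s = []
    top = np.argsort(a)[::-1][:3]
    for j in top:
        for dx, dy in ((15.0, 0.0), (-15.0, 0.0), (0.0, 15.0), (0.0, -15.0)):
            guess_r2 = max(dx * dx + dy * dy, 1.0)
            x0s.append((p[j, 0] + dx, p[j, 1] + dy,
                        np.log(max(a[j] * guess_r2, 1e-6))))

    cx = pos[:, 0].mean()
    lo = [cx - SEARCH_MARGIN_UM, pos[:, 1].min() - SEARCH_MARGIN_UM, -30.0]
    hi = [cx + SEARCH_MARGIN_UM, pos[:, 1].max() + SEARCH_MARGIN_UM, 60.0]

    best = None
    for x0 in x0s:
        x0 = np.clip(x0, lo, hi)
        try:
            res = optimize.least_squares(
                lambda q: _model(q, p) - a, x0, bounds=(lo, hi),
                xtol=1e-12, ftol=1e-12)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return SourceFit(np.nan, np.nan, np.nan, np.inf, False)
    x, y, log_s = best.x
    return SourceFit(float(x), float(y), float(np.exp(log_s)),
                     float(np.sqrt(2.0 * best.cost)), bool(best.success))


def absolute_depth(fit: SourceFit, shank_insertion_depth_um: float) -> float:
    """Depth below the cord surface: insertion depth minus the fitted local
    y (y = 0 at the deepest electrode of the shank)."""
    return shank_insertion_depth_um - fit.y_um


def localize_units(amp_maps: dict[int, AmplitudeMap],
                   geometry: ProbeGeometry) -> pd.DataFrame:
    """Trilaterate a cohort of units; one row per unit with absolute depth."""
    rows = []
    for u, m in amp_maps.items():
        try:
            fit = trilaterate(m, geometry)
        except ValueError:
            fit = SourceFit(np.nan, np.nan, np.nan, np.inf, False)
        depth = absolute_depth(fit, geometry.insertion_depth_um[m.shank]) \
            if np.isfinite(fit.y_um) else np.nan
        rows.append({"unit_id": u, "x_um": fit.x_um, "y_um": fit.y_um,
                     "depth_um": depth, "strength": fit.strength,
                     "residual": fit.residual, "converged": fit.converged})
    return pd.DataFrame(rows)
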