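"""Exploration-exploitation descriptives: KDE summaries and correlations.

Per agent condition, dwell time / fixation count / GTE distributions are
summarized by the kernel-density mode, the centroid (sample mean) and the
full width at half maximum (FWHM) of a Gaussian KDE, plus pairwise Pearson
correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde


@dataclass
class KdeSummary:
    mode: float
    centroid: float
    fwhm: float
    bandwidth: float


def kde_summary(values, bandwidth="silverman") -> KdeSummary:
    """Gaussian-KDE mode/centroid/FWHM of one sample.

    The density is evaluated on a 512-point grid spanning the data plus three
    bandwidths on each side; the FWHM is the distance between the outermost
    crossings of half the maximum density (linearly interpolated).  The
    bandwidth rule (Silverman by default) is reported because mode and FWHM
    depend on it.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample")
    kde = gaussian_kde(x, bw_method=bandwidth)
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, 512)
    dens = kde(grid)
    imax = int(np.argmax(dens))
    half = dens[imax] / 2.0
    above = dens >= half
    lo_i = int(np.argmax(above))
    hi_i = len(above) - 1 - int(np.argmax(above[::-1]))

    def _cross(i_out, i_in):
        # linear interpolation of the half-max crossing between two grid points
        if i_out < 0 or i_out >= len(grid):
            return grid[i_in]
        d0, d1 = dens[i_out], dens[i_in]
        if d1 == d0:
            return grid[i_in]
        f = (half - d0) / (d1 - d0)
        return grid[i_out] + f * (grid[i_in] - grid[i_out])

    left = _cross(lo_i - 1, lo_i)
    right = _cross(hi_i + 1, hi_i)
    return KdeSummary(
        mode=float(grid[imax]), centroid=float(x.mean()),
        fwhm=float(right - left), bandwidth=h,
    )


def correlation_matrix(table: pd.DataFrame, cols=("total_dwell", "fixation_count", "gte")) -> pd.DataFrame:
    """Pairwise Pearson correlations over listwise-complete rows.

    Zero-variance columns produce NaN entries (flagged missing) off the
    diagonal; the diagonal is 1.
    """
    sub = table[list(cols)].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows")
    arr = sub.to_numpy(float)
    k = arr.shape[1]
    out = np.full((k, k), np.nan)
    sd = arr.std(axis=0)
    for i in range(k):
        out[i, i] = 1.0
        for j in range(i + 1, k):
            if sd[i] > 0 and sd[j] > 0:
                r = np.corrcoef(arr[:, i], arr[:, j])[0, 1]
                out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=list(cols), columns=list(cols))


def condition_summaries(per_agent: pd.DataFrame) -> pd.DataFrame:
    """KDE summaries of dwell and GTE per agent condition.

    ``per_agent`` has one row per agent with columns ``agent_type``,
    ``total_dwell``, ``fixation_count``, ``gte``.
    """
    rows = []
    for cond, grp in per_agent.groupby("agent_type"):
        for var in ("total_dwell", "gte"):
            vals = grp[var].dropna()
            if len(vals) >= 10 and np.ptp(vals) > 0:
                s = kde_summary(vals)
                rows.append((cond, var, s.mode, s.centroid, s.fwhm, s.bandwidth))
            else:
                rows.append((cond, var, np.nan, float(vals.mean()) if len(vals) else np.nan,
                             np.nan, np.nan))
    return pd.DataFrame(rows, columns=["agent_type", "variable", "mode",
                                       "centroid", "fwhm", "bandwidth"])
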