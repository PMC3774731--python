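"""Quantitative analysis of per-cell traces.

Covers the shape and kinetics measures used to compare the model with live
imaging: cell eccentricity from the second-moment ellipse, smoothed rate
series, the lagged correlation between contractility rate and constriction
rate, stagnation-period detection, and normalization of model units to
seconds and square micrometres.

All functions operate on plain arrays (or the tidy trace DataFrame written
by the dynamics module), so they apply equally to tracked live-imaging
cell tables with the same columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mesh import polygon_second_moments

__all__ = [
    "eccentricity",
    "series_rate",
    "smooth_series",
    "lagged_correlation",
    "stagnation_periods",
    "normalize_times",
    "normalize_areas",
    "rate_lag_analysis",
    "ventral_mask",
]


def eccentricity(ring: np.ndarray) -> float:
    """AP/LV dimension ratio of the ellipse fitted to a cell polygon.

    The ellipse has the polygon's area-weighted second central moments;
    the returned ratio compares its extent along the AP (x) axis with its
    extent along the LV (y) axis.  1.0 means isotropic; > 1 means the cell
    is elongated along the AP axis.  Axis-aligned extents (projections of
    the moment ellipse) are used rather than principal-axis lengths, since
    the measure is defined relative to the embryo's body axes.
    """
    _, _, cov = polygon_second_moments(ring)
    if cov[1, 1] <= 0:
        raise ValueError("degenerate polygon: zero extent along LV axis")
    return float(np.sqrt(max(cov[0, 0], 0.0) / cov[1, 1]))


def smooth_series(values: np.ndarray, window: int) -> np.ndarray:
    """Centered local-linear smoother.

    A Savitzky-Golay filter of polynomial order 1: identical to a centred
    moving average in the interior of the series, but end samples come
    from the least-squares line through the first/last window, so a
    linear trend passes through unchanged.  ``window`` is rounded up to
    the next odd integer.
    """
    if window < 1:
        raise ValueError("window must be >= 1 sample")
    values = np.asarray(values, dtype=float)
    if window > values.size:
        raise ValueError("smoothing window longer than series")
    if window < 3:
        return values.copy()
    from scipy.signal import savgol_filter

    if window % 2 == 0:
        window += 1
    window = min(window, values.size if values.size % 2 else values.size - 1)
    return savgol_filter(values, window, polyorder=1, mode="interp")


def series_rate(values: np.ndarray, t: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered-difference derivative of the smoothed series.

    Same length as the input; the two ends use one-sided differences.
    """
    t = np.asarray(t, dtype=float)
    smoothed = smooth_series(values, window)
    return np.gradient(smoothed, t)


def lagged_correlation(
    rate_a: np.ndarray,
    rate_b: np.ndarray,
    offsets: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Pearson correlation of rate_a shifted forward by each offset.

    ``rate_a`` (e.g. contractility rate) at time t - offset is correlated
    with ``rate_b`` (e.g. constriction rate) at time t on the overlapping
    support.  Offsets are non-negative sample shifts.  Returns the per-
    offset correlations and the offset maximizing them.
    """
    rate_a = np.asarray(rate_a, dtype=float)
    rate_b = np.asarray(rate_b, dtype=float)
    if rate_a.shape != rate_b.shape:
        raise ValueError("series must have equal length")
    offsets = np.asarray(offsets, dtype=int)
    if np.any(offsets < 0):
        raise ValueError("offsets must be non-negative")
    n = rate_a.size
    corrs = np.empty(offsets.size)
    for k, off in enumerate(offsets):
        if n - off < 3:
            raise ValueError(f"overlap shorter than 3 samples at offset {off}")
        a = rate_a[: n - off] if off > 0 else rate_a
        b = rate_b[off:]
        # Pearson r; NaN when either series has zero variance on the
        # overlap (e.g. time-constant contractility)
        sa, sb = a.std(), b.std()
        if sa == 0.0 or sb == 0.0:
            corrs[k] = np.nan
        else:
            corrs[k] = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    if np.all(np.isnan(corrs)):
        return corrs, 0
    best = int(offsets[int(np.nanargmax(corrs))])
    return corrs, best


def stagnation_periods(
    area: np.ndarray,
    t: np.ndarray,
    tol_rate: float,
    min_duration: float,
    window: int = 5,
    onset_drop_frac: float = 0.05,
) -> list[tuple[float, float]]:
    """Maximal intervals of nearly constant area during constriction.

    An interval qualifies when the smoothed area rate stays within
    ``+- tol_rate`` for at least ``min_duration`` time units.  The plateau
    before constriction onset (before the smoothed area first drops by
    ``onset_drop_frac`` of its initial value) is excluded: a cell that has
    not yet started constricting is not stagnating.  Likewise an interval
    that runs to the end of the series is excluded: a stagnation is a
    *temporary* plateau after which area reduction recommences, not the
    final approach to force balance.  Returns sorted, non-overlapping
    (t_start, t_end) intervals.
    """
    if tol_rate <= 0 or min_duration <= 0:
        raise ValueError("tol_rate and min_duration must be positive")
    area = np.asarray(area, dtype=float)
    t = np.asarray(t, dtype=float)
    smoothed = smooth_series(area, window)
    rate = np.gradient(smoothed, t)
    onset_level = smoothed[0] * (1.0 - onset_drop_frac)
    below = np.flatnonzero(smoothed <= onset_level)
    onset_idx = int(below[0]) if below.size else area.size  # never constricts

    flat = np.abs(rate) < tol_rate
    intervals: list[tuple[float, float]] = []
    i = 0
    n = flat.size
    while i < n:
        if flat[i]:
            j = i
            while j + 1 < n and flat[j + 1]:
                j += 1
            if i >= onset_idx and j < n - 1 and t[j] - t[i] >= min_duration:
                intervals.append((float(t[i]), float(t[j])))
            i = j + 1
        else:
            i += 1
    return intervals


def normalize_times(t: np.ndarray, total_seconds: float = 600.0) -> np.ndarray:
    """Rescale model times so the full run spans ``total_seconds``.

    Implements the live-imaging convention: the number of time-steps to
    furrow completion corresponds to 10 minutes of real time.
    """
    t = np.asarray(t, dtype=float)
    if t.size < 2 or t[-1] <= t[0]:
        raise ValueError("need a completed run (increasing time span) to normalize")
    return (t - t[0]) * (total_seconds / (t[-1] - t[0]))


def normalize_areas(area: np.ndarray, a_init_model: float, initial_cell_area_um2: float) -> np.ndarray:
    """Map model areas to um^2 so the initial hexagon area hits the
    configured mean apical area at the end of cellularization."""
    if a_init_model <= 0 or initial_cell_area_um2 <= 0:
        raise ValueError("areas must be positive")
    return np.asarray(area, dtype=float) * (initial_cell_area_um2 / a_init_model)


def normalize_units(traces: pd.DataFrame, rule, a_init_model: float) -> pd.DataFrame:
    """Convert a tidy trace table to seconds and square micrometres.

    ``rule`` is a :class:`~furrowsim.config.NormalizationRule`; the run
    span maps to ``rule.total_seconds`` and ``a_init_model`` (the initial
    hexagon area in model units) maps to ``rule.initial_cell_area_um2``.
    Returns a copy with ``t_seconds`` and ``area_um2`` columns added.
    """
    out = traces.copy()
    out["t_seconds"] = normalize_times(traces["t"].to_numpy(), rule.total_seconds)
    out["area_um2"] = normalize_areas(
        traces["area"].to_numpy(), a_init_model, rule.initial_cell_area_um2
    )
    return out


def ventral_mask(rows: np.ndarray, margin: np.ndarray, midline_row: int) -> np.ndarray:
    """Ventral cells: the five central rows, margin cells excluded."""
    return (np.abs(np.asarray(rows) - midline_row) <= 2) & ~np.asarray(margin, dtype=bool)


def rate_lag_analysis(
    area: np.ndarray,
    gamma: np.ndarray,
    t_model: np.ndarray,
    *,
    total_seconds: float = 600.0,
    sample_dt: float = 1.0,
    window: int = 5,
    max_offset_seconds: float = 30.0,
) -> dict:
    """Lag between contractility rate and constriction rate over cells.

    Parameters
    ----------
    area, gamma
        (n_times, n_cells) trace arrays of the analysed cells.
    t_model
        Model times of the rows; internally normalized to
        ``total_seconds`` and resampled on a uniform ``sample_dt`` grid.

    For every cell the smoothed contractility rate is shifted forward by
    each candidate offset and correlated (Pearson) with the smoothed area-
    reduction rate (-dA/dt); correlations are averaged over cells per
    offset.  Returns offsets (seconds), the mean and per-cell correlation
    curves, the best offset, and the fraction of cells individually
    showing a positive correlation.
    """
    t_s = normalize_times(t_model, total_seconds)
    grid = np.arange(0.0, t_s[-1] + sample_dt / 2, sample_dt)
    offsets = np.arange(0, int(max_offset_seconds / sample_dt) + 1)

    n_cells = area.shape[1]
    per_cell = np.empty((n_cells, offsets.size))
    positive_r0 = 0
    for c in range(n_cells):
        a = np.interp(grid, t_s, area[:, c])
        g = np.interp(grid, t_s, gamma[:, c])
        constriction_rate = -series_rate(a, grid, window)
        gamma_rate = series_rate(g, grid, window)
        corrs, _ = lagged_correlation(gamma_rate, constriction_rate, offsets)
        per_cell[c] = corrs
        if np.any(np.nan_to_num(corrs, nan=-np.inf) > 0):
            positive_r0 += 1
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_corr = np.nanmean(per_cell, axis=0)
    if np.all(np.isnan(mean_corr)):
        best = np.nan
    else:
        best = float(offsets[int(np.nanargmax(mean_corr))]) * sample_dt
    return {
        "offsets_seconds": offsets * sample_dt,
        "mean_correlation": mean_corr,
        "per_cell_correlation": per_cell,
        "best_offset_seconds": best,
        "n_cells": n_cells,
        "frac_cells_positive": positive_r0 / max(n_cells, 1),
    }
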