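"""Instrument-series processing into 5-minute model predictors.

Raw inputs are a CTD pressure/temperature record at 5-s cadence and ADCP
profiles (backscatter amplitude and u/v/w velocity, 25 x 2-m bins, 10-min
cadence).  The module turns these into the nine predictors used by the
visitation model, on a common 5-minute grid:

``temp_2m``, ``temp_50m`` (degC), ``backscatter`` (dB, despiked depth mean),
``cs_48_5``, ``cs_8_5``, ``ls_48_5``, ``ls_8_5`` (m/s, slope-rotated
currents at two heights above the bed), ``vertical_velocity`` (m/s, depth
mean) and ``time_to_high_tide`` (signed hours, negative on the flood).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, medfilt

logger = logging.getLogger(__name__)

GRID_STEP = pd.Timedelta(minutes=5)

#: the nine predictor names, in canonical order
PREDICTORS = (
    "temp_2m",
    "temp_50m",
    "backscatter",
    "cs_48_5",
    "cs_8_5",
    "ls_48_5",
    "ls_8_5",
    "vertical_velocity",
    "time_to_high_tide",
)

#: ADCP geometry: 25 bins of 2 m spanning 0.5-50.5 m range from the transducer
ADCP_BIN_EDGES = np.arange(0.5, 50.6, 2.0)
ADCP_BIN_CENTERS = (ADCP_BIN_EDGES[:-1] + ADCP_BIN_EDGES[1:]) / 2
N_ADCP_BINS = 25

#: slope orientation: currents rotated 117 deg clockwise from north
ROTATION_DEG = 117.0

#: nominal hydrostatic conversion for warm tropical seawater; tide-phase
#: extraction only needs relative elevation, so the constant is not critical
M_PER_DBAR = 0.9928


@dataclass
class TidePhase:
    """Detected high/low tide times; highs and lows strictly alternate."""

    high_tide_times: pd.DatetimeIndex
    low_tide_times: pd.DatetimeIndex


def make_grid(start, end, step: pd.Timedelta = GRID_STEP) -> pd.DatetimeIndex:
    """Left-closed time bins [t, t+step) labelled by their start."""
    if step <= pd.Timedelta(0):
        raise ValueError("step must be positive")
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start >= end:
        raise ValueError("start must precede end")
    return pd.date_range(start, end, freq=step, inclusive="left")


def bin_mean(series: pd.Series, grid: pd.DatetimeIndex) -> pd.Series:
    """Mean of in-bin samples per grid bin; empty bins are NaN.

    ``series`` is indexed by sample time (e.g. the 5-s CTD record); each
    5-min bin mean pools the ~60 samples falling in [t, t+step).
    """
    step = grid[1] - grid[0] if len(grid) > 1 else GRID_STEP
    labels = series.index.floor(step)
    means = series.groupby(labels).mean()
    return means.reindex(grid)


def despike_running_median(values: np.ndarray, window: int = 3,
                           max_dev: float = 1.0) -> np.ndarray:
    """Replace single-bin spikes along the vertical with the running median.

    For each time step (row), a centred running median of length ``window``
    is computed along the bins (columns, shrunken windows at the edges);
    values deviating from it by more than ``max_dev`` are replaced by the
    median.  Values within ``max_dev`` are never altered, so the filter is
    idempotent on its own output.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    v = np.atleast_2d(values)
    half = window // 2
    med = np.empty_like(v)
    n = v.shape[1]
    for j in range(n):
        lo, hi = max(0, j - half), min(n, j + half + 1)
        med[:, j] = np.median(v[:, lo:hi], axis=1)
    out = np.where(np.abs(v - med) > max_dev, med, v)
    return out[0] if squeeze else out


def depth_mean(values: np.ndarray) -> np.ndarray:
    """Mean over the depth bins per time step, skipping missing bins.

    A time step with no finite bin at all is missing in the output.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    out = np.full(v.shape[0], np.nan)
    ok = np.isfinite(v)
    any_ok = ok.any(axis=1)
    sums = np.where(ok, v, 0.0).sum(axis=1)
    out[any_ok] = sums[any_ok] / ok.sum(axis=1)[any_ok]
    return out


def interpolate_linear(times: pd.DatetimeIndex, values: np.ndarray,
                       grid: pd.DatetimeIndex) -> pd.Series:
    """Linear interpolation onto the grid labels; no extrapolation.

    Grid bins outside the span of the non-missing samples are NaN (e.g.
    after an instrument stops recording).
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing samples to interpolate")
    t = times.asi8[ok].astype(float)
    g = grid.asi8.astype(float)
    out = np.interp(g, t, values[ok])
    out[(g < t[0]) | (g > t[-1])] = np.nan
    return pd.Series(out, index=grid)


def rotate_currents(u, v, angle_deg: float = ROTATION_DEG):
    """Rotate east/north velocity onto slope-aligned axes.

    With the default 117-deg clockwise rotation, the *longshore* axis is
    positive for flow toward compass bearing 297 deg (negative toward 117)
    and the *cross-shore* axis is positive toward 207 deg (negative toward
    27).  Speed is preserved (orthonormal rotation).
    """
    ls_bearing = np.deg2rad(angle_deg + 180.0)
    cs_bearing = np.deg2rad(angle_deg + 90.0)
    u, v = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
    longshore = u * np.sin(ls_bearing) + v * np.cos(ls_bearing)
    cross_shore = u * np.sin(cs_bearing) + v * np.cos(cs_bearing)
    return longshore, cross_shore


def unrotate_currents(longshore, cross_shore, angle_deg: float = ROTATION_DEG):
    """Inverse of :func:`rotate_currents` (exact, the rotation is orthonormal)."""
    ls_bearing = np.deg2rad(angle_deg + 180.0)
    cs_bearing = np.deg2rad(angle_deg + 90.0)
    ls = np.asarray(longshore, dtype=float)
    cs = np.asarray(cross_shore, dtype=float)
    u = ls * np.sin(ls_bearing) + cs * np.sin(cs_bearing)
    v = ls * np.cos(ls_bearing) + cs * np.cos(cs_bearing)
    return u, v


def adcp_bin_for_height(height_above_bed: float,
                        transducer_height: float = 3.0) -> int:
    """Index of the 2-m ADCP bin whose centre sits at the requested height.

    ``height_above_bed`` minus the transducer mounting height gives the
    range from the transducer; e.g. 8.5 m above the bed -> 5.5 m range ->
    bin 2, and 48.5 m -> 45.5 m range -> bin 22.
    """
    rng = height_above_bed - transducer_height
    hits = np.flatnonzero(np.isclose(ADCP_BIN_CENTERS, rng))
    if len(hits) != 1:
        raise ValueError(
            f"no ADCP bin centred at {rng} m range "
            f"(valid centres {ADCP_BIN_CENTERS[0]}..{ADCP_BIN_CENTERS[-1]} m)"
        )
    return int(hits[0])


def select_velocity_bins(profile_u: np.ndarray, profile_v: np.ndarray,
                         heights=(8.5, 48.5), transducer_height: float = 3.0):
    """Single-bin u and v series at the requested heights above the bed.

    Returns ``{height: (u_series, v_series)}`` with arrays over time.
    """
    out = {}
    for h in heights:
        j = adcp_bin_for_height(h, transducer_height)
        out[h] = (np.asarray(profile_u)[:, j], np.asarray(profile_v)[:, j])
    return out


def vertical_velocity_mean(profile_w: np.ndarray) -> np.ndarray:
    """Depth-mean vertical velocity per time step (no despiking applied:
    averaged velocity is low-noise, unlike backscatter amplitude)."""
    return depth_mean(profile_w)


def pressure_to_depth(pressure_dbar, atmospheric_dbar: float = 0.0):
    """Hydrostatic pressure-to-depth conversion (~0.9928 m/dbar).

    A constant atmospheric offset, if present in the record, is removed
    before conversion.  Only relative elevation matters for tide-phase
    extraction, so the fixed-density approximation is immaterial there.
    """
    p = np.asarray(pressure_dbar, dtype=float) - atmospheric_dbar
    if np.nanmin(p) < 0:
        raise ValueError("negative pressure after offset removal")
    return p * M_PER_DBAR


def extract_tide(depth: pd.Series, median_window: int = 501,
                 mean_window: int = 501,
                 min_spacing: pd.Timedelta = pd.Timedelta(hours=5.5)) -> TidePhase:
    """High/low tide times from a depth record.

    The record is cleaned with a median filter then a running mean (both
    ``501`` samples by default, sized for a 5-s record); local maxima at
    least ``min_spacing`` apart are high tides, and the same search on the
    negated record gives low tides.  After merging, highs and lows must
    alternate; where two peaks of the same type are adjacent the lower-
    prominence one is dropped (logged).
    """
    dt = (depth.index[1] - depth.index[0]).total_seconds()
    if (depth.index[-1] - depth.index[0]) <= 2 * min_spacing:
        raise ValueError("record too short to resolve tidal peaks")
    x = depth.to_numpy(dtype=float)
    x = medfilt(x, kernel_size=median_window)
    x = uniform_filter1d(x, size=mean_window, mode="nearest")
    dist = max(1, int(round(min_spacing.total_seconds() / dt)))
    hi_idx, hi_props = find_peaks(x, distance=dist, prominence=0)
    lo_idx, lo_props = find_peaks(-x, distance=dist, prominence=0)

    peaks = sorted(
        [(i, +1, p) for i, p in zip(hi_idx, hi_props["prominences"])]
        + [(i, -1, p) for i, p in zip(lo_idx, lo_props["prominences"])]
    )
    cleaned = []
    for pk in peaks:
        if cleaned and cleaned[-1][1] == pk[1]:
            drop = min(cleaned[-1], pk, key=lambda q: q[2])
            logger.info("dropped non-alternating %s tide peak at index %d",
                        "high" if drop[1] > 0 else "low", drop[0])
            if drop is cleaned[-1]:
                cleaned[-1] = pk
            continue
        cleaned.append(pk)
    highs = depth.index[[i for i, s, _ in cleaned if s > 0]]
    lows = depth.index[[i for i, s, _ in cleaned if s < 0]]
    return TidePhase(high_tide_times=highs, low_tide_times=lows)


def time_to_high_tide(grid: pd.DatetimeIndex,
                      high_tide_times: pd.DatetimeIndex,
                      quantum_hours: float = 5.0 / 60.0,
                      mask_beyond_half_cycle: bool = True) -> pd.Series:
    """Signed hours to the nearest high tide per grid bin.

    Negative before high water (flood), zero at it, positive after (ebb);
    quantised to 5-min steps.  By default, bins farther than half a tidal
    cycle (half the median high-to-high spacing) from every detected high
    are missing, so phase is never extrapolated past the ends of the
    record.
    """
    if len(high_tide_times) == 0:
        raise ValueError("need at least one high tide")
    g = grid.asi8.astype(float)
    h = np.sort(high_tide_times.asi8.astype(float))
    pos = np.searchsorted(h, g)
    prev = h[np.clip(pos - 1, 0, len(h) - 1)]
    nxt = h[np.clip(pos, 0, len(h) - 1)]
    nearest = np.where(np.abs(g - prev) <= np.abs(nxt - g), prev, nxt)
    hours = (g - nearest) / 3.6e12
    if mask_beyond_half_cycle:
        if len(h) > 1:
            half_cycle = np.median(np.diff(h)) / 3.6e12 / 2.0
        else:
            half_cycle = 12.42 / 2.0
        hours = np.where(np.abs(hours) > half_cycle, np.nan, hours)
    hours = np.round(hours / quantum_hours) * quantum_hours
    return pd.Series(hours, index=grid)


def assemble_design_matrix(presence_dets: pd.DataFrame,
                           grid: pd.DatetimeIndex,
                           predictors: dict[str, pd.Series],
                           focal_receiver: str | None = None) -> pd.DataFrame:
    """Presence/absence response plus the nine predictors, one row per bin.

    ``response`` is 1 where at least one (kept) detection of any tag falls
    in the bin — at the focal receiver only, if ``focal_receiver`` is given.
    Rows with any missing predictor are dropped; the drop count is recorded
    in ``result.attrs['n_dropped']``.
    """
    missing = set(PREDICTORS) - set(predictors)
    extra = set(predictors) - set(PREDICTORS)
    if missing or extra:
        raise ValueError(
            f"predictor names must match {PREDICTORS}; "
            f"missing={sorted(missing)} unexpected={sorted(extra)}"
        )
    dets = presence_dets
    if focal_receiver is not None:
        dets = dets[dets["receiver_id"] == focal_receiver]
    step = grid[1] - grid[0] if len(grid) > 1 else GRID_STEP
    binned = dets["timestamp"].dt.floor(step)
    hits = binned[binned.isin(grid)].unique()
    response = pd.Series(0, index=grid, dtype=int)
    response.loc[hits] = 1

    X = pd.DataFrame({name: predictors[name].reindex(grid) for name in PREDICTORS},
                     index=grid)
    X.insert(0, "response", response)
    complete = X.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    out = X[complete].copy()
    out.attrs["n_dropped"] = n_dropped
    if n_dropped:
        logger.info("dropped %d grid rows with missing predictors", n_dropped)
    return out


def collinearity_screen(X: pd.DataFrame, r_threshold: float = 0.6,
                        vif_threshold: float = 3.5) -> dict:
    """Pairwise Pearson correlations and variance inflation factors.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from an ordinary least-squares
    regression of predictor j on the other predictors (with intercept).
    Constant predictors get infinite VIF.  Flags list predictors/pairs at or
    beyond the thresholds.
    """
    cols = list(X.columns)
    if len(cols) < 2 or len(X) <= len(cols):
        raise ValueError("need >= 2 predictors and n > p")
    corr = X.corr()
    vif = {}
    A = X.to_numpy(dtype=float)
    for j, name in enumerate(cols):
        y = A[:, j]
        if np.isclose(y.std(), 0):
            vif[name] = np.inf
            continue
        others = np.delete(A, j, axis=1)
        Z = np.column_stack([np.ones(len(A)), others])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vif[name] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    pair_flags = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(cols)
        for b in cols[i + 1:]
        if abs(corr.loc[a, b]) >= r_threshold
    ]
    vif_flags = [name for name, v in vif.items() if v >= vif_threshold]
    return {"correlation": corr, "vif": vif,
            "flagged_pairs": pair_flags, "flagged_vif": vif_flags}
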