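"""Instrument-series processing: gridding, despiking, rotation, tides."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tidaltag import ocean_features as of


# ----------------------------------------------------------------- grids

@pytest.mark.parametrize("hours,expected", [(1, 12), (24, 288), (2400, 28800)])
def test_grid_bin_counts(hours, expected):
    grid = of.make_grid("2019-12-01", pd.Timestamp("2019-12-01")
                        + pd.Timedelta(hours=hours))
    assert len(grid) == expected


def test_grid_rejects_bad_inputs():
    with pytest.raises(ValueError):
        of.make_grid("2019-12-02", "2019-12-01")
    with pytest.raises(ValueError):
        of.make_grid("2019-12-01", "2019-12-02", step=pd.Timedelta(0))


def test_bin_mean_pools_samples():
    grid = of.make_grid("2019-12-01", "2019-12-01 00:15")
    idx = pd.date_range("2019-12-01", periods=120, freq="5s")
    s = pd.Series(np.concatenate([np.full(60, 27.7), np.arange(1.0, 61.0)]),
                  index=idx)
    out = of.bin_mean(s, grid)
    assert out.iloc[0] == pytest.approx(27.7)
    assert out.iloc[1] == pytest.approx(30.5)
    assert np.isnan(out.iloc[2])  # no samples in the third bin


# -------------------------------------------------------------- despiking

def test_despike_replaces_single_bin_spike():
    col = np.array([46.0, 46.0, 80.0, 46.0, 46.0])
    out = of.despike_running_median(col)
    assert out[2] == 46.0
    assert np.array_equal(out[[0, 1, 3, 4]], col[[0, 1, 3, 4]])


def test_despike_constant_and_idempotent():
    col = np.full(25, 46.1)
    assert np.array_equal(of.despike_running_median(col), col)
    rng = np.random.default_rng(0)
    noisy = 46 + rng.normal(0, 0.3, (40, 25))
    noisy[5, 10] += 9
    once = of.despike_running_median(noisy)
    twice = of.despike_running_median(once)
    assert np.array_equal(once, twice)


def brute_force_median_filter(col, window=3, max_dev=1.0):
    out = col.copy()
    half = window // 2
    for j in range(len(col)):
        seg = col[max(0, j - half): j + half + 1]
        med = np.median(seg)
        if abs(col[j] - med) > max_dev:
            out[j] = med
    return out


@given(st.lists(st.floats(0, 100, allow_nan=False), min_size=3, max_size=25))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_despike_matches_direct_recomputation(values):
    col = np.asarray(values)
    got = of.despike_running_median(col)
    assert np.allclose(got, brute_force_median_filter(col))


def test_despike_never_touches_values_near_median():
    rng = np.random.default_rng(1)
    col = 46 + rng.uniform(-0.4, 0.4, 25)  # all within max_dev of any median
    assert np.array_equal(of.despike_running_median(col), col)


# ------------------------------------------------------------ depth means

def test_depth_mean_values():
    assert of.depth_mean(np.full((3, 25), 46.1)) == pytest.approx([46.1] * 3)
    assert of.depth_mean(np.arange(1.0, 26.0)[None, :])[0] == 13.0


def test_depth_mean_skips_missing():
    row = np.full(25, 5.0)
    row[3] = np.nan
    assert of.depth_mean(row[None, :])[0] == pytest.approx(5.0)
    assert np.isnan(of.depth_mean(np.full((1, 25), np.nan))[0])


def test_vertical_velocity_mean_antisymmetric_column():
    col = np.concatenate([np.linspace(-0.1, -0.01, 12), [0.0],
                          np.linspace(0.01, 0.1, 12)[::-1]])
    assert of.vertical_velocity_mean(col[None, :])[0] == pytest.approx(0.0)


# ------------------------------------------------------------ interpolation

def test_interpolation_midpoint_and_no_extrapolation():
    times = pd.date_range("2019-12-01", periods=3, freq="10min")
    grid = of.make_grid("2019-11-30 23:55", "2019-12-01 00:30")
    out = of.interpolate_linear(times, np.array([0.0, 1.0, 1.0]), grid)
    assert np.isnan(out.loc["2019-11-30 23:55"])  # before first sample
    assert out.loc["2019-12-01 00:05"] == pytest.approx(0.5)
    assert out.loc["2019-12-01 00:10"] == pytest.approx(1.0)
    assert np.isnan(out.loc["2019-12-01 00:25"])  # after last sample


def test_interpolation_needs_two_points():
    times = pd.date_range("2019-12-01", periods=2, freq="10min")
    with pytest.raises(ValueError):
        of.interpolate_linear(times, np.array([1.0, np.nan]),
                              of.make_grid("2019-12-01", "2019-12-01 01:00"))


# ---------------------------------------------------------------- rotation

def _flow_toward(bearing_deg, speed):
    b = np.deg2rad(bearing_deg)
    return speed * np.sin(b), speed * np.cos(b)


@pytest.mark.parametrize("bearing,expected_ls,expected_cs", [
    (297, 0.5, 0.0),   # positive longshore convention
    (117, -0.5, 0.0),
    (207, 0.0, 0.5),   # positive cross-shore convention
    (27, 0.0, -0.5),
])
def test_rotation_sign_conventions(bearing, expected_ls, expected_cs):
    u, v = _flow_toward(bearing, 0.5)
    ls, cs = of.rotate_currents(u, v)
    assert ls == pytest.approx(expected_ls, abs=1e-12)
    assert cs == pytest.approx(expected_cs, abs=1e-12)


@given(st.floats(-2, 2), st.floats(-2, 2))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_rotation_is_an_isometry_and_invertible(u, v):
    ls, cs = of.rotate_currents(u, v)
    assert np.hypot(ls, cs) == pytest.approx(np.hypot(u, v), abs=1e-12)
    u2, v2 = of.unrotate_currents(ls, cs)
    assert u2 == pytest.approx(u, abs=1e-12)
    assert v2 == pytest.approx(v, abs=1e-12)


# ------------------------------------------------------------- bin picking

def test_velocity_bin_selection():
    assert of.adcp_bin_for_height(8.5) == 2     # 5.5 m from the transducer
    assert of.adcp_bin_for_height(48.5) == 22   # 45.5 m
    with pytest.raises(ValueError):
        of.adcp_bin_for_height(60.0)


def test_select_velocity_bins_extracts_columns():
    u = np.tile(np.arange(25.0), (4, 1))
    v = -u
    picked = of.select_velocity_bins(u, v)
    assert np.array_equal(picked[8.5][0], np.full(4, 2.0))
    assert np.array_equal(picked[48.5][1], np.full(4, -22.0))


# --------------------------------------------------------- pressure, tides

def test_pressure_to_depth_hydrostatic():
    assert of.pressure_to_depth(64.56) == pytest.approx(64.1, abs=0.05)
    assert of.pressure_to_depth(0.0) == 0.0
    assert of.pressure_to_depth(20.0) == pytest.approx(
        2 * of.pressure_to_depth(10.0))
    with pytest.raises(ValueError):
        of.pressure_to_depth(-1.0)


def _sinusoid_depth(days=3, period_h=12.42, noise=None, spikes=0):
    idx = pd.date_range("2019-12-01", periods=days * 17280, freq="5s")
    t = np.arange(len(idx)) * 5 / 3600.0
    x = 64.0 + 0.8 * np.cos(2 * np.pi * (t - 3.0) / period_h)
    if noise is not None:
        x = x + noise
    if spikes:
        rng = np.random.default_rng(3)
        pos = rng.integers(0, len(x), spikes)
        x[pos] += rng.choice([-3, 3], spikes)
    return pd.Series(x, index=idx), t


def test_tide_extraction_recovers_sinusoid_peaks():
    depth, t = _sinusoid_depth()
    tide = of.extract_tide(depth)
    highs = tide.high_tide_times
    assert 5 <= len(highs) <= 6
    # analytic peaks at t = 3.0 + k * 12.42 h
    got_h = (highs.asi8 - depth.index[0].value) / 3.6e12
    k = np.round((got_h - 3.0) / 12.42)
    assert np.max(np.abs(got_h - (3.0 + k * 12.42))) < 5.0 / 60.0
    spacings = np.diff(got_h)
    assert np.allclose(spacings, 12.42, atol=0.1)


def test_tide_extraction_monotone_ramp_has_no_interior_peaks():
    idx = pd.date_range("2019-12-01", periods=3 * 17280, freq="5s")
    depth = pd.Series(np.linspace(60, 66, len(idx)), index=idx)
    tide = of.extract_tide(depth)
    assert len(tide.high_tide_times) == 0


def test_tide_extraction_robust_to_spikes():
    clean, _ = _sinusoid_depth()
    spiky, _ = _sinusoid_depth(spikes=200)
    t_clean = of.extract_tide(clean)
    t_spiky = of.extract_tide(spiky)
    assert len(t_clean.high_tide_times) == len(t_spiky.high_tide_times)
    assert np.max(np.abs(t_clean.high_tide_times.asi8
                         - t_spiky.high_tide_times.asi8)) < 5 * 60 * 1e9


def test_tide_highs_and_lows_alternate():
    depth, _ = _sinusoid_depth(days=4)
    tide = of.extract_tide(depth)
    merged = sorted([(t, "H") for t in tide.high_tide_times]
                    + [(t, "L") for t in tide.low_tide_times])
    kinds = [k for _, k in merged]
    assert all(a != b for a, b in zip(kinds, kinds[1:]))


def test_tide_extraction_rejects_short_record():
    idx = pd.date_range("2019-12-01", periods=100, freq="5s")
    with pytest.raises(ValueError):
        of.extract_tide(pd.Series(np.ones(100), index=idx))


# ------------------------------------------------------- time to high tide

def test_time_to_high_tide_signs_and_quantum():
    grid = of.make_grid("2019-12-01", "2019-12-02")
    highs = pd.DatetimeIndex(["2019-12-01 06:00", "2019-12-01 18:25"])
    tth = of.time_to_high_tide(grid, highs)
    assert tth.loc["2019-12-01 06:00"] == 0.0
    assert tth.loc["2019-12-01 05:00"] == pytest.approx(-1.0)
    assert tth.loc["2019-12-01 08:00"] == pytest.approx(2.0)
    vals = tth.dropna().to_numpy()
    assert np.allclose(np.round(vals * 12), vals * 12, atol=1e-9)


def test_time_to_high_tide_sign_flip_and_linearity():
    grid = of.make_grid("2019-12-01", "2019-12-02")
    highs = pd.DatetimeIndex(["2019-12-01 06:00", "2019-12-01 18:25"])
    tth = of.time_to_high_tide(grid, highs).dropna()
    diffs = np.diff(tth.to_numpy())
    # piecewise linear in bin index: steps of +1/12 h except at the
    # midpoint between the two highs where it wraps negative
    assert ((np.abs(diffs - 1 / 12) < 1e-9).sum() + (diffs < 0).sum()
            == len(diffs))
    assert (diffs < 0).sum() == 1


def test_time_to_high_tide_masks_beyond_half_cycle():
    grid = of.make_grid("2019-12-01", "2019-12-03")
    highs = pd.DatetimeIndex(["2019-12-01 06:00", "2019-12-01 18:25"])
    tth = of.time_to_high_tide(grid, highs)
    assert tth.isna().any()  # the far end of day 2 is out of reach
    assert np.nanmax(np.abs(tth.to_numpy())) <= 6.3


# ----------------------------------------------------------- design matrix

def _toy_predictors(grid, rng):
    preds = {}
    for j, name in enumerate(of.PREDICTORS):
        preds[name] = pd.Series(rng.normal(size=len(grid)), index=grid)
    return preds


def test_design_matrix_response_and_drops():
    rng = np.random.default_rng(0)
    grid = of.make_grid("2019-12-01", "2019-12-01 01:00")
    preds = _toy_predictors(grid, rng)
    preds["temp_2m"].iloc[0] = np.nan  # forces one dropped row
    dets = pd.DataFrame({
        "timestamp": pd.to_datetime(["2019-12-01 00:31:00",
                                     "2019-12-01 00:32:00",
                                     "2019-12-01 00:33:30"]),
        "tag_id": "890",
        "receiver_id": "R1",
    })
    X = of.assemble_design_matrix(dets, grid, preds, focal_receiver="R1")
    assert X.attrs["n_dropped"] == 1
    assert len(X) + X.attrs["n_dropped"] == len(grid)
    assert X.loc["2019-12-01 00:30", "response"] == 1
    assert X["response"].sum() == 1  # all three pings fall in one bin


def test_design_matrix_rejects_wrong_predictor_names():
    rng = np.random.default_rng(0)
    grid = of.make_grid("2019-12-01", "2019-12-01 01:00")
    preds = _toy_predictors(grid, rng)
    preds["temperature"] = preds.pop("temp_2m")
    dets = pd.DataFrame(columns=["timestamp", "tag_id", "receiver_id"])
    with pytest.raises(ValueError, match="predictor names"):
        of.assemble_design_matrix(dets, grid, preds)


def test_design_matrix_prevalence_matches_ledger(small_bundle):
    env = small_bundle.predictors_true
    preds = {c: env[c] for c in of.PREDICTORS}
    X = of.assemble_design_matrix(small_bundle.detections, small_bundle.grid,
                                  preds, focal_receiver="R1")
    # detection probability < 1 and spurious pings mean approximate equality
    led = small_bundle.ledger()
    got = X["response"].mean()
    assert abs(got - led["prevalence"]) < 0.01


# ------------------------------------------------------------ collinearity

def test_collinearity_independent_predictors_have_unit_vif():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(10_000, 5)),
                     columns=list("abcde"))
    out = of.collinearity_screen(X)
    assert all(v < 1.05 for v in out["vif"].values())
    assert out["flagged_pairs"] == [] and out["flagged_vif"] == []


def test_collinearity_duplicate_predictor_flagged():
    rng = np.random.default_rng(0)
    a = rng.normal(size=500)
    X = pd.DataFrame({"a": a, "b": a, "c": rng.normal(size=500)})
    out = of.collinearity_screen(X)
    assert ("a", "b", pytest.approx(1.0)) in [
        (p[0], p[1], p[2]) for p in out["flagged_pairs"]]
    assert "a" in out["flagged_vif"] and "b" in out["flagged_vif"]


def test_collinearity_vif_matches_r_squared():
    rng = np.random.default_rng(7)
    n = 40_000
    x1 = rng.normal(size=n)
    # R^2 = var(x1) / (var(x1) + sigma^2) = 0.75 for sigma^2 = 1/3
    x2 = x1 + rng.normal(0, np.sqrt(1 / 3), n)
    X = pd.DataFrame({"x1": x1, "x2": x2, "x3": rng.normal(size=n)})
    out = of.collinearity_screen(X)
    assert out["vif"]["x2"] == pytest.approx(4.0, rel=0.05)
    assert "x2" in out["flagged_vif"]
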