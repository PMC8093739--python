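"""From raw instrument series to the 5-minute model design matrix.

Converts a synthetic pressure record to depth, extracts high/low tides,
despikes ADCP backscatter, rotates currents onto slope axes, and assembles
the nine-predictor design matrix with the presence/absence response.
"""

import pandas as pd

from tidaltag import ocean_features as of, synthetic_data as sd

bundle = sd.make_fixture(seed=7, size="small")
ocean = bundle.ocean

depth = pd.Series(of.pressure_to_depth(ocean["pressure"]),
                  index=ocean["pressure"].index)
tide = of.extract_tide(depth)
print(f"{len(tide.high_tide_times)} high tides and "
      f"{len(tide.low_tide_times)} low tides over 7 days "
      f"(truth: {len(ocean['high_tides'])} highs)")

grid = bundle.grid
bs = ocean["backscatter"].to_numpy()
n_touched = int((of.despike_running_median(bs) != bs).sum())
print(f"despiking replaced {n_touched} single-bin backscatter values")

picked = of.select_velocity_bins(ocean["u"].to_numpy(), ocean["v"].to_numpy())
ls, cs = of.rotate_currents(*picked[8.5])
print(f"near-bed longshore current: mean {ls.mean():+.3f} m/s "
      f"(positive = toward 297 degrees)")

predictors = {
    "temp_2m": of.bin_mean(ocean["ctd_2m"], grid),
    "temp_50m": of.bin_mean(ocean["ctd_50m"], grid),
    "backscatter": of.interpolate_linear(
        ocean["backscatter"].index,
        of.depth_mean(of.despike_running_median(bs)), grid),
    "vertical_velocity": of.interpolate_linear(
        ocean["w"].index, of.vertical_velocity_mean(ocean["w"].to_numpy()),
        grid),
    "time_to_high_tide": of.time_to_high_tide(grid, tide.high_tide_times),
}
for height, key in ((48.5, "48_5"), (8.5, "8_5")):
    uu, vv = picked[height]
    l, c = of.rotate_currents(uu, vv)
    predictors[f"ls_{key}"] = of.interpolate_linear(ocean["u"].index, l, grid)
    predictors[f"cs_{key}"] = of.interpolate_linear(ocean["u"].index, c, grid)

X = of.assemble_design_matrix(bundle.detections, grid, predictors,
                              focal_receiver="R1")
print(f"design matrix: {len(X)} rows ({X.attrs['n_dropped']} dropped for "
      f"missing predictors), prevalence {X['response'].mean():.3f}")

screen = of.collinearity_screen(X.drop(columns="response"))
print("max VIF %.2f; flagged pairs: %s"
      % (max(screen["vif"].values()), screen["flagged_pairs"] or "none"))
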