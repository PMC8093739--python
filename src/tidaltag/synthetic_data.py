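"""Synthetic tidally-forced instrument series and tag detections.

The generator emulates the study conditions at a semidiurnal reef site so
that every pipeline stage can be exercised against known truth: M2+S2
tides in the pressure record, flood-phase cold-water bores in the near-bed
temperature, diel warming in the near-surface temperature, bore-coupled
backscatter pulses (plus single-bin spikes to exercise the despiker),
tidally oscillating slope-aligned currents, and bin-level presence of 19
tagged animals drawn from a logistic model on the nine predictors with one
pairwise interaction.  Present tags ping at random 30-90 s intervals.

The covariates are built in two layers.  An *environmental state* on the
5-min grid carries the deterministic signal shapes plus process
variability (per-cycle bore-amplitude jitter, slow meteorological
temperature drift, sub-tidal current fluctuations) — without that
variability every covariate would be a deterministic function of tide
phase and no attribution of effects among them would be meaningful.  The
instrument series then observe this state at their own cadences with small
measurement noise.  Presence is driven by the state itself.

Signals are phenomenological templates, not hydrodynamics; presence is
simulated at the 5-min-bin level, not as animal trajectories, because the
analysis consumes bin-level presence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ocean_features as of
from ._util import child_seed

FOCAL_SITE = "Manta Alley"

#: default logistic presence coefficients on standardized predictors.
#: time-to-high-tide dominates (strong flood effect).
DEFAULT_BETA = {
    "temp_2m": -0.25,
    "temp_50m": 0.15,
    "backscatter": 0.15,
    "cs_48_5": -0.12,
    "cs_8_5": 0.12,
    "ls_48_5": 0.3,
    "ls_8_5": 0.2,
    "vertical_velocity": -0.2,
    "time_to_high_tide": -3.0,
}
#: the interacting covariates are deliberately dominated by tide-phase-
#: independent variability (diel/meteorological temperature cycle x
#: biological scattering drift): a product term involving any tide-locked
#: covariate would simply re-express itself through tide phase and could
#: never be attributed to the designed pair.
INTERACTION_PAIR = ("temp_50m", "backscatter")


@dataclass
class TruthSpec:
    """Ground-truth parameters of the synthetic site.

    Tidal amplitudes are metres, periods hours; temperatures degC;
    backscatter dB; currents m/s.  ``beta`` acts on internally standardized
    predictors; ``beta0`` sets the prevalence near 15% of bins occupied —
    the occupancy implied by hundreds of multi-bin resident events at a
    busy aggregation site over a multi-month deployment.
    """

    m2_amplitude: float = 0.8
    m2_period_h: float = 12.42
    m2_phase_h: float = 3.0
    s2_amplitude: float = 0.25
    s2_period_h: float = 12.0
    s2_phase_h: float = 1.0
    mean_depth_m: float = 64.1

    bore_drop_degc: float = 0.6      # near-bed cooling at mid-flood
    bore_center_h: float = -2.0      # hours relative to high tide
    bore_width_h: float = 0.7
    bore_jitter: float = 0.5         # per-cycle amplitude factor 1 +- jitter
    temp_2m_baseline: float = 27.7
    temp_50m_baseline: float = 29.1
    diel_amplitude: float = 0.4      # near-surface warming, peak mid-afternoon
    diel_peak_hour: float = 15.0
    temp_drift: float = 0.3          # slow (12-h knot) meteorological drift
    temp_noise: float = 0.05         # instrument noise, 5-s samples

    backscatter_baseline: float = 46.1
    backscatter_pulse_db: float = 1.5  # bore-coupled scattering pulse
    backscatter_drift: float = 2.0     # slow biological variability (6-h)
    backscatter_noise: float = 0.4     # per-bin instrument noise
    spike_rate_per_day: float = 2.0    # single-bin outliers for the despiker
    spike_db: float = 8.0

    ls_mean: float = -0.09
    ls_amp_surface: float = 0.30
    ls_amp_bed: float = 0.20
    cs_mean: float = -0.01
    cs_amp: float = 0.05             # bore inflow/outflow pulse
    current_fluct: float = 0.15      # sub-tidal fluctuation (2-h knots)
    current_noise: float = 0.01      # per-bin instrument noise
    w_mean: float = 0.002
    w_pulse: float = 0.01            # flood downwelling
    w_fluct: float = 0.006
    w_noise: float = 0.005

    beta0: float = -4.0
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    beta_interaction: float = 1.2
    interaction_pair: tuple = INTERACTION_PAIR

    n_tags: int = 19
    ping_interval_s: tuple = (30.0, 90.0)
    detection_prob: float = 0.9
    max_tags_per_bin: int = 2
    spurious_per_day: float = 1.0

    seed: int = 0

    def __post_init__(self):
        if min(self.m2_period_h, self.s2_period_h) <= 0:
            raise ValueError("tidal periods must be positive")
        if not 0 < self.detection_prob <= 1:
            raise ValueError("detection probability must be in (0, 1]")


def _hours_since(times: pd.DatetimeIndex, start: pd.Timestamp) -> np.ndarray:
    return (times.asi8 - pd.Timestamp(start).value) / 3.6e12


def tide_elevation(spec: TruthSpec, times: pd.DatetimeIndex,
                   start: pd.Timestamp) -> np.ndarray:
    """Noise-free M2+S2 surface elevation (m) relative to mean depth."""
    t = _hours_since(times, start)
    return (spec.m2_amplitude
            * np.cos(2 * np.pi * (t - spec.m2_phase_h) / spec.m2_period_h)
            + spec.s2_amplitude
            * np.cos(2 * np.pi * (t - spec.s2_phase_h) / spec.s2_period_h))


def analytic_high_tides(spec: TruthSpec, start, end) -> pd.DatetimeIndex:
    """High-tide instants of the noise-free elevation, to 1-min resolution."""
    fine = pd.date_range(start, end, freq="1min", inclusive="left")
    eta = tide_elevation(spec, fine, pd.Timestamp(start))
    from scipy.signal import find_peaks
    dist = int(round(5.5 * 60))
    idx, _ = find_peaks(eta, distance=dist)
    return fine[idx]


def _flood_shape(tth_hours: np.ndarray, spec: TruthSpec) -> np.ndarray:
    """Unit-height bore template: a Gaussian bump centred mid-flood."""
    s = np.exp(-((tth_hours - spec.bore_center_h) ** 2)
               / (2 * spec.bore_width_h**2))
    return np.where(np.isfinite(tth_hours) & (tth_hours < 0), s, 0.0)


def _tth(spec: TruthSpec, times: pd.DatetimeIndex, start, end) -> np.ndarray:
    # truth is never masked at the record edges; the pipeline's own
    # extraction applies the half-cycle mask
    highs = analytic_high_tides(spec, start, end)
    return of.time_to_high_tide(times, highs,
                                mask_beyond_half_cycle=False).to_numpy()


def _smooth_noise(rng: np.random.Generator, times: pd.DatetimeIndex,
                  sigma: float, knot: str) -> np.ndarray:
    """Slow stochastic component: Gaussian knots linearly interpolated."""
    knots = pd.date_range(times[0] - pd.Timedelta(knot),
                          times[-1] + 2 * pd.Timedelta(knot), freq=knot)
    vals = rng.normal(0, sigma, len(knots))
    return np.interp(times.asi8.astype(float), knots.asi8.astype(float), vals)


def environment(spec: TruthSpec, grid: pd.DatetimeIndex,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """The stochastic environmental state on the analysis grid.

    One row per 5-min bin with the nine predictors as the site actually
    "experiences" them: deterministic tidal/diel shapes plus process
    variability.  Presence is driven by this frame; the instruments observe
    it with additional measurement noise.
    """
    if rng is None:
        rng = np.random.default_rng(child_seed(spec.seed, 0))
    start = grid[0]
    end = grid[-1] + (grid[1] - grid[0])
    highs = analytic_high_tides(spec, start, end)
    tth = of.time_to_high_tide(grid, highs,
                               mask_beyond_half_cycle=False).to_numpy()
    shape = _flood_shape(tth, spec)
    # per-tidal-cycle amplitude jitter, drawn independently per covariate:
    # each bore response (cooling, scattering, in/outflow, downwelling)
    # varies on its own cycle to cycle, so no covariate is a clean proxy
    # for the others
    cycle = np.searchsorted(highs.asi8, grid.asi8)
    factors = rng.uniform(1 - spec.bore_jitter, 1 + spec.bore_jitter,
                          (5, len(highs) + 1))
    bore_t2, bore_bs, bore_cs48, bore_cs8, bore_w = (
        shape * f[cycle] for f in factors)

    hours = grid.hour + grid.minute / 60.0
    diel = np.cos(2 * np.pi * (hours - spec.diel_peak_hour) / 24.0)
    phase = 2 * np.pi * _hours_since(grid, start) / spec.m2_period_h

    sn = lambda sigma, knot: _smooth_noise(rng, grid, sigma, knot)
    env = pd.DataFrame({
        "temp_2m": spec.temp_2m_baseline - spec.bore_drop_degc * bore_t2
        + sn(spec.temp_drift, "12h"),
        "temp_50m": spec.temp_50m_baseline + spec.diel_amplitude * diel
        + sn(spec.temp_drift, "12h"),
        "backscatter": spec.backscatter_baseline
        + spec.backscatter_pulse_db * bore_bs
        + sn(spec.backscatter_drift, "6h"),
        "cs_48_5": spec.cs_mean - spec.cs_amp * bore_cs48
        + sn(spec.current_fluct / 2, "2h"),
        "cs_8_5": spec.cs_mean + spec.cs_amp * bore_cs8
        + sn(spec.current_fluct / 2, "2h"),
        "ls_48_5": spec.ls_mean + spec.ls_amp_surface * np.sin(phase)
        + sn(spec.current_fluct, "2h"),
        "ls_8_5": spec.ls_mean + spec.ls_amp_bed * np.sin(phase)
        + sn(spec.current_fluct, "2h"),
        "vertical_velocity": spec.w_mean - spec.w_pulse * bore_w
        + sn(spec.w_fluct, "2h"),
        "time_to_high_tide": tth,
    }, index=grid)
    return env


# the environmental state is the generator's view of the nine covariates
true_predictors = environment


def _env_at(env: pd.DataFrame, col: str, times: pd.DatetimeIndex) -> np.ndarray:
    return np.interp(times.asi8.astype(float),
                     env.index.asi8.astype(float), env[col].to_numpy())


def simulate_ocean(spec: TruthSpec, start, end,
                   env: pd.DataFrame | None = None) -> dict:
    """Generate the CTD (5-s) and ADCP (10-min, 25-bin) instrument series.

    Returns a dict with 5-s Series ``pressure`` (dbar), ``ctd_2m`` and
    ``ctd_50m`` (degC); 10-min DataFrames ``backscatter``, ``u``, ``v``,
    ``w`` (time x 25 bins); plus the truth entries ``high_tides`` and the
    slope-aligned current series used to build u and v.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end - start < pd.Timedelta(days=2):
        raise ValueError("simulate at least 2 days")
    if env is None:
        env = environment(spec, of.make_grid(start, end))
    rng = np.random.default_rng(child_seed(spec.seed, 1))

    t5s = pd.date_range(start, end, freq="5s", inclusive="left")
    eta = tide_elevation(spec, t5s, start)
    pressure = (spec.mean_depth_m + eta) / of.M_PER_DBAR \
        + rng.normal(0, 0.02, len(t5s))
    temp_2m = _env_at(env, "temp_2m", t5s) \
        + rng.normal(0, spec.temp_noise, len(t5s))
    temp_50m = _env_at(env, "temp_50m", t5s) \
        + rng.normal(0, spec.temp_noise, len(t5s))

    t10 = pd.date_range(start, end, freq="10min", inclusive="left")
    centers = of.ADCP_BIN_CENTERS
    # zero-mean vertical structure keeps the depth-mean equal to the state
    structure = np.linspace(1.0, -1.0, 25)
    bs = (_env_at(env, "backscatter", t10)[:, None] + structure
          + rng.normal(0, spec.backscatter_noise, (len(t10), 25)))
    n_spikes = rng.poisson(spec.spike_rate_per_day
                           * (end - start) / pd.Timedelta(days=1))
    spike_t = rng.integers(0, len(t10), n_spikes)
    spike_b = rng.integers(1, 24, n_spikes)  # interior bins only
    bs[spike_t, spike_b] += spec.spike_db

    # bins 2 and 22 (the analysis bins) carry the near-bed / near-surface
    # state exactly; other bins blend linearly between them
    frac = np.clip((centers - 5.5) / (45.5 - 5.5), 0.0, 1.0)
    ls_bed = _env_at(env, "ls_8_5", t10)
    ls_surf = _env_at(env, "ls_48_5", t10)
    cs_bed = _env_at(env, "cs_8_5", t10)
    cs_surf = _env_at(env, "cs_48_5", t10)
    ls_bins = np.outer(ls_bed, 1 - frac) + np.outer(ls_surf, frac)
    cs_bins = np.outer(cs_bed, 1 - frac) + np.outer(cs_surf, frac)
    u, v = of.unrotate_currents(ls_bins, cs_bins)
    u = u + rng.normal(0, spec.current_noise, u.shape)
    v = v + rng.normal(0, spec.current_noise, v.shape)
    w = (_env_at(env, "vertical_velocity", t10)[:, None]
         + rng.normal(0, spec.w_noise, (len(t10), 25)))

    return {
        "pressure": pd.Series(pressure, index=t5s),
        "ctd_2m": pd.Series(temp_2m, index=t5s),
        "ctd_50m": pd.Series(temp_50m, index=t5s),
        "backscatter": pd.DataFrame(bs, index=t10),
        "u": pd.DataFrame(u, index=t10),
        "v": pd.DataFrame(v, index=t10),
        "w": pd.DataFrame(w, index=t10),
        "high_tides": analytic_high_tides(spec, start, end),
        "longshore_truth": {8.5: ls_bed, 48.5: ls_surf},
        "cross_shore_truth": {8.5: cs_bed, 48.5: cs_surf},
    }


def simulate_presence(predictors: pd.DataFrame, spec: TruthSpec,
                      rng: np.random.Generator | None = None):
    """Per-bin presence probability and Bernoulli draw.

    Predictors are standardized internally (z-scores over the supplied
    frame) before the logistic model p = sigmoid(b0 + sum b_j z_j +
    b_int z_a z_b) is applied.  Returns ``(p, draws)`` as Series.
    """
    if rng is None:
        rng = np.random.default_rng(child_seed(spec.seed, 2))
    Z = (predictors - predictors.mean()) / predictors.std(ddof=0)
    eta = np.full(len(Z), spec.beta0)
    for name, b in spec.beta.items():
        eta += b * Z[name].to_numpy()
    a, b_ = spec.interaction_pair
    eta += spec.beta_interaction * Z[a].to_numpy() * Z[b_].to_numpy()
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite presence linear predictor")
    p = 1.0 / (1.0 + np.exp(-eta))
    draws = (rng.random(len(p)) < p).astype(int)
    return (pd.Series(p, index=predictors.index),
            pd.Series(draws, index=predictors.index))


def simulate_detections(presence: pd.Series, spec: TruthSpec,
                        tag_ids: list[str], receiver_id: str,
                        rng: np.random.Generator | None = None,
                        all_receivers: list[str] | None = None) -> pd.DataFrame:
    """Ping log implied by the presence draws.

    In each present 5-min bin, 1..``max_tags_per_bin`` tags ping at uniform
    30-90 s intervals at the focal receiver, each ping detected with
    ``detection_prob``.  Spurious isolated pings (tag-ID collisions/noise)
    are injected at ``spurious_per_day`` across all receivers to exercise
    the false-detection screen.
    """
    if rng is None:
        rng = np.random.default_rng(child_seed(spec.seed, 3))
    step = presence.index[1] - presence.index[0]
    step_s = step.total_seconds()
    lo, hi = spec.ping_interval_s
    rows = []
    for t0 in presence.index[presence.to_numpy() > 0]:
        k = min(int(rng.integers(1, spec.max_tags_per_bin + 1)), len(tag_ids))
        tags = rng.choice(tag_ids, size=k, replace=False)
        for tag in tags:
            s = rng.uniform(0, lo)
            while s < step_s:
                if rng.random() < spec.detection_prob:
                    rows.append((t0 + pd.Timedelta(seconds=round(s, 3)),
                                 tag, receiver_id))
                s += rng.uniform(lo, hi)
    span_days = (presence.index[-1] - presence.index[0]) / pd.Timedelta(days=1)
    n_spur = rng.poisson(spec.spurious_per_day * span_days)
    recs = all_receivers or [receiver_id]
    for _ in range(n_spur):
        t = presence.index[0] + pd.Timedelta(
            seconds=float(rng.uniform(0, span_days * 86400)))
        rows.append((t.round("s"), str(rng.choice(tag_ids)),
                     str(rng.choice(recs))))
    out = pd.DataFrame(rows, columns=["timestamp", "tag_id", "receiver_id"])
    return out.sort_values("timestamp", kind="stable").reset_index(drop=True)


def _metadata(spec: TruthSpec, start: pd.Timestamp):
    tags = pd.DataFrame({
        "tag_id": [f"{880 + i}" for i in range(spec.n_tags)],
        "manta_id": [f"SYN-MA-{i:04d}" for i in range(spec.n_tags)],
        "sex": ["F" if i % 2 == 0 else "M" for i in range(spec.n_tags)],
        "maturity": [("adult", "sub-adult", "juvenile")[i % 3]
                     for i in range(spec.n_tags)],
        "deploy_date": (start - pd.Timedelta(days=10)).date().isoformat(),
        "deploy_site": FOCAL_SITE,
    })
    receivers = pd.DataFrame({
        "receiver_id": [f"R{i}" for i in range(1, 6)],
        "site_name": [FOCAL_SITE, "Ile Sipaille", "Ile Sudest",
                      "North IdR Cleaning Station", "South Manta Alley"],
        "lat": [-6.64, -6.67, -6.70, -6.64, -6.67],
        "lon": [71.35, 71.32, 71.40, 71.32, 71.39],
        "depth_m": [70.0, 14.6, 15.0, 13.6, 14.2],
        "height_above_seabed_m": [48.0, 1.5, 1.8, 1.6, 1.8],
    })
    return tags, receivers


@dataclass
class SyntheticBundle:
    """Everything one synthetic deployment produces, plus its truth ledger."""

    spec: TruthSpec
    start: pd.Timestamp
    end: pd.Timestamp
    grid: pd.DatetimeIndex
    ocean: dict
    predictors_true: pd.DataFrame
    presence_prob: pd.Series
    presence: pd.Series
    detections: pd.DataFrame
    tags: pd.DataFrame
    receivers: pd.DataFrame

    @property
    def focal_receiver(self) -> str:
        return "R1"

    def ledger(self) -> dict:
        return {
            "seed": self.spec.seed,
            "n_bins": len(self.grid),
            "prevalence": float(self.presence.mean()),
            "n_present_bins": int(self.presence.sum()),
            "n_pings": int(len(self.detections)),
            "high_tides": [str(t) for t in self.ocean["high_tides"]],
            "beta": self.spec.beta,
            "beta0": self.spec.beta0,
            "interaction_pair": list(self.spec.interaction_pair),
            "beta_interaction": self.spec.beta_interaction,
        }


def make_fixture(seed: int = 0, size: str = "small",
                 spec: TruthSpec | None = None,
                 start="2019-12-01") -> SyntheticBundle:
    """Build a fully reproducible synthetic deployment.

    ``size="small"`` spans 7 days (2,016 five-min bins, desk-scale);
    ``size="paper-scale"`` spans 100 days (28,800 bins).
    """
    if size == "small":
        days = 7
    elif size == "paper-scale":
        days = 100
    else:
        raise ValueError("size must be 'small' or 'paper-scale'")
    if spec is None:
        spec = TruthSpec(seed=seed)
    else:
        spec = TruthSpec(**{**asdict(spec), "seed": seed})
    start = pd.Timestamp(start)
    end = start + pd.Timedelta(days=days)
    grid = of.make_grid(start, end)
    env = environment(spec, grid)
    ocean = simulate_ocean(spec, start, end, env=env)
    p, draws = simulate_presence(env, spec)
    tags, receivers = _metadata(spec, start)
    dets = simulate_detections(
        draws, spec, list(tags["tag_id"]), receiver_id="R1",
        all_receivers=list(receivers["receiver_id"]),
    )
    return SyntheticBundle(
        spec=spec, start=start, end=end, grid=grid, ocean=ocean,
        predictors_true=env, presence_prob=p, presence=draws,
        detections=dets, tags=tags, receivers=receivers,
    )


def write_fixture(bundle: SyntheticBundle, out_dir) -> dict:
    """Write the bundle as the delimited-text dialects the readers consume.

    Emits CTD/ADCP CSVs, the detection log, metadata tables and the truth
    ledger JSON; returns a path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save_series(name, s):
        p = out / f"{name}.csv"
        s.rename("value").rename_axis("datetime").to_csv(p)
        paths[name] = p

    save_series("pressure", bundle.ocean["pressure"])
    save_series("ctd_2m", bundle.ocean["ctd_2m"])
    save_series("ctd_50m", bundle.ocean["ctd_50m"])
    for name in ("backscatter", "u", "v", "w"):
        df = bundle.ocean[name].copy()
        df.columns = [f"bin_{j + 1}" for j in range(df.shape[1])]
        p = out / f"adcp_{name}.csv"
        df.rename_axis("datetime").to_csv(p)
        paths[f"adcp_{name}"] = p
    bundle.detections.to_csv(out / "detections.csv", index=False)
    paths["detections"] = out / "detections.csv"
    bundle.tags.to_csv(out / "tags.csv", index=False)
    paths["tags"] = out / "tags.csv"
    bundle.receivers.to_csv(out / "receivers.csv", index=False)
    paths["receivers"] = out / "receivers.csv"
    ledger = bundle.ledger()
    ledger["presence"] = bundle.presence.astype(int).tolist()
    ledger["presence_prob"] = [round(float(x), 8) for x in bundle.presence_prob]
    (out / "truth.json").write_text(json.dumps(ledger))
    paths["truth"] = out / "truth.json"
    return paths
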