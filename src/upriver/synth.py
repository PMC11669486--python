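"""Synthetic rivers, temperature records and tagged-fish cohorts.

The generator reproduces the statistical structure of an autumn
(October–November) chum-salmon upriver-migration study on a ~157 km river:

* a chainage-indexed river polyline with lower (0–21 km), narrow
  (21–54 km) and middle (54–157 km) sections and optional tributaries;
* an hourly river-temperature record per year — linear seasonal decline,
  diurnal sinusoid, inter-annual offset and AR(1) noise, reported at
  0.1 °C resolution, calibrated so early-October daily means sit inside
  the 12.8–20.8 °C aerobic-scope window and fall below it around 1 Nov;
* a cohort of tagged fish with saturating latent distance–time
  trajectories ``d_i(t) = (D_max + b0_i) (1 - exp(-t / tau)) + b1_i t``
  (initial speeds kept in a configurable 6–22 km·day⁻¹ band), daily
  observed positions with AR(1) positional noise mapped back onto the
  river line, mechanistic fates (arrival, scheduled tag-package release
  after 2–10 days, signal loss) and per-hour body-logger temperatures
  offset from the river record by Normal(-0.1, 0.7) °C.

Every fish keeps a :class:`TruthRecord` (including its stored noise
series), so downstream estimators can be scored against known ground
truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._utils import substream
from .river import RiverNetwork

__all__ = [
    "TempParams",
    "SynthConfig",
    "TruthRecord",
    "CohortData",
    "generate_river",
    "generate_temperature_series",
    "generate_cohort",
    "write_tracks_csv",
    "write_temperature_csv",
    "write_truth_json",
]

_DEFAULT_YEAR_OFFSETS = {
    2016: -0.4, 2017: 0.3, 2018: -0.2, 2019: 0.9, 2020: 0.0, 2021: 0.7,
}


@dataclass(frozen=True)
class TempParams:
    """Seasonal river-temperature model parameters (°C, days, hours)."""

    T_start: float = 16.0          # 1 Oct daily mean before year offset
    drift_per_day: float = -0.1    # linear seasonal decline
    diurnal_amp: float = 1.0       # amplitude of the daily sinusoid
    diurnal_peak_hour: float = 15.0
    year_offsets: dict = field(default_factory=lambda: dict(_DEFAULT_YEAR_OFFSETS))
    noise_sd: float = 0.3          # stationary SD of the AR(1) hourly noise
    noise_rho: float = 0.8
    resolution: float = 0.1        # reporting resolution of the gauge


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters for the synthetic cohort."""

    seed: int = 0
    n_fish: int = 48
    departure_window: tuple[str, str] = ("2021-10-01", "2021-11-20")
    p_october: float = 0.7
    # latent mean trajectory: hits ~100 km at day 10 with initial speed
    # near the middle of the observed 6-22 km/day band
    D_max_km: float = 160.0
    tau_days: float = 10.2
    sd_intercept: float = 3.0     # between-fish SD of the amplitude deviation
    sd_slope: float = 2.5         # between-fish SD of the linear speed deviation
    speed_band: tuple[float, float] = (6.0, 22.0)
    phi_true: float = 0.56        # lag-1 AR coefficient of positional noise
    obs_sd: float = 0.5           # stationary SD of positional noise (km)
    temp_params: TempParams = field(default_factory=TempParams)
    logger_bias_mean: float = -0.1
    logger_bias_sd: float = 0.7
    tag_release_range: tuple[int, int] = (2, 10)
    p_signal_loss: float = 0.3
    p_tag_package: float = 0.48
    post_arrival_days: int = 4    # confirmation window at the spawning site
    season_length_days: int = 20
    p_stay: float = 0.25
    max_stay_days: int = 3
    # river
    river_length_km: float = 157.0
    section_bounds: tuple[float, float] = (21.0, 54.0)
    mainstem_shape: str = "meander"
    vertex_spacing_km: float = 0.5
    tributaries: tuple[tuple[float, float], ...] = ((40.0, 8.0), (75.0, 10.0))
    # spawning-target chainage (month-dependent, a config choice)
    target_mean_oct: float = 85.0
    target_sd_oct: float = 25.0
    target_mean_nov: float = 45.0
    target_sd_nov: float = 15.0
    target_min_km: float = 15.0
    target_chainages: tuple[float, ...] | None = None  # explicit override

    def __post_init__(self):
        if self.n_fish < 1:
            raise ValueError("n_fish must be at least 1")
        if not (self.tau_days > 0):
            raise ValueError("tau must be positive")
        if not (0.0 <= self.p_signal_loss <= 1.0):
            raise ValueError("p_signal_loss must lie in [0, 1]")
        if not (abs(self.phi_true) < 1.0):
            raise ValueError("phi_true must lie in (-1, 1)")
        lo, hi = self.tag_release_range
        if not (1 <= lo <= hi):
            raise ValueError("tag_release_range must be an increasing positive pair")
        if self.obs_sd < 0:
            raise ValueError("obs_sd must be non-negative")


@dataclass
class TruthRecord:
    """Ground truth for one generated fish."""

    fish_id: str
    true_departure: pd.Timestamp
    month: str
    stay_days: int
    amplitude_km: float          # D_max + b0_i
    intercept_dev: float         # b0_i
    slope_dev: float             # b1_i
    initial_speed: float         # km/day at migration start
    tau_days: float
    true_fate: str               # located / censoring / not_located
    true_arrival_chainage: float  # NaN unless located
    arrival_day: float           # days since release (NaN if never)
    end_day: int
    tag_release_day: float       # NaN for VHF-only fish
    signal_loss_day: float       # NaN if no loss drawn
    logger: bool
    ar_noise: np.ndarray = field(repr=False)

    def latent_distance(self, t) -> np.ndarray:
        """Latent along-river distance (km) at ``t`` days since release."""
        t = np.asarray(t, dtype=float)
        tm = np.clip(t - self.stay_days, 0.0, None)
        d = self.amplitude_km * (1.0 - np.exp(-tm / self.tau_days)) + self.slope_dev * tm
        return np.clip(d, 0.0, None)


class CohortData(NamedTuple):
    tracks: pd.DataFrame
    loggers: pd.DataFrame
    truth: list[TruthRecord]


# ---------------------------------------------------------------------------
# river
# ---------------------------------------------------------------------------


def generate_river(config: SynthConfig = SynthConfig()) -> RiverNetwork:
    """Build the synthetic river network (deterministic given the config)."""
    if config.river_length_km < max(config.section_bounds):
        raise ValueError("river shorter than its section boundaries")
    spacing = config.vertex_spacing_km
    if not (0 < spacing <= 1.0):
        raise ValueError("vertex spacing must be positive and at most 1 km")
    mainstem = _polyline(
        config.river_length_km, spacing, shape=config.mainstem_shape, phase=0.0
    )
    lower, narrow = config.section_bounds
    sections = {
        "lower": (0.0, lower),
        "narrow": (lower, narrow),
        "middle": (narrow, config.river_length_km),
    }
    net = RiverNetwork(mainstem, sections=sections)
    tribs = []
    for k, (junction, length) in enumerate(config.tributaries):
        start = net.point_at_chainage(junction)
        coords = _polyline(length, spacing, shape="meander", phase=1.0 + k)
        # rotate the tributary away from the mainstem and anchor at the mouth
        ang = 1.0 + 0.8 * k
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        tribs.append((junction, coords @ rot.T + start))
    return RiverNetwork(mainstem, tribs, sections=sections)


def _polyline(length_km: float, spacing_km: float, shape: str, phase: float) -> np.ndarray:
    n_full = int(length_km / spacing_km + 1e-9)
    steps = [spacing_km] * n_full
    rem = length_km - n_full * spacing_km
    if rem > 1e-9:
        steps.append(rem)
    pts = [np.zeros(2)]
    s = 0.0
    for step in steps:
        if shape == "straight":
            heading = math.pi / 2.0
        elif shape == "meander":
            heading = math.pi / 2.0 + 0.6 * math.sin(2.0 * math.pi * s / 40.0 + phase)
        else:
            raise ValueError("shape must be 'straight' or 'meander'")
        pts.append(pts[-1] + step * 1000.0 * np.array([math.cos(heading), math.sin(heading)]))
        s += step
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------


def generate_temperature_series(
    years: Sequence[int], config: SynthConfig = SynthConfig(), seed: int | None = None
) -> pd.Series:
    """Hourly river temperature over 1 Oct – 30 Nov for each year.

    ``T(year, day, hour) = T_start + drift * day + A * sin(diurnal)
    + offset_year + AR(1) noise``, rounded to the gauge resolution.
    """
    years = list(years)
    if not years:
        raise ValueError("year list must be non-empty")
    p = config.temp_params
    rng = substream(config.seed if seed is None else seed, "temperature")
    pieces = []
    for year in sorted(years):
        idx = pd.date_range(f"{year}-10-01", f"{year}-11-30 23:00", freq="h")
        day_idx = (idx.normalize() - pd.Timestamp(f"{year}-10-01")).days.to_numpy()
        hours = idx.hour.to_numpy()
        base = (
            p.T_start
            + p.drift_per_day * day_idx
            + p.diurnal_amp * np.sin(2.0 * np.pi * (hours - (p.diurnal_peak_hour - 6.0)) / 24.0)
            + p.year_offsets.get(year, 0.0)
        )
        noise = _ar1(rng, len(idx), p.noise_rho, p.noise_sd)
        values = base + noise
        if p.resolution > 0:
            values = np.round(values / p.resolution) * p.resolution
        pieces.append(pd.Series(values, index=idx, name="temp_c"))
    return pd.concat(pieces)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    z = rng.standard_normal(n)
    e = np.empty(n)
    e[0] = sd * z[0]
    innov = sd * math.sqrt(max(1.0 - rho * rho, 0.0))
    for t in range(1, n):
        e[t] = rho * e[t - 1] + innov * z[t]
    return e


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def generate_cohort(
    river: RiverNetwork,
    temps: pd.Series,
    config: SynthConfig = SynthConfig(),
    seed: int | None = None,
) -> CohortData:
    """Generate tagged fish: daily tracks, hourly logger records, truth.

    Fate mechanism per fish: it is *located* when the latent trajectory
    reaches its drawn spawning-target chainage and remains observed there
    for more than two days; scheduled tag-package release (uniform integer
    day in ``tag_release_range``) or signal loss truncates tracking and
    yields *censoring* (three or more fixes over at least two days) or
    *not located* otherwise.
    """
    rng = substream(config.seed if seed is None else seed, "cohort")
    if config.target_chainages is not None:
        if max(config.target_chainages) > river.length_km:
            raise ValueError("river shorter than the maximum target chainage")

    window_start = pd.Timestamp(config.departure_window[0])
    window_end = pd.Timestamp(config.departure_window[1])

    track_rows, logger_rows, truth = [], [], []
    for i in range(config.n_fish):
        fish_id = f"F{i:03d}"
        release = _draw_departure(rng, window_start, window_end, config.p_october)
        month = release.month_name()
        stay = int(rng.integers(1, config.max_stay_days + 1)) if rng.random() < config.p_stay else 0

        b0 = float(np.clip(rng.normal(0.0, config.sd_intercept), -2.5 * config.sd_intercept,
                           2.5 * config.sd_intercept))
        amplitude = config.D_max_km + b0
        b1 = float(rng.normal(0.0, config.sd_slope))
        v0 = amplitude / config.tau_days + b1
        v0 = float(np.clip(v0, *config.speed_band))
        b1 = v0 - amplitude / config.tau_days
        # keep the latent path non-decreasing over the tracking horizon
        b1_floor = -amplitude / config.tau_days * math.exp(
            -config.season_length_days / config.tau_days
        )
        b1 = max(b1, b1_floor + 0.05)

        if config.target_chainages is not None:
            target = float(config.target_chainages[i % len(config.target_chainages)])
        else:
            if month == "October":
                target = rng.normal(config.target_mean_oct, config.target_sd_oct)
            else:
                target = rng.normal(config.target_mean_nov, config.target_sd_nov)
            target = float(np.clip(target, config.target_min_km, river.length_km - 2.0))

        arrival_mig = _time_to_reach(amplitude, config.tau_days, b1, target)
        arrival_day = stay + arrival_mig if np.isfinite(arrival_mig) else math.inf

        logger = rng.random() < config.p_tag_package
        lo, hi = config.tag_release_range
        tag_day = float(rng.integers(lo, hi + 1)) if logger else math.inf
        if rng.random() < config.p_signal_loss:
            # next-day losses dominate in the field (weak signal, early death)
            loss_day = 1.0 if rng.random() < 0.5 else float(rng.integers(2, 9))
        else:
            loss_day = math.inf

        first_site_day = math.ceil(arrival_day - 1e-9) if np.isfinite(arrival_day) else math.inf
        horizon = min(tag_day, loss_day, float(config.season_length_days))
        end_day = int(min(horizon, first_site_day + config.post_arrival_days))

        days = np.arange(end_day + 1)
        if np.isfinite(arrival_day) and first_site_day <= end_day and (
            end_day - first_site_day
        ) > 2.0:
            fate = "located"
        elif end_day >= 2 and (
            amplitude * (1.0 - math.exp(-max(end_day - stay, 0) / config.tau_days))
            + b1 * max(end_day - stay, 0)
        ) > 1.0:
            fate = "censoring"  # tracked while genuinely migrating, then lost
        else:
            fate = "not_located"

        rec = TruthRecord(
            fish_id=fish_id,
            true_departure=release,
            month=month,
            stay_days=stay,
            amplitude_km=amplitude,
            intercept_dev=b0,
            slope_dev=b1,
            initial_speed=v0,
            tau_days=config.tau_days,
            true_fate=fate,
            true_arrival_chainage=target if fate == "located" else math.nan,
            arrival_day=arrival_day if np.isfinite(arrival_day) else math.nan,
            end_day=end_day,
            tag_release_day=tag_day if np.isfinite(tag_day) else math.nan,
            signal_loss_day=loss_day if np.isfinite(loss_day) else math.nan,
            logger=logger,
            ar_noise=_ar1(rng, len(days), config.phi_true, config.obs_sd),
        )
        latent = np.minimum(rec.latent_distance(days), target)
        observed = np.clip(latent + rec.ar_noise, 0.0, river.length_km)
        for d, chain in zip(days, observed):
            annotation = ""
            if np.isfinite(tag_day) and d == end_day and end_day == int(tag_day):
                annotation = "tag_release"
            xy = river.point_at_chainage(chain)
            track_rows.append(
                {
                    "fish_id": fish_id,
                    "timestamp": release + pd.Timedelta(days=int(d)),
                    "day": int(d),
                    "x_m": xy[0],
                    "y_m": xy[1],
                    "chainage_obs_km": chain,
                    "annotation": annotation,
                    "month": month,
                }
            )
        truth.append(rec)

        if logger:
            hours = pd.date_range(release, release + pd.Timedelta(days=end_day), freq="h")
            river_t = temps.reindex(hours)
            if river_t.isna().any():
                raise ValueError(
                    f"temperature record does not cover fish {fish_id}'s deployment"
                )
            offsets = rng.normal(config.logger_bias_mean, config.logger_bias_sd, len(hours))
            for ts, temp in zip(hours, river_t.to_numpy() + offsets):
                logger_rows.append({"fish_id": fish_id, "timestamp": ts, "temp_c": temp})

    tracks = pd.DataFrame(track_rows)
    loggers = pd.DataFrame(logger_rows, columns=["fish_id", "timestamp", "temp_c"])
    return CohortData(tracks=tracks, loggers=loggers, truth=truth)


def _draw_departure(rng, start: pd.Timestamp, end: pd.Timestamp, p_october: float) -> pd.Timestamp:
    oct_end = min(end, pd.Timestamp(year=start.year, month=10, day=31))
    nov_start = pd.Timestamp(year=end.year, month=11, day=1)
    if end < nov_start or rng.random() < p_october:
        lo, hi = start, oct_end
    else:
        lo, hi = max(start, nov_start), end
    span = max((hi - lo).days, 0)
    day = int(rng.integers(0, span + 1))
    return lo + pd.Timedelta(days=day, hours=9)


def _time_to_reach(amplitude: float, tau: float, b1: float, target: float) -> float:
    """Smallest t with amplitude*(1-exp(-t/tau)) + b1*t >= target (days).

    With a negative slope deviation the curve can peak and fall back, so
    the first crossing is bracketed on a grid before bisecting.
    """
    f = lambda t: amplitude * (1.0 - math.exp(-t / tau)) + b1 * t - target
    grid = np.arange(0.0, 60.25, 0.25)
    vals = np.array([f(t) for t in grid])
    hits = np.nonzero(vals >= 0)[0]
    if hits.size == 0:
        return math.inf
    if hits[0] == 0:
        return 0.0
    lo, hi = grid[hits[0] - 1], grid[hits[0]]
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_tracks_csv(tracks: pd.DataFrame, path) -> None:
    out = tracks[["fish_id", "timestamp", "x_m", "y_m", "annotation"]].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_temperature_csv(temps: pd.Series, path) -> None:
    df = temps.rename("temp_c").rename_axis("timestamp").reset_index()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def write_truth_json(truth: list[TruthRecord], path) -> None:
    payload = []
    for rec in truth:
        d = asdict(rec)
        d["true_departure"] = rec.true_departure.isoformat()
        d["ar_noise"] = [round(float(v), 6) for v in rec.ar_noise]
        payload.append(d)
    with open(path, "w") as fh:
        json.dump(payload, fh)
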