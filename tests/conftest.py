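import numpy as np
import pandas as pd
import pytest

import upriver as u


@pytest.fixture(scope="session")
def default_config():
    return u.SynthConfig(seed=11)


@pytest.fixture(scope="session")
def river(default_config):
    return u.generate_river(default_config)


@pytest.fixture(scope="session")
def temps(default_config):
    return u.generate_temperature_series([2021], default_config)


@pytest.fixture(scope="session")
def cohort(river, temps, default_config):
    return u.generate_cohort(river, temps, default_config)


@pytest.fixture(scope="session")
def projected(cohort, river):
    return u.snap_track(cohort.tracks, river)


@pytest.fixture(scope="session")
def fate_records(projected):
    return u.classify_cohort(projected)


@pytest.fixture(scope="session")
def calibrated_curve():
    """AAS curve reproducing the 17.6 / 12.8-20.8 °C optimum and window."""
    return u.calibrate_curve(17.6, 12.8, 20.8, 0.9)


def modelled_cohort_config(seed: int) -> "u.SynthConfig":
    """Study conditions for trajectory-recovery runs: 18 modelled fish,
    October departures, no signal loss or tag packages so the filter keeps
    the whole cohort."""
    return u.SynthConfig(
        seed=seed, n_fish=18, p_signal_loss=0.0, p_tag_package=0.0, p_october=1.0
    )


def fit_modelled_cohort(seed: int):
    cfg = modelled_cohort_config(seed)
    river = u.generate_river(cfg)
    temps = u.generate_temperature_series([2021], cfg)
    cohort = u.generate_cohort(river, temps, cfg)
    proj = u.snap_track(cohort.tracks, river)
    data = u.filter_tracking_data(proj, u.classify_cohort(proj))
    return u.fit_trajectory_model(data)


def simulate_mixed_linear(
    rng: np.random.Generator,
    n_fish: int = 18,
    n_t: int = 10,
    phi: float = 0.0,
    sd_resid: float = 0.5,
    sd_intercept: float = 1.0,
    sd_slope: float = 2.5,
    mean_fn=lambda t: 15.0 * t - 0.55 * t**2,
) -> pd.DataFrame:
    """Data drawn exactly from the trajectory model's own assumptions."""
    rows = []
    for i in range(n_fish):
        t = np.arange(n_t, dtype=float)
        a = rng.normal(0.0, sd_intercept)
        c = rng.normal(0.0, sd_slope)
        e = np.empty(n_t)
        e[0] = rng.normal(0.0, sd_resid)
        for k in range(1, n_t):
            e[k] = phi * e[k - 1] + rng.normal(0.0, sd_resid * np.sqrt(1.0 - phi**2))
        y = mean_fn(t) + a + c * t + e
        rows += [{"fish_id": f"S{i:02d}", "t": tt, "d": yy} for tt, yy in zip(t, y)]
    return pd.DataFrame(rows)
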