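"""Synthetic multi-environment maize trial generator.

Emulates the two tables a breeding-trial network produces: per-environment
daily weather and a hybrid × environment performance table, together with
the ground truth needed to validate the downstream analysis by parameter
recovery (per-hybrid stress-sensitivity slopes and per-environment stress
scores).

Each environment sits on two independent climate axes:

* a **heat axis** controlling the summer temperature peak and the air
  humidity (hotter sites have drier air, hence larger vapour pressure
  deficits — the dominant physiological pathway of extreme heat), and
* a **dryness axis** controlling rainfall occurrence and amounts.

Daily maximum temperature is a seasonal sinusoid plus AR(1) noise with a
positive diurnal range; precipitation is Bernoulli occurrence × Gamma
amounts — the classic stochastic weather-generator form.  Planting falls a
fixed fraction into the spring warm-up and harvest follows after an
environment-specific season length, so every season stage-splits cleanly.

Ground-truth stress scores are deterministic functions of the generated
weather (stage-3 extreme degree days and vapour pressure deficit for heat;
stage-2/3 precipitation deficits for drought), computed here with local
arithmetic rather than through the feature pipeline, so recovery tests are
not circular.  Scores are negative with larger magnitude meaning more
stress.  Yields follow

    yield(h, e) = base_h + beta_heat_h · S_heat(e) + beta_drought_h · S_drought(e) + ε

with the drought term suppressed under normal irrigation, ε Gaussian, and
yields truncated at zero.  Each hybrid is assigned environments spanning
the stress range: one from the most-stressed heat decile, one from the
most-stressed drought decile (both preferring non-irrigated sites), one
per cell of a 3×3 heat×drought tercile grid, and random fill-ins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stress_features import SOIL_FEATURES, WEATHER_COLUMNS

logger = logging.getLogger(__name__)

IRRIGATION_CATEGORIES = ("none", "very_light", "light", "normal")

# substream tags: one global seed expands to per-entity generators so the
# output is reproducible independent of generation order
_PARAMS, _WEATHER, _ENV, _HYBRID, _ASSIGN = range(5)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic trial network."""

    n_environments: int = 150
    n_hybrids: int = 120
    years: Sequence[int] = (2014, 2015, 2016)
    season_length_range: tuple[int, int] = (150, 180)
    #: summer Tmax peak at the cool and hot end of the heat axis (°C)
    temp_peak_range: tuple[float, float] = (24.0, 38.0)
    temp_amplitude: float = 14.0
    temp_noise_sd: float = 3.0
    temp_ar1: float = 0.7
    diurnal_range_mean: float = 11.0
    diurnal_range_sd: float = 2.0
    #: wet-day probability at the wet and dry end of the dryness axis
    wet_day_prob_range: tuple[float, float] = (0.55, 0.15)
    rain_gamma_shape: float = 0.8
    rain_gamma_scale_range: tuple[float, float] = (8.0, 5.0)
    #: vapour pressure as a fraction of saturation at the cool and hot end
    humidity_factor_range: tuple[float, float] = (0.92, 0.45)
    planting_warmup_fraction: float = 0.55
    frac_heat_tolerant: float = 0.5
    frac_drought_tolerant: float = 0.5
    tolerant_slope_range: tuple[float, float] = (0.2, 0.8)
    susceptible_slope_range: tuple[float, float] = (1.4, 2.2)
    base_yield_mean: float = 110.0
    base_yield_sd: float = 8.0
    yield_noise_sd: float = 2.5
    # reported shares of irrigation levels across trial sites (77.96 / 0.16
    # / 1.77 / 22.11 %), renormalized to sum to one
    irrigation_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "none": 0.7796 / 1.02,
            "very_light": 0.0016 / 1.02,
            "light": 0.0177 / 1.02,
            "normal": 0.2211 / 1.02,
        }
    )
    envs_per_hybrid: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_environments < 2:
            raise ConfigurationError("n_environments must be >= 2")
        if self.n_hybrids < 1:
            raise ConfigurationError("n_hybrids must be >= 1")
        lo, hi = self.season_length_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("invalid season_length_range")
        for p in (*self.wet_day_prob_range, *self.humidity_factor_range,
                  self.frac_heat_tolerant, self.frac_drought_tolerant):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        probs = dict(self.irrigation_probs)
        if set(probs) != set(IRRIGATION_CATEGORIES):
            raise ConfigurationError(
                f"irrigation_probs must cover exactly {IRRIGATION_CATEGORIES}"
            )
        if any(not 0.0 <= p <= 1.0 for p in probs.values()):
            raise ConfigurationError("irrigation probabilities must lie in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("irrigation probabilities must sum to 1")
        if self.envs_per_hybrid < 2:
            raise ConfigurationError("envs_per_hybrid must be >= 2")
        if self.envs_per_hybrid > self.n_environments:
            raise ConfigurationError("envs_per_hybrid exceeds n_environments")
        if self.yield_noise_sd < 0:
            raise ConfigurationError("yield_noise_sd must be >= 0")


@dataclass(frozen=True)
class TrueHybridProfile:
    """Planted ground truth for one hybrid."""

    hybrid_id: str
    beta_heat: float
    beta_drought: float
    base_yield: float

    def __post_init__(self) -> None:
        if self.base_yield <= 0:
            raise ConfigurationError("base_yield must be positive")


@dataclass
class EnvRealization:
    """One simulated environment: climate axes, calendar, soil, weather."""

    env_id: str
    year: int
    heat_axis: float
    dry_axis: float
    planting_date: pd.Timestamp
    harvest_date: pd.Timestamp
    irrigation: str
    soil: dict[str, float]
    weather: pd.DataFrame
    s_heat: float
    s_drought: float


def env_id_for(index: int) -> str:
    return f"Env_{index:04d}"


@dataclass(frozen=True)
class _EnvParams:
    heat_axis: float
    dry_axis: float
    season_length: int
    temp_peak: float
    wet_day_prob: float
    rain_scale: float
    humidity: float


def _env_params(config: GeneratorConfig, env_index: int) -> _EnvParams:
    rng = _rng(config.seed, _PARAMS, env_index)
    t = float(rng.uniform())
    q = float(rng.uniform())
    lo, hi = config.season_length_range
    season_length = int(rng.integers(lo, hi + 1))

    def lerp(pair, x):
        return pair[0] + (pair[1] - pair[0]) * x

    return _EnvParams(
        heat_axis=t,
        dry_axis=q,
        season_length=season_length,
        temp_peak=lerp(config.temp_peak_range, t),
        wet_day_prob=lerp(config.wet_day_prob_range, q),
        rain_scale=lerp(config.rain_gamma_scale_range, q),
        humidity=lerp(config.humidity_factor_range, t),
    )


def _saturation_vp(t_c: np.ndarray) -> np.ndarray:
    # Magnus form, duplicated locally so truth arithmetic stays independent
    return 610.78 * np.exp(17.27 * t_c / (t_c + 237.3))


def generate_weather(config: GeneratorConfig, env_index: int) -> pd.DataFrame:
    """One calendar year of daily weather for environment ``env_index``.

    Deterministic given ``config.seed``: each environment draws from its own
    substream.  Tmax is a mid-July-peaked sinusoid plus AR(1) noise, Tmin is
    Tmax minus a positive diurnal range, precipitation is Bernoulli × Gamma,
    and vapour pressure is the environment's humidity factor times
    saturation at the daily mean temperature (so a factor of 1 gives
    saturated air and zero vapour pressure deficit everywhere).
    """
    params = _env_params(config, env_index)
    year = config.years[env_index % len(config.years)]
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy(float)
    rng = _rng(config.seed, _WEATHER, env_index)

    seasonal = params.temp_peak - config.temp_amplitude * (
        1.0 - np.cos(2.0 * np.pi * (doy - 200.0) / 365.25)
    )
    ar = np.empty(n)
    innov_sd = config.temp_noise_sd * np.sqrt(1.0 - config.temp_ar1**2)
    ar[0] = rng.normal(0.0, config.temp_noise_sd)
    shocks = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        ar[i] = config.temp_ar1 * ar[i - 1] + shocks[i - 1]
    tmax = seasonal + ar
    diurnal = np.clip(
        rng.normal(config.diurnal_range_mean, config.diurnal_range_sd, n), 3.0, None
    )
    tmin = tmax - diurnal
    tmean = (tmax + tmin) / 2.0

    wet = rng.random(n) < params.wet_day_prob
    amounts = rng.gamma(config.rain_gamma_shape, params.rain_scale, n)
    precip = np.where(wet, amounts, 0.0)

    es = _saturation_vp(tmean)
    vp = np.clip(params.humidity * es, 1e-6, es)

    day_length = 43200.0 + 10800.0 * np.cos(2.0 * np.pi * (doy - 172.0) / 365.25)
    solar = np.clip(
        250.0 + 120.0 * np.cos(2.0 * np.pi * (doy - 172.0) / 365.25)
        + rng.normal(0.0, 30.0, n),
        20.0,
        None,
    )
    swe = np.where(tmean < 0.0, 10.0, 0.0)

    return pd.DataFrame(
        {
            "date": dates,
            "day_length_s": day_length,
            "solar_radiation_wm2": solar,
            "tmax_c": tmax,
            "tmin_c": tmin,
            "precip_mm": precip,
            "vapour_pressure_pa": vp,
            "swe_kgm2": swe,
        }
    )[WEATHER_COLUMNS]


# coefficients turning weather aggregates into ground-truth stress scores
# (quintals/ha of yield change per unit of a unit-sensitivity hybrid)
_HEAT_EDD_COEF = 0.05      # per °C·day of stage-3 EDD
_HEAT_VPD_COEF = 0.35      # per mbar of stage-3 mean VPD
_DROUGHT_DEFICIT_COEF = 0.12   # per mm of stage-2/3 precipitation deficit
_CROP_DEMAND_MM_PER_DAY = 2.5


def true_stress_scores(
    weather: pd.DataFrame,
    planting_date: pd.Timestamp,
    harvest_date: pd.Timestamp,
) -> tuple[float, float]:
    """Deterministic ground-truth (S_heat, S_drought) for one season.

    Same functional families as the engineered features but computed with
    local, floor-based stage arithmetic independent of the feature pipeline.
    Both scores are <= 0; more negative means more stress.
    """
    idx = pd.DatetimeIndex(pd.to_datetime(weather["date"]))
    w = weather.set_index(idx)
    season = w.loc[
        pd.Timestamp(planting_date) : pd.Timestamp(harvest_date) - pd.Timedelta(days=1)
    ]
    gsl = len(season)
    b1, b2, b3 = int(0.30 * gsl), int(0.50 * gsl), int(0.75 * gsl)
    tmax = season["tmax_c"].to_numpy(float)
    tmin = season["tmin_c"].to_numpy(float)
    precip = season["precip_mm"].to_numpy(float)
    vp = season["vapour_pressure_pa"].to_numpy(float)

    edd3 = float(np.clip(tmax[b2:b3] - 30.0, 0.0, None).sum())
    tmean3 = (tmax[b2:b3] + tmin[b2:b3]) / 2.0
    vpd3 = float(
        np.clip(_saturation_vp(tmean3) - vp[b2:b3], 0.0, None).mean() / 100.0
    )
    s_heat = -(_HEAT_EDD_COEF * edd3 + _HEAT_VPD_COEF * vpd3)

    deficit2 = max(0.0, _CROP_DEMAND_MM_PER_DAY * (b2 - b1) - float(precip[b1:b2].sum()))
    deficit3 = max(0.0, _CROP_DEMAND_MM_PER_DAY * (b3 - b2) - float(precip[b2:b3].sum()))
    s_drought = -_DROUGHT_DEFICIT_COEF * (deficit2 + deficit3)
    return s_heat, s_drought


def _planting_doy(config: GeneratorConfig) -> int:
    # fixed fraction into the warm-up from the seasonal minimum (doy ~17)
    # to the seasonal maximum (doy ~200)
    return int(round(17 + config.planting_warmup_fraction * (200 - 17)))


def _generate_soil(rng: np.random.Generator) -> dict[str, float]:
    texture = rng.dirichlet((4.0, 3.0, 3.0)) * 100.0
    return {
        "sand": float(texture[0]),
        "clay": float(texture[1]),
        "silt": float(texture[2]),
        "ph": float(np.clip(rng.normal(6.5, 0.5), 4.5, 8.5)),
        "om": float(rng.lognormal(0.8, 0.4)),
        "cec": float(np.clip(rng.normal(15.0, 4.0), 2.0, None)),
        "awc": float(np.clip(rng.normal(0.12, 0.03), 0.02, 0.30)),
        "ksat": float(rng.lognormal(2.5, 0.8)),
    }


def generate_environment(config: GeneratorConfig, env_index: int) -> EnvRealization:
    """Weather, calendar, irrigation, soil and truth scores for one env."""
    params = _env_params(config, env_index)
    weather = generate_weather(config, env_index)
    year = config.years[env_index % len(config.years)]
    planting = pd.Timestamp(year, 1, 1) + pd.Timedelta(days=_planting_doy(config) - 1)
    harvest = planting + pd.Timedelta(days=params.season_length)
    rng = _rng(config.seed, _ENV, env_index)
    probs = [config.irrigation_probs[c] for c in IRRIGATION_CATEGORIES]
    irrigation = str(rng.choice(IRRIGATION_CATEGORIES, p=probs))
    soil = _generate_soil(rng)
    s_heat, s_drought = true_stress_scores(weather, planting, harvest)
    return EnvRealization(
        env_id=env_id_for(env_index),
        year=year,
        heat_axis=params.heat_axis,
        dry_axis=params.dry_axis,
        planting_date=planting,
        harvest_date=harvest,
        irrigation=irrigation,
        soil=soil,
        weather=weather,
        s_heat=s_heat,
        s_drought=s_drought,
    )


def generate_profiles(config: GeneratorConfig) -> list[TrueHybridProfile]:
    """Draw per-hybrid base yields and heat/drought sensitivity slopes."""
    profiles = []
    for j in range(config.n_hybrids):
        rng = _rng(config.seed, _HYBRID, j)
        beta_heat = float(
            rng.uniform(*config.tolerant_slope_range)
            if rng.random() < config.frac_heat_tolerant
            else rng.uniform(*config.susceptible_slope_range)
        )
        beta_drought = float(
            rng.uniform(*config.tolerant_slope_range)
            if rng.random() < config.frac_drought_tolerant
            else rng.uniform(*config.susceptible_slope_range)
        )
        base = float(max(40.0, rng.normal(config.base_yield_mean, config.base_yield_sd)))
        profiles.append(TrueHybridProfile(f"H{j:04d}", beta_heat, beta_drought, base))
    return profiles


def _assign_environments(
    config: GeneratorConfig,
    environments: Sequence[EnvRealization],
    hybrid_index: int,
) -> list[int]:
    """Pick a subset of environments spanning both stress axes.

    The exposure design is balanced so each hybrid sees the full range of
    both stresses with the two axes close to orthogonal across its sites
    (otherwise the separate heat and drought stability regressions would
    confound each other).  Guarantees: one environment from the
    most-stressed heat decile and one from the most-stressed drought decile
    (preferring sites without normal irrigation, which the stability
    analysis later excludes, and near-median on the other axis), one per
    cell of a 3×3 heat×drought tercile grid (preferring the environment
    most representative of the cell centre), random fill for the rest.
    """
    rng = _rng(config.seed, _ASSIGN, hybrid_index)
    k = config.envs_per_hybrid
    n = len(environments)
    s_heat = np.array([e.s_heat for e in environments])
    s_drought = np.array([e.s_drought for e in environments])
    nonnormal = np.array([e.irrigation != "normal" for e in environments])
    # rank-scaled coordinates so "near the centre" is unit-free
    h_rank = np.argsort(np.argsort(s_heat)) / max(n - 1, 1)
    d_rank = np.argsort(np.argsort(s_drought)) / max(n - 1, 1)

    chosen: list[int] = []

    def pick_near(pool, target_h=None, target_d=None, n_best=2):
        """Pick from ``pool``, preferring sites closest to the rank-space
        target; a small random choice among the best keeps designs varied."""
        avail = np.array([i for i in pool if i not in chosen])
        if avail.size == 0:
            return
        if target_h is None and target_d is None:
            chosen.append(int(rng.choice(avail)))
            return
        dist = np.zeros(avail.size)
        if target_h is not None:
            dist += (h_rank[avail] - target_h) ** 2
        if target_d is not None:
            dist += (d_rank[avail] - target_d) ** 2
        best = avail[np.argsort(dist)[: min(n_best, avail.size)]]
        chosen.append(int(rng.choice(best)))

    def decile_pool(scores):
        thr = np.quantile(scores, 0.10)
        pool = np.flatnonzero((scores <= thr) & nonnormal)
        return pool if pool.size else np.flatnonzero(scores <= thr)

    # extreme exposures, kept median on the other axis
    pick_near(decile_pool(s_heat), target_d=0.5)
    pick_near(decile_pool(s_drought), target_h=0.5)

    h_cell = np.digitize(h_rank, [1 / 3, 2 / 3])
    d_cell = np.digitize(d_rank, [1 / 3, 2 / 3])
    centres = (1 / 6, 3 / 6, 5 / 6)
    cells = [(a, b) for a in range(3) for b in range(3)]
    for ci in rng.permutation(len(cells)):
        if len(chosen) >= k:
            break
        a, b = cells[ci]
        pick_near(
            np.flatnonzero((h_cell == a) & (d_cell == b)),
            target_h=centres[a],
            target_d=centres[b],
        )
    while len(chosen) < min(k, n):
        pick_near(np.arange(n))
    return sorted(chosen)


def generate_performance(
    config: GeneratorConfig,
    environments: Sequence[EnvRealization],
    profiles: Sequence[TrueHybridProfile],
) -> pd.DataFrame:
    """Hybrid × environment performance table with planted yield model.

    yield = base + beta_heat·S_heat + beta_drought·S_drought + ε, the
    drought term dropped under normal irrigation, truncated at zero.
    """
    if len(profiles) != config.n_hybrids:
        raise ConfigurationError("profiles must cover all hybrids")
    rows = []
    for j, profile in enumerate(profiles):
        assigned = _assign_environments(config, environments, j)
        if len(assigned) < 2:
            logger.warning(
                "hybrid %s grown in < 2 environments; stability will be "
                "undefined",
                profile.hybrid_id,
            )
        rng = _rng(config.seed, _ASSIGN, j, 1)
        for i in assigned:
            env = environments[i]
            drought_term = 0.0 if env.irrigation == "normal" else (
                profile.beta_drought * env.s_drought
            )
            y = (
                profile.base_yield
                + profile.beta_heat * env.s_heat
                + drought_term
                + rng.normal(0.0, config.yield_noise_sd)
            )
            rows.append(
                {
                    "hybrid_id": profile.hybrid_id,
                    "env_id": env.env_id,
                    "yield": max(0.0, y),
                    "planting_date": env.planting_date,
                    "harvest_date": env.harvest_date,
                    "irrigation": env.irrigation,
                    **env.soil,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SyntheticDataset:
    """Everything one simulated trial network produces, truth included."""

    config: GeneratorConfig
    environments: list[EnvRealization]
    profiles: list[TrueHybridProfile]
    performance: pd.DataFrame

    @property
    def weather(self) -> dict[str, pd.DataFrame]:
        return {e.env_id: e.weather for e in self.environments}

    @property
    def truth_hybrids(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hybrid_id": [p.hybrid_id for p in self.profiles],
                "beta_heat": [p.beta_heat for p in self.profiles],
                "beta_drought": [p.beta_drought for p in self.profiles],
                "base_yield": [p.base_yield for p in self.profiles],
                "heat_tolerant_true": [p.beta_heat < 1.0 for p in self.profiles],
                "drought_tolerant_true": [p.beta_drought < 1.0 for p in self.profiles],
            }
        )

    @property
    def truth_envs(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "env_id": [e.env_id for e in self.environments],
                "s_heat": [e.s_heat for e in self.environments],
                "s_drought": [e.s_drought for e in self.environments],
                "heat_axis": [e.heat_axis for e in self.environments],
                "dry_axis": [e.dry_axis for e in self.environments],
                "irrigation": [e.irrigation for e in self.environments],
            }
        )

    def write(self, out_dir) -> None:
        """Write weather_<env>.csv per environment, performance.csv and the
        two truth tables (hybrid betas; environment stress scores)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for env in self.environments:
            w = env.weather.copy()
            w["date"] = w["date"].dt.date
            w.to_csv(out / f"weather_{env.env_id}.csv", index=False)
        perf = self.performance.copy()
        for col in ("planting_date", "harvest_date"):
            perf[col] = pd.to_datetime(perf[col]).dt.date
        perf.to_csv(out / "performance.csv", index=False)
        self.truth_hybrids.to_csv(out / "truth_hybrids.csv", index=False)
        self.truth_envs.to_csv(out / "truth_envs.csv", index=False)


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a full synthetic trial network from one seed."""
    environments = [
        generate_environment(config, i) for i in range(config.n_environments)
    ]
    profiles = generate_profiles(config)
    performance = generate_performance(config, environments, profiles)
    return SyntheticDataset(config, environments, profiles, performance)
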