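"""Stage-windowed heat and drought stress features from daily weather.

The growing season [planting, harvest) is split into four phenology-anchored
windows ending at ~30%, 50% and 75% of the growing season length (GSL),
roughly planting→tasseling (VT), VT→blister (R2), milk (R3)→physiological
maturity (R6), and R6→harvest.  Within each window we compute:

heat group (12 features)
    EDD1–4   extreme degree days, sum of max(0, Tmax − 30 °C)  [°C·days]
    CTD1–4   longest run of tropical days, Tmax > 30 °C        [days]
    CTN1–4   longest run of tropical nights, Tmin > 20 °C      [days]

drought group (14 features)
    PS1–4    precipitation sum                                  [mm]
    CDD1–4   longest run of dry days, precipitation < 1 mm      [days]
    VPD1–4   mean daily vapour pressure deficit                 [mbar]
    HTC2–3   Selyaninov hydrothermal coefficient, stages 2–3    [-]

HTC is only defined for the mid-season stages; early and late windows are
frequently too cool for its temperature sum, so only HTC2 and HTC3 enter the
feature vector.  Appending the eight soil descriptors gives a 34-element
vector per environment.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# thresholds (°C, mm) from the extreme-climate-index definitions in use
EDD_THRESHOLD_C = 30.0
TROPICAL_DAY_C = 30.0
TROPICAL_NIGHT_C = 20.0
DRY_DAY_MM = 1.0
HTC_BASE_C = 10.0

STAGE_FRACTIONS = (0.30, 0.50, 0.75)

HEAT_FEATURES = [f"{m}{s}" for m in ("EDD", "CTD", "CTN") for s in (1, 2, 3, 4)]
DROUGHT_FEATURES = (
    [f"{m}{s}" for m in ("PS", "CDD", "VPD") for s in (1, 2, 3, 4)]
    + ["HTC2", "HTC3"]
)
MET_FEATURES = HEAT_FEATURES + DROUGHT_FEATURES
SOIL_FEATURES = ["sand", "clay", "silt", "ph", "om", "cec", "awc", "ksat"]
ALL_FEATURES = MET_FEATURES + SOIL_FEATURES

#: canonical column order of a daily weather table
WEATHER_COLUMNS = [
    "date",
    "day_length_s",
    "solar_radiation_wm2",
    "tmax_c",
    "tmin_c",
    "precip_mm",
    "vapour_pressure_pa",
    "swe_kgm2",
]


class MissingWeatherError(ValueError):
    """Raised when the weather table does not cover the full season."""


def saturation_vapour_pressure(t_c):
    """Saturation vapour pressure in Pa over water at ``t_c`` °C.

    Magnus form es = 610.78 · exp(17.27 T / (T + 237.3)).
    """
    t = np.asarray(t_c, dtype=float)
    return 610.78 * np.exp(17.27 * t / (t + 237.3))


@dataclass(frozen=True)
class StageWindows:
    """Four half-open day-offset intervals partitioning [0, GSL)."""

    bounds: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        b = self.bounds
        if len(b) != 5 or b[0] != 0:
            raise ValueError("bounds must be (0, b1, b2, b3, gsl)")
        if any(b[i] >= b[i + 1] for i in range(4)):
            raise ValueError(f"stage windows must all be non-empty, got {b}")

    @property
    def gsl(self) -> int:
        return self.bounds[4]

    @property
    def lengths(self) -> tuple[int, int, int, int]:
        b = self.bounds
        return tuple(b[i + 1] - b[i] for i in range(4))  # type: ignore[return-value]

    def __iter__(self) -> Iterator[tuple[int, int]]:
        b = self.bounds
        for i in range(4):
            yield b[i], b[i + 1]


def split_stages(planting_date: dt.date, harvest_date: dt.date) -> StageWindows:
    """Partition the season into the four stress-sensitivity windows.

    Boundaries fall at round(0.30·GSL), round(0.50·GSL) and round(0.75·GSL)
    days after planting (banker's rounding on the half); windows are
    half-open ``[start, end)`` day offsets from planting.  Seasons shorter
    than 4 days cannot host four non-empty windows and are rejected.
    """
    gsl = (pd.Timestamp(harvest_date) - pd.Timestamp(planting_date)).days
    if gsl < 4:
        raise ValueError(
            f"growing season of {gsl} days cannot be split into four stages"
        )
    b1, b2, b3 = (int(round(f * gsl)) for f in STAGE_FRACTIONS)
    # guard against degenerate rounding on very short seasons
    b1 = max(b1, 1)
    b2 = max(b2, b1 + 1)
    b3 = min(max(b3, b2 + 1), gsl - 1)
    return StageWindows((0, b1, b2, b3, gsl))


def longest_run(mask) -> int:
    """Length of the longest contiguous run of True in a boolean series."""
    a = np.asarray(mask, dtype=bool)
    if a.size == 0:
        logger.warning("longest_run called on an empty series")
        return 0
    padded = np.concatenate(([False], a, [False]))
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    if changes.size == 0:
        return 0
    runs = changes[1::2] - changes[::2]
    return int(runs.max())


def edd(tmax_c) -> float:
    """Extreme degree days: Σ max(0, Tmax − 30 °C) over the window."""
    t = np.asarray(tmax_c, dtype=float)
    return float(np.clip(t - EDD_THRESHOLD_C, 0.0, None).sum())


def htc(precip_mm, tavg_c) -> float:
    """Selyaninov hydrothermal coefficient for one window.

    ΣP divided by one tenth of the sum of daily mean temperatures above
    10 °C; values in (0, 1) indicate dry conditions.  Returns NaN when no
    day in the window exceeds 10 °C (undefined denominator); callers impute
    the column median across environments before modelling.
    """
    p = np.asarray(precip_mm, dtype=float)
    t = np.asarray(tavg_c, dtype=float)
    warm = t[t > HTC_BASE_C]
    denom = 0.1 * warm.sum()
    if denom <= 0.0:
        return float("nan")
    return float(p.sum() / denom)


def vpd(tmax_c, tmin_c, vapour_pressure_pa) -> float:
    """Stage-mean vapour pressure deficit in mbar.

    Daily deficit = max(0, es(Tmean) − e_a) with Tmean = (Tmax + Tmin)/2 and
    es from the Magnus formula; supersaturated days (e_a > es) clamp to zero
    but still count toward the mean.
    """
    tmean = (np.asarray(tmax_c, float) + np.asarray(tmin_c, float)) / 2.0
    ea = np.asarray(vapour_pressure_pa, dtype=float)
    deficit = saturation_vapour_pressure(tmean) - ea
    n_super = int((deficit < 0).sum())
    if n_super:
        logger.info("clamped %d supersaturated days to zero deficit", n_super)
    deficit = np.clip(deficit, 0.0, None)
    if deficit.size == 0:
        return 0.0
    return float(deficit.mean() / 100.0)  # Pa -> mbar


def validate_weather(weather: pd.DataFrame) -> None:
    """Check a daily weather table for schema and physical consistency."""
    missing = [c for c in WEATHER_COLUMNS if c not in weather.columns]
    if missing:
        raise ValueError(f"weather table missing columns: {missing}")
    if (weather["tmax_c"] < weather["tmin_c"]).any():
        raise ValueError("tmax_c < tmin_c on some days")
    if (weather["precip_mm"] < 0).any():
        raise ValueError("negative precipitation")
    if (weather["vapour_pressure_pa"] <= 0).any():
        raise ValueError("non-positive vapour pressure")
    if (weather["swe_kgm2"] < 0).any():
        raise ValueError("negative snow water equivalent")


def extract_features(
    weather: pd.DataFrame,
    planting_date: dt.date,
    harvest_date: dt.date,
    soil: Mapping[str, float],
) -> pd.Series:
    """Compute the 34-element feature vector for one environment.

    26 meteorological features over the four stage windows plus the eight
    soil descriptors, in the canonical ``ALL_FEATURES`` order.  The weather
    table must cover every day of [planting, harvest).
    """
    validate_weather(weather)
    windows = split_stages(planting_date, harvest_date)
    idx = pd.DatetimeIndex(pd.to_datetime(weather["date"]))
    needed = pd.date_range(
        pd.Timestamp(planting_date),
        pd.Timestamp(harvest_date) - pd.Timedelta(days=1),
    )
    missing = needed.difference(idx)
    if len(missing):
        raise MissingWeatherError(
            "weather gap inside the season: "
            + ", ".join(d.date().isoformat() for d in missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    season = weather.set_index(idx).loc[needed]
    tmax = season["tmax_c"].to_numpy(float)
    tmin = season["tmin_c"].to_numpy(float)
    precip = season["precip_mm"].to_numpy(float)
    ea = season["vapour_pressure_pa"].to_numpy(float)
    tavg = (tmax + tmin) / 2.0

    values: dict[str, float] = {}
    for stage, (s, e) in enumerate(windows, start=1):
        values[f"EDD{stage}"] = edd(tmax[s:e])
        values[f"CTD{stage}"] = float(longest_run(tmax[s:e] > TROPICAL_DAY_C))
        values[f"CTN{stage}"] = float(longest_run(tmin[s:e] > TROPICAL_NIGHT_C))
        values[f"PS{stage}"] = float(precip[s:e].sum())
        values[f"CDD{stage}"] = float(longest_run(precip[s:e] < DRY_DAY_MM))
        values[f"VPD{stage}"] = vpd(tmax[s:e], tmin[s:e], ea[s:e])
        if stage in (2, 3):
            values[f"HTC{stage}"] = htc(precip[s:e], tavg[s:e])

    for name in SOIL_FEATURES:
        if name not in soil:
            raise KeyError(f"soil descriptor '{name}' missing")
        values[name] = float(soil[name])

    return pd.Series([values[f] for f in ALL_FEATURES], index=ALL_FEATURES)


def impute_missing(features: pd.DataFrame) -> pd.DataFrame:
    """Median-impute NaN feature values (undefined HTC) column-wise."""
    out = features.copy()
    for col in out.columns:
        n_nan = int(out[col].isna().sum())
        if n_nan == 0:
            continue
        med = out[col].median()
        if np.isnan(med):
            logger.warning("feature %s undefined everywhere; imputing 0", col)
            med = 0.0
        else:
            logger.info("imputed %d missing values of %s with median", n_nan, col)
        out[col] = out[col].fillna(med)
    return out


def features_table(
    weather_by_env: Mapping[str, pd.DataFrame],
    env_table: pd.DataFrame,
) -> pd.DataFrame:
    """Feature matrix for an environment table, one 34-column row per env.

    ``env_table`` needs env_id, planting_date, harvest_date and the soil
    columns (as produced by :func:`maizestress.performance_io.environment_table`).
    Undefined HTC values are median-imputed across environments.
    """
    rows = {}
    for rec in env_table.itertuples(index=False):
        env_id = rec.env_id
        if env_id not in weather_by_env:
            raise KeyError(f"no weather table for environment {env_id}")
        soil = {name: getattr(rec, name) for name in SOIL_FEATURES}
        rows[env_id] = extract_features(
            weather_by_env[env_id], rec.planting_date, rec.harvest_date, soil
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "env_id"
    return impute_missing(table)
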