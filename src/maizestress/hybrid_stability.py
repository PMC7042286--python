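"""Yield-stability regression and stress-tolerance classification of hybrids.

For each hybrid, ordinary least squares regresses its yields on the heat
and drought stress totals of the environments where it was grown —
separately, and jointly in a two-predictor regression — after excluding
samples under normal irrigation (irrigation removes the stress the index
measures).  The slope is a Finlay–Wilkinson-style adaptability measure:
stress totals become more negative with more stress, so a stress-sensitive
hybrid loses yield fast and shows a large positive slope, while slope < 1
marks stable yields and a stress-tolerant hybrid.

A hybrid can only earn a tolerance label for a stress type if it was grown
in at least one extreme environment (total below the 10th percentile) of
that type; hybrids never exposed to extreme conditions are non-tolerant by
definition.  Combined tolerance additionally requires both two-predictor
slopes below 1.  Negative slopes (yield rising with stress) satisfy the
literal slope < 1 rule and are classified tolerant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SLOPE_THRESHOLD = 1.0

SUMMARY_CATEGORIES = (
    "none",
    "drought_only",
    "heat_only",
    "heat_and_drought",
    "heat_drought_combined",
)


class ClassificationRuleError(RuntimeError):
    """A label combination outside the admissible set was produced."""


@dataclass
class Slopes:
    """OLS slopes of yield on stress; None where the fit is undefined."""

    slope_heat: float | None
    slope_drought: float | None
    slope_heat_multi: float | None
    slope_drought_multi: float | None
    n_env_used: int
    reason: str = ""


def _single_slope(x: np.ndarray, y: np.ndarray) -> float | None:
    if len(x) < 2 or np.ptp(x) == 0:
        return None
    return float(np.polyfit(x, y, 1)[0])


def stability_slopes(yields, heat_totals, drought_totals) -> Slopes:
    """Per-hybrid OLS slopes; inputs are aligned per-environment vectors.

    Callers must already have excluded normal-irrigation samples.  Single
    slopes need >= 2 environments with distinct stress values; the joint
    fit needs >= 3 environments and a full-rank (non-collinear) design.
    """
    y = np.asarray(yields, float)
    h = np.asarray(heat_totals, float)
    d = np.asarray(drought_totals, float)
    n = len(y)
    reason = ""
    if n < 2:
        return Slopes(None, None, None, None, n, "insufficient exposure")

    sh = _single_slope(h, y)
    sd = _single_slope(d, y)
    shm = sdm = None
    if n >= 3:
        design = np.column_stack([np.ones(n), h, d])
        if np.linalg.matrix_rank(design) == 3:
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            shm, sdm = float(coef[1]), float(coef[2])
        else:
            reason = "collinear stress totals"
    else:
        reason = "fewer than 3 environments for the joint fit"
    if sh is None or sd is None:
        reason = reason or "degenerate stress values"
    return Slopes(sh, sd, shm, sdm, n, reason)


def classify(
    slopes: Slopes,
    grown_in_extreme_heat: bool,
    grown_in_extreme_drought: bool,
) -> tuple[bool, bool, bool]:
    """(heat_tolerant, drought_tolerant, combined_tolerant) labels.

    Tolerance requires exposure to the relevant extreme conditions and a
    defined slope below 1.  Combined tolerance requires both single labels
    plus both joint-regression slopes below 1, keeping the label set
    consistent with the five admissible category combinations.
    """
    heat_tol = bool(
        grown_in_extreme_heat
        and slopes.slope_heat is not None
        and slopes.slope_heat < SLOPE_THRESHOLD
    )
    drought_tol = bool(
        grown_in_extreme_drought
        and slopes.slope_drought is not None
        and slopes.slope_drought < SLOPE_THRESHOLD
    )
    combined_tol = bool(
        heat_tol
        and drought_tol
        and slopes.slope_heat_multi is not None
        and slopes.slope_drought_multi is not None
        and slopes.slope_heat_multi < SLOPE_THRESHOLD
        and slopes.slope_drought_multi < SLOPE_THRESHOLD
    )
    return heat_tol, drought_tol, combined_tol


def classify_hybrids(
    performance: pd.DataFrame, stress: pd.DataFrame
) -> pd.DataFrame:
    """Stability slopes and tolerance labels for every hybrid.

    ``performance`` is a cleaned performance table; ``stress`` is the
    ranked stress table with heat_total/drought_total and extreme flags per
    env_id.  Extreme exposure counts any growing environment; slope fits
    exclude normal-irrigation samples.
    """
    required = {"env_id", "heat_total", "drought_total", "extreme_heat",
                "extreme_drought"}
    missing = required - set(stress.columns)
    if missing:
        raise KeyError(f"stress table missing columns: {sorted(missing)}")
    merged = performance.merge(stress, on="env_id", how="left", validate="m:1")
    if merged["heat_total"].isna().any():
        bad = merged.loc[merged["heat_total"].isna(), "env_id"].unique()
        raise KeyError(f"no stress totals for environments: {list(bad)[:5]}")

    rows = []
    for hybrid_id, grp in merged.groupby("hybrid_id", sort=True):
        grown_eh = bool(grp["extreme_heat"].any())
        grown_ed = bool(grp["extreme_drought"].any())
        fit_grp = grp[grp["irrigation"] != "normal"]
        slopes = stability_slopes(
            fit_grp["yield"], fit_grp["heat_total"], fit_grp["drought_total"]
        )
        heat_tol, drought_tol, combined_tol = classify(slopes, grown_eh, grown_ed)
        rows.append(
            {
                "hybrid_id": hybrid_id,
                "n_env_used": slopes.n_env_used,
                "slope_heat": slopes.slope_heat,
                "slope_drought": slopes.slope_drought,
                "slope_heat_multi": slopes.slope_heat_multi,
                "slope_drought_multi": slopes.slope_drought_multi,
                "grown_in_extreme_heat": grown_eh,
                "grown_in_extreme_drought": grown_ed,
                "heat_tolerant": heat_tol,
                "drought_tolerant": drought_tol,
                "combined_tolerant": combined_tol,
                "reason": slopes.reason,
            }
        )
    return pd.DataFrame(rows)


def classification_summary(results: pd.DataFrame) -> dict[str, int]:
    """Counts over the five admissible label combinations.

    none; drought only; heat only; heat + drought but not combined; all
    three.  Any other combination indicates a rule bug and raises
    :class:`ClassificationRuleError`.
    """
    counts = dict.fromkeys(SUMMARY_CATEGORIES, 0)
    for rec in results.itertuples(index=False):
        key = (bool(rec.heat_tolerant), bool(rec.drought_tolerant),
               bool(rec.combined_tolerant))
        category = {
            (False, False, False): "none",
            (False, True, False): "drought_only",
            (True, False, False): "heat_only",
            (True, True, False): "heat_and_drought",
            (True, True, True): "heat_drought_combined",
        }.get(key)
        if category is None:
            raise ClassificationRuleError(
                f"hybrid {rec.hybrid_id} has inadmissible labels {key}"
            )
        counts[category] += 1
    return counts


@dataclass
class IrrigationContrast:
    """Irrigated-vs-rainfed mean yield difference for one hybrid."""

    hybrid_id: str
    mean_difference: float
    t_statistic: float | None
    p_value: float | None
    n_normal: int
    n_other: int


def irrigation_contrast(
    performance: pd.DataFrame, hybrid_id: str
) -> IrrigationContrast:
    """Difference between mean yield under normal irrigation and elsewhere,
    with a two-sided Welch t-test (needs >= 2 samples in each group;
    otherwise the difference is reported and the test skipped)."""
    grp = performance[performance["hybrid_id"] == hybrid_id]
    normal = grp.loc[grp["irrigation"] == "normal", "yield"].to_numpy(float)
    other = grp.loc[grp["irrigation"] != "normal", "yield"].to_numpy(float)
    if len(normal) == 0 or len(other) == 0:
        raise ValueError(
            f"hybrid {hybrid_id} lacks samples in one irrigation group"
        )
    diff = float(normal.mean() - other.mean())
    if len(normal) < 2 or len(other) < 2:
        logger.info("hybrid %s: too few samples for a t-test", hybrid_id)
        return IrrigationContrast(hybrid_id, diff, None, None, len(normal), len(other))
    t, p = stats.ttest_ind(normal, other, equal_var=False)
    if np.isnan(t):  # both groups constant: no within-group variance
        t = 0.0
        p = 1.0 if diff == 0.0 else 0.0
    return IrrigationContrast(
        hybrid_id, diff, float(t), float(p), len(normal), len(other)
    )
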