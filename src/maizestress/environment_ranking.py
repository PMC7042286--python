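"""Environment stress indices and ranking from explained contributions.

Each environment's observed feature value is approximated by the nearest of
its 11 grid values and the mean contribution at that grid point is looked
up.  Summing the looked-up contributions over the 12 heat features gives
the environment's total heat stress, over the 14 drought features its total
drought stress, both in quintals/ha of predicted yield change.  Lower
(more negative) totals mean more stress; environments below the 10th
percentile of either total count as extreme.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .stress_features import DROUGHT_FEATURES, HEAT_FEATURES

EXTREME_PERCENTILE = 10.0


def nearest_grid_value(x: float, grid) -> float:
    """Grid point minimizing |x − g|; ties go to the lower value.

    Values outside the grid range clamp to the nearest endpoint.
    """
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty grid")
    # argmin keeps the first (lower) point on an exact midpoint tie
    return float(grid[int(np.argmin(np.abs(grid - x)))])


def _lookup(x: float, grid: np.ndarray, deltas: np.ndarray) -> float:
    return float(deltas[int(np.argmin(np.abs(grid - x)))])


def total_stress(
    features: Mapping[str, float] | pd.Series,
    contributions: pd.DataFrame,
) -> tuple[float, float]:
    """(heat_total, drought_total) for one environment.

    ``contributions`` is the table produced by
    :func:`maizestress.contribution_explainer.explain_all`.  The lookup uses
    mean_delta regardless of the significance flag; soil features are not
    part of either total.
    """
    by_feature = {f: grp for f, grp in contributions.groupby("feature")}
    totals = {"heat": 0.0, "drought": 0.0}
    for group, names in (("heat", HEAT_FEATURES), ("drought", DROUGHT_FEATURES)):
        for name in names:
            if name not in by_feature:
                raise KeyError(f"no contribution grid for feature '{name}'")
            grp = by_feature[name].sort_values("grid_value")
            totals[group] += _lookup(
                float(features[name]),
                grp["grid_value"].to_numpy(float),
                grp["mean_delta"].to_numpy(float),
            )
    return totals["heat"], totals["drought"]


def stress_table(
    features: pd.DataFrame, contributions: pd.DataFrame
) -> pd.DataFrame:
    """Per-environment stress totals for a feature matrix indexed by env_id."""
    rows = []
    for env_id, feat in features.iterrows():
        heat, drought = total_stress(feat, contributions)
        rows.append({"env_id": env_id, "heat_total": heat, "drought_total": drought})
    return pd.DataFrame(rows)


def rank_environments(
    stress: pd.DataFrame, percentile: float = EXTREME_PERCENTILE
) -> pd.DataFrame:
    """Rank environments by stress and flag extremes.

    Rank 1 is the most stressed (lowest total); ties break stably by
    env_id.  An environment is extreme when its total is strictly below the
    linear-interpolation percentile of that stress type.
    """
    out = stress.copy()
    for kind in ("heat", "drought"):
        col = f"{kind}_total"
        order = out.sort_values([col, "env_id"], kind="stable").index
        ranks = pd.Series(np.arange(1, len(out) + 1), index=order)
        out[f"{kind}_rank"] = ranks.reindex(out.index).astype(int)
        threshold = np.percentile(out[col].to_numpy(float), percentile)
        out[f"extreme_{kind}"] = out[col] < threshold
    return out
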