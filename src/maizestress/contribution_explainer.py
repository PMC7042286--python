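"""Perturbation-based explanation of the yield model.

For every feature the observed range is divided into 10 bands bounded by 11
equidistant grid values.  A fixed draw of surrogate rows is pushed through
the model twice — unaltered, and with the feature forced to the grid value
— and the mean and standard deviation of the 500 per-row yield differences
quantify that value's contribution.  The sign convention is altered minus
original, so a negative mean means the value depresses predicted yield; a
contribution is flagged significant when mean + SD < 0, i.e. even an
optimistic one-SD reading stays below zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_GRID = 11
N_ALTER = 500


def build_grid(features: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-feature grids of 11 equidistant values over the observed range.

    Grids come from the original environment data, not the surrogates.
    Constant features get a single-point grid and are flagged inert.
    """
    grids: dict[str, np.ndarray] = {}
    for col in features.columns:
        lo = float(features[col].min())
        hi = float(features[col].max())
        if hi <= lo:
            logger.warning("feature %s is constant; inert single-point grid", col)
            grids[col] = np.array([lo])
        else:
            grids[col] = np.linspace(lo, hi, N_GRID)
    return grids


def _draw_rows(n_surrogates: int, n: int, seed: int) -> np.ndarray:
    if n > n_surrogates:
        raise ValueError(f"cannot draw {n} rows from {n_surrogates} surrogates")
    return np.random.default_rng(seed).choice(n_surrogates, size=n, replace=False)


def contribution(
    model,
    surrogates: pd.DataFrame,
    feature: str,
    value: float,
    n: int = N_ALTER,
    seed: int = 0,
    rows: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean and SD of yield change when ``feature`` is forced to ``value``.

    ``rows`` allows reusing one fixed draw across many (feature, value)
    tests; otherwise ``n`` rows are drawn without replacement using ``seed``.
    SD uses the n−1 (sample) denominator.
    """
    if rows is None:
        rows = _draw_rows(len(surrogates), n, seed)
    sub = surrogates.iloc[rows]
    base = np.asarray(model.predict(sub.to_numpy(float)), float)
    altered = sub.copy()
    altered[feature] = value
    pred = np.asarray(model.predict(altered.to_numpy(float)), float)
    delta = pred - base
    sd = float(np.std(delta, ddof=1)) if len(delta) > 1 else 0.0
    return float(delta.mean()), sd


def explain_all(
    model,
    surrogates: pd.DataFrame,
    grids: dict[str, np.ndarray],
    n: int = N_ALTER,
    seed: int = 0,
    resample_per_test: bool = False,
) -> pd.DataFrame:
    """Contribution grid for every feature: columns feature, grid_index,
    grid_value, mean_delta, sd_delta, significant.

    One fixed draw of ``n`` surrogate rows is reused for every
    (feature, value) pair unless ``resample_per_test`` asks for an
    independent draw per test (noisier between grid points but closer to
    fully independent Monte Carlo).
    """
    fixed_rows = None if resample_per_test else _draw_rows(len(surrogates), n, seed)
    records = []
    test_counter = 0
    for feature, grid in grids.items():
        for gi, value in enumerate(grid):
            if resample_per_test:
                rows = _draw_rows(len(surrogates), n, seed + 1 + test_counter)
                test_counter += 1
            else:
                rows = fixed_rows
            mean_d, sd_d = contribution(
                model, surrogates, feature, float(value), n=n, rows=rows
            )
            records.append(
                {
                    "feature": feature,
                    "grid_index": gi,
                    "grid_value": float(value),
                    "mean_delta": mean_d,
                    "sd_delta": sd_d,
                    "significant": bool(mean_d + sd_d < 0.0),
                }
            )
    return pd.DataFrame(records)
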