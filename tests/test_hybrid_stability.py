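"""Yield-stability slopes, tolerance classification and irrigation contrast."""

import numpy as np
import pandas as pd
import pytest

from maizestress import hybrid_stability as hs


def _slopes(**kw):
    base = dict(slope_heat=0.5, slope_drought=0.5, slope_heat_multi=0.5,
                slope_drought_multi=0.5, n_env_used=8)
    base.update(kw)
    return hs.Slopes(**base)


class TestStabilitySlopes:
    def test_noiseless_linear_yield_recovers_slope(self):
        heat = np.array([-8.0, -5.0, -3.0, -1.0])
        yields = 0.5 * heat + 100.0
        out = hs.stability_slopes(yields, heat, np.zeros(4) - 1.0)
        assert out.slope_heat == pytest.approx(0.5)

    def test_constant_yield_gives_zero_slopes(self):
        out = hs.stability_slopes(
            np.full(5, 90.0), np.arange(5.0) - 9.0, np.arange(5.0) - 7.0)
        assert out.slope_heat == pytest.approx(0.0, abs=1e-12)
        assert out.slope_drought == pytest.approx(0.0, abs=1e-12)

    def test_six_points_match_normal_equations(self):
        rng = np.random.default_rng(4)
        h = rng.uniform(-10, 0, 6)
        d = rng.uniform(-12, 0, 6)
        y = 1.7 * h + 0.4 * d + rng.normal(0, 1, 6) + 95.0
        out = hs.stability_slopes(y, h, d)
        # closed-form single OLS slope
        assert out.slope_heat == pytest.approx(
            np.cov(h, y, ddof=1)[0, 1] / np.var(h, ddof=1))
        # normal equations for the joint fit
        X = np.column_stack([np.ones(6), h, d])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert out.slope_heat_multi == pytest.approx(beta[1])
        assert out.slope_drought_multi == pytest.approx(beta[2])

    def test_degenerate_inputs_flagged(self):
        out = hs.stability_slopes([100.0], [-1.0], [-1.0])
        assert out.slope_heat is None
        assert out.reason == "insufficient exposure"
        collinear = hs.stability_slopes(
            [90.0, 95.0, 99.0], [-1.0, -2.0, -3.0], [-2.0, -4.0, -6.0])
        assert collinear.slope_heat_multi is None
        assert "collinear" in collinear.reason


class TestClassify:
    def test_tolerant_when_slope_below_one_and_exposed(self):
        assert hs.classify(_slopes(), True, True) == (True, True, True)

    def test_steep_slope_is_susceptible(self):
        labels = hs.classify(_slopes(slope_heat=1.2), True, True)
        assert labels[0] is False

    def test_never_grown_in_extremes_is_non_tolerant(self):
        labels = hs.classify(_slopes(slope_heat=0.3), False, True)
        assert labels[0] is False and labels[2] is False

    def test_undefined_slopes_are_non_tolerant(self):
        slopes = _slopes(slope_heat=None, slope_heat_multi=None)
        assert hs.classify(slopes, True, True) == (False, True, False)

    def test_monotone_in_slope(self):
        for slope in (2.0, 1.0, 0.99, 0.2, -0.5):
            tolerant = hs.classify(_slopes(slope_heat=slope), True, True)[0]
            lowered = hs.classify(_slopes(slope_heat=slope - 0.5), True, True)[0]
            assert lowered >= tolerant  # lowering never flips to non-tolerant


def _grid_scenario(betas, noise=0.0, seed=0):
    """Performance + stress tables over a 4x4 grid of stress combinations."""
    heat_levels = np.array([-12.0, -8.0, -4.0, -0.5])
    drought_levels = np.array([-14.0, -9.0, -5.0, -1.0])
    # small offsets break ties so the strict <10th-percentile rule flags
    # the most stressed corner environments as extreme
    envs = [
        {"env_id": f"E{i}{j}", "heat_total": h + 0.01 * j,
         "drought_total": d + 0.01 * i}
        for i, h in enumerate(heat_levels)
        for j, d in enumerate(drought_levels)
    ]
    stress = hs.pd.DataFrame(envs)
    from maizestress.environment_ranking import rank_environments

    stress = rank_environments(stress)
    rng = np.random.default_rng(seed)
    rows = []
    for hybrid, (bh, bd) in betas.items():
        for env in envs:
            rows.append({
                "hybrid_id": hybrid, "env_id": env["env_id"],
                "yield": max(0.0, 100.0 + bh * env["heat_total"]
                             + bd * env["drought_total"]
                             + rng.normal(0.0, noise)),
                "irrigation": "none",
            })
    return pd.DataFrame(rows), stress


class TestClassifyHybrids:
    def test_planted_all_tolerant_fraction_recovered_exactly(self):
        # 10 hybrids, 20% planted tolerant to everything, noiseless
        betas = {f"T{i}": (0.4, 0.5) for i in range(2)}
        betas.update({f"S{i}": (1.8, 1.6) for i in range(8)})
        performance, stress = _grid_scenario(betas)
        results = hs.classify_hybrids(performance, stress)
        summary = hs.classification_summary(results)
        assert summary["heat_drought_combined"] == 2
        assert summary["none"] == 8
        assert sum(summary.values()) == 10

    def test_only_low_stress_exposure_counts_as_none(self):
        betas = {"H1": (0.2, 0.2)}
        performance, stress = _grid_scenario(betas)
        # keep only the mildest environments (no extremes)
        mild = stress.nlargest(6, "heat_total")["env_id"]
        performance = performance[performance["env_id"].isin(mild)]
        results = hs.classify_hybrids(performance, stress)
        summary = hs.classification_summary(results)
        assert summary["none"] == 1

    def test_removing_irrigated_rows_of_others_leaves_slope_alone(self):
        betas = {"H1": (0.5, 0.5), "H2": (1.5, 1.5)}
        performance, stress = _grid_scenario(betas)
        performance.loc[performance["hybrid_id"] == "H2", "irrigation"] = "normal"
        with_h2 = hs.classify_hybrids(performance, stress)
        only_h1 = hs.classify_hybrids(
            performance[performance["hybrid_id"] == "H1"], stress)
        h1_a = with_h2.set_index("hybrid_id").loc["H1", "slope_heat"]
        h1_b = only_h1.set_index("hybrid_id").loc["H1", "slope_heat"]
        assert h1_a == pytest.approx(h1_b)

    def test_inadmissible_combination_raises(self):
        results = pd.DataFrame([{
            "hybrid_id": "X", "heat_tolerant": False,
            "drought_tolerant": False, "combined_tolerant": True,
        }])
        with pytest.raises(hs.ClassificationRuleError):
            hs.classification_summary(results)


class TestIrrigationContrast:
    def _frame(self, normal, other):
        rows = [{"hybrid_id": "H1", "irrigation": "normal", "yield": y}
                for y in normal]
        rows += [{"hybrid_id": "H1", "irrigation": "none", "yield": y}
                 for y in other]
        return pd.DataFrame(rows)

    def test_identical_groups(self):
        out = hs.irrigation_contrast(
            self._frame([90.0, 100.0, 110.0], [90.0, 100.0, 110.0]), "H1")
        assert out.mean_difference == 0.0
        assert out.p_value == pytest.approx(1.0)

    def test_constant_groups_mean_shift(self):
        out = hs.irrigation_contrast(
            self._frame([100.0] * 3, [80.0] * 3), "H1")
        assert out.mean_difference == pytest.approx(20.0)
        assert out.p_value == 0.0

    def test_welch_statistic_hand_formula(self):
        a = np.array([101.0, 104.0, 99.0, 110.0])
        b = np.array([90.0, 85.0, 97.0, 88.0, 92.0])
        out = hs.irrigation_contrast(self._frame(a, b), "H1")
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert out.t_statistic == pytest.approx((a.mean() - b.mean()) / se)

    def test_single_sample_group_skips_test(self):
        out = hs.irrigation_contrast(self._frame([100.0], [80.0, 90.0]), "H1")
        assert out.p_value is None
        assert out.mean_difference == pytest.approx(15.0)
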