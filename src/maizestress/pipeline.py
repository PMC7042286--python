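"""End-to-end orchestration of the environment-stress analysis.

Preprocess the performance table, build the environment table and feature
matrix, evaluate and fit the yield model, fit the surrogate density model,
explain feature contributions, rank environments by stress and classify
hybrids — one call, all seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from . import (
    contribution_explainer,
    density_enrichment,
    environment_ranking,
    hybrid_stability,
    performance_io,
    stress_features,
    yield_model,
)


@dataclass
class PipelineResult:
    """All intermediate and final artefacts of one pipeline run."""

    preprocess_report: performance_io.PreprocessReport
    env_table: pd.DataFrame
    features: pd.DataFrame
    evaluation_all: yield_model.ModelEvaluation
    evaluation_excl_normal: yield_model.ModelEvaluation | None
    model: object
    pca: density_enrichment.PcaTransform
    component_scan: density_enrichment.ComponentScan
    gmm: density_enrichment.GmmModel
    surrogates: pd.DataFrame
    contributions: pd.DataFrame
    stress: pd.DataFrame
    stability: pd.DataFrame
    summary: dict[str, int]


def run_pipeline(
    performance: pd.DataFrame,
    weather_by_env: Mapping[str, pd.DataFrame],
    seed: int = 0,
    k_folds: int = 10,
    n_surrogates: int = 10_000,
    n_alter: int = 500,
) -> PipelineResult:
    """Run the full analysis on a performance table plus weather tables.

    The cross-validated evaluation is reported both on all environments and
    on the subset without normal irrigation (when large enough); the model
    used for explanation is refit on all environments.
    """
    clean, report = performance_io.preprocess(performance)
    env_table = performance_io.environment_table(clean)
    features = stress_features.features_table(weather_by_env, env_table)
    features = features.loc[env_table["env_id"]]
    y = pd.Series(env_table["mean_yield"].to_numpy(), index=features.index)

    evaluation_all = yield_model.cross_validate(features, y, k=k_folds, seed=seed)
    excl_mask = (env_table["irrigation"] != "normal").to_numpy()
    evaluation_excl = None
    if excl_mask.sum() >= max(k_folds, yield_model.MIN_ENVIRONMENTS):
        evaluation_excl = yield_model.cross_validate(
            features[excl_mask], y[excl_mask], k=k_folds, seed=seed
        )

    model = yield_model.fit(features, y, seed=seed)

    pca = density_enrichment.fit_pca(features)
    projected = pca.transform(features)
    scan = density_enrichment.select_components(projected, seed=seed)
    gmm = density_enrichment.fit_vbgmm(projected, scan.m_init, seed=seed)
    surrogates = density_enrichment.sample_surrogates(gmm, pca, n_surrogates, seed=seed)

    grids = contribution_explainer.build_grid(features)
    contributions = contribution_explainer.explain_all(
        model, surrogates, grids, n=n_alter, seed=seed
    )

    stress = environment_ranking.stress_table(features, contributions)
    stress = environment_ranking.rank_environments(stress)

    stability = hybrid_stability.classify_hybrids(clean, stress)
    summary = hybrid_stability.classification_summary(stability)

    return PipelineResult(
        preprocess_report=report,
        env_table=env_table,
        features=features,
        evaluation_all=evaluation_all,
        evaluation_excl_normal=evaluation_excl,
        model=model,
        pca=pca,
        component_scan=scan,
        gmm=gmm,
        surrogates=surrogates,
        contributions=contributions,
        stress=stress,
        stability=stability,
        summary=summary,
    )
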