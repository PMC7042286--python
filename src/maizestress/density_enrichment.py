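"""Density modelling of the environment feature vectors and surrogate sampling.

The 34 features are z-scored, projected by PCA onto the smallest subspace
explaining >= 99% of variance, and modelled there with a Gaussian mixture
p(w) = Σ_j π_j N(w; μ_j, Σ_j).  The component count is initialized from an
AIC/BIC scan of plain EM fits (M = 2…20, minimum of the two argmins) and
refined by a variational Bayesian GMM with a stick-breaking (truncated
Dirichlet-process) weight prior, which prunes surplus components by driving
their weights toward zero.  Surrogate feature vectors are drawn in the
subspace and mapped back through the inverse PCA/standardization transform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.mixture import BayesianGaussianMixture, GaussianMixture

logger = logging.getLogger(__name__)

VARIANCE_TARGET = 0.99
WEIGHT_FLOOR = 1e-3  # components above this weight count as "effective"
M_SCAN_RANGE = (2, 20)


@dataclass
class PcaTransform:
    """Standardization + truncated PCA with forward and inverse maps."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (k, d) loadings on standardized features
    explained_variance_ratio: np.ndarray  # all components, not just k
    feature_names: list[str] | None = None

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        return (X - self.mean) / self.scale @ self.components.T

    def inverse(self, W) -> np.ndarray:
        W = np.asarray(W, float)
        return W @ self.components * self.scale + self.mean

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaTransform":
        return cls(
            mean=np.asarray(d["mean"], float),
            scale=np.asarray(d["scale"], float),
            components=np.asarray(d["components"], float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], float),
            feature_names=d.get("feature_names"),
        )


def fit_pca(X, variance_target: float = VARIANCE_TARGET) -> PcaTransform:
    """Standardize and fit PCA keeping the smallest k reaching the target.

    Features are z-scored first: raw units (mbar, mm, percentage points)
    are incommensurate and would otherwise dominate the variance budget.
    Constant columns get unit scale so they survive the round trip.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a PCA")
    if np.isnan(X).any():
        raise ValueError("missing values must be imputed before PCA")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    pca = PCA().fit(Z)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    reach = np.flatnonzero(cum >= variance_target - 1e-12)
    if reach.size:
        k = int(reach[0]) + 1
    else:
        k = len(evr)  # rank-deficient input: cap at rank
        logger.warning("variance target %.2f unreachable; k capped at rank %d",
                       variance_target, k)
    return PcaTransform(
        mean=mean,
        scale=scale,
        components=pca.components_[:k].copy(),
        explained_variance_ratio=evr,
        feature_names=names,
    )


@dataclass
class ComponentScan:
    """AIC/BIC scan of EM-GMM fits used to seed the variational fit."""

    m_values: list[int]
    aic: list[float]
    bic: list[float]
    m_init: int


def _choose_m(m_values, aic, bic) -> int:
    """Initial component count: min of the AIC argmin and the BIC argmin.

    np.argmin takes the first occurrence, so ties break toward smaller M.
    """
    m_values = np.asarray(m_values)
    return int(min(m_values[np.argmin(aic)], m_values[np.argmin(bic)]))


def select_components(
    W, seed: int = 0, m_min: int = M_SCAN_RANGE[0], m_max: int = M_SCAN_RANGE[1]
) -> ComponentScan:
    """Scan EM-GMM component counts and pick the parsimonious criterion min."""
    W = np.asarray(W, float)
    if W.shape[0] <= m_max:
        m_max = max(m_min, W.shape[0] - 1)
        logger.warning("few samples; scan truncated at M=%d", m_max)
    ms, aics, bics = [], [], []
    for m in range(m_min, m_max + 1):
        try:
            gm = GaussianMixture(
                n_components=m, covariance_type="full", random_state=seed
            ).fit(W)
        except Exception as exc:  # EM failure: skip this M
            logger.warning("EM-GMM failed at M=%d: %s", m, exc)
            continue
        ms.append(m)
        aics.append(float(gm.aic(W)))
        bics.append(float(gm.bic(W)))
    if not ms:
        raise RuntimeError("EM-GMM failed at every component count")
    return ComponentScan(ms, aics, bics, _choose_m(ms, aics, bics))


@dataclass
class GmmModel:
    """Fitted mixture in the PCA subspace: weights, means, full covariances."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    converged: bool = True
    weight_floor: float = WEIGHT_FLOOR

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-6 or (self.weights < 0).any():
            raise ValueError("mixture weights must be a probability vector")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def effective_components(self) -> int:
        return int((self.weights > self.weight_floor).sum())

    def log_density(self, W) -> np.ndarray:
        from scipy.stats import multivariate_normal

        W = np.atleast_2d(np.asarray(W, float))
        comp = np.stack(
            [
                np.log(max(self.weights[j], 1e-300))
                + multivariate_normal.logpdf(
                    W, self.means[j], self.covariances[j], allow_singular=True
                )
                for j in range(self.n_components)
            ]
        )
        from scipy.special import logsumexp

        return logsumexp(comp, axis=0)

    def to_json(self, path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "converged": self.converged,
            "weight_floor": self.weight_floor,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GmmModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            weights=np.asarray(d["weights"], float),
            means=np.asarray(d["means"], float),
            covariances=np.asarray(d["covariances"], float),
            converged=d["converged"],
            weight_floor=d["weight_floor"],
        )


def fit_vbgmm(
    W,
    m_init: int,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 500,
) -> GmmModel:
    """Variational Bayesian GMM with stick-breaking prior truncated at m_init.

    Dirichlet concentration 1/m_init (a common stick-breaking default);
    covariances are regularized to stay positive definite.  On
    non-convergence the best iterate is returned with ``converged=False``.
    """
    W = np.asarray(W, float)
    vb = BayesianGaussianMixture(
        n_components=m_init,
        covariance_type="full",
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=1.0 / m_init,
        random_state=seed,
        tol=tol,
        max_iter=max_iter,
        reg_covar=1e-6,
    ).fit(W)
    if not vb.converged_:
        logger.warning("VB-GMM did not converge within %d iterations", max_iter)
    return GmmModel(
        weights=vb.weights_.copy(),
        means=vb.means_.copy(),
        covariances=vb.covariances_.copy(),
        converged=bool(vb.converged_),
    )


def sample_surrogates(
    gmm: GmmModel, pca: PcaTransform, n: int, seed: int = 0
) -> pd.DataFrame:
    """Draw ``n`` surrogate feature vectors in the original feature space.

    Component indicators then Gaussian draws via Cholesky factors, all from
    one seeded generator; the subspace sample is back-projected through the
    inverse PCA transform.  Values are not clipped to observed ranges.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    comp = rng.choice(gmm.n_components, size=n, p=gmm.weights)
    k = gmm.means.shape[1]
    z = rng.standard_normal((n, k))
    W = np.empty((n, k))
    for j in range(gmm.n_components):
        idx = np.flatnonzero(comp == j)
        if idx.size == 0:
            continue
        cov = gmm.covariances[j]
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(cov + 1e-9 * np.eye(k))
        W[idx] = gmm.means[j] + z[idx] @ L.T
    X = pca.inverse(W)
    columns = pca.feature_names or [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=columns)
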