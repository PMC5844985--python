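"""Comparison methods as module-level functions over the estimator classes.

These wrap :mod:`mmpen.estimators` for callers holding the domain containers
(:class:`GenotypeMatrix`, :class:`Phenotype`) rather than bare arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix, NoiseModel, Phenotype
from .estimators import ElasticNetCD, RegPIRegressor, UnivariateRegressor

__all__ = [
    "ElasticNetConfig",
    "univariate_regression",
    "regpi_closed_form",
    "elastic_net_cd",
    "cv_select_lambda",
]


@dataclass
class ElasticNetConfig:
    alpha: float = 1.0
    lam: float = 0.508
    max_sweeps: int = 1000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam <= 0:
            raise ValueError("lam must be positive")


def _unpack(g, y):
    X = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    yv = y.values if isinstance(y, Phenotype) else np.asarray(y, dtype=float)
    return X, yv


def univariate_regression(g, y) -> tuple[np.ndarray, np.ndarray]:
    """Marginal slope and standard error per SNP."""
    X, yv = _unpack(g, y)
    est = UnivariateRegressor().fit(X, yv)
    return est.coef_, est.stderr_


def regpi_closed_form(g, y, noise: NoiseModel | float,
                      prior_precision: np.ndarray) -> np.ndarray:
    """Generalized-ridge closed form (X'S^-1X + D)^-1 X'S^-1 y."""
    X, yv = _unpack(g, y)
    sigma2 = float(noise.sigma2[0]) if isinstance(noise, NoiseModel) else float(noise)
    est = RegPIRegressor(prior_precision=prior_precision,
                         noise_variance=sigma2).fit(X, yv)
    return est.coef_


def elastic_net_cd(g, y, config: ElasticNetConfig) -> np.ndarray:
    """Coordinate-descent elastic net / LASSO on the unscaled RSS objective."""
    X, yv = _unpack(g, y)
    est = ElasticNetCD(alpha=config.alpha, lam=config.lam,
                       max_sweeps=config.max_sweeps, tol=config.tol).fit(X, yv)
    return est.coef_


def cv_select_lambda(g, y, lambda_grid, folds: int = 2,
                     config: ElasticNetConfig | None = None,
                     seed: int = 0) -> tuple[float, list[float]]:
    """Pick lambda by k-fold cross-validated held-out phenotype NMSE.

    Samples are split by a seeded permutation; per lambda the score is the
    mean over folds of ||y_val - X_val b_train||^2 / ||y_val||^2.  Ties break
    toward the larger lambda (sparser model).
    """
    config = config or ElasticNetConfig()
    lambda_grid = list(lambda_grid)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if not lambda_grid:
        raise ValueError("lambda grid is empty")
    X, yv = _unpack(g, y)
    N = len(yv)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    fold_idx = [perm[i::folds] for i in range(folds)]
    for idx in fold_idx:
        if np.var(yv[idx]) == 0:
            raise ValueError("a CV fold has zero phenotype variance")

    nmse = []
    for lam in lambda_grid:
        scores = []
        for i in range(folds):
            val = fold_idx[i]
            train = np.concatenate([fold_idx[j] for j in range(folds) if j != i])
            est = ElasticNetCD(alpha=config.alpha, lam=lam,
                               max_sweeps=config.max_sweeps,
                               tol=config.tol).fit(X[train], yv[train])
            pred = X[val] @ est.coef_
            scores.append(float(np.sum((yv[val] - pred) ** 2) / np.sum(yv[val] ** 2)))
        nmse.append(float(np.mean(scores)))

    best = 0
    for i in range(1, len(lambda_grid)):
        # strict improvement or tie with larger lambda wins
        if nmse[i] < nmse[best] or (nmse[i] == nmse[best]
                                    and lambda_grid[i] > lambda_grid[best]):
            best = i
    return float(lambda_grid[best]), nmse
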