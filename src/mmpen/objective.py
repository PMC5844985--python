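"""Objective F = L + w·C: Gaussian negative log-likelihood plus mixture penalty.

L is the negative log of a Gaussian likelihood N(Xb, Sigma_eps) with diagonal
Sigma_eps.  C is the spike-and-slab penalty: per SNP j the cost is
``c_j = -log[ pi1_j * p1(b_j) + (1 - pi1_j) * p0(b_j) ]`` where p1 is a normal
"slab" of sd slab_sd_j and p0 is either a narrow normal spike or a smoothed
Laplace null.  All mixture arithmetic runs in log space (log-sum-exp), so the
penalty, its gradient and its curvature stay finite for extreme beta and for
pi1 down to the smallest positive floats.

Because the penalty is separable, its Hessian is diagonal; the Hessian of F is
X' Sigma^-1 X + w * diag(curvature), so Hessian-vector products need only two
matrix-vector products and one elementwise product — the full n x n matrix is
never formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import GenotypeMatrix, NoiseModel, Phenotype, PriorSpec

__all__ = [
    "ObjectiveConfig",
    "ObjectiveEvaluation",
    "component_pdf",
    "component_logpdf_derivs",
    "penalty_terms",
    "neg_log_likelihood",
    "hessian_vector_product",
    "evaluate_objective",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ObjectiveConfig:
    """weight multiplies the penalty C in F = L + weight * C (default: equal)."""

    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("penalty weight must be positive")


@dataclass
class ObjectiveEvaluation:
    F: float
    L: float
    C: float
    gradient: np.ndarray
    responsibilities: np.ndarray


def component_pdf(beta_j: float, family: str, scale: float,
                  smoothing_eps: float = 0.0) -> float:
    """Density of one mixture component at ``beta_j``.

    normal:  (2 pi s^2)^{-1/2} exp(-b^2 / 2 s^2)
    laplace: (2 b)^{-1} exp(-sqrt(beta^2 + eps) / b)   (smoothed |beta|)
    """
    if scale <= 0:
        raise ValueError("component scale must be positive")
    b = float(beta_j)
    if family == "normal":
        return float(np.exp(-0.5 * (b / scale) ** 2) / (np.sqrt(2 * np.pi) * scale))
    if family == "laplace":
        s = np.sqrt(b * b + smoothing_eps)
        return float(np.exp(-s / scale) / (2.0 * scale))
    raise ValueError(f"unknown component family {family!r}")


def component_logpdf_derivs(beta: np.ndarray, family: str, scale: np.ndarray,
                            smoothing_eps: float = 0.0
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log p, p'/p, p''/p) for a component, vectorized over SNPs."""
    beta = np.asarray(beta, dtype=float)
    scale = np.broadcast_to(np.asarray(scale, dtype=float), beta.shape)
    if family == "normal":
        var = scale**2
        logp = -0.5 * LOG_2PI - np.log(scale) - 0.5 * beta**2 / var
        d1 = -beta / var                       # (log p)' = p'/p
        d2 = d1**2 - 1.0 / var                 # p''/p = (p'/p)^2 + (log p)''
        return logp, d1, d2
    if family == "laplace":
        s = np.sqrt(beta**2 + smoothing_eps)
        s = np.maximum(s, 1e-300)              # exact-zero beta with eps=0
        logp = -np.log(2.0 * scale) - s / scale
        d1 = -beta / (scale * s)
        # (log p)'' = -eps / (b * s^3); p''/p = d1^2 + (log p)''
        d2 = d1**2 - smoothing_eps / (scale * s**3)
        return logp, d1, d2
    raise ValueError(f"unknown component family {family!r}")


def penalty_terms(beta: np.ndarray, prior: PriorSpec
                  ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Mixture penalty C, its gradient, per-SNP curvature and responsibilities.

    With m_j the mixture density, c_j = -log m_j, grad_j = -m'/m and
    curvature_j = (m'/m)^2 - m''/m.  The causal responsibility is
    r_j = pi1_j p1_j / m_j.  pi1 in {0, 1} degenerates to the single
    component exactly.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != prior.pi1.shape:
        raise ValueError("beta and prior length mismatch")
    logp1, d1_1, d2_1 = component_logpdf_derivs(beta, "normal", prior.slab_sd)
    null_family = "normal" if prior.null_family == "normal_spike" else "laplace"
    logp0, d1_0, d2_0 = component_logpdf_derivs(
        beta, null_family, np.full_like(beta, prior.null_scale),
        prior.smoothing_eps)

    with np.errstate(divide="ignore"):
        logw1 = np.log(prior.pi1)          # -inf where pi1 == 0
        logw0 = np.log1p(-prior.pi1)       # -inf where pi1 == 1
    stacked = np.stack([logw1 + logp1, logw0 + logp0])
    logm = logsumexp(stacked, axis=0)
    # responsibilities from log densities; exact 0/1 at degenerate pi1
    resp = np.exp(np.minimum(logw1 + logp1 - logm, 0.0))

    # m'/m and m''/m as responsibility-weighted component ratios
    ratio1 = resp * d1_1 + (1.0 - resp) * d1_0
    ratio2 = resp * d2_1 + (1.0 - resp) * d2_0
    cost = float(-logm.sum())
    grad = -ratio1
    curvature = ratio1**2 - ratio2
    if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(curvature))):
        raise FloatingPointError("non-finite penalty derivatives")
    return cost, grad, curvature, resp


def neg_log_likelihood(beta: np.ndarray, g: GenotypeMatrix | np.ndarray,
                       y: Phenotype | np.ndarray, noise: NoiseModel | float
                       ) -> tuple[float, np.ndarray]:
    """Gaussian negative log-likelihood and its gradient.

    L = (d/2) log 2pi + 1/2 log|Sigma| + 1/2 (y - Xb)' Sigma^-1 (y - Xb)
    with d the length of the residual vector and Sigma = sigma2 * I.
    grad = -X' Sigma^-1 (y - Xb).
    """
    X = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    yv = y.values if isinstance(y, Phenotype) else np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite beta")
    if isinstance(noise, NoiseModel):
        if noise.sigma2.size != 1:
            raise ValueError("per-window fit expects a single residual variance")
        sigma2 = float(noise.sigma2[0])
    else:
        sigma2 = float(noise)
    if not np.isfinite(sigma2) or sigma2 <= 0:
        raise ValueError("residual variance must be positive and bound to data")
    d = len(yv)
    resid = yv - X @ beta
    L = 0.5 * d * LOG_2PI + 0.5 * d * np.log(sigma2) + 0.5 * resid @ resid / sigma2
    grad = -(X.T @ resid) / sigma2
    return float(L), grad


def hessian_vector_product(v: np.ndarray, g: GenotypeMatrix | np.ndarray,
                           noise: NoiseModel | float, curvature: np.ndarray,
                           weight: float = 1.0) -> np.ndarray:
    """H v = X' Sigma^-1 (X v) + weight * curvature * v, never forming H."""
    X = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    sigma2 = float(noise.sigma2[0]) if isinstance(noise, NoiseModel) else float(noise)
    v = np.asarray(v, dtype=float)
    return X.T @ (X @ v) / sigma2 + weight * np.asarray(curvature) * v


def evaluate_objective(beta: np.ndarray, g, y, noise, prior: PriorSpec,
                       config: ObjectiveConfig | None = None) -> ObjectiveEvaluation:
    """Full objective F = L + weight * C with gradient and responsibilities."""
    config = config or ObjectiveConfig()
    L, grad_L = neg_log_likelihood(beta, g, y, noise)
    C, grad_C, _, resp = penalty_terms(beta, prior)
    return ObjectiveEvaluation(
        F=L + config.weight * C,
        L=L,
        C=C,
        gradient=grad_L + config.weight * grad_C,
        responsibilities=resp,
    )
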