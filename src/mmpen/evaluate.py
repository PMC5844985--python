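"""Accuracy metrics and multi-method benchmarking.

PPV (positive predictive value) is the fraction of selected variants that are
truly causal; NPV is the fraction of declared nulls that are truly null.
Effect-size accuracy is measured by Pearson correlation and by NMSE,
``||beta_hat - beta_true||^2 / ||beta_true||^2`` (on effect sizes; the
cross-validation in :mod:`mmpen.baselines` separately uses phenotype-space
NMSE).  Undefined metrics (empty denominators, zero-variance estimates) are
flagged explicitly rather than silently propagated as NaN.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PriorSpec
from .estimators import (ElasticNetCD, MixtureModelRegressor, RegPIRegressor,
                         UnivariateRegressor)
from .simulate import SimConfig, SimTruth, simulate_dataset

__all__ = ["ConfusionCounts", "BenchmarkRow", "classify_variants", "ppv_npv",
           "effect_metrics", "benchmark_compare", "rows_to_frame",
           "make_method"]

UNDEFINED = "undefined"  # sentinel for metrics with empty denominators


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class BenchmarkRow:
    method: str
    seed: int
    sparsity_param: float
    correlation: float | str
    nmse: float | str
    ppv: float | str
    npv: float | str
    n_selected: int
    runtime_s: float
    failed: bool = False


def classify_variants(beta_hat: np.ndarray,
                      responsibilities: np.ndarray | None = None,
                      rule: str = "responsibility",
                      threshold: float = 0.5) -> np.ndarray:
    """Select putatively causal variants.

    ``responsibility``: selected iff r_j > threshold (mixture fits).
    ``magnitude``: selected iff |beta_hat_j| > threshold; threshold 0 gives
    nonzero-support selection for exactly-sparse estimators (LASSO).
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    if rule == "responsibility":
        if responsibilities is None:
            raise ValueError("responsibility rule requires responsibilities")
        if not 0.0 < threshold < 1.0:
            raise ValueError("responsibility threshold must be in (0, 1)")
        return np.asarray(responsibilities, dtype=float) > threshold
    if rule == "magnitude":
        if threshold < 0:
            raise ValueError("magnitude threshold must be >= 0")
        return np.abs(beta_hat) > threshold
    raise ValueError(f"unknown selection rule {rule!r}")


def ppv_npv(selected: np.ndarray, truth: SimTruth | np.ndarray
            ) -> tuple[float | str, float | str, ConfusionCounts]:
    """Positive/negative predictive values with explicit undefined flags."""
    selected = np.asarray(selected, dtype=bool)
    causal = truth.causal if isinstance(truth, SimTruth) else np.asarray(truth, bool)
    if selected.shape != causal.shape:
        raise ValueError("selection and truth length mismatch")
    counts = ConfusionCounts(
        tp=int(np.sum(selected & causal)),
        fp=int(np.sum(selected & ~causal)),
        tn=int(np.sum(~selected & ~causal)),
        fn=int(np.sum(~selected & causal)),
    )
    ppv = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else UNDEFINED
    npv = counts.tn / (counts.tn + counts.fn) if counts.tn + counts.fn else UNDEFINED
    return ppv, npv, counts


def effect_metrics(beta_hat: np.ndarray, beta_true: np.ndarray
                   ) -> tuple[float | str, float]:
    """(Pearson correlation, NMSE) of estimated vs true effect sizes."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float)
    if beta_hat.shape != beta_true.shape:
        raise ValueError("effect vector length mismatch")
    denom = float(beta_true @ beta_true)
    if denom == 0:
        raise ValueError("beta_true is identically zero; NMSE undefined")
    nmse = float(np.sum((beta_hat - beta_true) ** 2)) / denom
    if np.std(beta_hat) == 0 or np.std(beta_true) == 0:
        corr: float | str = UNDEFINED
    else:
        corr = float(np.corrcoef(beta_hat, beta_true)[0, 1])
    return corr, nmse


# ---------------------------------------------------------------------------
# Benchmark harness


def make_method(name: str, threshold: float | None = None, **kw) -> dict:
    """Standard method configurations used in the comparisons.

    mm_cp   - mixture penalty, constant pi1 (default 0.01), Laplace null
    mm_ep   - mixture penalty with the generating enrichment (pi1 = pi_1)
    mm_prior- mixture penalty with an externally supplied pi1 vector
    infinitesimal - pi1 = 1, normal slab (ridge-equivalent)
    regpi   - closed-form generalized ridge with enrichment precisions
    lasso   - coordinate-descent LASSO
    univariate - per-SNP marginal regression
    """
    return {"name": name, "threshold": threshold, "kw": kw}


def _fit_method(method: dict, X: np.ndarray, y: np.ndarray,
                truth: SimTruth) -> tuple[np.ndarray, np.ndarray | None, str, float]:
    """Returns (beta_hat, responsibilities|None, rule, sparsity_param)."""
    name = method["name"]
    kw = dict(method.get("kw") or {})
    if name in ("mm_cp", "mm_ep", "mm_prior", "infinitesimal"):
        if name == "mm_cp":
            kw.setdefault("pi1", 0.01)
            kw.setdefault("null_family", "laplace")
        elif name == "mm_ep":
            pi_true = float(np.mean(truth.causal))
            pi1 = np.where(truth.categories.enriched,
                           min(0.5, max(pi_true, 1e-3) /
                               max(float(np.mean(truth.categories.enriched)), 1e-12)),
                           1e-4)
            kw.setdefault("pi1", pi1)
            kw.setdefault("null_family", "normal_spike")
        elif name == "infinitesimal":
            kw["pi1"] = 1.0
            kw.setdefault("null_family", "normal_spike")
        est = MixtureModelRegressor(**kw).fit(X, y)
        pi_arr = np.atleast_1d(np.asarray(est.pi1, dtype=float))
        return est.coef_, est.responsibilities_, "responsibility", float(pi_arr.mean())
    if name == "regpi":
        pi_true = float(np.mean(truth.causal))
        enr = truth.categories.enriched
        pi1 = np.where(enr, max(pi_true, 1e-3) /
                       max(float(np.mean(enr)), 1e-12), 1e-4)
        pi1 = np.clip(pi1, 1e-6, 1.0)
        kw.setdefault("pi1", pi1)
        est = RegPIRegressor(**kw).fit(X, y)
        return est.coef_, None, "magnitude", float(np.mean(pi1))
    if name == "lasso":
        kw.setdefault("alpha", 1.0)
        if "lam" not in kw:
            # two-fold CV over a geometric grid below the full-shrinkage point
            from .baselines import cv_select_lambda
            lam_max = 2.0 * float(np.abs(X.T @ y).max())
            grid = list(lam_max * np.logspace(-2.5, -0.1, 8))
            kw["lam"], _ = cv_select_lambda(X, y, grid, folds=2, seed=0)
        est = ElasticNetCD(**kw).fit(X, y)
        return est.coef_, None, "support", float(kw["lam"])
    if name == "univariate":
        est = UnivariateRegressor().fit(X, y)
        return est.coef_, np.abs(est.zscores_), "zscore", 0.0
    raise ValueError(f"unknown method {name!r}")


def _select(beta_hat, resp, rule, threshold=None):
    if rule == "responsibility":
        return classify_variants(beta_hat, resp, "responsibility",
                                 0.5 if threshold is None else threshold)
    if rule == "support":
        return classify_variants(beta_hat, None, "magnitude", 0.0)
    if rule == "zscore":
        thr = 3.0 if threshold is None else threshold
        return np.asarray(resp) > thr
    return classify_variants(beta_hat, None, "magnitude",
                             0.0 if threshold is None else threshold)


def benchmark_compare(scenario: SimConfig, methods: list[dict],
                      n_replicates: int, seeds: list[int] | None = None
                      ) -> list[BenchmarkRow]:
    """Fit every method on identical simulated replicates; one row each.

    A method failure on one replicate flags that row and the run continues.
    """
    if not methods:
        raise ValueError("need at least one method")
    if seeds is None:
        seeds = list(range(n_replicates))
    if len(seeds) != n_replicates:
        raise ValueError("seeds length must equal n_replicates")
    from dataclasses import replace
    rows: list[BenchmarkRow] = []
    for seed in seeds:
        cfg = replace(scenario, seed=int(seed))
        g, y, truth = simulate_dataset(cfg)
        X, yv = g.dosages, y.values
        for method in methods:
            t0 = time.perf_counter()
            try:
                beta_hat, resp, rule, sparsity = _fit_method(method, X, yv, truth)
                selected = _select(beta_hat, resp, rule,
                                   method.get("threshold"))
                corr, nmse = effect_metrics(beta_hat, truth.beta_true)
                ppv, npv, _ = ppv_npv(selected, truth)
                rows.append(BenchmarkRow(
                    method=method["name"], seed=int(seed),
                    sparsity_param=sparsity, correlation=corr, nmse=nmse,
                    ppv=ppv, npv=npv, n_selected=int(selected.sum()),
                    runtime_s=time.perf_counter() - t0))
            except Exception:
                rows.append(BenchmarkRow(
                    method=method["name"], seed=int(seed), sparsity_param=np.nan,
                    correlation=UNDEFINED, nmse=UNDEFINED, ppv=UNDEFINED,
                    npv=UNDEFINED, n_selected=0,
                    runtime_s=time.perf_counter() - t0, failed=True))
    return rows


def rows_to_frame(rows: list[BenchmarkRow]) -> pd.DataFrame:
    """Tidy benchmark table (one row per method x replicate)."""
    return pd.DataFrame([vars(r) for r in rows])
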