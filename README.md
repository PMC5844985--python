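# mmpen — mixture-model penalty regression for SNP effect sizes

`mmpen` estimates per-SNP effect sizes and selects genetic causal variants in
the multivariate GWAS model

    y = X β + ε,        ε ~ N(0, Σε),

where `X` is an N×n standardized genotype dosage matrix (raw entries 0/1/2)
and `y` a quantitative phenotype.  Instead of an L1/L2 distance penalty, the
fit minimizes

    F(β) = L(β) + Σⱼ cⱼ(βⱼ),
    L(β) = const + ½ (y − Xβ)ᵀ Σε⁻¹ (y − Xβ),
    cⱼ(βⱼ) = −log[ π̃₁ⱼ p₁(βⱼ) + (1 − π̃₁ⱼ) p₀(βⱼ) ],

i.e. a spike-and-slab mixture prior used *explicitly* as a penalty: `p₁` is a
wide normal "slab" for causal effects, `p₀` a narrow normal spike or Laplace
null, and `π̃₁ⱼ` the specified prior probability that SNP j is causal.  Per-SNP
priors let functional-annotation enrichment or the posterior probabilities of
external fine-mapping tools (DAP, PAINTOR, CAVIAR, ...) flow straight into the
optimization.  `F` is minimized by nonlinear conjugate gradient with a
Newton–Raphson line search whose directional curvature comes from
Hessian–vector products `Hv = XᵀΣε⁻¹(Xv) + c″∘v` — the n×n Hessian is never
formed.

Audience: statistical geneticists benchmarking penalized-regression
fine-mapping, and anyone needing annotation-informed effect-size estimates
from individual-level genotype data.

Special cases recovered by the same code path: `π̃₁ = 1` is the infinitesimal
(ridge-equivalent) model; constant `π̃₁ = 0.01` with a Laplace null is the
constant-prior configuration (MM-CP); `π̃₁` set to the generating enrichment
is the enriched-prior configuration (MM-EP); the closed-form generalized
ridge (`RegPIRegressor`) is its analytic counterpart.

## Worked example

```python
import numpy as np
from mmpen import (SimConfig, simulate_dataset, MixtureModelRegressor,
                   classify_variants, ppv_npv, effect_metrics)

cfg = SimConfig(n_samples=2000, n_snps=500, n_chromosomes=1,
                enriched_fraction=0.04, causal_param=0.5,
                heritability=0.5, seed=0)
g, y, truth = simulate_dataset(cfg)          # 10 causal SNPs, h² = 0.5

est = MixtureModelRegressor(pi1=0.01, null_family="laplace").fit(
    g.dosages, y.values)
sel = classify_variants(est.coef_, est.responsibilities_,
                        "responsibility", 0.5)
corr, nmse = effect_metrics(est.coef_, truth.beta_true)
ppv, npv, _ = ppv_npv(sel, truth)
print(f"corr={corr:.3f} nmse={nmse:.3f} ppv={ppv:.3f} npv={npv:.4f} "
      f"selected={sel.sum()}")
```

prints

```
corr=0.994 nmse=0.013 ppv=0.889 npv=0.9959 selected=9
```

meaning: the estimated effects correlate 0.994 with the truth, 9 variants
exceed causal responsibility 0.5, 8 of them are truly causal (PPV 0.889), and
99.6 % of the declared nulls are truly null.  The univariate baseline on the
same data reaches correlation ≈ 0.80.

A command-line interface covers the same pipeline:

```bash
mmpen simulate --n-samples 2000 --n-snps 500 --seed 0 --out sim/
mmpen fit --genotypes sim/genotypes.tsv --phenotype sim/phenotype.tsv \
      --method mmp --pi1 0.01 --null laplace --out fit/
mmpen evaluate --estimates fit/estimates.tsv --truth sim/truth.tsv --out eval/
```

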