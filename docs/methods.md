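# Methods

## Model and objective

The phenotype is modeled as `y = Xβ + ε`, `ε ~ N(0, Σε)` with `X` the N×n
standardized dosage matrix.  The fitted objective is `F = L + w·C`:

- `L = (N/2)·log 2π + ½·log|Σε| + ½(y − Xβ)ᵀΣε⁻¹(y − Xβ)` — the Gaussian
  negative log-likelihood.  The normalizing exponent uses the dimension of
  the residual vector (N); this constant does not affect the minimizer.
- `C = Σⱼ cⱼ(βⱼ)`, `cⱼ = −log[π̃₁ⱼ p₁ⱼ(βⱼ) + (1 − π̃₁ⱼ) p₀ⱼ(βⱼ)]` — a
  spike-and-slab mixture density used directly as a per-SNP penalty.  The
  slab `p₁ⱼ` is normal with sd `σ̃₁ⱼ` (default 1); the null `p₀ⱼ` is either a
  narrow normal spike of sd `σ₀` (default 0.01) or a Laplace density of scale
  `σ₀`.  The weight `w` (default 1) trades likelihood against penalty;
  raising it suits architectures known to be strongly polygenic.

All mixture arithmetic is done in log space with log-sum-exp, so the penalty,
its gradient, its curvature and the causal responsibilities
`rⱼ = π̃₁ⱼp₁ⱼ/mⱼ` stay finite for `|β|` up to 10³ and `π̃₁` down to the
smallest positive doubles.  Degenerate priors `π̃₁ⱼ ∈ {0, 1}` reduce exactly
to the single-component cost.

The Laplace null is non-differentiable at 0; the implementation substitutes
the smooth surrogate `√(β² + ε_s)` with `ε_s = 1e-8` by default, keeping the
smoothness assumptions of the conjugate-gradient machinery valid, rather than
working with subgradients.

Σε is restricted to a scalar variance per fitting window,
`σ² = (1 − h²_window)·Var(y)`, with per-window heritability obtained by
dividing the assumed total heritability equally among windows.  Windows are
non-overlapping per-chromosome blocks (or fixed-size blocks of consecutive
SNPs) fitted independently; standardization is applied to whatever SNP set is
loaded, i.e. effectively per window in the windowed pipeline.

## Optimization

Nonlinear conjugate gradient with restarts: `d₀ = −g₀`,
`d_{k+1} = −g_{k+1} + βₖ dₖ`, with βₖ selectable among Fletcher–Reeves,
Polak–Ribière⁺ (default — the standard robust choice for non-convex
objectives), Dai–Yuan and Hager–Zhang; restart to steepest descent every n
iterations or whenever the update vanishes or the direction loses descent.

The step length comes from a Newton–Raphson line search (≤ 5 Newton steps,
starting from the previously accepted step): `φ′(t) = ∇F(β+td)ᵀd` and
`φ″(t) = dᵀH(β+td)d`, where the Hessian–vector product
`Hv = XᵀΣε⁻¹(Xv) + w·c″∘v` costs two matrix–vector products and one
elementwise product because the penalty is separable — the n×n Hessian is
never materialized.  Wherever the spike-and-slab penalty makes `φ″ ≤ 0` or
the Newton step fails to decrease F, the search falls back to Armijo
backtracking (c₁ = 1e-4, up to 50 halvings).  This safeguard makes the
recorded objective trace non-increasing on every fit; a failed backtrack
(step 0) is treated as a stall and stops the iteration.

Convergence: `‖g‖∞ < 1e-6` or relative objective change `< 1e-10`;
`max_iter = min(10·n, 5000)`.  β is initialized at 0 unless warm-started.
Only local minimization is claimed — the penalty is non-convex — and the
brute-force-oracle tests use instances the oracle itself verifies unimodal.

An optional three-stage annealing schedule multiplies the null scale by
{10, √10, 1}, warm-starting each stage from the previous solution: a homotopy
from a near-ridge problem to the target spike that empirically preserves or
improves the final objective on sparse instances.  π̃₁ is held fixed across
stages.

## Baselines

- Univariate regression: `β̂ⱼ = xⱼᵀy / xⱼᵀxⱼ` with per-SNP standard errors.
- Generalized ridge / regularized pseudo-inverse:
  `β̂ = (XᵀΣε⁻¹X + D)⁻¹XᵀΣε⁻¹y`, `D = diag(1/(π₁ⱼσ₁ⱼ²))` — the
  Gaussian-prior MAP solution and the analytic counterpart of the
  enriched-prior mixture fit (the two are cross-checked against each other in
  the tests).
- Elastic net / LASSO by cyclic coordinate descent on
  `‖Xβ − y‖² + λΣⱼ[½(1−α)βⱼ² + α|βⱼ|]` — note the unscaled residual sum of
  squares; comparisons with 1/(2N)-scaled λ conventions must rescale
  explicitly.  The per-coordinate update is
  `soft(xⱼᵀr, λα/2)/(xⱼᵀxⱼ + λ(1−α)/2)`.  α = 0 (pure ridge) is accepted.
- λ selection by k-fold (default 2-fold) cross-validated held-out phenotype
  NMSE over a user grid; ties break toward larger λ (sparser).  In the
  benchmark harness the LASSO default selects λ by 2-fold CV over a geometric
  grid below the full-shrinkage point `λ_max = 2·max|xⱼᵀy|`.  NMSE appears in
  two distinct roles: phenotype-space NMSE for CV, effect-size NMSE
  (`‖β̂ − β‖²/‖β‖²`) in benchmark rows.

## Synthetic data

The simulator emulates a genome-scale benchmark design at desk scale:

- Genotypes: per SNP, MAF uniform in (0.05, 0.5); two haplotypes per sample
  drawn from a latent Gaussian AR(1) chain (autocorrelation `ld_rho`,
  default 0.3) thresholded at Φ⁻¹(MAF).  This preserves every SNP's marginal
  MAF exactly while giving adjacent-allele correlation that increases
  monotonically with `ld_rho`; `ld_rho` is the latent-scale autocorrelation,
  not the realized allele r.
- Annotations and effects: `enriched_fraction` (default 2 %) of SNPs get an
  enriched category (Exon/3′UTR/5′UTR); half of the enriched SNPs are causal
  (≈ 1 % of all SNPs), with effects i.i.d. N(0, 1); nulls are exactly zero.
- Phenotype: `y = Xβ + ε` with the noise draw rescaled so the realized
  heritability `Var(Xβ)/Var(y)` hits the 0.5 target in-sample up to the
  chance covariance between signal and noise (within 0.05 at N = 5000, and
  much tighter typically).

Default scenario: N = 2000 samples, 2000 SNPs over 4 pseudo-chromosomes —
roughly 1/100 of the genome-wide design in both dimensions.  What the
emulation deliberately omits: recombination-map-aware LD, population
structure and relatedness, case/control liability traits, and the long-range
LD of real reference panels.  Passing tests therefore demonstrate correctness
of the estimators and the qualitative method ordering under local-LD sparse
architectures, not performance on real cohort data.

## Selection rules and metrics

The detection rule is explicit per estimator: mixture fits select by causal
responsibility > 0.5; LASSO by nonzero support; univariate by |z| > 3.  PPV =
TP/(TP+FP) over selected variants, NPV = TN/(TN+FN) over declared nulls;
empty denominators are reported as an explicit `undefined` sentinel, never as
silent NaN.  Effect-size accuracy is Pearson correlation (scale/shift
invariant — the infinitesimal model keeps ordering while underestimating
magnitudes, which correlation forgives and NMSE does not) and effect-space
NMSE.

## Numerical and design choices

- Missing genotypes are mean-imputed per column (count logged); variance
  denominators are N−1 throughout.
- VCF input: biallelic SNVs with GT fields only; multiallelic records are
  skipped with a warning.  Priors and annotations join by variant ID so any
  external fine-mapping output can be supplied.
- Prior probabilities slightly outside [0, 1] (within 0.1) are clipped with a
  warning; values further out raise, as they usually indicate a wrong column.
- The benchmark harness exposes replicate counts and seeds as free
  parameters; every simulation, fit and CV split is reproducible bit-for-bit
  from its seed.

## Problem sizes used in the checks

The test suite and the acceptance script run at desk scale: oracle
equivalence on 100×30 systems and 1–3-SNP exhaustive grids, method-ordering
comparisons on 20 replicates of N = 2000, n = 500 with 10 causal SNPs, sweep
curves on N = 800, n = 200, and simulator calibration at N = 5000.  These
sizes were chosen so a full run completes in a few minutes on one CPU while
keeping Monte-Carlo error well below the margins being asserted.

## Known limitations

- The mixture penalty is non-convex: different warm starts (or annealing) can
  reach different local minima; the descent guarantee is per-run.
- The equal split of heritability across windows is a modeling convenience;
  real per-window genetic variance varies.
- The univariate baseline's `predict` is the marginal-slope linear
  combination, intentionally not a joint fit.
- Effective-sample-size issues (relatedness, structure) are out of scope.
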