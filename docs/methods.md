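# Methods

This note documents the statistical model, the numerical and design
choices behind it, what the synthetic-data generator does and does not
emulate, and the known limitations. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Model

Yield (z-transformed, so total variance ≈ 1) of genotype *i* in
environment *j* — an environment being one (location, year, field block)
combination — is

    y_ij = g_i + e_j + ξ_ij + ε_ij,   ε_ij ~ N(0, σ_j²),  σ_j⁻² ~ Gamma(α_j, β_j)

with a separate residual precision per environment (shape–rate
convention; defaults (10, 1), prior mean noise variance ≈ 0.1).

The genetic main effect vector is a kernel regression on the genomic
kernel, `g* = K_g a_g0 + e_g0`, with `a_g0 ~ N(0, λ_g0⁻¹ I)` and
isotropic residual `σ_g0²`. The environment main effect is a plain random
effect `e_j ~ N(0, σ_e0²)`, `σ_e0² = 0.25` — it deliberately absorbs the
per-environment yield level so that the yield z-transform can stay
global. The interaction matrix is low-rank, `Ξ = H_g H_eᵀ`, each side a
kernel regression: `H_g = K_g A_g + E_g` (entries of `A_g` i.i.d.
`N(0, λ_g⁻¹)`, noise `σ_g²`) and symmetrically `H_e = K_e A_e + E_e` on
the composite environmental kernel. All priors are conjugate.

**Inference** is coordinate-ascent variational Bayes over the fully
factorized posterior
q(σ_j⁻²) q(a_g0) q(g) q(e) q(A_g) q(H_g rows) q(A_e) q(H_e rows).
The update order is: residual precisions → (a_g0, g) → e → (A_g, H_g) →
(A_e, H_e), cycled; main effects first stabilizes the factorization. The
ELBO is evaluated after every sweep, must never decrease (guarded with
relative slack 1e−6; a decrease raises an error because it can only come
from an inconsistent update), and convergence is declared at relative
ELBO change < 1e−6 (default cap 200 sweeps). The `A`-block posterior
covariances are constant across sweeps and factorized once. Replicated
observations of one (i, j) cell are averaged with the replicate count
kept as a precision weight. Correctness of the update algebra is checked
two ways in the tests: ELBO monotonicity across 20 random instances, and
agreement of posterior means with an independent Gibbs sampler on a 5×4
instance (max deviation < 0.05).

**Initialization.** Latent factor means start from small seeded Gaussian
draws (sd 0.01) — the symmetric zero state is a stationary point of the
factorization — and the main effects from a ridge-style warm start
(`a_g0` from per-genotype means pushed through its own update).

### Prediction and identifiability

For new genotypes/environments with kernel rows `k_g, k_e` against the
training sets, the mean prediction is
`ŷ = k_g a_g0' + ê + (k_g A_g)(k_e A_e')ᵀ`, where `ê` is the posterior
mean effect for a training environment and 0 (the prior mean) for a new
one.

The primed quantities are an exact reparameterization of the fitted
surface: the likelihood does not pin the column means of the latent
environment factors to zero, so `H_e` can absorb a genotype-main-effect
component `H_g · m` (m = mean factor across training environments). A
new environment far outside the training support has `k_e A_e → 0`, and
the naive predictor would silently drop that absorbed component — making
the interaction model strictly worse than the additive one precisely
where extrapolation fails. We therefore fold the mean into the genetic
regression, `a_g0' = a_g0 + A_g m`, and predict with centred environment
factors, `A_e' = A_e − d mᵀ` with `d` the ridge representation of the
constant vector (computable from the stored posterior covariance). The
fitted training surface is unchanged; remote environments now revert to
the full additive prediction.

### Historical-weather protocol

Environments enter the model only through covariates; location and year
are never regression factors. To predict a future season at a known
location (soil and location known, in-season weather not), we build, for
each historical year at that location, the season covariates (fixed
May 1 – August 31 window, 123 days, regardless of sowing date), form
composite kernel rows with the frozen training normalizations and kernel
weights, predict, and return the per-genotype **median** across years
(midpoint convention for even counts). The median is bounded by the
per-year extremes by construction.

## Kernels

Every kernel passes two normalizations: unit diagonal
(`K̃ = K / √(diag·diagᵀ)`), then total variance (`K̃̃ = c K̃` with
`c = [Σ_i Var(k̃_i)]^{−1/2}`, population column variances), so that
summed kernels contribute a priori equal variance. The Gaussian kernel is
`exp(−‖Δ‖²/(2h))` with bandwidth h = number of covariates. The default
environmental registry holds 8 kernels: soil {Gaussian, linear}, rain and
temperature season vectors {Gaussian, linear}, the soil×rain Hadamard
product of the two Gaussian kernels (Schur product, PSD-preserving), and
growth-zone indicators (linear, used as-is). Covariate columns are
standardized on the training environments (indicator blocks excepted);
all scalers, per-kernel constants and the final composite scaling are
frozen at fit time so cross-kernel rows for new environments live in
exactly the training geometry. Learned kernel weights may be negative, so
the composite is projected onto the PSD cone (negative eigenvalues
clipped to zero) and new-environment rows are projected onto the retained
eigenspace. The genomic kernel is the linear kernel on column-centred
dosages, through the same normalization pipeline; centring is our choice
(standard for genomic relationship matrices) and is absorbed by the
calibration either way.

## Kernel weights (multi-kernel learning)

The per-kernel weights are learned by variational Bayesian multiple-
kernel regression with per-environment mean yields as the target: sample
weights `a` with per-sample Gamma precision priors (shape 1, scale 10 —
the stronger-shrinkage setting), intermediate outputs per kernel with a
shared learned Gamma precision, kernel weights with Gamma precision
priors (1, 1), fixed zero bias, and Gamma (1, 1) output noise precision.
Posterior-mean weights are rescaled to unit sum of squares with the
largest-magnitude weight positive, and are learned on training
environments only, then frozen — required so no information leaks from
validation or test environments. Convergence is declared when the
normalized weight direction stabilizes (max-abs change < 1e−6, cap 200
iterations); the direction is the only quantity consumed downstream,
which makes the criterion scale-free — with near-noiseless targets the
raw weight magnitudes keep drifting long after the direction has
converged. Non-convergence returns the best iterate with a warning.

## Variance-target calibration

Hyperparameters are not estimated from data; they are solved from
interpretable variance targets, with prior Monte-Carlo simulation
standing in for intractable expectations:

* `σ_g0² = 0.05 · Var_genetic` and `λ_g0` such that the prior variance of
  `K_g a_g0` (population variance of the vector's elements, averaged over
  draws) is `0.95 · Var_genetic` — 95% of the genetic effect is signal;
* each interaction side satisfies the analogous 95% condition,
  `Tr(Var(K A)) / (Tr(Var(K A)) + R σ²) = 0.95` with the trace summing
  population column variances over the R components;
* the interaction magnitude is tied to the genetic variance through Φ:
  the expected per-environment population column variance of `H_g H_eᵀ`
  equals `Φ · R · Var_genetic`, so at Φ = 1 each latent component
  contributes as much yield variance per cell as the genetic main
  effect. We state this condition **per environment** deliberately: under
  a summed-over-environments convention the implied per-cell interaction
  variance would shrink as 1/N_e, making Φ meaningless for realistic
  environment counts and contradicting the intent that interactions be
  comparable to main effects.

All of these functionals are linear in the inverse precisions, so one
Monte-Carlo estimate at unit precision per kernel suffices (no iterative
search); the estimator is cross-checked in the tests against the closed
form `E[Var_pop(K a)] = τ (mean diag K² − mean K²)`. The interaction
product is split symmetrically: each side's factor is set to
`√(Φ · Var_genetic · N_e)` (the environment-side factor is a sum over
environments). The grids offered to validation selection are
`Var_genetic ∈ {0.2, 0.4, 0.6}` and `Φ ∈ {0.5, 1}`. `estimate_ptve`
reports the implied prior variance shares (genetic / environment /
interaction / noise) by full prior simulation.

## Baselines

**GBLUP**: `y = Xβ + Zu + ε`, `u ~ N(0, σ_u² K_g)`, field-block (i.e.
environment) indicators as fixed effects. REML via the spectral
reparameterization: eigendecompose the fixed-effect-projected kernel
(with an identity offset so projection zeros separate from genuine null
directions), then a bounded one-dimensional search over the variance
ratio; BLUP and new-line prediction through kernel rows. Verified against
direct mixed-model-equation solves and a brute-force optimizer of the
profiled restricted likelihood (agreement to 1e−4).

**GE-BLUP**: a random effect over genotype×environment cells with
covariance `σ_u² (Σ_G ⊗ Σ_E)` restricted to observed cells — each needed
entry is a product of two kernel entries, so the dense Kronecker product
is never formed (a guard refuses more than 6000 observed cells). The
environmental kinship summarizes weather per crop stage: stage timing
from cumulative daily mean temperature above base 0 °C (configurable;
5 °C is also common in Nordic agronomy), heading at 440.2 °C·d and
ripening at 905.9 °C·d; vegetative = 3 weeks from sowing, heading window
−2/+1 weeks around the estimated heading day, grain filling from the day
after until one week past estimated ripening. Per stage: mean and sd of
daily temperature and rain (12 covariates) + 4 soil proportions + one-hot
growth zones, z-normalized, linear kernel, unit-diagonal normalized. For
prediction in unseen environments the fixed-effect contribution is the
training mean (≈ 0 on the z scale); per-fold Pearson correlation is
unaffected by that constant.

## Evaluation protocol

Six setups order the difficulty of prediction; the strictest (Setup 6)
requires test locations ∉ training locations, test years ∉ training
years, and test genotypes to be progeny absent from training. Validation
splits inside each training set satisfy the same constraints. Fold
construction is deterministic given a seed and invariant to record order.
Accuracy is the Pearson correlation between predicted and observed yields
pooled within a fold (one location-year), aggregated across folds on the
Fisher z scale (`tanh(mean(atanh r))`). Hyperparameter selection, when
enabled, maximizes Fisher-averaged validation correlation with ties
broken toward the simpler model (smaller R, then Var_genetic, then Φ).
The sensitivity analysis reports the median and central 90% interval of
(model − GBLUP) score differences per interaction rank across
perturbations, classifying environments as harmed/neutral/helped by
whether the interval excludes zero.

## Synthetic data

The generator emulates a northern-European barley programme at desk
scale. Defaults: 40 parents + 160 progeny (random bi-parental crosses,
one allele per parent with probability dosage/2), 400 SNPs with MAF
uniform on (0.1, 0.5); 6 locations × 5 years × 1 field (30
environments); observation density 0.4. Climate: location-specific base
temperature (12–16 °C) plus a mid-July-peaking sinusoid and AR(1) noise
(φ = 0.6, sd 2.5); rainfall as location-specific wet-day Bernoulli
(0.25–0.55) × log-normal amounts; soils Dirichlet(2,2,2) + Beta(2,8)
organic, fixed per field; sowing dates uniform May 1–20 (needed only by
GE-BLUP).

Yields follow the model's own decomposition with exact variance scaling:
genetic 0.4 (middle of the calibration grid), environment 0.25, G×E 0.4
(a strong-interaction regime, as the study design requires), noise 0.1.
The interaction is rank-1 by default: `ξ_ij = γ_i s_j` with stress
`s_j` = standardized clay × season-rain-total and polygenic
susceptibility `γ_i` — the minimal mechanism matching a soil×rain-driven
G×E, leaving higher-rank recovery testable by summing mechanisms. The
environment main effect is **half covariate-driven** (−stress, since
waterlogging depresses every genotype's yield) and half i.i.d.: with a
purely i.i.d. environment effect, per-environment mean yields would
carry no information about growing conditions and the mean-yield
multiple-kernel weight learning would regress pure noise — concentrated,
arbitrary kernel weights that destroy the composite kernel's soil/rain
content. Real multi-environment trials do not behave that way (drought
and waterlogging visibly depress site means), so the covariate-driven
share is the realistic condition and the one under which the weight
learning is meaningful.

What the generator does **not** emulate: real Finnish geography or
meteorology, linkage disequilibrium and genetic map structure (markers
are independent), selection during breeding, spatial field trends,
sowing-date effects on the season window, or missing-data patterns of
real trial networks. Passing end-to-end tests therefore demonstrate the
machinery and its qualitative behaviour under the stated generative
assumptions, not field performance.

## Numerical conventions and edge cases

* Population (1/N) variances everywhere (z-transform, kernel
  normalizations, calibration).
* Season window May 1 – Aug 31, non-leap 123-day convention (Feb 29 never
  intersects it); up to 5 missing days per variable are filled (linear
  interpolation for temperature, zero for rain), more is an error.
* Genotype QC order: markers (MAF < 0.05 or missingness > 5%) first, then
  lines (> 5% missing), then per-marker mean imputation of the residual
  missingness (the handling of the small remainder is our choice).
* Kernel PSD tolerance: min eigenvalue ≥ −1e−8 × max; composites are
  projected onto the PSD cone.
* Zero-variance test folds are skipped with a warning (correlation
  undefined); Fisher averaging rejects |r| = 1.
* Degenerate inputs (single observed cell, all-zero kernel rows,
  single-environment GE-BLUP) are exercised in the tests and return
  finite, heavily shrunk estimates rather than errors.

## Known limitations

* The genetic-main-effect prior covariance implied by the kernel
  regression is `λ⁻¹K_g² + σ² I` (not `∝ K_g` as in GBLUP); when the true
  architecture matches GBLUP's covariance, GBLUP retains a small edge in
  pure breeding-value prediction (~0.02 correlation at the default
  scale). The G×E machinery must earn back that margin, which mirrors the
  small cold-start margins reported for this class of methods.
* Kernel-weight learning needs informative per-environment means; with
  few environments the weight posterior is noisy even then.
* Extrapolation of the environment factors to locations far outside the
  training covariate support degrades toward the additive prediction
  (by design, via the identifiability reparameterization) — the model
  cannot conjure stress estimates for climates it has never seen.
* Single trait, Gaussian likelihood, no marker×environment terms, no
  MCMC; the variational posterior underestimates uncertainty as usual.
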