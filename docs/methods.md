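# Methods

`famet` implements the standard two-stage factor-analytic analysis of
multi-environment trials (METs), together with the classical AMMI and GGE
decompositions and the derived genetic parameters breeders report alongside
them. This note records the models, the numerical choices, and what the
synthetic study design does and does not establish.

## Stage 1: single-trial mixed model

Each trial (one year x location environment) is analysed as a randomized
complete block design,

    y = mu + replicate + genotype + e,

with replicate and genotype random, `replicate ~ N(0, sigma_r^2)`,
`genotype ~ N(0, sigma_g^2)`, `e ~ N(0, sigma_e^2)`, fitted by REML.
On a complete balanced RCBD the REML solution coincides with the ANOVA
moment estimators `sigma_g^2 = (MS_G - MS_E)/r`, `sigma_e^2 = MS_E`,
`sigma_r^2 = (MS_R - MS_E)/m` whenever those are interior, and the
implementation uses that closed form directly, falling back to bounded
quasi-Newton REML on the log-variance scale (L-BFGS-B, multistart, analytic
gradients, variance floor 1e-10) when a component hits the boundary or the
trial is incomplete at plot level. This matters in practice: cell-level
unbalance between trials leaves each individual trial balanced, so almost
all stage-1 fits take the closed form.

Reported per-trial statistics:

- Cullis heritability `H2 = 1 - mean(PEV) / (2 sigma_g^2)`, clipped to
  [0, 1], where PEV is the prediction error variance of the genotype BLUPs
  from the mixed-model equations;
- experimental accuracy, by default `sqrt(1 - mean(PEV)/sigma_g^2)`; the
  non-root form `1 - mean(PEV)/sigma_g^2` is available via
  `accuracy(..., as_printed=True)` because both conventions circulate —
  the root form is the standard "selective accuracy" definition;
- `CV% = 100 sigma_e / mu` (the residual SD, not variance, over the trial
  mean — the only dimensionally sensible reading);
- adjusted means (BLUEs) from the companion genotype-fixed fit, which feed
  stage 2 unshrunken. Using BLUPs instead would bias the stage-2 loadings
  toward zero.

Residual diagnostics flag standardized conditional residuals beyond 3.5 SD;
flags are advisory and nothing is removed automatically.

## Stage 2: factor-analytic model of the genetic covariance

The genotype x environment table of adjusted means is modelled as

    mean_il = tau_l + u_il + e_il,

rows `u_i ~ N(0, Sigma)` iid across genotypes with the FA(k) structure
`Sigma = Lambda Lambda' + diag(Psi)` (`Lambda` s x k environment loadings,
`Psi` environment-specific variances), and `e_il ~ N(0, d_l)` the stage-1
noise carried into stage 2. Estimation is REML with the environment
intercepts profiled out by GLS; because rows are independent given `tau`,
the likelihood factorises over genotypes and is evaluated per missingness
pattern from cached sufficient statistics, with an analytic gradient from
the identity `dl/dtheta = -1/2 [tr(P dV) - y'P dV P y]` chained to the free
entries of `Lambda` and `log Psi`.

Identifiability choices:

- `Lambda` carries the upper-triangle-zero gauge during optimisation; all
  interpretation happens after varimax rotation.
- With a single mean per cell, a *free* diagonal `d` is confounded with
  `Psi` (only `Psi + d` enters the likelihood). `stage2_resid="absorb"`
  (default) therefore sets `d = 0` and lets `Psi` absorb the stage-1 noise;
  `stage2_resid="fixed"` sets `d_l` to the mean squared stage-1 contrast SE
  per environment (`sigma_e^2 / r`), which is known rather than estimated,
  making `G_hat = Lambda Lambda' + diag(Psi)` an approximately unbiased
  genetic covariance. The pipeline uses "fixed" whenever SEs are available.
  The contrast SE deliberately excludes the replicate-effect variance,
  which is shared by all genotypes of a trial and absorbed by `tau_l`.

Model search fits FA(1)..FA(kmax) and selects the minimum of
`AIC = -2 logREML + 2 NP`, `NP = s k - k(k-1)/2 + s` variance parameters.
Each order receives the previous order's solution padded with a zero column
as an extra start, so `logREML` is non-decreasing in k by construction.
Multistarts are seeded from the eigendecomposition of the pairwise-complete
sample covariance of environment columns.

Derived quantities: overall and per-factor variance explained
`100 tr(Lambda Lambda') / tr(Lambda Lambda' + Psi)`; genetic correlations
`rho_ll' = G_ll' / sqrt(G_ll G_l'l')`; genotype scores and cell-level
predictions `tau_l + lambda_l' f_i (+ specific-effect BLUP where tested)`
for every cell including untested ones; and the observed-vs-fitted Pearson
correlation as a scalar goodness-of-fit summary.

## Stability: varimax and latent regression

Factor rotation uses raw varimax (Kaiser row-normalization optional, off by
default since the convention is not universal), delegated to statsmodels'
gradient-projection rotation; factors are then reordered by explained
variance and sign-fixed so each column's largest-magnitude loading is
positive, with genotype scores co-rotated so fitted values, `G_hat` and all
variance shares are unchanged.

The latent regression reads the rotated model genotype-wise: for factor r
the genotype's predicted values across environments lie on
`mean_BLUP_i + f_ir x`, where x is the environment loading. The slope
`beta_1 = f_ir` is taken directly from the rotated score — no re-fitting —
which on noiseless data coincides exactly with the OLS slope of predicted
values on loadings. Classification defaults: `|beta_1| <= 0.5` stable,
`beta_1 >= 1` responsive, `beta_1 <= -1` negatively responsive, otherwise
intermediate; both thresholds are exposed because they are conventions, not
estimates.

## AMMI and GGE

AMMI double-centers the complete two-way table (grand mean, genotype and
environment main effects — the genotype effect is part of the additive
model even though some formulations omit it) and decomposes the interaction
residual by SVD. Term n is tested with Gollob's statistic:
`df_n = m + s - 1 - 2n`, `F_n = (lambda_n^2 / df_n) / (sigma_e^2 / R)` on
the means scale when a pooled residual variance and replicate count are
supplied. Stability ranking is by `|IPCA1|` ascending with ties broken by
genotype main effect. GGE centers by environment only, retaining G + GxE,
and reports symmetrically scaled coordinates (`sqrt(lambda_n)` to each
side) with per-PC variance shares.

Missing cells are imputed beforehand by EM: alternate an additive
main-effects fill with a rank-r SVD reconstruction of the interaction until
the largest imputed-cell change falls below 1e-6 (cap 20000 iterations; the
alternation converges linearly, slowly at high missingness). Imputed cells
are flagged and the missing pattern must keep the table connected.

## Joint variance components and covariate correlations

The compound joint model `y = env(fixed) + genotype + genotype:env + e` is
fitted by REML on all plots; derived parameters follow the standard MET
formulary: `sigma_p^2 = sigma_g^2 + sigma_gxe^2/E + sigma_e^2/(E R)`,
`CVg = 100 sqrt(sigma_g^2)/mean`, `CVr = 100 sqrt(sigma_e^2)/mean`,
`r_ge = sigma_g^2/(sigma_g^2 + sigma_gxe^2)`,
`r_i^2 = sigma_gxe^2/(sigma_g^2 + sigma_gxe^2 + sigma_e^2)`,
entry-mean `H2 = sigma_g^2/sigma_p^2`, and `P - G = CVp - CVg` with
`CVp = 100 sqrt(sigma_p^2)/mean`. Under unbalance, E and R enter as
harmonic means of per-genotype environment counts and per-cell replicate
counts (they reduce to the plain counts when balanced). Random terms are
tested by REML likelihood ratio with the boundary-corrected 50:50
`chi2(0):chi2(1)` mixture.

Loading-covariate association uses plain Pearson correlation per
(factor, covariate) pair over shared environments, two-sided p from
`t = r sqrt((n-2)/(1-r^2))`, starred at 0.05/0.01/0.001 without multiplicity
adjustment (the convention for such tables); Benjamini-Hochberg is available
behind a flag.

## Synthetic study design

The generator draws exactly the structure the FA analysis assumes: loadings
`Lambda` with N(1.5, 1.5^2) first column (a dominant, mostly-positive first
factor, giving the predominantly positive between-environment genetic
correlations and nonzero genotype main effect typical of real MET data) and
N(0, 1.5^2) further columns; specific variances uniform on (0.5, 2);
genotype scores standard normal; environment main effects N(0, 6^2) around
a grand mean of 24 t/ha; replicate effects N(0, 0.8^2); plot residual SDs
uniform on (1.8, 3.6) per environment, i.e. CV% of roughly 7-15 and
single-trial Cullis H2 mostly in 0.6-0.9. Unbalance removes whole
genotype x environment cells completely at random subject to every genotype
retaining at least half the environments and the environment-sharing graph
staying connected — mirroring how clone promotion/removal between seasons
unbalances a breeding programme. One covariate ("Rain") is engineered as
`r z(Lambda_1) + sqrt(1-r^2) z(noise)` with population correlation r = 0.58
to the first-factor loadings; the rest are independent noise on plausible
weather-station scales.

What this does **not** emulate: spatial field trend within trials, residual
non-normality or outliers, misspecification of the FA structure (specific
deviations are drawn independently per environment, exactly the model's
assumption), covariates that act through the mean rather than the loading
structure, and pedigree/genomic relatedness among genotypes. Passing tests
therefore demonstrate correctness and calibration of the machinery under
the assumed model, not robustness to model violation.

Problem sizes used in the shipped studies: the end-to-end study runs 22
genotypes x 20 environments x 3 replicates with 20% cell unbalance (the
genotype count of a typical advanced-trial cohort); the recovery study runs
200 genotypes x 10 environments over 10 seeds, where the sample-covariance
floor itself has ~10% Frobenius error, so the observed ~0.13 median
recovery error for REML-from-means is close to the information-theoretic
limit of the design.

## Known limitations

- Stage 1 supports RCBD only: no spatial row-column or AR1xAR1 residual
  models, no heterogeneous block variances within a trial.
- Stage 2 places the FA structure on the genetic covariance only; replicate
  and residual structures are per-trial diagonal (absorbed at stage 1).
- One trait at a time; no multi-trait factor models.
- AMMI significance is Gollob's liberal F-test; no permutation or
  cross-validation alternatives.
- The EM imputation assumes cells are missing at random given main effects
  and the low-rank interaction; informative missingness (e.g. culling on
  low yield) would bias both AMMI and GGE.
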