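# Methods

## The model

`pedreml` fits the classical *animal model* for one or two traits:

    y = X b + Z u + e

where `y` stacks the phenotypic records, `b` holds fixed effects
(contemporary groups such as slaughter-date batches, and continuous
covariates such as slaughter age), `u` holds one additive-genetic effect
per pedigree animal and `e` the residuals.  The random effects are
multivariate normal with

    Var(u) = G ⊗ A        Var(e) = R ⊗ I

`A` is the numerator relationship matrix implied by the pedigree
(`a(i,j)` = twice the coancestry; `diag(A) = 1 + F` with `F` the
inbreeding coefficient), `G` and `R` are the t×t additive-genetic and
residual (co)variance matrices (t ∈ {1, 2}), and `⊗` is the Kronecker
product.  Residuals are independent across animals; for animals missing
one trait, `R` is restricted to the observed pattern — the only coherent
reading of `R ⊗ I` under unequal bivariate designs.

Assumptions worth stating explicitly: additive gene action only (no
dominance, maternal or permanent-environment components), homogeneous
residual variance across contemporary groups, unknown parents treated as
unrelated non-inbred founders (no unknown-parent groups), and marbling
score — a 1–9 grade — treated as a continuous response.

## Pedigree machinery

* **Tabular A** (dense, small pedigrees; default limit 2,000 animals,
  configurable): `a(i,j) = 0.5 (a(j,s_i) + a(j,d_i))`,
  `a(i,i) = 1 + 0.5 a(s_i,d_i)`, unknown parents contributing zero.
* **Inbreeding** by Meuwissen–Luo path accumulation over the L·D·L'
  decomposition of A, giving `F` and the Mendelian-sampling variances
  `d_i = 0.5 − 0.25 (F_s + F_d)` (0.75 − 0.25 F with one known parent,
  1 with none).  `diag(A) = 1 + F` holds exactly because both come from
  the same recursion, and `log|A| = Σ log d_i`.
* **Sparse A⁻¹** by Henderson's rules with inbreeding: each animal adds
  `α = 1/d_i` to at most nine cells.  Verified against the dense inverse
  of the tabular A on batches of random pedigrees (1e-8 tolerance).

## REML estimation

The restricted (error-contrast) log-likelihood

    logL = −½ [ log|V| + log|X'V⁻¹X| + y'Py + (N−p) log 2π ]

is evaluated on observed records only, so `V = (G ⊗ A_φ) + R`-blocks with
`A_φ` the relationship block among phenotyped animals (ancestors enter
only through `A_φ`).  Two exact evaluation strategies share one
interface and are cross-checked against each other in the tests:

* **Eigen path** (every phenotyped animal recorded for all traits): one
  symmetric eigendecomposition `A_φ = U D U'` turns `V` into independent
  t×t blocks per eigen-record; each subsequent REML iteration is O(n).
* **Dense path** (arbitrary missing-trait patterns): `V` built densely
  on the stacked records; O(N³) per iteration, intended for the desk
  scales this package targets (≲ 5,000 records).

Both produce the analytic gradient, the average-information matrix
`AI_ij = ½ y'P V_i P V_j P y` and an exact EM update (the EM G-update
uses the identity `A_{φ·}A⁻¹A_{·φ} = A_φ`, which keeps even EM inside the
observed-record space).  This observed-record design replaces the more
traditional sparse mixed-model-equations route with Takahashi selected
inverses: at these problem sizes it is exact, simpler to verify against
dense oracles, and faster on the complete-record layouts the recovery
experiments use.

**Iteration scheme** (`fit`): two EM warm-up sweeps, then AI steps
`θ ← θ + AI⁻¹ ∇logL` with up to 10 step-halvings if the likelihood would
decrease or leave the parameter space, and an EM fallback when halving
fails.  Convergence uses the relative criterion

    C = Σ_i (θ_i − θ_i*)² / Σ_i θ_i²   <   1e-12 (default)

with `max_iter = 200`.  The asymptotic covariance of the estimates is
the inverse of the final AI matrix.

**Numerical choices.** Start values: `G = 0.4 diag(vp)`,
`R = 0.6 diag(vp)` with `vp` the per-trait sample phenotypic variance,
zero covariances — away from boundaries and scale-free.  Variances are
floored at `1e-10 · vp`; if a step leaves the positive-definite cone, G
(or R) is bent by flooring its eigenvalues at `1e-8 · trace`; both events
are flagged on the fit (`boundary`, `bent`) rather than hidden.  Fixed
effects use first-level-drop coding with covariates centred at their
sample mean; REML is invariant to both conventions, one is fixed for
reproducibility.

**Reduced models.** `fit_constrained` zeroes the genetic covariance
(df = 1 reduced model) or both covariances (df = 2), excluding them from
θ.  The EM M-step under a diagonal constraint is the constrained
maximiser, so monotonicity is preserved.

## Derived parameters

* Heritability `h² = σ²g / (σ²g + σ²e)`; phenotypic (co)variances are
  `P = G + R` (no other components exist in the model).
* Genetic / phenotypic correlations `r = cov / √(var_X var_Y)`.
* Genetic coefficient of variation `CVg% = √σ²g / x̄ × 100`.
* **Standard errors** by repeated sampling: 10,000 draws from
  `N(θ̂, AI⁻¹)`, the SE being the standard deviation of the parameter
  function over draws.  Draws with negative variances or non-PD G/R are
  redrawn (and counted); if more than half the draws are invalid the
  estimate is too close to a boundary and an error is raised instead of
  reporting a biased SE.
* **Significance** of correlations by likelihood-ratio tests:
  `−2(logL_reduced − logL_full)` against the 95th chi-squared percentile,
  3.84 at df = 1 (genetic covariance zeroed) and 5.99 at df = 2 (both
  covariances zeroed).

## The synthetic-data generator

Because the source records live behind institutional portals, validation
is a parameter-recovery exercise: the generator simulates, forward in
time, exactly the process the estimator assumes — discrete-generation
pedigrees (random or paternal-half-sib-heavy mating, the latter echoing
a progeny-test design), breeding values gene-dropped so that
`Var(u) = G ⊗ A` (using the same `d_i` as the estimator, so simulator
and estimator are internally coherent), i.i.d. slaughter-date
contemporary-group effects assigned in generation blocks, a normally
distributed slaughter age (23.71 ± 0.64 months by default) entering
through per-trait slopes, and residuals from `R` restricted to each
record's observed pattern.  A configurable fraction of animals carries
only the always-recorded traits, emulating the nested carcass/cut
recording scheme (default 0.383 in the carcass×cut preset, matching
5,622 vs 3,467 records).  Presets carry the published trait means and
(co)variance magnitudes (e.g. carcass weight 370.48 kg, σ²g 303.64,
σ²e 783.07; carcass-weight×brisket rg = 0.73, rp = 0.78); date-effect
SDs and age slopes are set so the simulated phenotypic coefficients of
variation land near the published summary statistics, since the study
does not report contemporary-group variances.

What the generator does **not** emulate — and hence what passing
recovery tests do not establish about real data: selection or
assortative mating across generations, pedigree errors, categorical
thresholds for the marbling score, heterogeneous residual variances,
seasonal structure in slaughter dates, and the full 60,060-animal,
11-generation pedigree (tests run at a desk scale of roughly 500–3,300
animals).

## Validation scales and observed behaviour

* Oracle equivalence: AI-REML on an 8-record toy agrees with a grid +
  simplex maximisation of the directly evaluated dense likelihood to
  1e-4 relative; the balanced half-sib animal model agrees with the
  closed-form ANOVA sire-variance estimator within its sampling error.
* Parameter recovery: 3,000 phenotyped animals over 4 generations, true
  h² = 0.40, rg = 0.60, rp = 0.50; across 10 seeds every component of G
  and R is recovered within two empirical SDs.
* LRT calibration: under a true zero genetic covariance the df = 1 test
  rejects at the nominal 5% over 200 replicates of 600 phenotyped
  animals.  600 is the smallest replicate size at which no replicate
  touches the positive-definiteness boundary; below that (e.g. 240
  records) boundary bending inflates the rejection rate — a small-sample
  property of the test, not of the implementation.
* `scripts/acceptance.py` reports replicate means over two simulated
  carcass-weight×brisket datasets of 1,500 phenotyped steers each — a
  precision choice: single desk-scale replicates leave 1–2 SE of
  sampling noise on h² and rg, which replicate averaging halves.

## Known limitations

* At most two traits per fit (the study design never needs more); no
  maternal, permanent-environment or dominance components; no genomic
  relationships or single-step extensions; no unknown-parent groups.
* The dense missing-pattern path scales as O(N³) per iteration and is
  not intended for national-evaluation data volumes.
* Sampling SEs assume the asymptotic normal approximation of the REML
  estimates; near boundaries they are refused rather than approximated.
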