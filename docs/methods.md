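# Methods

## The problem

In a two-arm parallel cluster-randomized trial (CRT), intact groups —
clinics, schools, practices — are randomized to intervention or control, and
heterogeneity-of-treatment-effect (HTE) analyses ask whether the intervention
effect differs across patient subgroups (sex, age group, baseline severity).
The regression model for participant *j* of cluster *i* is

    g(E[Y_ij | U_i]) = β0 + trt_i·β_trt + gr_ij'β_gr + (trt_i × gr_ij)'β_mod + RE_ij,

with canonical links (identity/log/logit for continuous/count/binary
outcomes); the null of homogeneous effects is β_mod = 0.

The package exists because the *random-effect* part of this model decides
whether the HTE test is valid. If the within-cluster correlation differs by
subgroup — members of subgroup *k* in cluster *i* share a latent effect
U_{i,k}, with Cov(U_{i,k}, U_{i,k'}) = Σ_{kk'} — then a model with a single
cluster intercept (RE_ij = U_i, "GLMM") understates the standard error of
β̂_mod and its Wald test rejects a true null far above the nominal 5% level.
Three analyses are implemented and compared:

* **GLMM** — common random intercept, U_i ~ N(0, σ²);
* **GLMM2 (maximal GLMM)** — subgroup-specific effects U_i ~ MVN(0, Σ),
  fitted in the equivalent random-intercept-plus-subgroup-slope
  parametrization with unstructured covariance;
* **GEE** — marginal model with independence working correlation and
  cluster-robust sandwich variance.

The common-intercept model is the rank-one special case Σ = σ²J of the
maximal model.

## Fitting

**Cell collapse.** Because the only regressors are the cluster-level arm and
the person-level subgroup, every likelihood depends on the data only through
per-(cluster, subgroup) cell sizes m, sums S and (Gaussian) sums of squares
SS. All fitting code works on these sufficient statistics, making the cost
of one likelihood evaluation independent of cluster sizes — the property
that lets the Monte-Carlo harness run thousands of fits in minutes.

**Linear mixed models** are fitted by profiling: for a value of the relative
covariance factor Λ (Σ_u = σ²ΛΛ'), the GLS fixed effects and the residual
variance have closed forms, and the profiled (restricted) log-likelihood is
optimized over the lower-triangular entries of Λ. REML is the default
(the convention of the reference mixed-model software); ML is used when
likelihood-ratio tests are requested.

**Poisson and Bernoulli GLMMs** use the Laplace approximation to the
marginal likelihood — the default of the reference implementation whose
behaviour the simulation findings characterize. Random effects are
spherically reparametrized (u_i = Λv_i, v_i ~ N(0, I)), so Σ^{-1} is never
formed and boundary covariances need no special casing. Fitting has two
stages: (1) the covariance factor alone is optimized with (β, v) solved by
penalized IRLS inside each evaluation; (2) β joins the outer quasi-Newton
optimization of the exact Laplace objective, with only the conditional modes
profiled, because the log-determinant term depends on β for non-identity
links. Stage 2 reproduces the reference implementation's estimates and
log-likelihoods to ~4 decimal places on test problems. vcov(β̂) is the
inverse Schur complement of the β-block of the joint penalized Hessian at
the optimum, conditioning on the estimated covariance parameters — i.e. no
propagation of Σ̂ uncertainty, exactly the Wald output whose small-sample
behaviour the simulations measure.

**Covariance parametrization.** The factor's diagonal is box-bounded at zero
rather than log-transformed. This is deliberate: singular fits (a variance
estimated at 0, or a correlation at ±1) are a first-class object of study
here, and the boundary must be *reachable exactly* for the singular-fit
counts to be meaningful. A log-Cholesky parametrization maps the boundary to
−∞ and can only approach it. The optimizer is L-BFGS-B with
finite-difference gradients and a Nelder-Mead polish whenever the solution
is near the boundary or the gradient stage failed; the polish prevents the
finite-difference gradient from stalling a diagonal at zero when the true
optimum is small but positive. Starting values: linear mixed models start
the random-effect share at 10% of the total outcome variance (50% as a
fallback on failure); Poisson/Bernoulli GLMMs start the covariance factor at
the unit diagonal — the reference software's default. The GLMM start
matters scientifically, not just numerically: with small true random effects
the profiled Laplace surface has boundary corners that attract the
optimization path from a far start, and the reported singular-fit
frequencies are a property of that path. A deliberately better-informed
start (available via ``fit(start=...)``) finds interior optima with higher
likelihood in a noticeable share of such replicates and correspondingly
fewer singular fits; the default reproduces the reference behaviour that
practitioners actually observe. A single optimization path is used per fit
(fallback starts engage only on failure) for the same reason.

**Singularity** is declared when any Cholesky diagonal falls below
tol·(geometric mean of the nonzero diagonals + tol), or an implied
correlation is within tol of ±1; tol defaults to 1e-4, comparable to the
mixed-model software convention, and is configurable because reported
singular-fit counts depend on it.

**GEE** point estimates are the plain GLM fit (independence working
correlation makes the estimating equations the GLM score equations, solved
by Newton scoring on cells); inference uses the cluster-robust sandwich
A^{-1}(Σ_i U_iU_i')A^{-1}. No finite-sample multiplier is applied by default
(exposed as an option).

## Inference for HTE

For two-level subgroups the test is a Wald t on the single interaction
coefficient; for three-level subgroups a global likelihood-ratio chi-square
test (ML fits, df = 2). Gaussian mixed-model Wald tests use Satterthwaite
df at every cluster count (the reference t-test default; for within-cluster
interaction contrasts at 50+ clusters the df runs into the thousands, so the
test is practically z). Non-Gaussian mixed-model Wald tests with ≥50
clusters use t with N − q df (q = cluster-level fixed-effect parameters);
GEE uses z.

With few clusters (12 in the study designs) the corrections are:

* **Satterthwaite** (continuous outcomes): df = 2(c'Ĉc)²/(∇g'A∇g) with
  g(γ) = c'C(γ)c differentiated by central finite differences (relative step
  1e-4) over γ = (covariance factor entries, log σ²) and A the inverse
  observed information of the (restricted) log-likelihood in γ, computed by
  finite-difference Hessian; df floored at 1. Agrees with the reference
  t-test implementation to ~1% on test designs. At boundary fits the
  information can be singular; a pseudo-inverse is used, and the harness
  falls back to the residual-cluster df (recorded per replicate) when the
  computation degenerates entirely.
* **Residual-cluster df**: N minus the number of cluster-level fixed-effect
  parameters (12 − 2 = 10 in the study designs).
* **Between-within df**: columns constant within clusters get the
  between-cluster df N − q_b, within-cluster columns get M − N − q_w. The
  treatment-by-subgroup interaction is classified *between* by default: it
  contains the cluster-level treatment factor, and this matches the helper
  software whose corrected tests produced the few-cluster operating
  characteristics this package reproduces (its rejection rates are only
  attainable with a small df for the interaction). The classical rule
  (interaction → within) is available via ``interaction_as="within"``.
* **Parametric bootstrap**: B = 100 refits of the same model on data
  simulated from the fitted (β̂, Σ̂) on the observed design; percentile CI
  with linear interpolation; decision by 0 ∉ CI; failed refits dropped and
  counted, with >20% failures an error.
* **Fay–Graubard** (GEE): Wald F with the unadjusted sandwich in the
  statistic and the "d-tilde" denominator df. d-tilde treats the sandwich
  quadratic form as Σ_i z_i² with z_i = c'A^{-1}H_iU_i,
  H_i = diag{(1 − min(b, [A_iA^{-1}]_jj))^{-1/2}} (truncation b = 0.75), and
  approximates Cov(z) by the model-based blocks δ_ij A_i − A_iA^{-1}A_j
  (scores are residuals after estimating β); then
  d = (tr C)²/‖C‖_F². For I identical clusters this gives exactly I − 1.
  The bias-adjusted sandwich is exposed as an option for the statistic.

The **two-step procedure** fits the maximal model first and, on a singular
fit, refits the common-intercept model and reports its test (flagged
``used_fallback``). The **correction selector** encodes which method held
the nominal level for each (true model, fitted model, outcome type) cell:
Satterthwaite for all Gaussian mixed fits; for count/binary —
between-within (maximal fitted, maximal true), residual-cluster (intercept
fitted under maximal truth; binary maximal under maximal truth), parametric
bootstrap (maximal fitted when the common intercept is the truth), and
between-within for the correctly specified common-intercept model; GEE
always Fay–Graubard.

## The simulator

`make_scenario` exposes seven preset data-generating conditions spanning:
moderate subgroup-specific random effects with 50/100 clusters of 100;
the same covariances shrunk by 1/10 (singular fits become common); 12
clusters with fixed (100) or varying (25, 50, 100, 150, 300) sizes; a
common-intercept truth (the maximal model is overfitted); a three-level
subgroup; arm-heterogeneous covariance (control covariance scaled by 1.4);
and a non-null interaction for power. Fixed-effect presets per outcome type:
(0, 0.5, 0.3, 0) continuous, (−1, −0.07, −0.5, 0) count,
(−1.66, −0.32, −0.08, 0) binary; Gaussian residual variance 0.64; subgroups
Bernoulli(0.5) (or uniform over three levels); 1:1 cluster randomization.
Varying sizes are cycled over clusters in id order — the size list is
shorter than the cluster count and no assignment rule is canonical, so a
deterministic cycle was chosen; it balances sizes across arms in
expectation, and realized sizes are recorded.

A master seed spawns five independent substreams (randomization, sizes,
subgroups, random effects, outcomes): changing one generator component never
perturbs the others, and identical (spec, seed) give bit-identical data.

What the generator does *not* emulate: covariates beyond one subgroup
factor, informative cluster size, subgroup imbalance across clusters,
unequal allocation, multiple clustering levels. Passing tests therefore
certify the operating characteristics under these idealized conditions,
not under real-data complications such as confounding or informative sizes.

## The Monte-Carlo harness

`run_scenario` runs replicate grids with per-replicate seeds spawned from
(master seed, replicate index), so subsets of replicates are independently
reproducible and results are invariant to the number of workers. Per model
it reports bias and empirical SD of β̂_mod, the rejection rate with its
Monte-Carlo standard error √(r(1−r)/R), singular-fit and fallback counts,
and failures (recorded, excluded from rate denominators, never silently
dropped). Reproductions in the test suite use 1000 replicates for Gaussian
designs and 300 for Poisson/Bernoulli mixed-model designs; published
Monte-Carlo rates are matched within ±3√(r(1−r)/R) (the singular-fit
fraction within ±0.08, since it additionally depends on the singularity
threshold). These sizes keep a full run of the suite in a few minutes on a
single core while leaving the bands narrow enough to detect the headline
effects (nominal ~5% vs inflated 20–47%).

## Numerical choices and edge cases

* Inner Newton loops (conditional modes, PIRLS): gradient max-norm < 1e-8,
  ≤100 iterations, step-halving ≤30; failures carried to the fit level, never
  silent.
* The Laplace objective's final optimizer improvement is stored on the
  results object as a convergence certificate.
* Binary separation (an all-0 or all-1 treatment-by-subgroup cell) is
  flagged on the results, not fatal.
* Degenerate contrasts, non-CRT data (treatment varying within cluster),
  non-contiguous subgroup codes, rank-deficient designs and odd cluster
  counts raise immediately with specific messages.
* The LRT statistic is floored at 0 (boundary/optimizer noise can make it
  marginally negative); a deficit beyond 1e-4 raises instead.

## Known limitations

* Laplace (not adaptive quadrature) is the production estimator, matching
  the reference software's default; adaptive Gauss–Hermite appears only as a
  test oracle. For the small random-effect variances studied here the
  approximation error is far below Monte-Carlo noise.
* Wald SEs condition on Σ̂ (by design — this is the output under study);
  no Kenward–Roger-type propagation is offered.
* Small-sample corrections are implemented for the Wald t-test only; the
  global LRT is used uncorrected (it showed adequate control in the
  three-level designs).
* Exchangeable/AR working correlations for GEE, offsets, covariate
  adjustment and multiple clustering levels are out of scope.
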