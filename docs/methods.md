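# Methods

## Structural model

Each compound (clozapine = parent, norclozapine = metabolite) is described
by a first-order absorption depot, a plasma compartment, a chain of transit
compartments carrying drug from plasma into brain extracellular fluid (ECF),
and a brain-ECF compartment returning drug to plasma through an
intercompartmental clearance. Clozapine is eliminated directly (CL_clo/F)
and by conversion to norclozapine (CL_clo-met/F); the converted mass enters
the norclozapine plasma compartment 1:1 in mg (no molecular-weight
correction — the clearances are estimated on the mass scale). With the
default structure (two parent transit compartments, one metabolite, no lag
times) the parent-side equations are

    d(depot)/dt   = -Ka * depot
    d(plasma)/dt  =  Ka * depot - (CL + CL_met)/Vp * plasma - Ktr * plasma
                     + Q/Vb * brain
    d(transit_i)/dt = Ktr * (upstream_i - transit_i)        i = 1..n
    d(brain)/dt   =  Ktr * transit_n - Q/Vb * brain

and analogously for the metabolite, whose plasma compartment additionally
receives CL_clo-met/Vp_clo × plasma_clo. A cumulative-elimination state
closes the mass balance: every column of the rate matrix sums to zero, and
the total system mass plus eliminated mass equals the bioavailable dose at
all times (tested to < 1e-9 relative).

The transit chain is mass-balanced: plasma effluxes at rate Ktr·A_plasma
through identical-rate transit compartments into brain. The original
microdialysis study reports Ktr and Q as named parameters without the
differential form; a concentration-driven, non-mass-balanced link cannot
be excluded. The mass-balanced chain is this package's documented convention: it is
the standard implementation of transit delays, and its implied steady-state
unbound brain:plasma ratio, Kp,uu = Ktr·V_plasma/Q (≈ 0.12 for clozapine,
0.039 for norclozapine), is consistent with the reported net-efflux finding.
The ratio is exercised against an independent constant-infusion oracle built
on the augmented matrix exponential.

Units are fixed: mg, L, minutes, mg/L. Bioavailability F multiplies the dose
amount at depot entry; between-animal variability on F is exp(η) and is not
truncated at 1 (apparent parameters absorb F). Pre-dose samples (−30 and
0 min) are exactly zero by the observation-before-dose convention.

### Solvers

The system is linear and time-invariant between dose events, so the
reference solver propagates the state with matrix exponentials — exact up to
floating point, and immune to the stiffness introduced by the fast
brain-return rate (Q/Vb ≈ 9.4 min⁻¹ against absorption rates of
~0.003–0.008 min⁻¹). An LSODA route (`solver="numeric_ode"`, rtol 1e-10,
atol 1e-13) serves as an independent cross-check; the two agree to < 1e-6
relative on the study design and the numeric route falls back to the matrix
exponential with a warning if integration fails. In the estimation hot path
the sampling schedule is pre-compiled into a propagation plan: one matrix
exponential per unique inter-event interval (obtained as matrix powers of
the smallest interval when intervals are integer multiples of it), then
matrix–vector propagation; subjects never exposed to the parent compound use
only the metabolite sub-system.

## Stochastic model and estimation

Between-animal variability is log-normal via P_i = P_TV·exp(η_i),
η ~ N(0, ω²), with a diagonal Ω on {Q_clo, Ktr1, F_clo, CL_met, V_met-p,
Ka_met} by default. The tabulated variability and residual values are
interpreted as standard deviations (ω, σ), not variances. Residual error is
proportional per observation channel: DV = pred·(1 + σ_channel·ε). Rows at
t ≤ 0 and below-quantification rows are excluded from the likelihood by
default.

The objective function value (OFV) is −2 log marginal likelihood including
2π constants. Two approximations are provided:

* **pooled** — all η fixed at 0; a plain Gaussian proportional-error
  likelihood. Fast, but it conflates between-animal variability with
  residual error, so ω is not estimated and σ estimates are inflated.
* **laplace** (default) — per-subject Laplace approximation: the conditional
  mode η̂ is found by a damped Gauss–Newton iteration whose Hessian is
  J'WJ + Ω⁻¹ with J = ∂pred/∂η (forward differences, step 1e-4) and
  W = 1/(σ·pred)², i.e. the interaction weights evaluated at the conditional
  mode; the same matrix supplies the log-determinant correction. With all
  ω = 0 the Laplace OFV equals the pooled OFV exactly (same code path).

This is an FOCE-with-interaction-class approximation; no attempt is made to
reproduce any specific estimation software bit-for-bit, and the package's
accuracy claim is parameter recovery on synthetic data, not OFV equality
with other tools.

The outer problem optimises log-transformed fixed effects, ω and σ with
L-BFGS-B. Numerical choices that matter:

* Fixed effects are bounded to ±log(200) around their starting values — a
  wide trust region that keeps rate constants away from regions where the
  matrix exponential degrades numerically.
* The finite-difference step of the outer gradient is 1e-5 on the log scale,
  chosen to dominate the small history dependence of the warm-started inner
  optimisations; warm starts themselves are committed only when the OFV
  improves, keeping the objective a near-pure function of the parameters.
* An early line-search failure can masquerade as convergence; the optimiser
  is restarted from its returned point until progress genuinely stops.
* For the Laplace method a pooled pre-fit of the fixed effects provides the
  starting point (`prefit_pooled=True`).
* The brain-ECF volumes (0.214 and 0.25 L, literature values) and both
  bioavailabilities (1) are fixed, matching the final rat model. V_clo-b/F
  and V_met-b/F are taken as the fixed pair (the tabulated estimates are
  authoritative where the running text is ambiguous).
* Starting values: perturbed truth for synthetic experiments; for user data
  a log-scale multi-start (× / ÷ 3, seeded, default seed 20140820) is
  available via `multistart=`.
* Standard errors can be computed from the finite-difference Hessian of the
  OFV (`compute_se=True`), but the bootstrap is the primary uncertainty
  tool.

Empirical Bayes estimates re-run the inner optimisation at the final
population estimates. On noise-free data the EBEs are near zero but not
exactly zero: the proportional-error log-variance term shifts the
conditional mode by O(σ²). This is a property of the estimator, not a bug,
and the tests bound it accordingly.

## Diagnostics

* **Residuals.** Individual-level IWRES = (obs − ipred)/(σ·ipred) at the
  EBEs. Population-level CWRES decorrelate the observation vector with the
  first-order conditional linearisation around η̂: mean = ipred − Jη̂,
  covariance = JΩJ' + diag((σ·ipred)²), factored by Cholesky with an
  eigenvalue-clipped fallback when ill-conditioned. Residuals against a zero
  prediction are flagged non-finite and counted rather than propagated.
* **VPC.** n replicate studies (default 1000) are simulated under the fitted
  model on the dataset's own design; the 5th/50th/95th percentiles of the
  replicate-wise medians are reported per channel and timepoint together
  with the observed median.
* **Bootstrap.** Animals are resampled with replacement within arm
  (stratified, preserving the 4 + 5 arm sizes on the original design; the original analysis does not
  state stratification — it is chosen here to preserve
  the two-arm design). Each replicate is refitted starting from the point
  estimates; non-converging replicates are excluded and counted, and the
  result is flagged if more than 20% fail. The default replicate count is
  1000.

## Synthetic data

The generator reproduces the study design exactly: two arms (clozapine
10 mg/kg SC, 4 × 0.35 kg; norclozapine 10 mg/kg SC, 5 × 0.34 kg), plasma
samples at 0, 15, 30, 60, 90, 120, 240, 360, 480 min and brain-ECF samples
every 30 min from −30 to 480 min. Its default generating values are the
reference population estimates, variability and residual SDs of the final
rat model. Norclozapine in brain ECF after clozapine dosing is emitted as a
below-quantification-flagged row (not deleted), keeping the dataset schema
uniform. Body weights are fixed at the arm means (only means are reported);
an optional uniform spread is available. Proportional-noise draws that would
produce a non-positive concentration are redrawn — at the study's σ ≤ 0.109
this is a > 9σ event and effectively never fires.

What the generator does *not* emulate: assay/calibration error structure,
microdialysis probe recovery, dropout, or any model misspecification.
Passing recovery tests therefore demonstrates estimator correctness under
the assumed model, not robustness of the original study's conclusions to
model error.

## Human translation and occupancy

Brain-disposition parameters (Q, V_brain, Ktr for both compounds) are scaled
by (W_human/W_rat)^0.75 for clearances, ^1 for volumes and ^−0.25 for rate
constants (0.35 kg → 70 kg by default, ratio 200). The rate-constant
exponent is applied with a negative sign: k = CL/V scales as
W^0.75/W^1 = W^−0.25, and a positive sign would make human brain transfer
faster than rat, contradicting the scaling rationale.

The human plasma side is a one-compartment model with first-order oral
absorption for each compound, mirroring the rat plasma structure. Its
constants are literature values and are deliberately *required*
configuration — no defaults ship. The fraction converted fm (default 0.5)
splits total clozapine clearance (conversion = fm·CL, other elimination =
(1−fm)·CL) rather than adding clearance; fm at the boundary values 0 or 1 is
implemented with a vanishing (1e-15-scaled) complementary clearance to keep
the parameter set valid. The metabolite absorption rate constant is unused
(norclozapine arises only by conversion) and is set to the scaled rat value
so the human parameter set passes the same positivity validation.

Simulation operates on unbound concentrations throughout; the unbound
fraction fu (default 0.03) only converts published total concentrations for
the overlay report, whose window is configurable with a 12–24 h post-dose
default. Steady state under once-daily dosing is computed by superposition
of the single-dose solution over enough intervals for the slowest system
eigenvalue to wash in (tolerance 1e-6), or by explicit repeated dosing with
a 0.1% last-two-intervals check; the two agree to < 1e-4 relative.
Population simulation draws η once per seed and reuses the subjects across
doses, so dose-linearity is exact in the outputs. The rat between-animal
variability spec is carried over to the like-named human parameters; what
variability the original human simulation used is not reported.

Receptor occupancy uses the single-site law of mass action,
100·C/(C + K_d), the standard form with 50% occupancy at C = K_d.
Clozapine and norclozapine D2 occupancies are reported separately, not
combined competitively. K_d values (nM) and molecular weights
(clozapine 326.8, norclozapine 312.8 g/mol) enter through a receptor panel
whose entries require a provenance reference tag; the norclozapine panel is
restricted to D2 by default. Because the published human plasma constants
and K_d values are not part of this package, the overlay and occupancy
figures are reproducible only conditionally on a user-supplied
configuration; the examples ship clearly-labelled synthetic stand-ins.

## Problem sizes and runtimes

The recovery experiment behind `scripts/acceptance.py` uses 24 animals per
arm (double-digit animal counts make the 3×RSE recovery bands meaningful)
and one Laplace fit from a ±35% perturbed start; it completes in a few
minutes on one CPU. The replicate-recovery property test uses 10 such
studies with the variability parameters held at their generating values
(halving the outer dimension without affecting fixed-effect recovery). VPC
checks use 1000 replicates; the bootstrap acceptance check uses 200 pooled
replicates on the original 4+5-animal design.

## Known limitations

* Transport is linear: no saturable (P-glycoprotein-like) efflux mechanism,
  no physiologically based brain model.
* Ω is diagonal; no covariates; no SAEM/importance-sampling estimators.
* The Laplace approximation shares the small-sample biases of
  linearisation-based mixed-effects estimators; ω estimates in particular
  inherit the usual downward shrinkage at 4–5 animals per arm.
* BQL handling is exclusion (or inclusion via flag), not a censored
  likelihood.
* Human translation assumes the rat brain-transfer structure and allometric
  exponents transfer unchanged; no CYP1A2-based metabolic scaling or
  covariate effects.
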