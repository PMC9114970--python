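# Methods

This note documents the statistical procedures implemented in `commvar`,
the assumptions behind them, the defaults of the synthetic-data generator,
and the numerical choices that matter for reproducing results.

## Data model

The unit of observation is one coded communicative act (an "event") in a
mother–infant dyad: signalling individual and her group, species
(Bornean/Sumatran), research setting (wild/captive), infant age in years
(1–7), parity (1–6), the 7-level social context and its binarization,
signalling direction, gesture type, and two binary outcomes — `redo`
(the signal was repeated/elaborated after failure; defined for
mother-signalled events) and `satisfactory` (the interaction ended in an
apparently satisfactory outcome; defined for infant requests). Direction
filtering is centralized in the pipeline: the redoings analysis consumes
mother-signalled events, the responsiveness analysis consumes infant
requests, and repertoires are built from mother-signalled acts. Stage
modules themselves are direction-agnostic.

## Repertoire similarity

Types used fewer than 2 times by an individual are dropped first; the
individual is retained only if her remaining instance total strictly
exceeds 30 ("customary" repertoires of adequately sampled individuals).
The instance filter counts instances of *retained* types; with the
opposite order the two filters agree on all but knife-edge cases, and the
chosen order is the more conservative one. Exclusions are reported, never
silent.

Dyadic similarity is the Dice coefficient over type sets. The
within-versus-between-setting contrast (and the within-wild versus
within-captive contrast) is tested per species by permuting setting labels
over individuals while holding the similarity matrix fixed. Label
permutation is the standard scheme for dyadic matrices: it preserves the
dependence structure among dyads sharing an individual. The one-tailed
Monte-Carlo p uses add-one smoothing, p = (1 + #{null ≥ observed}) /
(N + 1), so the minimum attainable p is 1/(N+1); ties between null and
observed carry half weight, which leaves continuous statistics untouched
but keeps a completely signal-free (constant) matrix at p ≈ 0.5 rather
than spuriously saturating a tail. Significance is declared only at
p ≤ 0.025 or p ≥ 0.975, because the permutation null of a difference
statistic need not be symmetric around zero; empirical type-I error of
this rule under exchangeable labels is 0.048 (1000 replicates, asserted in
the test suite at 0.05 ± 0.015). An exact mode enumerates all distinct
label assignments for small matrices and uses classic full-weight ≥
counting, matching exhaustive enumeration.

## Binomial mixed models

Both responses are modelled as Bernoulli with a logit link. Fixed effects:
setting (wild = 1), species (Sumatran = 1), infant age, parity (both
untransformed covariates) and the binary context. Random effects: crossed
intercepts for mother and group; the random-regression variant adds an
individual slope over the binary context, bivariate-normal with the
individual intercept (variances σ²_id, σ²_slope, correlation ρ). Mothers
never change groups, so the nesting present in the data is represented
without aliasing by distinct mother/group labels.

Estimation is maximum likelihood with the Laplace approximation. The
conditional mode of the random effects is found by a penalized Newton
inner loop; the random-effect design has pure indicator structure, so all
Z-products reduce to index gathers and bincounts and the penalized Hessian
is assembled block-wise, with one dense Cholesky per iteration. The outer
optimization (L-BFGS-B, finite-difference gradients, warm-started inner
modes) runs jointly over the fixed effects and the variance parameters —
standard deviations on the log scale, the intercept–slope correlation
through tanh of an unconstrained parameter, i.e. a Cholesky
parameterization of the 2×2 covariance. No REML (undefined for this
likelihood), no priors, no penalization.

Numerical choices:

* outer tolerances: relative likelihood change 1e−11, projected gradient
  1e−6, log-SD bounds [−7, 3]; a stalled optimizer is polished with
  Nelder–Mead and, failing that, flagged `converged=False` — never
  silently accepted;
* a variance whose log-SD reaches the lower bound (σ² ≤ ~1e−6) is
  reported as a boundary estimate of 0;
* separation is detected as |β| > 15 on the logit scale (flagged), and a
  constant response raises immediately;
* Wald covariance of β is the Schur complement of the joint penalized
  Hessian at the mode, conditional on the variance parameters — the
  standard GLMM Wald covariance.

Accuracy: on a 10-group × 20-observation single-intercept fixture the
implementation agrees with an independently coded one-node adaptive
Gauss–Hermite oracle to < 1e−6 and with `lme4::glmer` (Laplace) to ~1e−4
in log-likelihood, estimates and random-effect SD. The Laplace
approximation itself differs from exact (50-node) quadrature by ~0.01–0.07
log-likelihood units at this cluster size — an inherent property of the
approximation, identical in lme4 — so log-likelihoods should be compared
only between models fitted with the same approximation, which is how the
package uses them (LRT, AIC).

Wald 95% intervals achieve nominal coverage for the within-individual
context effect; cluster-level effects (setting, species) under-cover
(~0.7–0.8) with 26 mothers because the intervals are conditional on the
estimated variance parameters — the familiar few-clusters caveat, shared
by the standard GLMM software this mirrors.

The likelihood-ratio test for individual identity compares the full model
against one lacking the mother intercept, with the naive χ²(df = parameter
difference) reference. Because the null value σ² = 0 lies on the boundary
of the parameter space this reference is conservative; the output records
that caveat rather than correcting it, keeping the procedure exactly as
practised.

## Repeatability and random regression

Latent-scale adjusted repeatability uses the logistic residual variance
π²/3 ≈ 3.2899:

    R_level = σ²_level / (σ²_id + σ²_group + π²/3).

Fixed effects are in the model but their variance is not added to the
denominator (adjusted, not enhanced, repeatability). Group-level R uses
the same denominator, so R_individual + R_group ≤ 1 always. Under random
slopes repeatability is context-dependent; the package reports R at the
reference context (slope term = 0) and says so in the result.

Uncertainty comes from a parametric bootstrap: simulate responses from the
fitted model (fresh random effects and Bernoulli noise), refit, recompute
R; the SE is the bootstrap SD and the CI the percentile interval truncated
at 0. The p-value instead comes from the boundary-conservative LRT on the
original data. The two procedures answer different questions, which is why
a CI touching 0 can coexist with a very small p.

Random-intercept versus random-regression models are compared on AIC
(k counts fixed effects plus variance parameters, including the
correlation); the slope model is accepted only when ΔAIC > 7, strictly.
The LRT between the two (df = 2) is reported alongside.

## Synthetic-data generator

The generator is the package's study-conditions definition, not a test
fixture. Defaults:

* **Roster**: 26 mothers in 7 groups — wild Bornean (9), wild Sumatran
  (8), three Bornean zoos (2+1+1), two Sumatran zoos (3+2). Infant age ~
  uniform {1..7}, parity ~ uniform {1..6}, independent per mother (they
  are moderators, not part of the variance-partition claims).
* **Effort**: events per mother ~ Poisson(160) truncated at ≥ 1
  (unbalanced effort without modelling observation time); 22% of events
  are mother-signalled, so mothers average ~35 signalled acts — enough
  that the >30-instance repertoire filter excludes a handful of mothers,
  reproducing the observed 26 → ~19 exclusion structure — while infant
  requests total ~3250, the scale of the responsiveness analysis.
* **Latent model**: β = (−1.0, −0.3 wild, +0.2 Sumatran, +0.05 age,
  −0.05 parity, +0.8 context) on the logit scale; σ²_id = 0.382,
  σ²_group = 0.15 (latent individual R exactly 0.10), σ²_slope = 1.0,
  ρ = +0.3 (individuals differ substantially in their context shift, with
  plastic individuals tending to higher intercepts). The binary context is
  i.i.d. Bernoulli(0.35) per event — the analysis treats context as a
  fixed covariate and no temporal structure is claimed. These values were
  calibrated once so the generated data reproduce the magnitudes the
  analysis is designed to detect (within-setting Dice ≈ 0.69 vs between
  ≈ 0.58; random-regression ΔAIC of order 10 for the sparse response and
  of order 50–80 for the dense one) and are not revisited.
* **Repertoires**: a global pool of 14 gesture types, 70% shared between
  settings and the remainder split alternately; each mother omits each
  available type with probability 0.15 and spreads usage by a symmetric
  Dirichlet (concentration 5). Both responses are drawn from the same
  linear predictor (independent draws at the same probability for the
  off-direction column), so either analysis recovers the same truth.

What the generator does *not* emulate: gesture sequences in time, modality
switching, video-coding noise, vocalizations, partner (infant) effects,
and any dependence of context on setting or age. Passing tests therefore
demonstrate that the estimators recover the parameters of the assumed
generative model at the study's size — not that the model is correct for
real orang-utan data.

## Problem sizes used in validation

Parameter recovery runs 50 replicates of the full study shape (26
mothers, ~3500 analysed events) per slope-variance condition; at truth
R = 0.10 the mean estimated R is ~0.09 (within ±0.03), the ΔAIC > 7 rule
selects a spurious slope model in 0/50 replicates at σ²_slope = 0 and
detects σ²_slope = 1.5 in 50/50. Type-I calibration of the permutation
rule uses 1000 replicates of 16 exchangeable individuals. Bootstrap
examples in the tests use 20–30 replicates; the acceptance script uses
100. Single-fit recovery is additionally checked at 200 mothers × 50
events (σ̂²_id within ±0.2 of 1.0).

## Known limitations

* Laplace-only integration (no quadrature upgrade for single-factor
  models); variance components of binary data with few clusters retain
  the usual downward ML bias.
* The LRT and the repeatability p share the boundary conservativeness
  described above.
* Group repeatability is estimated from 7 groups and often hits the
  boundary at 0 in any single replicate.
* The bootstrap refits the same specification it simulated from;
  model-misspecification uncertainty is not propagated.
* The reader targets this package's event schema; adapters for external
  deposits are future work.
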