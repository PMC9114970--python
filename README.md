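# commvar

Variance partitioning of individual variation and plasticity in
mother–infant gestural communication.

## The scientific problem

Comparative studies of primate communication usually analyse population or
species means and treat variation around those means as noise. Behavioural
ecology's reaction-norm framework instead decomposes repeated observations
of the same individuals into

* **behavioural type** — between-individual differences in average
  behaviour (the individual's random *intercept*),
* **individual plasticity** — between-individual differences in how
  behaviour shifts across social contexts (the individual's random
  *slope*), and
* environmental and developmental moderators (research setting, species,
  infant age, parity).

`commvar` implements this full analysis for infant-directed communication
in orang-utan mothers observed in the wild and in zoos, with two binary
communicative tactics as responses: **gestural redoings** (repeating or
elaborating a gesture after communicative failure, i.e. persistence) and
**responsiveness** (reacting to an infant's request with a satisfactory
outcome). Because real field data of this kind are hard to obtain, the
package ships a first-class synthetic-data generator that emulates the
study design (2 species × 2 settings, 7 groups, 26 mothers, unbalanced
repeated observations) with known ground-truth parameters, so every stage
of the analysis is testable end to end.

## Models and statistics

**Repertoire similarity.** An individual's *customary repertoire* is the
set of gesture types she used at least twice, retained only if her total
instance count exceeds 30. Similarity between two repertoires A, B is the
Dice coefficient

    D = 2|A ∩ B| / (|A| + |B|).

Whether mothers in the same research setting share more types than mothers
in different settings is tested by matrix permutation: setting labels are
permuted over individuals (N = 1000) while the dyadic matrix stays fixed,
and the one-tailed p is judged against the asymmetric thresholds p ≤ 0.025
or p ≥ 0.975 (the null of a difference statistic need not be symmetric
around zero).

**Behavioural reaction norms.** Responses are modelled with binomial logit
mixed models fitted by Laplace-approximated maximum likelihood,
implemented in the package itself:

    logit P(y_ij = 1) = x_ij' β + u_i + v_g(i) + s_i · context_ij
    (u_i, s_i) ~ N(0, Σ),   v_g ~ N(0, σ²_group)

with fixed effects for setting, species, infant age, parity and the
binarized social context, crossed random intercepts for mother and group,
and (in the random-regression variant) correlated individual slopes over
context. The package provides Wald standard errors, AIC, likelihood-ratio
tests, conditional modes (BLUPs), variance inflation factors and
per-individual reaction-norm predictions.

**Repeatability.** On the latent scale of a logit model the residual
variance is π²/3, so adjusted repeatability at a level is

    R_level = σ²_level / (σ²_id + σ²_group + π²/3),

with parametric-bootstrap standard errors and confidence intervals and a
likelihood-ratio p-value for the focal variance component. Random-intercept
and random-slope models are compared on AIC with the strict rule that the
slope model is preferred only when ΔAIC > 7.

## Worked example

```python
import dataclasses
import commvar as cv
from commvar.glmm import GlmmSpec, build_design, fit_glmm, lrt
from commvar.reaction_norms import compare_models, repeatability

config = dataclasses.replace(cv.PopulationConfig(), seed=42)
truth = cv.TruthParameters()          # latent individual R = 0.10
roster = cv.generate_population(config)
events, effects = cv.generate_events(
    roster, truth, config, dataclasses.replace(cv.RepertoireConfig(), seed=42)
)

# responsiveness to infant requests
requests = events.query("direction == 'infant_to_mother'")
design = build_design(requests, GlmmSpec(response="satisfactory"))
fit = fit_glmm(design)
reduced = fit_glmm(design.with_spec(
    dataclasses.replace(design.spec, mother_intercept=False)))
slope = fit_glmm(design.with_spec(
    dataclasses.replace(design.spec, mother_slope=True)), start=fit.varcomps)

print(f"n = {design.n_obs} events, {design.n_mothers} mothers")
print(f"sigma2_id = {fit.varcomps['sigma2_id']:.3f}, "
      f"sigma2_group = {fit.varcomps['sigma2_group']:.3f}")
print(f"R_individual = {repeatability(fit, 'individual').R:.3f}")
test = lrt(fit, reduced)
print(f"LRT for mother identity: chi2(1) = {test.statistic:.2f}, p = {test.p_value:.2g}")
comp = compare_models(fit, slope)
print(f"random regression: dAIC = {comp.delta_aic:.1f} -> prefer {comp.preferred} model")
```

Output:

```
n = 3255 events, 26 mothers
sigma2_id = 0.405, sigma2_group = 0.000
R_individual = 0.110
LRT for mother identity: chi2(1) = 127.35, p = 1.6e-29
random regression: dAIC = 100.1 -> prefer slope model
```

Reading it: at this seed the fitted individual intercept variance (0.405)
is close to the generating value (0.382), giving an estimated latent
repeatability of 0.110 against a true 0.10 — about 11% of the latent
variance in responsiveness is attributable to stable differences between
mothers. The group variance collapsed to the boundary (only 7 groups carry
information about it). Individual identity is strongly supported by the
LRT, and the random-regression model (mothers differ in how much they
shift responsiveness between begging and other contexts; the generator's
slope variance is 1.0) beats the intercept-only model by far more than the
ΔAIC > 7 threshold.

The same analysis is available from the shell:

```
commvar simulate --seed 42 --output-dir sim
commvar run-all --input sim/events.csv --seed 42 --output-dir results
```

which writes `report.yaml` plus delimited tables (similarity matrix,
repertoire counts, BLUPs, reaction-norm predictions).

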