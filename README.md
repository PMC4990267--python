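# fleet-rum

Sequential random-utility modeling of tuna purse-seine fleet spatial
behavior: where does a vessel make its first set after leaving port, and
to which region does it switch (or stay) each day at sea?

The package is aimed at quantitative fisheries scientists and fleet-dynamics
modelers.  It implements, end to end:

* **A two-stage discrete-choice model.** A fishing trip is split into a
  *first set* decision made in port and daily *switching* decisions at sea.
  On each choice occasion a vessel picks one of R regions (default 12,
  partitioning the eastern Pacific fishing grounds).  The systematic
  utility of region *r* is

  V(r) = Σₖ X(r,k) βₖ + Σⱼ Zⱼ θ(j,r)

  where X are region-varying covariates (lagged log CPUE and RPUE
  expectations, log distance cost proxies, quartile-count environmental
  variables) sharing one coefficient per feature, and Z are
  decision-invariant covariates (trip accumulators, the MEI climate index,
  an October–March dummy) interacted with region indicators (Z ⊗ I), with
  θ(·, R) ≡ 0 for the base region.  With iid extreme-value errors, choice
  probabilities are the conditional logit Π(r) = exp V(r) / Σₛ exp V(s).

* **Maximum-likelihood estimation** with analytic gradient and Hessian
  (Newton iteration; the conditional-logit likelihood is globally concave),
  stratified into 16 models: 2 dolphin-mortality-limit (DML) statuses × 4
  vessel size classes × 2 stages.  Results objects carry estimates, standard
  errors, McFadden LRI / Aldrich–Nelson / Estrella pseudo-R², and a
  `summary()` table.  An optional normal-mixing mixed-logit mode is included.

* **Prediction evaluation**: the share of occasions whose
  highest-probability region equals the observed region, tabulated by
  period × DML × size class.

* **An iterative trip simulator**: first-set choice, then daily switching
  with trip-state updates, until exogenous termination (days at sea,
  cumulative distance, or hold capacity).

* **A synthetic fleet generator**: because the underlying observer data are
  confidential, the package generates schema-identical event logs by
  running the simulator with known ground-truth coefficients — making
  estimation a parameter-recovery problem with a checkable answer.

## Worked example

Generate a single-stratum synthetic fleet (6 large DML vessels over 10
months), rebuild the choice occasions from the event logs, and refit the
switching model:

```python
import numpy as np
from fleetrum import SyntheticScenario, generate_dataset, fit_conditional_logit

scenario = SyntheticScenario.compact(seed=7, n_vessels=6, n_months=10)
data = generate_dataset(scenario)
occasions = [o for o in data.occasions() if o.stage == "switch"]
result = fit_conditional_logit(occasions)
print(result.summary())

truth = data.ground_truth[(1, "large", "switch")]
print("true beta:", np.round(truth.beta, 3))
print("estimated:", np.round(result.estimates.beta, 3))
print("std error:", np.round(result.std_errors.beta, 3))
```

Output (abridged):

```
Conditional logit results
======================================================================
Stage: switch   Stratum: None
N occasions: 1345   Alternatives: 12   Parameters: 25
lnL: -557.289   lnL0: -3342.199
McFadden LRI: 0.8333   Aldrich-Nelson: 0.8055   Estrella: 0.9999
Converged: True (20 iterations)
...
true beta: [ 0.4    0.25  -2.185]
estimated: [ 0.401  0.169 -2.041]
std error: [1.455 1.497 0.07 ]
```

The 1,345 observed set-day choices recover the generating coefficients:
the strongly negative log-distance cost (−2.19) is estimated as −2.04
(SE 0.07), and the CPUE/RPUE expectation effects are within one standard
error of truth (their SEs are wide because regional catch and revenue
expectations are highly correlated).  lnL0 is the equal-share null
(N·ln 1/12), so the LRI of 0.83 says the fitted utilities explain most of
the choice variation in this synthetic fleet.

The same workflow scales to the full fleet: `fit_stratified` on a
complete synthetic fleet returns the 2 × 4 × 2 = 16 stratified models, and
`fleetrum.fit_eval.prediction_table` produces the percent-perfectly-
predicted tables by period, DML and vessel size.

## Command line

```bash
fleet-rum synth --out run/ --seed 1 --set compact=true   # write a dataset
fleet-rum fit --set n_vessels_per_stratum=5              # 16-model pipeline
fleet-rum evaluate                                       # + prediction table
fleet-rum simulate --n-trips 20 --seed 3 --out trips.csv
fleet-rum config                                         # show configuration
```

Every pipeline run writes a `manifest.json` with the seed and SHA-256
checksums of all artifacts; reruns with the same configuration are
byte-identical.

## Layout

| Module | Contents |
|---|---|
| `fleetrum.regions` | region partition, point-to-region assignment, great-circle distances |
| `fleetrum.features` | Table-style covariate construction: CPUE/RPUE, quartile counts, trip state, occasions |
| `fleetrum.choice` | conditional logit model/results, stratified fitting, mixed-logit mode |
| `fleetrum.fit_eval` | pseudo-R² measures, percent-perfect prediction tables |
| `fleetrum.sequential` | termination rules, first-set/switch prediction, trip simulator |
| `fleetrum.synthetic_fleet` | scenario, environment/fleet/price generators, recovery experiments |
| `fleetrum.config` / `fleetrum.cli` | YAML run configuration, pipeline, `fleet-rum` CLI |

See `docs/methods.md` for the model's assumptions, the generator's design
and its limitations, and the numerical choices made.
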