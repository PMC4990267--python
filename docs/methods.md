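# Methods

## The model

A purse-seine trip is modeled as a sequence of discrete location choices
over R labeled regions (default 12, an approximate partition of the
eastern Pacific fishing grounds between 150°W–75°W and 25°S–35°N).  Two
stages share one functional form but are estimated separately, because the
information sets differ:

* **First set.**  Decided in port, before departure.  Covariates are
  evaluated at the departure port; the chosen alternative is the region of
  the trip's first set.
* **Switching.**  One decision per day at sea.  Every region — including
  the current one — is in the choice set, so "staying" is itself a choice.
  A choice is observed on every day carrying at least one set; covariates
  are evaluated from the previous day's trip state.

Utility of region r on occasion n is

    V[n, r] = sum_k X[n, r, k] * beta_k  +  sum_j Z[n, j] * theta[j, r],

with iid type-I extreme-value errors integrated out analytically, giving
conditional-logit choice probabilities.  The Z features are constant
across alternatives within an occasion, so their effects are identified
only relative to a base region: theta[:, R] = 0 (the Kronecker Z ⊗ I
construction).  Differences in X across regions identify beta; adding a
constant to an X feature in every region changes nothing (tested).

### Covariates

Region-varying (X):

* `CPUE_1`, `RPUE_1` — one-month-lagged log regional expectations:
  ln((YFT+BET+SKJ)/(DF+1e-4) + 1e-4) and
  ln((YFT·YFTP + BET·(SKJP+100) + SKJ·SKJP)/(DF+1e-5)), with DF = days
  fished in the region-month.  The juvenile bigeye price is the skipjack
  price plus $100/t.  A zero-revenue region-month floors the RPUE log
  argument at 1e-12 rather than erroring: the published offset guards only
  the divisor.
* `Dist_Exp`, `Dist_Arr` — ln(1 + km) great-circle distance from the
  current position (or port) to each region midpoint, and from each
  midpoint to the arrival port.  `Dist_Arr` enters the switching stage
  only.  Distances use the haversine formula on the IUGG mean sphere
  (6371.0088 km); ellipsoidal precision is immaterial for a cost proxy.
* Environmental quartile counts — for SST, SSH, mixed-layer depth, O2 at
  150 m and chlorophyll: the number of 1°×1° cells in the region strictly
  below the first (`_L`) or at/above the third (`_H`) reference quartile.
  Reference thresholds for SST (26.8, 28.7 °C), SSH (0.6, 0.7 m), MLD
  (18.6, 38.8 m) and O2 (0.4, 1.0 ml/l) ship as immutable defaults;
  chlorophyll thresholds are not published and are computed from a
  reference sample of dolphin-set-like cells with the linear-interpolation
  ("type 7") quantile rule.

Decision-invariant (Z): trip accumulators (distance, days, travel days,
search days, catch by species since departure; travel, search, set counts
and catch in the last fished region), the monthly MEI value, and an
October–March dummy.  Accumulators with unbounded natural scales (km,
days, tons) enter as ln(1 + value), matching the log specification of the
model while tolerating zeros; set counts, MEI and the dummy enter raw.

**First-stage Z default.**  At the moment of departure every trip
accumulator is identically zero, so a first-stage design including them
would carry all-zero Z ⊗ I columns and a singular information matrix.  The
default first-stage Z list is therefore MEI + Oct–Mar only; the switching
stage uses all sixteen accumulators plus both.  Feature lists are fully
configurable per stage (`FeatureConfig`) for users who time the first
choice differently.

### Stratification

Fleets are heterogeneous: a vessel with a dolphin mortality limit (DML)
fishes a different métier than one without, and trip calculus varies with
hold capacity.  Fits are stratified by DML (0/1) × size class × stage —
16 models.  Size classes are half-open capacity bins [363, 700), [700,
1050), [1050, 1250), [1250, 1800] t; a boundary capacity belongs to the
larger class (a deterministic rule; the published ranges print touching
endpoints).  Strata with fewer occasions than a configurable floor
(default 20) are reported as skipped, never silently fitted.

## Estimation

Maximum likelihood by damped Newton iteration from a zero start, with the
analytic gradient and the analytic Hessian (the observed information).
The conditional-logit log likelihood is globally concave, so convergence
is declared at gradient max-norm < 1e-6 and multistart agreement is a
tested invariant.  Standard errors come from the inverse observed
information at the optimum; a singular information matrix (collinear
columns) falls back to pseudo-inverse steps and is flagged.  Any
|coefficient| > 30 on the log-odds scale raises a separation warning —
with region-specific theta blocks, a region never chosen within a stratum
is enough to push its coefficients toward −∞, and the flag makes that
visible rather than letting it masquerade as a fit.

The null model for the pseudo-R² measures is the zero-parameter
equal-share model, lnL0 = N·ln(1/R).  The three measures use the standard
definitions: McFadden LRI = 1 − lnL/lnL0; Aldrich–Nelson =
2ΔlnL/(2ΔlnL+N); Estrella = 1 − (lnL/lnL0)^(−(2/N)·lnL0).

A mixed-logit mode (normal mixing over selected X coefficients, simulated
likelihood over scrambled Halton draws) is provided but off by default:
no mixing distributions are specified for this fishery, and the
fixed-coefficient conditional logit is the estimable, testable core.

## Prediction and evaluation

A choice is "perfectly predicted" when the highest-probability region
(ties to the lowest region id, for determinism) equals the observed one.
Tables report observed count A, perfect-fit count B, and 100·B/A rounded
to the nearest integer — rounding, not truncation, is the convention that
reproduces the published cells (7921/29516 = 26.84 prints as 27).  For an
uninformative model the expected rate is 1/R, a tested sanity bound.

## The sequential simulator

`simulate_trip` runs the model forward: first-set choice in port, a
cruise-speed steam (15 kn ≈ 667 km/day) to the chosen region with no sets
in transit, then one switching decision per day until termination.
Termination is exogenous: days at sea ≥ max_days, cumulative distance ≥
max_distance (both per size class), or total catch ≥ 90% of hold
capacity, checked in that order.  Default limits are (50, 75, 110, 172)
days and (12, 16, 20, 26) thousand km by size class: the day cap for the
largest class matches the longest observed trip, and the distance caps
bracket the fleet-wide average of roughly 10,000 km steamed per trip.
Prediction mode is `argmax` by default ("choose the most probable
region"); `sample` mode draws from the choice distribution with a seeded
generator and is what the data generator uses.

**Within-day resolution of switching decisions.**  Each day's decision is
sampled from the model given the previous day's state and resolves the
same day: staying means a local roaming hop to a nearby cell of the
current region; switching means relocating into the chosen region within
the day (travel-heavy hours, possibly a set on arrival).  This is a
deliberate design choice with a statistical reason.  If a switch instead
triggered a multi-day steam with the set days later, observed set-day
choices would be censored toward regions already closest to the vessel,
and the observable data would be *perfectly* classified by "nearest
region" — a complete-separation artifact under which no estimator can
recover the generating coefficients.  Resolving decisions within the day
makes every observed set-day choice an unconditional draw from the
conditional logit given the covariates an estimator reconstructs from the
event log, which is exactly the property the recovery experiments test.
The multi-day steam abstraction is retained where it is harmless: the
outbound leg to the first set, where no decisions occur.

Catches are a plug-in (`GammaCatchModel` by default: per-set independent
gamma draws by set type and species; DML vessels mostly make dolphin
sets, others split between floating-object and unassociated sets).  The
choice model itself has no catch process; the plug-in exists only to
drive the trip-state covariates and the capacity termination.

## The synthetic fleet generator

Real observer logs are confidential, so the generator emulates the data
*schema* and the decision process, not the real ocean:

* **Fleet**: ~150 vessels by default, split over the eight DML × size
  strata, capacities uniform within class, DML vessels departing mostly
  from the northern (Mexican) port.
* **Environment**: five monthly 1°×1° fields, each a linear
  latitude/longitude gradient plus a sinusoidal seasonal cycle plus
  seeded Gaussian noise, parameterized so realized values straddle the
  published quartile thresholds.
* **Regional expectations**: region-month fishing totals (gamma effort
  and catch around a fixed regional attractiveness profile, with
  Dirichlet species shares) pushed through the same lagged CPUE/RPUE
  formulas the estimator applies to logs.  Species shares must vary by
  region-month: with fixed shares, RPUE − CPUE is constant across regions
  within a month and the two covariates become collinear in the
  difference space that identifies beta.
* **Prices / MEI**: constant levels plus seeded monthly noise; a
  multi-year sinusoid plus noise.
* **Ground truth**: per-stratum coefficient sets with the fishery's
  qualitative signs — strongly negative log-distance cost (< −2, steeper
  for smaller vessels), positive CPUE/RPUE expectations, negative oxygen-
  barrier effects — and small deterministic pseudo-random theta values.

Everything is a pure function of the scenario seed (byte-identical
reruns, tested).  The default scenario's median simulated trip length
lands near 45 days, the observed fleet median — a realism target, not an
assertion.

What the generator does **not** emulate, hence what passing tests do and
do not show: regional expectations are exogenous (no feedback from the
simulated fleet's own catches into next month's CPUE); there is no
spatial autocorrelation in unobserved utility, no information sharing
between vessels, no port choice, no weather; and synthetic switching
behavior is considerably more predictable than real fleets (within-sample
percent-perfect on synthetic data runs far above the 27–53% seen with
real observer data, whose behavioral noise no stylized generator
reproduces).  Recovery results therefore demonstrate the *estimator* is
correct under the model's own assumptions — not that the model captures
everything real fleets do.

### Recovery benchmarks

The standard recovery configuration is a compact single-stratum scenario
(`SyntheticScenario.compact`): three X features (CPUE, RPUE, expected
distance) and two Z features (distance since departure, MEI), 25
parameters, ≥5,000 switching occasions from 15 vessels over 24 months.
Estimates land within 3 reported SEs of truth, and over 50 replicates of
a smaller instance the 2-SE coverage sits near the nominal 95%.  The
compact configuration keeps the parameter count small enough that a
"every parameter within 3 SE" check is statistically meaningful; the full
17-Z-feature switching model (201 parameters) is exercised in the 16-model
pipeline, where thin strata can and do trip the separation flag — that is
reported, not hidden.

## Numerical choices

* Quantile rule: linear interpolation between order statistics (type 7).
* Boundary ties: points on shared region boundaries assign to the lowest
  region id; probability ties predict the lowest region id.
* Quartile counting: strict `<` below Q1, `>=` at Q3, per the published
  variable definitions; cells with missing values drop from both counts.
* Degenerate RPUE (zero revenue): floor at ln(1e-12).
* Softmax: max-subtraction; probabilities sum to 1 within 1e-12.
* Newton steps: halving line search; pseudo-inverse fallback on singular
  information; convergence at gradient max-norm 1e-6, cap 100 iterations.
* Seeds: a scenario seed expands through `SeedSequence.spawn`, so adding
  vessels or months never reshuffles other vessels' draws.

## Known limitations

* The packaged 12-region partition is an approximate rectangular grid;
  the partition actually used with observer data follows oceanography and
  is not published.  All geometry is an input (GeoJSON).
* The first-stage model cannot identify trip-accumulator effects under
  port-time evaluation (see above); analyses that date the first choice
  at the first set instead can re-enable those features but then inherit
  the censoring caveat.
* The mixed-logit mode uses a numerical gradient and is intended for
  small models only.
* Out-of-sample evaluation supports both observed-covariate prediction
  (refit and predict on held-out occasions) and forward simulation; which
  of the two a given study needs depends on whether covariates for the
  prediction period are observed.
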