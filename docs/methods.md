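# Methods

`flocklearn` implements a pipeline for detecting social transmission of
foraging information in a mixed-species population of wild birds (two
species, adults and juveniles) visiting RFID-logged feeders, together with
a generative simulator that provides ground truth for every stage.  This
note records the models, the numerical choices, and the limits of what the
test suite demonstrates.

## Gathering events

Visits at a feeding station arrive in bursts when a flock lands.  Events
are detected per station by one-dimensional Gaussian mixture models over
visit timestamps, fitted within day-long windows anchored at the first
visit of the stream (anchoring makes detection exactly invariant to a
global time shift).  The number of components K is chosen by BIC over
1..min(k_max, n) with an early stop after three consecutive worsenings;
duplicate timestamps are harmless because component variances are floored
at 1 s².  Visits go to their maximum-responsibility component.  A
station-wide post-pass merges components whose assigned time ranges overlap
or fall within `merge_gap` (default 120 s) of each other: interleaved or
abutting fragments cannot be separate simultaneous gatherings at one
feeder, and the slack also heals clusters cut by a window boundary.  The
two-minute default is far below the typical silence between gatherings
(tens of minutes at realistic visit rates) and far above the spacing of
visits within one.

Day-window fitting (rather than segmenting at silent gaps) is deliberate:
with blocks of only one burst (n ≈ 10) the BIC penalty `p log n` is too
weak and the mixture overfits; a full day of visits gives BIC enough data
to resist spurious splits.

## Association network

The edge weight between birds A and B is the simple ratio index

    SRI = x / (x + y_A + y_B + y_AB),

tallied over *sampling periods* — maximal sets of temporally overlapping
events pooled across stations, so y_AB counts periods in which the two
birds were seen simultaneously at different feeders.  Pairs never
co-sampled get weight 0 (the expected-observation sums require defined
weights everywhere), with the count of such pairs recorded.  Only
pre-training ("plain food") visits feed the network; the phase filter is
explicit in the pipeline.

The homogenized counterpart replaces each demonstrator's column by its mean
`Σ_i a_ij / n`, preserving the demonstrator's total expected audience
(column sums) to machine precision.  Whether the mean should exclude the
observer itself (divide by n−1) is not determinable from the source
material; dividing by n is the default, with `exclude_self=True` available.

## Expected observations and choice models

For each visit (choice) at time t the table carries the bird's own prior
palatable/unpalatable visit counts N± (strictly before t, ties at the same
timestamp do not see each other) and the network-weighted expected numbers
of observed feeding events O± = Σ_{j≠i} N±_j(t) a_ij, split by the
demonstrator's age (adult/juvenile) and species relation to the chooser
(conspecific/heterospecific).  The eight finest cells sum exactly to their
pooled margins on every row.

Choices are modelled with binomial mixed models: a per-bird random
intercept B_i and, on the logit scale,

    p(unpalatable) = logit⁻¹(α + β_asoc+ N+ + β_asoc− N− + β_soc+ O+ + β_soc− O− + B_i)

with split-cell and difference reparameterisations for the demonstrator
classes, all affinely equivalent (identical likelihood; the difference
coefficient is the between-class contrast).  Predictors are z-standardized
by default and every fit carries back-transformed coefficients
(β/SD, with the intercept adjusted by Σ β·mean/SD).

No frequentist binomial GLMM with a scalar random intercept exists in the
installed Python stack, so the marginal likelihood is implemented here:
adaptive Gauss–Hermite quadrature (25 nodes, per-group Newton modes with
curvature scaling) as the default, and a fixed-node Gauss–Hermite variant
with an analytic gradient for simulation inner loops.  The two agree to
~1e-4 on shared fixtures, and both agree with lme4's `glmer` (nAGQ = 25) to
a few 1e-3 on coefficients, SD, and log-likelihood; at a zero-variance
boundary the fit coincides with ordinary logistic regression.  L-BFGS-B
with σ ≥ 0, ftol 1e-8, 500 iterations; Wald SEs from a finite-difference
Hessian; boundary σ estimates are reported as 0 with a flag, and their row
is dropped from the covariance.  Rank-deficient design columns are dropped
and recorded on the fit.  AIC = −2ℓ + 2k with k counting coefficients plus
the intercept SD.

Daily learning curves use the same engine with binomial counts per
bird-day and an orthogonal (QR) degree-2 polynomial of day crossed with
species and age; model selection starts from the three-way interaction and
keeps the lowest-AIC member of a nested set.  Raw-power day coding is
available behind `raw_poly`.

## The simulation null for network-mediated effects

A significant coefficient on O± does not by itself show that learning
follows the network.  The test holds the observed visit skeleton fixed and
re-simulates outcomes under *homogenized* social learning: covariates are
recomputed on the fly from simulated prior outcomes through the homogenized
network, outcomes are drawn from the fitted model with per-bird intercepts
redrawn from the estimated SD (a generative null over the population;
conditional modes would be the alternative), each replicate is refitted
with covariates rebuilt from the observed network, and the Wald Z of the
target coefficient is collected.  The simulation p-value is the fraction of
replicates at least as far from the null mean as the observed Z (distance
in either direction).  Non-converged replicates are dropped and counted;
more than 20% is an error.

Two observations from the validation suite, reported rather than hidden:

* Because the null takes its effect size from the fitted model, the null Z
  distribution is centred near an attenuated copy of the observed Z.  The
  distance-from-mean p-value is therefore conservative when the social
  effect is weakly estimated, approaching nominal behaviour only when the
  effect is strongly significant — which is exactly the situation in which
  the procedure is intended to be applied (it is run only on social effects
  already found significant).  At the colony sizes the validation suite can
  afford (15–30 birds), measured type-I rejection at 0.05 is ~1%, below
  nominal; power under network-following generation still clearly exceeds
  it.
* The appetitive (O+) analogue of the test is less conservative than the
  avoidance (O−) one; the suite reports both rates side by side without
  asserting the asymmetry.

## Order-of-acquisition diffusion analysis

Reversal learning (first visits to the previously unpalatable colour) is
analysed by OADA.  At each acquisition event the relative rate for naive
bird i is

    R_i = exp(β_A x_i) + Σ_m s_m exp(β_S x_i) Σ_j a^(m)_ij z_j(t),

with x_i the species indicator, z_j informed status, and a^(m) the observed
network masked by demonstrator age and/or species relation (columns of the
excluded class zeroed; masks of one estimated network, not re-estimated
networks) or the homogenized network.  The event contribution is
log(R_acquirer / Σ_naive R_i); a common baseline rate cancels, so only the
order informs the fit.  Censored never-acquirers stay in every risk set.
"Equal asocial and social rates between species" ties β_A = β_S.

Fitting is box-constrained L-BFGS-B (s ≥ 0) with five seeded starts;
model sets are compared by AICc (n = number of acquisition events) and
Akaike weights, with summed weights per transmission class
(observed / homogeneous / asocial) reported alongside the best model's
parameters.  Confidence intervals for s are profile-likelihood intervals
(χ²₁ cut-off, bisection-bracketed, boundary-respecting); with the true rate
on the 0 boundary the MLE sits at 0 in about half of replicates, as
boundary asymptotics dictate — recovery checks assert that behaviour, not
near-certain boundary estimates.  %ST (the share of acquisitions
attributable to a network) is the mean per-event social fraction of the
acquirer's rate, with intervals obtained by recomputation at the profile
endpoints.  First-visit timestamp ties are a hard error naming the birds;
a deterministic (time, bird id) tie-break is behind a flag.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
the field site's dynamics.  Birds belong to overlapping flocks (every bird
has a primary flock; extra memberships with probability
`flock_membership_overlap`); an event is hosted by one uniformly chosen
flock, members attend independently (`attendance_prob`), and attendees'
visit counts are Poisson with a per-bird mean-one lognormal activity
multiplier (`activity_sd`, default 0.6) — real colonies show
order-of-magnitude differences in visit counts, and that heterogeneity is
what gives the network-null test its contrast.  Visit times within an
event form a Gaussian burst (SD = duration/4) around the event midpoint,
matching what a mixture-model detector assumes about flock arrivals.  The
closed-form true network is the probability that a pair is together at a
sampled gathering, conditional on at least one of them being seen — the
estimand of the simple ratio index — so the empirical SRI converges to it.

Colour choices in the avoidance phase are drawn from the logistic model
above using the bird's true running counts; when bird j feeds, every other
bird's latent counter R± increments by a_ij, included independently with
probability p_o.  Hence E(R) = p_o·O, and at p_o = 1 the simulator's R±
equals the pipeline's O± exactly on every row — the identity the oracle
tests rely on.  Reversal diffusions are Gillespie draws from the OADA rate
model with known s per transmission network, censored at `reversal_days`.

Default study conditions (frozen before the validation runs they govern):
60 birds, 75% juveniles, 40% of the focal species, 4 flocks, 3 stations,
8 experiment days, 6 events per station-day of 300 s, 2 visits per
bird-event, α = −0.5, β_asoc+ = −0.10, β_asoc− = −0.15, β_soc+ = 0,
β_soc− = −0.05, intercept SD 0.25, s = {adult: 10, juvenile: 0},
asocial base rate 1/day, 9 reversal days.  The intercept SD is kept
moderate deliberately: a bird's cumulative personal counts are themselves
driven by its intercept, and at realistic series lengths strong
heterogeneity partially aliases with β_asoc−, a finite-sample
self-confounding of sequential designs that the recovery suite would
otherwise measure as under-coverage.  The same mechanism leaves a visible
negative skew in β_asoc− estimates even at SD 0.25; coverage stays at or
above the asserted 90% but closer to it than for the other coefficients.

Validation problem sizes: oracle equivalence on ≤ 12-bird fixtures;
parameter recovery on 100 replicates of 60-bird avoidance studies;
null-test calibration on 200 replicates of 15-bird colonies with 200 inner
simulations each (the field analysis used 1000) and power on 30 replicates
of 30-bird colonies; OADA recovery on 100 replicates of 50-bird diffusions.

## Known limitations

* No spatial movement, feeder depletion, competition, per-bird observation
  probabilities, or forgetting of past observations; visits equal feeds.
* The flock generator is a stand-in with closed-form structure, not an
  estimate of any real colony's dynamics; passing recovery tests shows the
  estimators are correct under the assumed model, not that the model fits
  field data.
* The simulation null's conservatism at weak signal (above) means p_s
  values near the threshold should be interpreted cautiously when the
  underlying Wald Z is modest.
* Exact reproduction of published coefficient values from field data is
  sensitive to GLMM integration details; agreement within the reported
  standard error is the appropriate standard.
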