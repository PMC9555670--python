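# Methods

## Setting and data model

`proxnet` analyses logs from wearable ultra-wideband proximity tags handed
out to customers of a public space (the motivating case is a supermarket
running behavioural distancing interventions). Each tag assesses, once per
second, its distance in centimetres to every other tag in range; a raw-log
row is `timestamp_s, reporter_tag, opposing_tag, distance_cm`. Timestamps
are integer seconds from an arbitrary epoch; sub-second input is floored.

Physical tags are reused over the day, so tag activity must be split into
wearing sessions before records can be attributed to people. A tag's
appearances (as reporter or opposing tag) are split wherever consecutive
appearances are more than `gap_threshold_s` apart (default **120 s**: tags
sit in a charger between customers, and 120 s separates reuses while
tolerating brief dropouts; the value is configurable because no ground truth
pins it down). Each maximal run becomes a closed interval `[start_s, end_s]`
and a participant id `tag#ordinal`; visit duration is `end − start + 1` s.
A worn tag that never ranges another tag produces no records and is
invisible — an accepted limitation of presence-by-appearance.

Reciprocal reports of one pair at one second are merged by taking the
**minimum** distance. This is the conservative choice for a distancing
analysis (it can only declare people closer), and it makes the per-(pair,
second) table a function, which the rest of the pipeline assumes.

## Household groups

Members of one household may legitimately stay close, so their mutual
proximity must not count as distancing contacts. Group membership is
inferred per pair from three criteria:

1. **close**: ≥ 10 seconds at ≤ 80 cm (inclusive, reading "within 80 cm"
   at 1 Hz as per-second records);
2. **proximity**: < 150 cm for ≥ 25% of the visit duration. The reference
   duration is the **shorter** of the two visits, so a household member who
   shops briefly still qualifies; the alternative (overlap duration) is a
   configuration switch. The strict `<` matches the contact definition.
3. **co-exit**: session ends at most 60 s apart.

Pairs meeting at least 2 of 3 criteria are linked, and groups are the
**connected components** of the link graph: in a three-person household
where only adjacent pairs qualify, all three must land in one group, which
pairwise assignment alone cannot guarantee. Pairs whose sessions never
overlap are skipped. Within-group pairs are excluded from everything
downstream; contacts with outsiders are retained.

## Contacts

A contact second is a second at which a cross-group pair is **strictly
below 150 cm** (1.5 m distancing rule). Strictness matters only for
integer-centimetre values exactly at the threshold and is configurable. A
dyad's contact duration sums all qualifying seconds, contiguous or not; at
1 Hz the count is the duration in seconds. No minimum duration is imposed
by default (`min_contact_seconds = 1`); field studies sometimes drop
one-second blips, so the filter exists but is off.

Analysis windows are half-open `[t0, t1)` on integer seconds. Participants
are selected if their session intersects the window; contact durations are
recomputed from the per-second table restricted to the window, i.e.
straddling contacts are truncated rather than kept whole or dropped —
truncation keeps durations consistent with the windowed time base. Hourly
summaries (participant count, median number of unique contacts) feed a
simple linear regression of median hourly contacts on crowdedness.

## The b2 network model

Condition comparisons use the b2 model, the undirected, unweighted
reduction of the multilevel p2 family: no reciprocity, no dyadic
predictors, no network-level random effects, and one random effect per
actor (sender and receiver effects collapse). For eligible dyads (i, j):

    y_ij ~ Bernoulli(p_ij)
    logit(p_ij) = μ + Σ_k γ_k (x_ik + x_jk) + A_i + A_j
    A_i ~ N(0, σ_A²)

Two condition networks (disjoint actor sets, different days) are stacked
into one network with an actor-level condition dummy; **cross-condition
dyads are structurally excluded** from the likelihood rather than coded as
zeros, since those pairs were never co-present and treating them as
observed non-contacts would drag the density estimate down. The stacked fit
uses a single pooled likelihood with shared (μ, γ, σ_A) across blocks.

Because the dummy enters through both endpoints, a within-condition dyad's
log-odds shift is 2γ; the reported odds ratio is **exp(γ)**, the per-actor
convention. Both conventions are defensible; exp(γ) is reported because the
covariate is an actor attribute, and the draws are exposed so exp(2γ) is
one line away.

Priors are the conventional diffuse p2-family choices: N(0, 10²) on μ and
each γ_k, Inverse-Gamma(0.001, 0.001) on σ_A². All are configurable in
`B2Spec`.

### Sampler

Metropolis-within-Gibbs:

* random-walk Metropolis for μ, each γ_k, and each A_i (single-site, using
  only the actor's own dyads);
* conjugate inverse-gamma draw for σ_A² given A;
* per-block proposal scales adapted every 50 burn-in sweeps toward a
  20–50% acceptance rate and **frozen after burn-in**, so the recorded
  chain is a fixed, detailed-balance-preserving kernel.

The fixed effects are only weakly identified against linear combinations of
the actor effects: μ trades off against the mean of A, and the coefficient
of a condition dummy against the dummy-weighted mean of A. Single-site
updates walk that ridge slowly and understate posterior spread at feasible
chain lengths. Each sweep therefore ends with **translation moves** along
the likelihood-invariant directions — propose `(μ + 2d, A − d)` or
`(γ_k + d, A − d·x_k)` with `d ~ N(0, s)` — which leave every dyad's
log-odds unchanged and are accepted on the prior ratio alone. These are
exact Metropolis moves (unlike deterministic post-sweep re-centring, which
perturbs the invariant distribution) and they restore nominal interval
coverage in simulation.

Chains start from an over-dispersed jitter around the empirical density
intercept. Defaults are 4 chains × (2,000 burn-in + 10,000 draws); the
validation suite uses 2 chains × (500 + 1,500) at 60–150 actors, which the
recovery study below shows is adequate at those sizes. Degenerate inputs:
an all-edges or no-edges network warns that the intercept is weakly
identified but proceeds (the priors keep it proper); a non-finite
likelihood aborts. `fix_sigma_a=0` pins the random effects at zero, giving
plain dyadic logistic regression.

Odds ratios are summarised by the posterior mean of exp(γ_k) with a central
95% percentile interval (not HPD — the simplest reading of a "95% credible
interval"). Convergence is monitored with split R-hat and ESS (via ArviZ),
warning above R-hat 1.05. A Newton-Raphson MLE of the no-random-effects
model (`logistic_mle_oracle`) serves as an independent reference:
with σ_A pinned at 0 the posterior means of (μ, γ) agree with it to within
0.05 on simulated 60-actor networks.

### Validation by simulation

* **Parameter recovery**: 20 networks of 150 actors simulated at μ = −2.5,
  γ = −0.2, σ_A = 0.6; the posterior-mean γ has |mean bias| ≤ 0.1 and the
  95% interval covers the truth in ≥ 80% of replications (observed 18/20).
* **End-to-end sign recovery**: paired simulated conditions with the
  encounter rate reduced by a log-shift of −0.7 yield OR < 1 in ≥ 18 of 20
  seeded runs of the whole pipeline.

## Supporting statistics

Implemented from first principles (scipy supplies only distribution
functions), two-sided throughout since sidedness conventions vary:

* **Mann-Whitney U** on per-dyad contact durations. U counts pairs with
  `x_i < y_j` plus half per tie. Exact mode computes the permutation null
  of U by dynamic programming over tie groups of the pooled sample and is
  used when `n1·n2 ≤ 10,000`; the two-sided p is the null probability of
  `|U − n1n2/2| ≥ |U_obs − n1n2/2|`. Larger samples use the normal
  approximation with tie-corrected variance and continuity correction.
  Per-dyad (not per-participant) durations are compared, matching how
  duration descriptives are tabulated.
* **Welch t** for rating vectors, with Satterthwaite df; zero variance in
  both samples with equal means gives t = 0, p = 1, otherwise the infinite
  statistic is flagged.
* **Simple linear regression** of median hourly unique contacts on hourly
  participant count, with `F = (R²/(1−R²))(n−2)` on (1, n−2) df. Constant
  predictor is an error; constant response gives slope 0, R² 0, F 0.

All three hold their nominal 5% type-I rate within 3 binomial SEs over
1,000 null simulations, and the exact U mode reproduces brute-force split
enumeration for small samples.

## Synthetic data generator

No raw tag data ships with the package, so a generator produces inputs
with the statistical structure the pipeline assumes, at two levels.

`simulate_b2_network` draws dyads directly from the b2 model — the
generative counterpart of the estimator, used for recovery tests.

`simulate_tag_stream` emits a full raw log: customer parties arrive as a
Poisson process (defaults: 3 participating customers/min; party sizes
75/20/4/1% for 1–4; log-normal visits, mean 15 min, SD 7.5 min — a typical
mid-size-supermarket regime), each party draws tags from a finite pool
(reusable 300 s after return; un-equippable parties are turned away),
household pairs record sustained ~60 ± 15 cm proximity every second of
common presence and exit within 10 s of each other, and cross-party pairs
meet in brief log-normal encounters (mean 8 s) around 100 ± 25 cm at 0.02
encounters per co-present pair-minute — chosen so that an hour yields
median unique-contact counts in the mid-single digits, the order observed
in supermarket-scale deployments. Pairs also range each other at ambient
distances (uniform 200–500 cm, 0.3 sightings per pair-minute): real tags
in a busy store report neighbours well beyond contact range, and these
mid-range rows keep a participant's timeline contiguous so sessionization
does not fragment sparse visitors. Distances above a 500 cm recording
horizon are simply absent, which is what keeps real UWB logs sparse.
Condition effects are planted by shifting the log encounter rate
(`contact_logodds_shift`), giving a known-sign contact-propensity
difference.

The generator is deliberately not a pedestrian model: distance traces are
piecewise-constant per-second values with no kinematics, no store
geometry, no queueing, and no measurement error model beyond the planted
distributions. Passing tests therefore demonstrate that the pipeline's
logic is correct under the data model it assumes — not that the heuristics
(session gap, group criteria) are robust to real-world sensor noise,
which no deposited raw dataset exists to calibrate against.

All randomness flows from one `numpy` generator per simulation; a pipeline
run derives per-condition seeds from the global seed, and identical seeds
reproduce every output byte-for-byte.

## Known limitations

* Presence is inferred from records; a tag out of range of all others is
  invisible, and sparse visitors can still fragment into multiple
  participants if ambient traffic is very low.
* The 25% proximity denominator, the strict-vs-inclusive 1.5 m reading,
  and transitive group closure are declared conventions, configurable but
  not empirically identified.
* The b2 fit assumes dyad independence given actor effects; transitivity
  or spatial clustering beyond what actor effects absorb is not modelled.
* Odds ratios compare contact propensity between stacked networks observed
  on different occasions; anything confounded with occasion (crowdedness,
  customer mix) is absorbed into the condition effect, which is why
  comparisons should be windowed to matched hours.
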