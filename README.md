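# proxnet

Contact networks from wearable proximity-sensor logs, and Bayesian
comparison of behavioural interventions.

`proxnet` is for researchers who measure physical-distancing behaviour
directly: ultra-wideband tags worn by visitors of a public space (a
supermarket, a fair) record pairwise distances at 1 Hz, and the question is
whether an intervention — a reward for keeping distance, signage, changed
entry rules — reduces how many close contacts people make. The package
turns raw tag logs into contact networks and quantifies condition
differences with a dyadic network model, handling the unglamorous middle:
tags reused by many customers, households who are allowed to stay close,
and sensor streams that only exist when tags are in range.

## Pipeline

1. **Ingest** — parse raw logs (`timestamp_s, reporter_tag, opposing_tag,
   distance_cm`), split each tag's activity into wearing sessions (gap
   rule, default 120 s), assign participant ids, and merge reciprocal
   reports per (pair, second) by minimum distance.
2. **Group detection** — flag household pairs by three criteria (≥ 10 s at
   ≤ 80 cm; < 1.5 m for ≥ 25% of the shorter visit; exits ≤ 60 s apart),
   link pairs meeting ≥ 2 of 3, take connected components, and exclude
   within-group proximity from all contact counts.
3. **Contacts** — a contact second is a cross-group pair strictly below
   150 cm; durations sum qualifying seconds; time windows, per-participant
   degrees, and hourly crowdedness summaries.
4. **Comparison** — two condition networks stacked with a condition dummy
   (cross-condition dyads structurally excluded) and fitted with the b2
   model; plus Mann-Whitney U on contact durations, Welch t on rating
   vectors, and a crowdedness regression.

## The b2 model

The core inferential tool is the b2 model, the undirected, unweighted
reduction of the multilevel p2 family for social networks. For each
eligible dyad (i, j):

```
y_ij ~ Bernoulli(p_ij),   logit(p_ij) = μ + Σ_k γ_k (x_ik + x_jk) + A_i + A_j,
A_i ~ N(0, σ_A²)
```

μ is the density intercept, x_ik actor covariates (e.g. a condition
dummy), and A_i a latent per-actor contact propensity. Priors are
N(0, 10²) on μ and γ and Inverse-Gamma(0.001, 0.001) on σ_A². Estimation
is Metropolis-within-Gibbs with burn-in-adapted proposal scales and exact
translation moves along the weakly identified fixed-effect/random-effect
directions; odds ratios are reported as the posterior mean of exp(γ) with
a central 95% credible interval. See `docs/methods.md` for the full
account, including sampler validation by parameter recovery.

## Worked example

No raw tag data is publicly deposited, so the package ships a synthetic
generator with the same statistical structure (visit sessions, tag reuse,
households, background encounters). The example simulates a control hour
and a "reward" hour with a planted reduction in encounter propensity
(log-rate shift −0.7), runs the full pipeline, and compares:

```python
from proxnet.pipeline import PipelineConfig, cmd_simulate, cmd_preprocess, cmd_compare

config = PipelineConfig.from_dict({
    "seed": 42,
    "output_dir": "out",
    "conditions": {
        "control": {"simulate": {"duration_s": 3600}},
        "reward": {"simulate": {"duration_s": 3600, "contact_logodds_shift": -0.7}},
    },
    "parameters": {"b2": {"n_chains": 2, "n_burnin": 500, "n_iter": 1500}},
})
cmd_simulate(config)
report = cmd_compare(config, "control", "reward", cmd_preprocess(config))

for name in ("control", "reward"):
    d = report["descriptives"][name]
    print(f"{name}: n = {d['n_participants']['value']:.0f} participants, "
          f"median unique contacts = {d['degree']['median']:.0f}, "
          f"median contact duration = {d['duration_s']['median']:.1f} s")
print(report["b2"]["formatted"])
dt = report["duration_test"]
print(f"contact durations: U = {dt['U']:.0f}, p = {dt['p_value']:.3g}")
```

Output:

```
control: n = 199 participants, median unique contacts = 10, median contact duration = 7.0 s
reward: n = 181 participants, median unique contacts = 4, median contact duration = 7.0 s
OR = 0.66, 95% Credible Interval (CI) [0.58, 0.75]
contact durations: U = 225620, p = 0.959
```

The odds ratio below 1 with an interval excluding 1 recovers the planted
reduction in contact propensity: a participant in the reward condition has
0.66 times the odds of forming a contact with any given co-present
stranger. The planted effect thins contacts without shortening the
survivors, and the duration test correctly finds nothing (p = 0.96).

The same steps are available from the shell:

```sh
proxnet simulate -c config.yaml
proxnet preprocess -c config.yaml
proxnet compare -c config.yaml control reward
proxnet report out/report_control_vs_reward.json
```

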