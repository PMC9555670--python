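"""Synthetic data generators.

Two levels of simulation back the test pyramid:

* :func:`simulate_b2_network` draws a dyad-level binary network directly
  from the b2 generative model, for estimator checks against known
  parameters;
* :func:`simulate_tag_stream` emits a full raw 1 Hz tag log of a store
  visit stream — reused physical tags, per-customer wearing sessions,
  household groups in sustained close proximity that exit together, and
  sporadic background encounters between strangers — plus the ground truth
  needed to verify the pipeline end to end.

The stream generator mimics the statistical structure the pipeline assumes,
not physics: distance traces are piecewise-constant per-second values with
no kinematics, and tags only record pairs closer than a recording horizon
(default 500 cm), which is what keeps real ultra-wideband logs sparse.
Condition-level differences in contact propensity are planted by shifting
the log background-encounter rate (``contact_logodds_shift``), giving a
two-condition run a known-sign effect for the network model to recover.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import RAW_LOG_COLUMNS


@dataclass(frozen=True)
class B2Truth:
    """Known parameters of the b2 generative model.

    ``mu``: density intercept (log-odds); ``gamma``: actor-covariate effects
    (log-odds per actor); ``sigma_a``: SD of the actor random effects;
    ``actor_effects``: the drawn per-actor effects (filled by the
    simulator).
    """

    mu: float
    gamma: tuple[float, ...] = ()
    sigma_a: float = 0.0
    actor_effects: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        vals = [self.mu, self.sigma_a, *self.gamma]
        if not np.all(np.isfinite(vals)):
            raise ValueError("b2 parameters must be finite")
        if self.sigma_a < 0:
            raise ValueError("sigma_a must be non-negative")


def simulate_b2_network(
    truth: B2Truth,
    covariates: np.ndarray,
    n_actors: int,
    seed: int,
) -> tuple[np.ndarray, B2Truth]:
    """Draw an undirected binary network from the b2 model.

    Each unordered dyad (i, j) is an independent Bernoulli edge with
    log-odds ``mu + sum_k gamma_k (x_ik + x_jk) + A_i + A_j`` where
    ``A_i ~ Normal(0, sigma_a^2)``.  Returns the symmetric zero-diagonal
    adjacency matrix and the truth with the drawn actor effects filled in.
    """
    X = np.asarray(covariates, dtype=float).reshape(n_actors, -1)
    if X.shape[0] != n_actors:
        raise ValueError("covariates must have one row per actor")
    gamma = np.asarray(truth.gamma, dtype=float)
    if X.shape[1] != len(gamma):
        raise ValueError("covariate count does not match gamma length")
    rng = np.random.default_rng(seed)
    A = rng.normal(0.0, truth.sigma_a, size=n_actors)
    contrib = X @ gamma if len(gamma) else np.zeros(n_actors)
    eta = truth.mu + np.add.outer(contrib + A, contrib + A)
    prob = 1.0 / (1.0 + np.exp(-eta))
    upper = rng.uniform(size=(n_actors, n_actors)) < prob
    adjacency = np.triu(upper, k=1)
    adjacency = adjacency | adjacency.T
    return adjacency, B2Truth(
        mu=truth.mu, gamma=truth.gamma, sigma_a=truth.sigma_a,
        actor_effects=tuple(float(a) for a in A),
    )


@dataclass(frozen=True)
class StreamConfig:
    """Parameters of the raw tag-log simulator.

    Defaults emulate a mid-size supermarket hour as seen through a voluntary
    tag scheme: roughly three participating customers arriving per minute,
    visits averaging 15 minutes, mostly solo shoppers with some pairs,
    brief (~8 s) background encounters around one metre, and household
    members staying around 60 cm apart and leaving within seconds of each
    other.
    """

    duration_s: int = 3600
    arrival_rate: float = 3.0            # participating customers per minute
    visit_mean_s: float = 900.0          # log-normal visit duration, natural-scale mean
    visit_sd_s: float = 450.0
    group_size_probs: tuple[float, ...] = (0.75, 0.20, 0.04, 0.01)
    group_proximity_cm: float = 60.0     # typical within-household distance
    group_proximity_sd_cm: float = 15.0
    coexit_lag_s: int = 10               # household members exit within this lag
    encounter_rate: float = 0.02         # background encounters per co-present pair per minute
    encounter_mean_s: float = 8.0        # log-normal encounter duration
    encounter_sd_s: float = 5.0
    encounter_dist_mean_cm: float = 100.0
    encounter_dist_sd_cm: float = 25.0
    ambient_rate: float = 0.3            # mid-range sightings per co-present pair per minute
    ambient_dist_min_cm: float = 200.0   # ambient distances uniform up to the horizon
    n_tags: int = 150
    recharge_gap_s: int = 300            # minimum idle gap between reuses of one tag
    record_horizon_cm: int = 500         # pairs farther apart produce no record
    report_both_sides: bool = True       # both tags of a pair report each second
    condition_label: str = "baseline"
    contact_logodds_shift: float = 0.0   # planted condition effect on encounter rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.arrival_rate < 0:
            raise ValueError("arrival_rate must be non-negative")
        positive = [self.visit_mean_s, self.visit_sd_s, self.encounter_mean_s,
                    self.encounter_sd_s, self.encounter_dist_mean_cm,
                    self.group_proximity_cm, self.coexit_lag_s,
                    self.recharge_gap_s, self.record_horizon_cm, self.n_tags]
        if min(positive) <= 0:
            raise ValueError("durations, distances and rates must be strictly positive")
        if self.encounter_rate < 0 or self.ambient_rate < 0:
            raise ValueError("encounter and ambient rates must be non-negative")
        if not (0 < self.ambient_dist_min_cm <= self.record_horizon_cm):
            raise ValueError("ambient_dist_min_cm must lie within the recording horizon")
        if abs(sum(self.group_size_probs) - 1.0) > 1e-9 or min(self.group_size_probs) < 0:
            raise ValueError("group_size_probs must be a probability vector")


@dataclass
class GroundTruth:
    """What the simulator planted, for pipeline verification.

    ``sessions``: (participant id, tag id, start s, end s) wearing intervals;
    ``group_map``: participant id -> group id; ``true_contacts``: for every
    cross-group pair that ever produced a record, the per-second distance
    trace as (second, distance_cm) pairs.
    """

    sessions: list[tuple[str, str, int, int]] = field(default_factory=list)
    group_map: dict[str, str] = field(default_factory=dict)
    true_contacts: dict[tuple[str, str], list[tuple[int, int]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sessions": self.sessions,
            "group_map": self.group_map,
            "true_contacts": {f"{a}|{b}": trace for (a, b), trace in
                              sorted(self.true_contacts.items())},
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            sessions=[tuple(s) for s in payload["sessions"]],
            group_map=payload["group_map"],
            true_contacts={
                tuple(key.split("|")): [tuple(t) for t in trace]
                for key, trace in payload["true_contacts"].items()
            },
        )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a log-normal with the given natural-scale
    mean and SD."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_tag_stream(config: StreamConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a raw 1 Hz tag log plus its ground truth.

    Customer parties arrive as a Poisson process (rate scaled so that
    *customers* arrive at ``arrival_rate`` per minute), draw a party size
    and a shared log-normal visit duration, and receive physical tags from a
    finite pool (a tag becomes reusable ``recharge_gap_s`` after it is
    returned; parties that cannot be fully equipped are turned away and do
    not appear).  Household pairs produce a close-proximity record every
    second of their common presence and exit within ``coexit_lag_s`` of each
    other; cross-party pairs meet in brief encounters arriving at
    ``encounter_rate * exp(contact_logodds_shift)`` per minute of
    co-presence, and additionally range each other at ambient (beyond
    contact) distances at ``ambient_rate`` per minute, which keeps each
    participant's record timeline contiguous.  Distances above
    ``record_horizon_cm`` are never recorded.  Output is deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    horizon = config.record_horizon_cm

    # --- arrivals: parties of customers -------------------------------------
    sizes = np.arange(1, len(config.group_size_probs) + 1)
    mean_size = float(sizes @ np.array(config.group_size_probs))
    party_rate_per_s = config.arrival_rate / mean_size / 60.0
    arrivals: list[float] = []
    t = 0.0
    while config.arrival_rate > 0:
        t += rng.exponential(1.0 / party_rate_per_s) if party_rate_per_s > 0 else np.inf
        if t >= config.duration_s:
            break
        arrivals.append(t)

    v_mu, v_sigma = _lognormal_params(config.visit_mean_s, config.visit_sd_s)
    tag_free_at = np.zeros(config.n_tags)  # earliest second each tag is reusable
    truth = GroundTruth()
    participants: list[tuple[str, int, int, int]] = []  # pid, group idx, start, end
    n_turned_away = 0
    pid_counter = 0

    for g_idx, arr in enumerate(arrivals):
        size = int(rng.choice(sizes, p=config.group_size_probs))
        start = int(arr)
        visit = max(30.0, rng.lognormal(v_mu, v_sigma))
        base_exit = start + int(visit)
        exits = base_exit + rng.integers(0, config.coexit_lag_s + 1, size=size)
        free = np.flatnonzero(tag_free_at <= arr)
        if len(free) < size:
            n_turned_away += size
            continue
        gid = f"TG{g_idx:05d}"
        for m in range(size):
            tag = int(free[m])
            end = int(exits[m])
            tag_free_at[tag] = end + config.recharge_gap_s
            pid_counter += 1
            pid = f"P{pid_counter:05d}"
            truth.sessions.append((pid, f"T{tag:03d}", start, end))
            truth.group_map[pid] = gid
            participants.append((pid, g_idx, start, end))

    # --- per-pair distance traces -------------------------------------------
    # traces[(pid_a, pid_b)] = {second: distance_cm}, pid_a < pid_b
    traces: dict[tuple[str, str], dict[int, int]] = {}

    def add_trace(pa: str, pb: str, seconds: np.ndarray, dists: np.ndarray) -> None:
        key = (pa, pb) if pa < pb else (pb, pa)
        store = traces.setdefault(key, {})
        for s, d in zip(seconds.tolist(), dists.tolist()):
            d = int(round(d))
            if d > horizon:
                continue
            d = max(d, 1)
            if s in store:
                store[s] = min(store[s], d)
            else:
                store[s] = d

    e_mu, e_sigma = _lognormal_params(config.encounter_mean_s, config.encounter_sd_s)
    rate_eff = config.encounter_rate * np.exp(config.contact_logodds_shift) / 60.0

    by_group: dict[int, list[tuple[str, int, int]]] = {}
    for pid, g_idx, s, e in participants:
        by_group.setdefault(g_idx, []).append((pid, s, e))

    # within-household traces: sustained close proximity over the common stay
    for members in by_group.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                pa, sa, ea = members[a]
                pb, sb, eb = members[b]
                lo, hi = max(sa, sb), min(ea, eb)
                if hi < lo:
                    continue
                secs = np.arange(lo, hi + 1)
                dists = rng.normal(config.group_proximity_cm,
                                   config.group_proximity_sd_cm, size=len(secs))
                np.clip(dists, 1, horizon, out=dists)
                add_trace(pa, pb, secs, dists)

    # background encounters between members of different parties
    ordered = sorted(participants, key=lambda p: (p[2], p[0]))
    for i in range(len(ordered)):
        pa, ga, sa, ea = ordered[i]
        for j in range(i + 1, len(ordered)):
            pb, gb, sb, eb = ordered[j]
            if sb > ea:
                break
            if ga == gb:
                continue
            lo, hi = max(sa, sb), min(ea, eb)
            overlap = hi - lo + 1
            if overlap <= 0:
                continue
            # ambient mid-range sightings keep a participant's timeline
            # contiguous, as a tag in a busy store keeps ranging neighbours
            # well beyond contact distance
            n_amb = rng.poisson(config.ambient_rate / 60.0 * overlap)
            if n_amb:
                secs = rng.integers(lo, hi + 1, size=n_amb)
                dists = rng.uniform(config.ambient_dist_min_cm, horizon, size=n_amb)
                add_trace(pa, pb, secs, dists)
            n_enc = rng.poisson(rate_eff * overlap)
            for _ in range(n_enc):
                e_start = int(rng.integers(lo, hi + 1))
                e_len = max(1, int(round(rng.lognormal(e_mu, e_sigma))))
                e_end = min(hi, e_start + e_len - 1)
                secs = np.arange(e_start, e_end + 1)
                dists = rng.normal(config.encounter_dist_mean_cm,
                                   config.encounter_dist_sd_cm, size=len(secs))
                np.clip(dists, 1, horizon, out=dists)
                key = (pa, pb) if pa < pb else (pb, pa)
                add_trace(pa, pb, secs, dists)
                truth.true_contacts.setdefault(key, [])

    # record cross-group traces in the ground truth
    same_group = {tuple(sorted((a, b))) for members in by_group.values()
                  for x, (a, *_r1) in enumerate(members)
                  for (b, *_r2) in members[x + 1:]}
    for key, store in traces.items():
        if key in same_group:
            continue
        truth.true_contacts[key] = sorted((int(s), int(d)) for s, d in store.items())
    truth.true_contacts = {k: v for k, v in truth.true_contacts.items() if v}

    # --- emit records --------------------------------------------------------
    pid_tag = {pid: tag for pid, tag, *_ in truth.sessions}
    rows_t: list[int] = []
    rows_rep: list[str] = []
    rows_opp: list[str] = []
    rows_d: list[int] = []
    for (pa, pb), store in sorted(traces.items()):
        ta, tb = pid_tag[pa], pid_tag[pb]
        for s, d in sorted(store.items()):
            rows_t.append(s)
            rows_rep.append(ta)
            rows_opp.append(tb)
            rows_d.append(d)
            if config.report_both_sides:
                rows_t.append(s)
                rows_rep.append(tb)
                rows_opp.append(ta)
                rows_d.append(d)
    records = pd.DataFrame(
        {
            "timestamp_s": pd.Series(rows_t, dtype=np.int64),
            "reporter_tag": pd.Series(rows_rep, dtype=str),
            "opposing_tag": pd.Series(rows_opp, dtype=str),
            "distance_cm": pd.Series(rows_d, dtype=np.int64),
        }
    )
    records.sort_values(
        ["timestamp_s", "reporter_tag", "opposing_tag"], kind="stable",
        inplace=True, ignore_index=True,
    )
    if n_turned_away:
        logging.getLogger(__name__).info(
            "simulate_tag_stream: %d customers turned away (tag pool exhausted)",
            n_turned_away,
        )
    return records, truth


def match_participants(truth: GroundTruth, sessions) -> dict[str, str]:
    """Map pipeline participant ids to simulator participant ids.

    A recovered session (from :func:`proxnet.ingest.sessionize`) is matched
    to the unique planted wearing of the same tag whose interval contains
    it.  Raises :class:`ValueError` on an ambiguous or missing match.
    Several recovered sessions may map to one planted participant when a
    sparse timeline was split by the session gap rule.
    """
    by_tag: dict[str, list[tuple[str, int, int]]] = {}
    for pid, tag, start, end in truth.sessions:
        by_tag.setdefault(tag, []).append((pid, start, end))
    mapping: dict[str, str] = {}
    for s in sessions:
        hits = [pid for pid, start, end in by_tag.get(s.tag_id, [])
                if start <= s.start_s and s.end_s <= end]
        if len(hits) != 1:
            raise ValueError(
                f"session {s.participant_id} [{s.start_s}, {s.end_s}] matches "
                f"{len(hits)} planted wearings of tag {s.tag_id}"
            )
        mapping[s.participant_id] = hits[0]
    return mapping


def write_raw_log(records: pd.DataFrame, path: str | Path) -> None:
    """Write a records table as a raw-log CSV (header
    ``timestamp_s,reporter_tag,opposing_tag,distance_cm``); round-trips
    losslessly through :func:`proxnet.ingest.parse_raw_log`."""
    out = records[RAW_LOG_COLUMNS] if len(records) else pd.DataFrame(columns=RAW_LOG_COLUMNS)
    out.to_csv(path, index=False)
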