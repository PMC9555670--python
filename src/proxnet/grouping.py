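"""Household / shopping-group detection.

Customers who enter a store together (a household) are allowed to stay close
to each other, so their mutual proximity must not be counted as distancing
contacts.  Group membership is not registered at the door; it is inferred
from the proximity traces via three pairwise criteria:

1. *close*: at least ``min_close_seconds`` one-second assessments at a
   distance of at most ``close_dist_cm`` (default: 10 s within 80 cm);
2. *proximity*: within ``prox_dist_cm`` (default 150 cm, strict ``<``) for
   at least ``min_prox_fraction`` (default 25%) of the visit duration, read
   against the shorter of the two visits;
3. *co-exit*: the two participants' sessions end at most
   ``max_coexit_lag_s`` (default 60 s) apart.

A pair meeting at least ``min_criteria`` (default 2) of the three is linked;
groups are the connected components of the resulting graph, so a household
whose members qualify only pairwise in a chain still forms one group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .ingest import VisitSession


@dataclass(frozen=True)
class GroupParams:
    close_dist_cm: int = 80
    min_close_seconds: int = 10
    prox_dist_cm: int = 150
    min_prox_fraction: float = 0.25
    max_coexit_lag_s: int = 60
    min_criteria: int = 2

    def __post_init__(self) -> None:
        if min(self.close_dist_cm, self.min_close_seconds, self.prox_dist_cm,
               self.max_coexit_lag_s) <= 0:
            raise ValueError("all group-criteria thresholds must be positive")
        if not (0 < self.min_prox_fraction <= 1):
            raise ValueError("min_prox_fraction must lie in (0, 1]")
        if self.min_criteria not in (1, 2, 3):
            raise ValueError("min_criteria must be 1, 2 or 3")


@dataclass(frozen=True)
class PairCriteria:
    """Evaluation of the three group criteria for one unordered pair."""

    pair: tuple[str, str]
    c_close: bool
    c_prox: bool
    c_coexit: bool
    n_met: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_met", int(self.c_close) + int(self.c_prox) + int(self.c_coexit))


def evaluate_pair_criteria(
    pair: tuple[str, str],
    distances_cm: np.ndarray,
    sessions: dict[str, VisitSession],
    params: GroupParams = GroupParams(),
) -> PairCriteria:
    """Evaluate the three group criteria for one pair.

    ``distances_cm`` is the pair's per-second distance trace from
    :func:`proxnet.ingest.symmetrize` (one value per second with a record;
    seconds without a record do not count toward any criterion).  The 25%
    proximity criterion is referenced against the *shorter* of the two visit
    durations, so a brief-visit household member can still qualify.
    """
    d = np.asarray(distances_cm)
    s_a, s_b = sessions[pair[0]], sessions[pair[1]]
    c_close = int(np.count_nonzero(d <= params.close_dist_cm)) >= params.min_close_seconds
    reference = min(s_a.duration_s, s_b.duration_s)
    prox_seconds = int(np.count_nonzero(d < params.prox_dist_cm))
    c_prox = prox_seconds >= params.min_prox_fraction * reference
    c_coexit = abs(s_a.end_s - s_b.end_s) <= params.max_coexit_lag_s
    return PairCriteria(pair=pair, c_close=c_close, c_prox=c_prox, c_coexit=c_coexit)


def evaluate_all_pairs(
    pair_seconds: pd.DataFrame,
    sessions: list[VisitSession],
    params: GroupParams = GroupParams(),
) -> pd.DataFrame:
    """Criteria audit table for every co-present pair.

    Pairs whose sessions do not overlap in time are skipped (they cannot be
    a shopping group).  Pairs with overlapping sessions but no proximity
    records are evaluated with an empty distance trace, so only the co-exit
    criterion can hold for them.

    Returns columns ``participant_a, participant_b, c_close, c_prox,
    c_coexit, n_met``.
    """
    by_id = {s.participant_id: s for s in sessions}
    traced = {
        (a, b): sub["distance_cm"].to_numpy()
        for (a, b), sub in pair_seconds.groupby(["participant_a", "participant_b"], sort=True)
    }
    # co-present pairs: session intervals intersect
    ordered = sorted(sessions, key=lambda s: (s.start_s, s.participant_id))
    pairs: set[tuple[str, str]] = set(traced)
    for i, s1 in enumerate(ordered):
        for s2 in ordered[i + 1 :]:
            if s2.start_s > s1.end_s:
                break
            pairs.add(tuple(sorted((s1.participant_id, s2.participant_id))))
    rows = []
    for a, b in sorted(pairs):
        crit = evaluate_pair_criteria(
            (a, b), traced.get((a, b), np.empty(0, dtype=np.int64)), by_id, params
        )
        rows.append((a, b, crit.c_close, crit.c_prox, crit.c_coexit, crit.n_met))
    return pd.DataFrame(
        rows, columns=["participant_a", "participant_b", "c_close", "c_prox", "c_coexit", "n_met"]
    )


def assign_groups(
    criteria: pd.DataFrame,
    participants: list[str],
    min_criteria: int = 2,
) -> dict[str, str]:
    """Partition participants into groups.

    An edge is drawn between every pair meeting at least ``min_criteria``
    criteria; groups are the connected components (transitive closure), so
    the assignment is a partition.  Participants in no qualifying pair form
    singleton groups.  Group ids are ``G0001, G0002, ...`` assigned in order
    of each group's lexicographically smallest member, which makes the
    mapping deterministic.
    """
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(participants)
    qualifying = criteria[criteria["n_met"] >= min_criteria]
    graph.add_edges_from(zip(qualifying["participant_a"], qualifying["participant_b"]))
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    group_map: dict[str, str] = {}
    for k, comp in enumerate(components, start=1):
        gid = f"G{k:04d}"
        for pid in comp:
            group_map[pid] = gid
    return group_map


def groups_to_frame(group_map: dict[str, str]) -> pd.DataFrame:
    items = sorted(group_map.items())
    return pd.DataFrame(items, columns=["participant_id", "group_id"])
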