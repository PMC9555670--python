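"""Undirected binary contact networks with actor covariates.

The network view of the data is deliberately coarse: an edge records that
two participants came within the distancing threshold at least once
(undirected, unweighted); contact durations are kept alongside as optional
edge weights for descriptive use only.  Two condition networks (different
days, disjoint participants) are stacked into one comparison network in
which cross-condition dyads are *structurally excluded* — those pairs were
never co-present, and treating them as observed non-contacts would bias the
density estimate downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ContactNetwork:
    """Undirected binary network over participants.

    ``adjacency`` and ``dyad_mask`` are symmetric with zero diagonal;
    ``dyad_mask`` marks eligible dyads (pairs that could have been in
    contact), and every edge must be eligible.  ``covariates`` is an
    actor-by-k DataFrame aligned with ``actors``; ``weights`` holds contact
    durations in seconds where edges exist.
    """

    actors: list[str]
    adjacency: np.ndarray
    covariates: pd.DataFrame
    weights: np.ndarray | None = None
    dyad_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.actors)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match actor count")
        if self.dyad_mask is None:
            self.dyad_mask = ~np.eye(n, dtype=bool)
        self.dyad_mask = np.asarray(self.dyad_mask, dtype=bool)
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if not np.array_equal(self.dyad_mask, self.dyad_mask.T):
            raise ValueError("dyad_mask must be symmetric")
        if np.any(np.diag(self.adjacency)) or np.any(np.diag(self.dyad_mask)):
            raise ValueError("diagonal must be zero")
        if np.any(self.adjacency & ~self.dyad_mask):
            raise ValueError("edges on ineligible dyads")
        if list(self.covariates.index) != list(self.actors):
            raise ValueError("covariates index must equal the actor list")

    @property
    def n_actors(self) -> int:
        return len(self.actors)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def n_eligible_dyads(self) -> int:
        return int(self.dyad_mask.sum()) // 2

    def density(self) -> float:
        """Edge count over eligible dyad count."""
        return self.n_edges / self.n_eligible_dyads


def build_network(
    participants: list[str],
    contacts: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> ContactNetwork:
    """Build a contact network: one node per participant, an edge wherever a
    dyadic contact exists, duration as edge weight.  All off-diagonal dyads
    are eligible.  Contacts naming a participant outside ``participants``
    raise :class:`ValueError`.
    """
    n = len(participants)
    index = {p: i for i, p in enumerate(participants)}
    if len(index) != n:
        raise ValueError("duplicate participant ids")
    adjacency = np.zeros((n, n), dtype=bool)
    weights = np.zeros((n, n), dtype=float)
    for a, b, dur in zip(
        contacts["participant_a"], contacts["participant_b"], contacts["contact_seconds"]
    ):
        if a not in index or b not in index:
            raise ValueError(f"contact references unknown participant: {a!r}-{b!r}")
        i, j = index[a], index[b]
        adjacency[i, j] = adjacency[j, i] = True
        weights[i, j] = weights[j, i] = float(dur)
    if covariates is None:
        covariates = pd.DataFrame(index=pd.Index(participants, name="participant_id"))
    else:
        covariates = covariates.loc[participants]
    return ContactNetwork(
        actors=list(participants), adjacency=adjacency, covariates=covariates, weights=weights
    )


def combine_networks(
    net_a: ContactNetwork, net_b: ContactNetwork, dummy_name: str = "condition"
) -> ContactNetwork:
    """Stack two condition networks into one comparison network.

    Actors are ``net_a``'s then ``net_b``'s, each in input order.  The new
    actor covariate ``dummy_name`` is 0 for ``net_a`` actors and 1 for
    ``net_b`` actors; original covariates are carried over (missing ones
    filled with 0).  Cross-network dyads are ineligible in ``dyad_mask``.
    Actor id collisions raise :class:`ValueError`.
    """
    overlap = set(net_a.actors) & set(net_b.actors)
    if overlap:
        raise ValueError(f"actor id collision between networks: {sorted(overlap)[:5]}")
    na, nb = net_a.n_actors, net_b.n_actors
    n = na + nb
    adjacency = np.zeros((n, n), dtype=bool)
    adjacency[:na, :na] = net_a.adjacency
    adjacency[na:, na:] = net_b.adjacency
    weights = np.zeros((n, n), dtype=float)
    if net_a.weights is not None:
        weights[:na, :na] = net_a.weights
    if net_b.weights is not None:
        weights[na:, na:] = net_b.weights
    mask = np.zeros((n, n), dtype=bool)
    mask[:na, :na] = net_a.dyad_mask
    mask[na:, na:] = net_b.dyad_mask
    cov = pd.concat([net_a.covariates, net_b.covariates], axis=0).fillna(0.0)
    if dummy_name in cov.columns:
        raise ValueError(f"covariate {dummy_name!r} already present")
    cov[dummy_name] = [0.0] * na + [1.0] * nb
    cov.index = pd.Index(net_a.actors + net_b.actors, name="participant_id")
    return ContactNetwork(
        actors=net_a.actors + net_b.actors,
        adjacency=adjacency,
        covariates=cov,
        weights=weights,
        dyad_mask=mask,
    )


def write_edge_list(network: ContactNetwork, edge_path: str | Path, node_path: str | Path) -> None:
    """Write the network as an edge CSV (``actor_a,actor_b,weight``) and a
    node CSV (``participant_id`` plus covariate columns)."""
    ii, jj = np.nonzero(np.triu(network.adjacency, k=1))
    w = network.weights if network.weights is not None else np.zeros_like(network.adjacency, float)
    edges = pd.DataFrame(
        {
            "actor_a": [network.actors[i] for i in ii],
            "actor_b": [network.actors[j] for j in jj],
            "weight": [int(w[i, j]) for i, j in zip(ii, jj)],
        }
    )
    edges.to_csv(edge_path, index=False)
    nodes = network.covariates.reset_index()
    nodes.rename(columns={nodes.columns[0]: "participant_id"}, inplace=True)
    nodes.to_csv(node_path, index=False)


def read_edge_list(edge_path: str | Path, node_path: str | Path) -> ContactNetwork:
    """Inverse of :func:`write_edge_list`; a dangling actor reference in the
    edge file raises :class:`ValueError`."""
    edges = pd.read_csv(edge_path)
    nodes = pd.read_csv(node_path)
    actors = [str(a) for a in nodes["participant_id"]]
    covariates = nodes.set_index("participant_id")
    covariates.index = pd.Index(actors, name="participant_id")
    known = set(actors)
    for col in ("actor_a", "actor_b"):
        missing = set(map(str, edges[col])) - known
        if missing:
            raise ValueError(f"edge file references unknown actors: {sorted(missing)[:5]}")
    contacts = pd.DataFrame(
        {
            "participant_a": edges["actor_a"].astype(str),
            "participant_b": edges["actor_b"].astype(str),
            "contact_seconds": edges["weight"],
        }
    )
    return build_network(actors, contacts, covariates)
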