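"""Summary plots: hourly crowdedness vs contacts, contact-network view, and
MCMC traces."""

from __future__ import annotations

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .b2 import B2Results
from .network import ContactNetwork
from .stats import simple_linreg


def plot_crowdedness(hourly: pd.DataFrame, ax=None):
    """Scatter of median unique contacts against hourly participant count,
    with the least-squares line when it is defined."""
    if ax is None:
        _, ax = plt.subplots()
    data = hourly.dropna()
    ax.scatter(data["n_participants"], data["median_degree"], color="tab:blue")
    if len(data) >= 3 and data["n_participants"].nunique() > 1:
        reg = simple_linreg(data["n_participants"], data["median_degree"])
        xs = np.linspace(data["n_participants"].min(), data["n_participants"].max(), 50)
        ax.plot(xs, reg.intercept + reg.slope * xs, color="tab:red",
                label=f"$R^2$ = {reg.r_squared:.2f}")
        ax.legend()
    ax.set_xlabel("participants per hour")
    ax.set_ylabel("median unique contacts")
    return ax


def plot_network(network: ContactNetwork, ax=None, seed: int = 0):
    """Spring-layout view of the contact network, edge width by duration."""
    if ax is None:
        _, ax = plt.subplots()
    g = nx.Graph()
    g.add_nodes_from(network.actors)
    ii, jj = np.nonzero(np.triu(network.adjacency, k=1))
    w = network.weights if network.weights is not None else np.ones_like(network.adjacency)
    for i, j in zip(ii, jj):
        g.add_edge(network.actors[i], network.actors[j], weight=float(w[i, j]))
    pos = nx.spring_layout(g, seed=seed)
    widths = [0.5 + np.log1p(d["weight"]) for _, _, d in g.edges(data=True)]
    nx.draw_networkx_nodes(g, pos, ax=ax, node_size=30, node_color="tab:blue")
    nx.draw_networkx_edges(g, pos, ax=ax, width=widths, alpha=0.5)
    ax.set_axis_off()
    return ax


def plot_trace(results: B2Results, parameter: str = "mu", ax=None):
    """Per-chain trace of a scalar parameter (``mu``, ``sigma_a`` or a
    covariate name)."""
    if ax is None:
        _, ax = plt.subplots()
    if parameter == "mu":
        draws = results.mu
    elif parameter == "sigma_a":
        draws = results.sigma_a
    else:
        draws = results._gamma_draws(parameter)
    for c in range(draws.shape[0]):
        ax.plot(draws[c], lw=0.6, label=f"chain {c}")
    ax.set_xlabel("iteration")
    ax.set_ylabel(parameter)
    ax.legend(fontsize="small")
    return ax
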