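"""Sensorimotor graphs: directed dependency graphs and their sink nodes.

Nodes are SIP-derived signal channels; edges are pairwise dependencies.  For
an asymmetric measure matrix (AT, GC, TE) an edge i -> j is kept when the
net weight w_ij - w_ji exceeds a threshold, yielding a directed graph whose
sinks — nodes that only receive — are the signature of passive (inanimate)
entities: a thing that cannot accelerate by itself never transfers
acceleration outward.  For a symmetric correlation matrix, thresholding
|rho| gives an undirected graph whose connected components realize
"what moves together clusters together" (self vs. other).
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .correlation import CorrelationMatrix

AUTONOMOUS = "autonomous"
PASSIVE = "passive"
UNRESOLVED = "unresolved"


def _labels_values(m) -> tuple[list, np.ndarray]:
    if isinstance(m, dict):
        return list(m["labels"]), np.asarray(m["values"], dtype=float)
    return list(m.labels), np.asarray(m.values, dtype=float)


def build_directed_graph(m, theta_frac: float = 0.1) -> nx.DiGraph:
    """Threshold an asymmetric measure matrix into a directed SM graph.

    Edge i -> j is kept iff the net weight w_ij - w_ji > theta, with
    theta = theta_frac * max|entry|; the edge weight is the net value.
    An all-zero matrix yields an edgeless graph.
    """
    labels, values = _labels_values(m)
    if values.shape[0] != values.shape[1]:
        raise ValueError("measure matrix must be square")
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    scale = float(np.max(np.abs(values)))
    theta = theta_frac * scale
    g.graph["threshold_rule"] = {"kind": "net_fraction_of_max", "theta_frac": theta_frac, "theta": theta}
    if scale == 0.0:
        return g
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            net = values[i, j] - values[j, i]
            if net > theta:
                g.add_edge(labels[i], labels[j], weight=float(net))
    return g


def find_sinks(g: nx.DiGraph) -> dict:
    """Label every node autonomous / passive / unresolved.

    passive <=> sink: no outgoing kept edge and at least one incoming.
    Isolated nodes are unresolved (the measure saw nothing).
    """
    labels = {}
    for node in g.nodes:
        out_deg = g.out_degree(node)
        in_deg = g.in_degree(node)
        if out_deg == 0 and in_deg >= 1:
            labels[node] = PASSIVE
        elif out_deg == 0 and in_deg == 0:
            labels[node] = UNRESOLVED
        else:
            labels[node] = AUTONOMOUS
    return labels


def cluster_entities(c: CorrelationMatrix, corr_threshold: float = 0.3) -> list:
    """Partition channels by connected components of the |rho| >= t graph.

    Undefined (NaN) correlations contribute no edge.  Returns a list of
    frozensets of channel labels, sorted by their smallest member.
    """
    rho = np.asarray(c.rho, dtype=float)
    if rho.shape[0] != rho.shape[1]:
        raise ValueError("need a square correlation matrix")
    labels = list(c.labels_cols)
    g = nx.Graph()
    g.add_nodes_from(labels)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            r = rho[i, j]
            if np.isfinite(r) and abs(r) >= corr_threshold:
                g.add_edge(labels[i], labels[j])
    comps = [frozenset(comp) for comp in nx.connected_components(g)]
    return sorted(comps, key=lambda s: sorted(s)[0])


def surrogate_edge_threshold(
    per_episode_values: np.ndarray, rng: np.random.Generator, n_shuffles: int = 200, q: float = 0.95
) -> float:
    """Optional significance threshold from episode-sign shuffles.

    Given per-episode net contributions for one ordered pair, the surrogate
    distribution flips each episode's direction at random; the q-quantile of
    the |shuffled sum| is a significance bar for the observed |sum|.
    """
    vals = np.asarray(per_episode_values, dtype=float)
    sums = np.empty(n_shuffles)
    for s in range(n_shuffles):
        signs = rng.choice([-1.0, 1.0], size=len(vals))
        sums[s] = abs(float((signs * vals).sum()))
    return float(np.quantile(sums, q))
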