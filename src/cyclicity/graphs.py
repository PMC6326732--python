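"""Leader-follower graphs over selected channel pairs.

For each selected pair the group "votes": a subject's vote is the sign of
its mean normalized lead-matrix entry across runs, so each subject counts
once.  The majority direction becomes a directed edge whose weight is the
vote proportion — a consistency measure — and whose strength is the group
mean of the normalized entries.  Nodes are layered so that activity flows
downward: a node's layer is one more than its deepest predecessor within
the retained edge set (cycles are broken first by discarding the
weakest-weight edge on each cycle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import DataError, LeadMatrix
from .features import CohortFeatures

__all__ = [
    "LeaderFollowerGraph",
    "normalize_lead",
    "sign_matrix",
    "consistency_graph",
    "assign_layers",
    "flipped_edges",
]

log = logging.getLogger(__name__)


def normalize_lead(lm: LeadMatrix, mode: str = "max") -> LeadMatrix:
    """Scale a lead matrix into [-1, 1] to make subjects comparable.

    ``max`` divides by the largest absolute entry (default); ``frobenius``
    divides by the Frobenius norm.
    """
    scale = np.abs(lm.values).max() if mode == "max" else np.linalg.norm(lm.values)
    if scale == 0:
        raise DataError("cannot normalize a zero lead matrix")
    return LeadMatrix(lm.values / scale, list(lm.channel_labels))


def sign_matrix(lm: LeadMatrix) -> LeadMatrix:
    """±1 direction matrix; exact zeros stay zero (and are logged)."""
    s = np.sign(lm.values)
    n_zero = int(np.sum(s[np.triu_indices_from(s, k=1)] == 0))
    if n_zero:
        log.info("sign_matrix: %d pair(s) have exactly zero lead value", n_zero)
    return LeadMatrix(s, list(lm.channel_labels))


@dataclass
class LeaderFollowerGraph:
    """Directed consistency graph over selected channel pairs."""

    graph: nx.DiGraph
    pairs: list[tuple[str, str]]
    layers: dict[str, int] = field(default_factory=dict)

    def edge_table(self) -> list[dict]:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "weight": d["weight"],
                    "strength": d["strength"],
                    "layer_source": self.layers.get(u),
                    "layer_target": self.layers.get(v),
                }
            )
        return rows


def _normalized_feature_table(features: CohortFeatures, pairs) -> tuple[np.ndarray, list[int]]:
    """Rows renormalized by each run's max |entry|; columns = selected pairs."""
    scale = np.abs(features.X).max(axis=1, keepdims=True)
    if np.any(scale == 0):
        raise DataError("a run has an all-zero lead matrix")
    cols = []
    for p in pairs:
        if p not in features.pair_index:
            raise KeyError(f"pair {p} not present in feature table")
        cols.append(features.pair_index.index(p))
    return features.X / scale, cols


def consistency_graph(
    features: CohortFeatures, pairs: list[tuple[str, str]]
) -> LeaderFollowerGraph:
    """Majority-direction graph for one group's runs.

    Edge ``u -> v`` means u leads v (positive normalized entry for pair
    (u, v)) for the majority of subjects; weight is that majority's
    proportion of the voting subjects; strength is the group-mean
    normalized entry.  Subjects whose mean entry is exactly zero abstain
    (logged, counted to neither direction).
    """
    xn, cols = _normalized_feature_table(features, pairs)
    subjects = features.subjects
    g = nx.DiGraph()
    for p in pairs:
        g.add_node(p[0])
        g.add_node(p[1])
    for p, c in zip(pairs, cols):
        votes = []
        for s in subjects:
            mask = (features.meta["subject"] == s).to_numpy()
            v = float(np.sign(xn[mask, c].mean()))
            if v == 0:
                log.info("subject %s abstains on pair %s (zero mean entry)", s, p)
                continue
            votes.append(v)
        if not votes:
            raise DataError(f"no votes for pair {p}")
        votes_arr = np.array(votes)
        n_pos = int((votes_arr > 0).sum())
        strength = float(xn[:, c].mean())
        if n_pos * 2 >= len(votes):  # ties resolved toward the positive direction
            u, v, w = p[0], p[1], n_pos / len(votes)
        else:
            u, v, w = p[1], p[0], 1 - n_pos / len(votes)
        g.add_edge(u, v, weight=w, strength=strength)
    lfg = LeaderFollowerGraph(g, list(pairs))
    lfg.layers = assign_layers(lfg)
    return lfg


def assign_layers(graph: LeaderFollowerGraph | nx.DiGraph) -> dict[str, int]:
    """Longest-path layering after cycle-breaking.

    Sources sit at layer 0; every other node at 1 + the max layer of its
    predecessors in the retained edge set.  Cycles are broken by repeatedly
    removing the lowest-weight edge on a cycle (deterministic: ties by edge
    order), with a log line per removal.
    """
    g = graph.graph.copy() if isinstance(graph, LeaderFollowerGraph) else graph.copy()
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: g.edges[e[0], e[1]].get("weight", 1.0))
        log.info("breaking cycle by dropping edge %s -> %s", weakest[0], weakest[1])
        g.remove_edge(weakest[0], weakest[1])
    layers: dict[str, int] = {}
    for node in nx.topological_sort(g):
        preds = list(g.predecessors(node))
        layers[node] = 0 if not preds else 1 + max(layers[p] for p in preds)
    return layers


def flipped_edges(
    graph_a: LeaderFollowerGraph, graph_b: LeaderFollowerGraph
) -> list[tuple[str, str]]:
    """Pairs whose majority direction differs between the two groups."""
    if set(map(frozenset, graph_a.pairs)) != set(map(frozenset, graph_b.pairs)):
        raise DataError("graphs must be built over the same pair set")
    flips = []
    for p in graph_a.pairs:
        a_dir = graph_a.graph.has_edge(p[0], p[1])
        b_dir = graph_b.graph.has_edge(p[0], p[1])
        if a_dir != b_dir:
            flips.append(p)
    return flips
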