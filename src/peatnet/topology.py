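"""Network modules and topological node roles (Zi-Pi classification).

Modules are clusters of densely interconnected nodes found by modularity
maximization on the unweighted, unsigned adjacency (edge signs are kept for
reporting but ignored for topology, the standard convention for Zi-Pi
analysis). Each non-isolated node then gets two coordinates:

* Zi, the within-module degree z-score: how connected the node is inside
  its own module relative to the other members —
  ``Zi = (k_is - mean_s) / sd_s`` with ``k_is`` the node's links to its own
  module ``s`` (Zi = 0 when ``sd_s = 0``, so uniform or singleton modules
  never produce NaN);
* Pi, the participation coefficient: how evenly the node's links spread
  over modules — ``Pi = 1 - sum_t (k_it / k_i)^2``; 0 means all links stay
  in one module.

Roles follow the classic Zi > 2.5 / Pi > 0.625 cut-offs: module hubs
(Zi > 2.5, Pi <= 0.625), connectors (Zi <= 2.5, Pi > 0.625), network hubs
(both), peripherals (neither). Values exactly at a threshold fall in the
lower category — the inequalities are strict — and module hubs, connectors,
and network hubs together are the "critical nodes" of keystone screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .sparcc import CorrelationNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ZI_THRESHOLD",
    "PI_THRESHOLD",
    "CRITICAL_ROLES",
    "ModulePartition",
    "detect_modules",
    "node_roles",
    "topology_summary",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.625

#: Role labels counted as critical nodes for keystone screening.
CRITICAL_ROLES = frozenset({"module hub", "connector", "network hub"})


@dataclass
class ModulePartition:
    """Module assignment for every non-isolated node.

    ``assignments`` maps node -> module index; modules are numbered by
    decreasing size (ties by smallest member ID) so module 0 is always the
    largest. Isolated nodes are excluded and listed separately.
    """

    assignments: dict[str, int]
    modularity_q: float
    isolated: list[str]

    @property
    def n_modules(self) -> int:
        return len(set(self.assignments.values()))

    def members(self, module: int) -> list[str]:
        return sorted(n for n, m in self.assignments.items() if m == module)

    def module_sizes(self) -> pd.Series:
        return pd.Series(self.assignments).value_counts().sort_index()

    def as_series(self) -> pd.Series:
        return pd.Series(self.assignments, name="module").sort_index()


def detect_modules(
    net: CorrelationNetwork, seed: int = 0, method: str = "greedy"
) -> ModulePartition:
    """Partition the network into modules by modularity maximization.

    ``method="greedy"`` (default) uses Clauset-Newman-Moore greedy
    agglomeration, which is deterministic; ``method="louvain"`` is
    available and uses ``seed``. Nodes are processed in sorted-ID order so
    ties break reproducibly. Isolated (degree-0) nodes are excluded from
    the partition and reported.
    """
    g = net.to_graph()
    isolated = sorted(n for n, d in g.degree() if d == 0)
    g.remove_nodes_from(isolated)
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        raise ValueError("network has no edges; nothing to partition")
    # rebuild with sorted node/edge insertion for order-independent output
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes))
    h.add_edges_from(sorted(tuple(sorted(e)) for e in g.edges))
    if method == "greedy":
        communities = nx.community.greedy_modularity_communities(h)
    elif method == "louvain":
        communities = nx.community.louvain_communities(h, seed=seed)
    else:
        raise ValueError(f"unknown module detection method {method!r}")
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignments = {node: m for m, comm in enumerate(communities) for node in comm}
    q = nx.community.modularity(h, communities)
    logger.info(
        "detected %d modules (Q = %.3f); %d isolated nodes excluded",
        len(communities),
        q,
        len(isolated),
    )
    return ModulePartition(assignments=assignments, modularity_q=float(q), isolated=isolated)


def node_roles(net: CorrelationNetwork, part: ModulePartition) -> pd.DataFrame:
    """Zi, Pi, and the four-way role for every partitioned node.

    Returns a table indexed by node with columns ``module``, ``k`` (total
    degree), ``k_within`` (links into the node's own module), ``zi``,
    ``pi``, ``role``. Degree-0 nodes are excluded (they are not in the
    partition).
    """
    nodes = sorted(part.assignments)
    missing = [n for n in nodes if n not in net.taxa]
    if missing:
        raise ValueError(f"partition contains unknown nodes: {missing[:5]}")
    adj = net.adjacency.loc[nodes, nodes].to_numpy()
    modules = np.array([part.assignments[n] for n in nodes])
    n_modules = modules.max() + 1
    # per-node links into each module: (nodes x modules)
    member = np.zeros((len(nodes), n_modules))
    member[np.arange(len(nodes)), modules] = 1.0
    k_to_module = adj @ member
    k_total = k_to_module.sum(axis=1)
    if (k_total == 0).any():
        bad = [nodes[i] for i in np.flatnonzero(k_total == 0)]
        raise ValueError(f"degree-0 nodes cannot be classified: {bad[:5]}")
    k_within = k_to_module[np.arange(len(nodes)), modules]
    zi = np.zeros(len(nodes))
    for m in range(n_modules):
        mask = modules == m
        sd = k_within[mask].std()
        if sd > 0:
            zi[mask] = (k_within[mask] - k_within[mask].mean()) / sd
        # sd == 0 (uniform within-degree or singleton module): Zi stays 0
    pi = 1.0 - ((k_to_module / k_total[:, None]) ** 2).sum(axis=1)
    hub = zi > ZI_THRESHOLD
    conn = pi > PI_THRESHOLD
    role = np.where(
        hub & conn,
        "network hub",
        np.where(hub, "module hub", np.where(conn, "connector", "peripheral")),
    )
    return pd.DataFrame(
        {
            "module": modules,
            "k": k_total.astype(int),
            "k_within": k_within.astype(int),
            "zi": zi,
            "pi": pi,
            "role": role,
        },
        index=pd.Index(nodes, name="node"),
    )


def topology_summary(net: CorrelationNetwork, part: ModulePartition | None = None) -> dict:
    """The topological characteristics compared between land-use networks."""
    summary = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_positive_edges": net.n_positive_edges,
        "n_negative_edges": net.n_negative_edges,
    }
    if part is not None:
        summary["n_modules"] = part.n_modules
        summary["modularity_q"] = part.modularity_q
    return summary
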