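"""Network topology: summary metrics, module detection, and node roles.

All metrics are computed on the unweighted simple graph (edge signs are
bookkeeping attributes only).  Modules come from greedy agglomerative
modularity maximization with a deterministic tie-break; node roles follow
the within-module degree z-score (Zi) and participation coefficient (Pi)
scheme with the conventional thresholds Zi = 2.5 and Pi = 0.62.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError
from .network import degree_powerlaw_r2, edge_sign_counts

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_MODULE_HUB = "module hub"
ROLE_NETWORK_HUB = "network hub"


# --------------------------------------------------------------------------
# Simple arithmetic helpers (also used to audit published summaries)
# --------------------------------------------------------------------------

def average_degree(n_nodes: int, n_edges: int) -> float:
    """avg K = 2E/N."""
    if n_nodes <= 0:
        raise InputError("n_nodes must be positive")
    return 2.0 * n_edges / n_nodes


def edge_sign_fractions(n_positive: int, n_negative: int) -> tuple[float, float]:
    """Percent of positive and negative edges among all edges."""
    total = n_positive + n_negative
    if total <= 0:
        raise InputError("no edges")
    return 100.0 * n_positive / total, 100.0 * n_negative / total


# --------------------------------------------------------------------------
# Clustering and path distance
# --------------------------------------------------------------------------

def local_clustering(G: nx.Graph, node) -> float:
    """Triangles through ``node`` / (k(k-1)/2); 0 when degree < 2."""
    if node not in G:
        raise InputError(f"node {node!r} not in network")
    return float(nx.clustering(G, node))


def average_path_distance(G: nx.Graph) -> float:
    """Mean geodesic distance over connected node pairs.

    Components are handled separately; disconnected pairs are excluded
    rather than counted as infinite.
    """
    total, pairs = 0.0, 0
    for component in nx.connected_components(G):
        if len(component) < 2:
            continue
        sub = G.subgraph(component)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        pairs += len(component) * (len(component) - 1)
    if pairs == 0:
        return float("nan")
    return total / pairs  # ordered pairs cancel the factor of 2


# --------------------------------------------------------------------------
# Modularity and module detection
# --------------------------------------------------------------------------

def modularity(G: nx.Graph, partition: dict) -> float:
    """Newman modularity Q = sum_c [e_c/m - (d_c/2m)^2]."""
    missing = [n for n in G.nodes if n not in partition]
    if missing:
        raise InputError(f"partition missing nodes: {missing[:5]}")
    m = G.number_of_edges()
    if m == 0:
        raise InputError("modularity undefined for an edgeless network")
    intra: dict = {}
    degree_sum: dict = {}
    for u, v in G.edges:
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0) + 1
    for node, deg in G.degree():
        c = partition[node]
        degree_sum[c] = degree_sum.get(c, 0) + deg
    return sum(intra.get(c, 0) / m - (d / (2.0 * m)) ** 2
               for c, d in degree_sum.items())


def detect_modules(G: nx.Graph) -> tuple[dict, float]:
    """Greedy agglomerative modularity maximization.

    Starting from singleton communities, repeatedly merge the connected
    community pair with the largest modularity gain, running the merge
    sequence to completion and keeping the best partition seen along the
    way; ties break on the lexicographically smallest pair of community
    representatives (smallest member node id).  A deterministic local
    refinement pass then moves single nodes between neighbouring
    communities while any move still increases Q, which repairs the
    occasional short-sighted early merge.  Module ids are renumbered
    1..m by decreasing size.  Deterministic by construction.
    """
    m = G.number_of_edges()
    if m == 0:
        raise InputError("cannot detect modules in an edgeless network")
    nodes = sorted(G.nodes, key=str)
    members: dict = {n: {n} for n in nodes}
    degree_sum = {n: G.degree(n) for n in nodes}
    links: dict = {}                           # inter-community edge counts
    for u, v in G.edges:
        if u == v:
            continue
        key = tuple(sorted((u, v), key=str))
        links[key] = links.get(key, 0) + 1

    def snapshot():
        return {n: rep for rep, com in members.items() for n in com}

    best_partition = snapshot()
    best_q = modularity(G, best_partition)
    q = best_q
    while links:
        best_gain, best_pair, best_key = -np.inf, None, None
        for (a, b), e_ab in links.items():
            gain = e_ab / m - degree_sum[a] * degree_sum[b] / (2.0 * m * m)
            key = (str(a), str(b))
            if gain > best_gain + 1e-12 or (
                    gain > best_gain - 1e-12 and
                    (best_key is None or key < best_key)):
                best_gain, best_pair, best_key = gain, (a, b), key
        a, b = best_pair
        keep, drop = (a, b) if str(a) < str(b) else (b, a)
        members[keep] |= members.pop(drop)
        degree_sum[keep] += degree_sum.pop(drop)
        merged_links: dict = {}
        for (x, y), e in links.items():
            x = keep if x == drop else x
            y = keep if y == drop else y
            if x == y:
                continue
            key = tuple(sorted((x, y), key=str))
            merged_links[key] = merged_links.get(key, 0) + e
        links = merged_links
        q += best_gain
        if q > best_q + 1e-12:
            best_q = q
            best_partition = snapshot()

    comm_of = dict(best_partition)
    members = {n: set() for n in nodes}        # labels = node ids; some empty
    for node, rep in comm_of.items():
        members[rep].add(node)
    comm_degree = {rep: sum(G.degree(n) for n in com)
                   for rep, com in members.items()}

    def move_gain(node, target):
        a = comm_of[node]
        if target == a:
            return 0.0
        k_i = G.degree(node)
        k_ia = sum(1 for nb in G.neighbors(node) if comm_of[nb] == a)
        k_it = sum(1 for nb in G.neighbors(node) if comm_of[nb] == target)
        return ((k_it - k_ia) / m
                - k_i * (k_i + comm_degree[target] - comm_degree[a])
                / (2.0 * m * m))

    def apply_move(node, target):
        a = comm_of[node]
        k_i = G.degree(node)
        members[a].discard(node)
        comm_degree[a] -= k_i
        members[target].add(node)
        comm_degree[target] += k_i
        comm_of[node] = target

    def single_move_sweep() -> bool:
        moved = False
        for node in nodes:
            a = comm_of[node]
            # candidates: neighbouring communities plus a fresh singleton
            candidates = {comm_of[nb] for nb in G.neighbors(node)} - {a}
            if members[node] and node not in members[node]:
                pass  # label in use by another community; no fresh split
            elif not members[node]:
                candidates.add(node)
            best_gain, best_c = 0.0, None
            for c in sorted(candidates, key=str):
                gain = move_gain(node, c)
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            if best_c is not None:
                apply_move(node, best_c)
                moved = True
        return moved

    def swap_pass() -> bool:
        for u in nodes:
            for v in nodes:
                if str(v) <= str(u) or comm_of[u] == comm_of[v]:
                    continue
                a, b = comm_of[u], comm_of[v]
                g1 = move_gain(u, b)
                apply_move(u, b)
                g2 = move_gain(v, a)
                if g1 + g2 > 1e-12:
                    apply_move(v, a)
                    return True
                apply_move(u, a)  # revert
        return False

    for _ in range(200):  # refinement until a fixed point
        moved = single_move_sweep()
        if not moved and not swap_pass():
            break

    ordered = sorted((com for com in members.values() if com),
                     key=lambda s: (-len(s), min(map(str, s))))
    partition = {n: i + 1 for i, com in enumerate(ordered) for n in com}
    return partition, modularity(G, partition)


# --------------------------------------------------------------------------
# Topology summary
# --------------------------------------------------------------------------

@dataclass
class TopologySummary:
    """The per-network summary record (one table row per site)."""

    cutoff: float | None
    n_nodes: int
    n_edges: int
    r2_powerlaw: float | None
    n_positive: int
    n_negative: int
    avg_degree: float
    avg_clustering: float
    avg_path_distance: float
    modularity: float
    module_count: int

    def to_series(self, name: str = "") -> pd.Series:
        return pd.Series(self.__dict__, name=name)


def topology_summary(G: nx.Graph, partition: dict | None = None
                     ) -> TopologySummary:
    """Compute the full topology record for one network."""
    if G.number_of_nodes() == 0:
        raise InputError("empty network")
    if partition is None:
        partition, q = detect_modules(G)
    else:
        q = modularity(G, partition)
    pos, neg = edge_sign_counts(G)
    return TopologySummary(
        cutoff=G.graph.get("cutoff"),
        n_nodes=G.number_of_nodes(),
        n_edges=G.number_of_edges(),
        r2_powerlaw=degree_powerlaw_r2(G),
        n_positive=pos,
        n_negative=neg,
        avg_degree=average_degree(G.number_of_nodes(), G.number_of_edges()),
        avg_clustering=float(nx.average_clustering(G)),
        avg_path_distance=average_path_distance(G),
        modularity=q,
        module_count=len(set(partition.values())),
    )


# --------------------------------------------------------------------------
# Zi / Pi node roles
# --------------------------------------------------------------------------

def classify_role(zi: float, pi: float) -> str:
    if zi >= ZI_THRESHOLD:
        return ROLE_NETWORK_HUB if pi >= PI_THRESHOLD else ROLE_MODULE_HUB
    return ROLE_CONNECTOR if pi >= PI_THRESHOLD else ROLE_PERIPHERAL


def node_roles(G: nx.Graph, partition: dict) -> pd.DataFrame:
    """Per-node Zi, Pi, and topological role.

    Zi is the z-score of a node's within-module degree against its module
    members (population standard deviation; Zi = 0 for zero-spread
    modules).  Pi = 1 - sum_s (k_is / k_i)^2 over modules s.
    """
    missing = [n for n in G.nodes if n not in partition]
    if missing:
        raise InputError(f"partition missing nodes: {missing[:5]}")
    nodes = list(G.nodes)
    within = {}
    per_module: dict = {}
    for node in nodes:
        counts: dict = {}
        for nb in G.neighbors(node):
            c = partition[nb]
            counts[c] = counts.get(c, 0) + 1
        within[node] = counts
        per_module.setdefault(partition[node], []).append(
            counts.get(partition[node], 0))

    stats = {c: (np.mean(v), np.std(v)) for c, v in per_module.items()}
    rows = []
    for node in nodes:
        c = partition[node]
        k = G.degree(node)
        mean, sd = stats[c]
        zi = 0.0 if sd == 0.0 else (within[node].get(c, 0) - mean) / sd
        pi = (0.0 if k == 0 else
              1.0 - sum((ks / k) ** 2 for ks in within[node].values()))
        rows.append({"node": node, "module": c, "Zi": zi, "Pi": pi,
                     "role": classify_role(zi, pi)})
    return pd.DataFrame(rows).set_index("node")


def role_census(roles: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages (2 decimals) per topological role."""
    if roles.empty:
        raise InputError("empty role table")
    counts = roles["role"].value_counts()
    out = pd.DataFrame({
        "count": [int(counts.get(role, 0)) for role in
                  (ROLE_PERIPHERAL, ROLE_CONNECTOR, ROLE_MODULE_HUB,
                   ROLE_NETWORK_HUB)],
    }, index=pd.Index([ROLE_PERIPHERAL, ROLE_CONNECTOR, ROLE_MODULE_HUB,
                       ROLE_NETWORK_HUB], name="role"))
    out["percent"] = (100.0 * out["count"] / len(roles)).round(2)
    return out


# --------------------------------------------------------------------------
# Cross-network node comparison
# --------------------------------------------------------------------------

@dataclass
class NodeSetComparison:
    shared: list
    unique_a: list
    unique_b: list
    union: list

    @property
    def counts(self) -> dict:
        return {"shared": len(self.shared), "unique_a": len(self.unique_a),
                "unique_b": len(self.unique_b), "union": len(self.union)}


def compare_node_sets(net_a, net_b) -> NodeSetComparison:
    """Shared / unique / union node ids of two networks (or iterables)."""
    a = set(net_a.nodes) if hasattr(net_a, "nodes") else set(net_a)
    b = set(net_b.nodes) if hasattr(net_b, "nodes") else set(net_b)
    return NodeSetComparison(
        shared=sorted(a & b, key=str),
        unique_a=sorted(a - b, key=str),
        unique_b=sorted(b - a, key=str),
        union=sorted(a | b, key=str),
    )
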