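"""PhONA graph assembly and network analytics.

A PhONA graph joins two layers: the OTU-OTU association network (signed
SparCC edges) and signed links from a single phenotype node to the OTUs a
predictive model selected.  On the OTU-only layer the module computes
summary attributes (node degree as edges/nodes, density over unordered
pairs, negative:positive link ratio), detects modules by maximising
Newman-Girvan modularity with simulated annealing, and assigns each node one
of the four Guimera-Amaral roles from its within-module degree z-score and
participation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import DataError
from .phenotype_selection import PhenotypeModel

__all__ = [
    "PHENOTYPE_NODE",
    "NetworkAttributes",
    "build_phona",
    "otu_subgraph",
    "network_attributes",
    "detect_modules_sa",
    "modularity",
    "node_roles",
]

PHENOTYPE_NODE = "phenotype"

Z_THRESHOLD = 2.5
P_THRESHOLD = 0.62

DEFAULT_T0 = 1.0
DEFAULT_COOLING = 0.995
DEFAULT_STEPS_PER_NODE = 10_000


# ---------------------------------------------------------------------------
# Graph assembly
# ---------------------------------------------------------------------------

def build_phona(edges: pd.DataFrame, model: PhenotypeModel | None,
                phenotype_node: str = PHENOTYPE_NODE,
                retain_isolated_predictive: bool = True,
                taxonomy: pd.DataFrame | None = None) -> nx.Graph:
    """Merge an OTU-OTU edge set and a phenotype model into one graph.

    ``edges`` needs columns source, target, weight, sign.  Every selected OTU
    gets a link to the phenotype node signed by its reduced-GLM coefficient;
    selected OTUs absent from the association network are kept as otherwise
    isolated nodes when ``retain_isolated_predictive`` is on, else dropped.
    Optional ``taxonomy`` (indexed by OTU id) is copied onto node attributes.
    """
    g = nx.Graph()
    g.add_node(phenotype_node, node_kind="phenotype")
    for rec in edges.itertuples(index=False):
        if rec.source == rec.target:
            raise DataError(f"self-loop on {rec.source!r}")
        g.add_node(rec.source, node_kind="otu")
        g.add_node(rec.target, node_kind="otu")
        g.add_edge(rec.source, rec.target, weight=float(rec.weight),
                   sign=rec.sign, edge_kind="otu-otu")
    if model is not None:
        for otu in model.selected_otus:
            if otu not in g:
                if not retain_isolated_predictive:
                    continue
                g.add_node(otu, node_kind="otu")
            g.add_edge(phenotype_node, otu,
                       weight=float(model.coefficients[otu]),
                       sign=model.signs[otu], edge_kind="otu-phenotype")
    if taxonomy is not None:
        for otu in g.nodes:
            if otu in taxonomy.index:
                for col in taxonomy.columns:
                    g.nodes[otu][str(col)] = str(taxonomy.loc[otu, col])
    return g


def otu_subgraph(g: nx.Graph, phenotype_node: str = PHENOTYPE_NODE) -> nx.Graph:
    """The OTU-only layer: drop the phenotype node and its links."""
    nodes = [n for n in g.nodes if n != phenotype_node]
    return g.subgraph(nodes).copy()


# ---------------------------------------------------------------------------
# Network attributes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkAttributes:
    """Summary attributes of one association network.

    ``node_degree`` is edges/nodes (the convention of the per-treatment
    summary tables this mirrors; half the usual mean degree, which is also
    exposed as ``mean_degree``); ``density`` is edges over unordered pairs.
    """

    n_nodes: int
    n_edges: int
    n_negative: int
    n_positive: int
    n_modules: int | None = None

    @property
    def node_degree(self) -> float:
        return self.n_edges / self.n_nodes if self.n_nodes else 0.0

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes if self.n_nodes else 0.0

    @property
    def density(self) -> float:
        pairs = self.n_nodes * (self.n_nodes - 1) / 2
        return self.n_edges / pairs if pairs else 0.0

    @property
    def neg_pos_ratio(self) -> float | None:
        if self.n_positive == 0:
            return None
        return self.n_negative / self.n_positive

    def rounded(self) -> dict:
        """Attributes at report precision (degree 1 dp, density/ratio 2 dp)."""
        ratio = self.neg_pos_ratio
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "node_degree": round(self.node_degree, 1),
            "density": round(self.density, 2),
            "n_modules": self.n_modules,
            "n_negative": self.n_negative,
            "n_positive": self.n_positive,
            "neg_pos_ratio": "NA" if ratio is None else round(ratio, 2),
        }


def network_attributes(g: nx.Graph, n_modules: int | None = None) -> NetworkAttributes:
    """Attributes of the OTU-only layer of ``g`` (phenotype node excluded)."""
    sub = otu_subgraph(g) if PHENOTYPE_NODE in g else g
    if sub.number_of_nodes() < 1:
        raise DataError("network_attributes needs at least one node")
    signs = [d.get("sign", "positive") for _, _, d in sub.edges(data=True)]
    n_neg = sum(s == "negative" for s in signs)
    return NetworkAttributes(
        n_nodes=sub.number_of_nodes(),
        n_edges=sub.number_of_edges(),
        n_negative=n_neg,
        n_positive=len(signs) - n_neg,
        n_modules=n_modules,
    )


def attributes_from_counts(n_nodes: int, n_edges: int, n_negative: int,
                           n_positive: int, n_modules: int | None = None,
                           ) -> NetworkAttributes:
    """Derived attributes straight from printed node/edge/sign counts."""
    return NetworkAttributes(n_nodes=n_nodes, n_edges=n_edges,
                             n_negative=n_negative, n_positive=n_positive,
                             n_modules=n_modules)


# ---------------------------------------------------------------------------
# Modularity via simulated annealing
# ---------------------------------------------------------------------------

def modularity(g: nx.Graph, partition: dict) -> float:
    """Newman-Girvan modularity of a node -> module-id partition
    (unsigned, unweighted skeleton)."""
    if g.number_of_edges() == 0:
        return 0.0
    groups: dict = {}
    for node, mod in partition.items():
        groups.setdefault(mod, set()).add(node)
    return nx.algorithms.community.modularity(g, list(groups.values()), weight=None)


class _SAState:
    """Mutable partition bookkeeping for O(deg) modularity deltas."""

    def __init__(self, g: nx.Graph):
        self.nodes = list(g.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.adj = [np.array([self.index[v] for v in g.neighbors(n)], dtype=np.int64)
                    for n in self.nodes]
        self.deg = np.array([len(a) for a in self.adj], dtype=np.int64)
        self.m = g.number_of_edges()
        n = len(self.nodes)
        self.comm = np.arange(n)             # node -> module id
        self.d_tot = self.deg.astype(float).copy()   # sum of degrees per module
        self.e_in = np.zeros(n)              # internal edge count per module
        for i in range(n):
            for j in self.adj[i]:
                if self.comm[i] == self.comm[j] and i < j:
                    self.e_in[self.comm[i]] += 1

    def set_partition(self, comm: np.ndarray) -> None:
        self.comm = comm.copy()
        self.d_tot = np.zeros(len(self.nodes))
        self.e_in = np.zeros(len(self.nodes))
        for i in range(len(self.nodes)):
            self.d_tot[self.comm[i]] += self.deg[i]
            for j in self.adj[i]:
                if self.comm[i] == self.comm[j] and i < j:
                    self.e_in[self.comm[i]] += 1

    def links_to(self, i: int, mod: int) -> int:
        return int((self.comm[self.adj[i]] == mod).sum())

    def move_delta(self, i: int, target: int) -> float:
        a = self.comm[i]
        if a == target:
            return 0.0
        m = self.m
        k = self.deg[i]
        k_a = self.links_to(i, a)
        k_b = self.links_to(i, target)
        d_a = self.d_tot[a]
        d_b = self.d_tot[target]
        return ((k_b - k_a) / m
                - ((d_b + k) ** 2 + (d_a - k) ** 2 - d_a ** 2 - d_b ** 2) / (4 * m * m))

    def apply_move(self, i: int, target: int) -> None:
        a = self.comm[i]
        self.e_in[a] -= self.links_to(i, a)
        self.comm[i] = target
        self.e_in[target] += self.links_to(i, target)
        self.d_tot[a] -= self.deg[i]
        self.d_tot[target] += self.deg[i]

    def merge_delta(self, a: int, b: int) -> float:
        members_a = np.where(self.comm == a)[0]
        e_ab = sum(self.links_to(i, b) for i in members_a)
        return e_ab / self.m - self.d_tot[a] * self.d_tot[b] / (2 * self.m * self.m)

    def apply_merge(self, a: int, b: int) -> None:
        members_a = np.where(self.comm == a)[0]
        e_ab = sum(self.links_to(i, b) for i in members_a)
        self.comm[members_a] = b
        self.e_in[b] += self.e_in[a] + e_ab
        self.e_in[a] = 0.0
        self.d_tot[b] += self.d_tot[a]
        self.d_tot[a] = 0.0

    def q(self) -> float:
        m = self.m
        return float((self.e_in / m - (self.d_tot / (2 * m)) ** 2).sum())


def detect_modules_sa(g: nx.Graph, seed: int = 0,
                      t0: float = DEFAULT_T0,
                      cooling: float = DEFAULT_COOLING,
                      n_steps: int | None = None) -> tuple[dict, float]:
    """Maximise modularity Q by simulated annealing.

    Proposals are single-node moves (biased toward modules of the node's
    neighbours, which mixes far faster on sparse graphs) plus occasional
    module merges; temperature cools geometrically once per sweep of
    ``n_nodes`` proposals.  The best partition seen is returned, with module
    ids renumbered 0..k-1.  Deterministic given ``seed``.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        return {}, 0.0
    if g.number_of_edges() == 0:
        return {node: i for i, node in enumerate(nodes)}, 0.0
    rng = np.random.default_rng(seed)
    state = _SAState(g)
    if n_steps is None:
        n_steps = DEFAULT_STEPS_PER_NODE * n
    temp = t0
    best_comm = state.comm.copy()
    best_q = state.q()
    q = best_q
    for step in range(n_steps):
        if step and step % n == 0:
            temp *= cooling
            if temp < 1e-6:
                break
        if rng.random() < 0.02:
            mods = np.unique(state.comm)
            if len(mods) >= 2:
                a, b = rng.choice(mods, size=2, replace=False)
                d = state.merge_delta(a, b)
                if d > 0 or rng.random() < math.exp(min(d / temp, 0.0)):
                    state.apply_merge(a, b)
                    q += d
        else:
            i = int(rng.integers(n))
            neigh = state.adj[i]
            if len(neigh) and rng.random() < 0.8:
                target = int(state.comm[neigh[rng.integers(len(neigh))]])
            else:
                target = int(rng.integers(n))  # any module slot, incl. empty
            d = state.move_delta(i, target)
            if d > 0 or rng.random() < math.exp(min(d / temp, 0.0)):
                state.apply_move(i, target)
                q += d
        if q > best_q + 1e-12:
            best_q = q
            best_comm = state.comm.copy()
    # greedy polish from the best partition: best single-node moves to
    # neighbouring modules until no improvement remains
    state.set_partition(best_comm)
    improved = True
    while improved:
        improved = False
        for i in range(n):
            targets = {int(state.comm[j]) for j in state.adj[i]}
            best_d, best_t = 0.0, None
            for t in targets:
                d = state.move_delta(i, t)
                if d > best_d + 1e-12:
                    best_d, best_t = d, t
            if best_t is not None:
                state.apply_move(i, best_t)
                improved = True
    best_comm = state.comm.copy()
    # renumber modules densely
    labels = {}
    partition = {}
    for node, c in zip(state.nodes, best_comm):
        partition[node] = labels.setdefault(int(c), len(labels))
    return partition, modularity(g, partition)


# ---------------------------------------------------------------------------
# Node roles
# ---------------------------------------------------------------------------

def node_roles(g: nx.Graph, partition: dict) -> pd.DataFrame:
    """Guimera-Amaral role table from a module partition.

    z_i is the within-module degree z-score (sample sd over module members;
    sd = 0 gives z = 0) and P_i = 1 - sum_s (k_is/k_i)^2 the participation
    coefficient.  Roles: z >= 2.5 & P >= 0.62 network hub; z >= 2.5 module
    hub; P >= 0.62 connector; else peripheral.  Link signs are ignored.
    """
    missing = [n for n in g.nodes if n not in partition]
    if missing:
        raise DataError(f"partition does not cover nodes: {missing[:5]}")
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["module", "z", "P", "role"],
                            index=pd.Index([], name="node"))
    within = {}
    per_module_links: dict = {}
    for node in g.nodes:
        counts: dict = {}
        for nb in g.neighbors(node):
            counts[partition[nb]] = counts.get(partition[nb], 0) + 1
        per_module_links[node] = counts
        within[node] = counts.get(partition[node], 0)
    # z-score of within-module degree, per module
    members: dict = {}
    for node in g.nodes:
        members.setdefault(partition[node], []).append(node)
    z = {}
    for mod, group in members.items():
        ks = np.array([within[n] for n in group], dtype=float)
        mean = ks.mean()
        sd = ks.std(ddof=1) if len(ks) > 1 else 0.0
        for node, k in zip(group, ks):
            z[node] = (k - mean) / sd if sd > 0 else 0.0
    rows = []
    for node in g.nodes:
        k = g.degree(node)
        if k == 0:
            part = 0.0
        else:
            part = 1.0 - sum((c / k) ** 2 for c in per_module_links[node].values())
        zi = z[node]
        if zi >= Z_THRESHOLD and part >= P_THRESHOLD:
            role = "network hub"
        elif zi >= Z_THRESHOLD:
            role = "module hub"
        elif part >= P_THRESHOLD:
            role = "connector"
        else:
            role = "peripheral"
        rows.append({"node": node, "module": partition[node], "z": zi,
                     "P": part, "role": role})
    return pd.DataFrame(rows).set_index("node")


def annotate_graph(g: nx.Graph, partition: dict, roles: pd.DataFrame) -> nx.Graph:
    """Copy module ids and roles onto node attributes (in place, returned)."""
    for node in g.nodes:
        if node in partition:
            g.nodes[node]["module"] = int(partition[node])
        if node in roles.index:
            g.nodes[node]["role"] = str(roles.loc[node, "role"])
            g.nodes[node]["z"] = float(roles.loc[node, "z"])
            g.nodes[node]["P"] = float(roles.loc[node, "P"])
    return g
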