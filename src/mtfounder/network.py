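"""Median-joining haplotype networks and parsimony-tree extraction.

Haplotypes are encoded as binary presence/absence vectors over the
segregating substitution sites of the input. A minimum spanning network
(all edges that occur in some minimum spanning tree, relaxed by the ε
tolerance) is iteratively augmented with *median vectors* — majority
consensus of connected node triples — whenever a median shortens the
network, then pruned of latent vectors that add no parsimony. With
ε = 0 on tree-like data the result is the minimum-spanning parsimony
network.

For small unit-weight inputs (at most ``EXACT_SITE_LIMIT`` segregating
sites and ``EXACT_TERMINAL_LIMIT`` observed haplotypes) the construction
is exact: the full median closure of the observed haplotypes — which for
binary characters contains every maximum-parsimony (Steiner) tree — is
computed and pruned to a minimum Steiner tree's node set with the
Dreyfus–Wagner dynamic program, so the network is guaranteed to contain
a maximum-parsimony tree. Larger inputs fall back to the classic
median-joining heuristic.

All orderings are canonical (sorted vectors, sorted edges), so the
network is invariant to input permutation.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import networkx as nx

from .errors import MtFounderError
from .reference import HotspotList
from .variants import VariantProfile

Site = Tuple[int, str]           # (position, derived allele)
Vector = Tuple[int, ...]         # 0/1 per site

MAX_SEGREGATING_SITES = 200
EXACT_SITE_LIMIT = 8          # exact Steiner construction up to 2^8 closure
EXACT_TERMINAL_LIMIT = 10     # Dreyfus-Wagner over at most 2^9 subsets


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph
    sites: Tuple[Site, ...]
    weights: Tuple[float, ...]
    epsilon: int = 0

    def observed_nodes(self) -> List[Vector]:
        return [v for v, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    def median_nodes(self) -> List[Vector]:
        return [v for v, d in self.graph.nodes(data=True) if d["kind"] == "median"]

    def length(self) -> float:
        """Total length of a minimum spanning tree over the network's
        nodes restricted to the network's own edges."""
        mst = nx.minimum_spanning_tree(self.graph, weight="weight")
        return sum(d["weight"] for *_, d in mst.edges(data=True))


def _distance(a: Vector, b: Vector, weights: Sequence[float]) -> float:
    return sum(w for x, y, w in zip(a, b, weights) if x != y)


def _diff_sites(a: Vector, b: Vector, sites: Sequence[Site]) -> List[str]:
    out = []
    for x, y, (pos, alt) in zip(a, b, sites):
        if x != y:
            out.append(f"{pos}{alt}")
    return out


def encode_profiles(profiles: Sequence[VariantProfile],
                    hotspots: Optional[HotspotList] = None
                    ) -> Tuple[Dict[Vector, List[VariantProfile]], Tuple[Site, ...]]:
    """Binary-encode profiles over their segregating substitution sites.

    Hotspot sites are dropped (the default down-weighting to zero).
    Returns the distinct haplotype vectors with their carriers, and the
    site list in positional order.
    """
    hs = hotspots.positions if hotspots else frozenset()
    all_states = [frozenset(p.substitution_state(hs).items()) for p in profiles]
    union = sorted(set().union(*all_states)) if all_states else []
    # segregating only: drop sites carried by everyone
    sites = tuple(s for s in union
                  if sum(s in st for st in all_states) < len(all_states)
                  or len(all_states) == 1)
    carriers: Dict[Vector, List[VariantProfile]] = {}
    for p, st in zip(profiles, all_states):
        vec = tuple(1 if s in st else 0 for s in sites)
        carriers.setdefault(vec, []).append(p)
    return carriers, sites


def _msn_edges(nodes: Sequence[Vector], weights: Sequence[float],
               epsilon: int = 0) -> List[Tuple[Vector, Vector, float]]:
    """Edges of the ε-relaxed minimum spanning network (Kruskal rounds:
    at each distance level, link every pair of distinct components at
    that level; ε admits levels up to merge level + ε)."""
    nodes = sorted(nodes)
    dist = {}
    for a, b in itertools.combinations(nodes, 2):
        dist[(a, b)] = _distance(a, b, weights)
    levels = sorted(set(dist.values()))
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    edges: List[Tuple[Vector, Vector, float]] = []
    merged_at: Dict[FrozenSet, float] = {}
    for level in levels:
        # component structure at round start
        comp = {v: find(v) for v in nodes}
        joins = []
        for (a, b), d in dist.items():
            if d == level and comp[a] != comp[b]:
                edges.append((a, b, d))
                joins.append((a, b))
        for a, b in joins:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    if epsilon > 0:
        # admit extra links within epsilon of an existing alternative
        have = {frozenset((a, b)) for a, b, _ in edges}
        best = {}
        g = nx.Graph()
        g.add_weighted_edges_from(edges)
        for (a, b), d in dist.items():
            if frozenset((a, b)) in have:
                continue
            try:
                path_cost = nx.shortest_path_length(g, a, b, weight="weight")
            except nx.NetworkXNoPath:
                path_cost = float("inf")
            if d <= path_cost + epsilon:
                edges.append((a, b, d))
    return edges


def _median(a: Vector, b: Vector, c: Vector) -> Vector:
    return tuple(1 if x + y + z >= 2 else 0 for x, y, z in zip(a, b, c))


def _median_closure(observed: Sequence[Vector]) -> List[Vector]:
    """Full median closure of a set of binary vectors: repeatedly add the
    majority vector of every node triple until no new vector appears.
    For binary characters the closure contains every maximum-parsimony
    tree of the observed set (it is the median network)."""
    import numpy as np

    k = len(observed[0])
    nodes = {tuple(v) for v in observed}
    fresh = set(nodes)
    while fresh:
        pool = np.array(sorted(nodes), dtype=np.int8)
        new: set = set()
        for u in sorted(fresh):
            uu = np.array(u, dtype=np.int8)
            med = (pool[:, None, :] + pool[None, :, :] + uu) >= 2
            for row in np.unique(med.reshape(-1, k), axis=0):
                m = tuple(int(b) for b in row)
                if m not in nodes:
                    new.add(m)
        fresh = new
        nodes |= new
    return sorted(nodes)


def _steiner_nodes(observed: Sequence[Vector], candidates: Sequence[Vector],
                   weights: Sequence[float]) -> Tuple[float, List[Vector]]:
    """Minimum Steiner tree of ``observed`` over the candidate node pool
    under the weighted-Hamming metric (Dreyfus-Wagner dynamic program).
    Returns the optimal length and the retained node set (terminals plus
    the Steiner points of one canonical optimal tree)."""
    import numpy as np

    nodes = sorted(candidates)
    index = {v: i for i, v in enumerate(nodes)}
    arr = np.array(nodes, dtype=np.int16)
    w = np.asarray(weights, dtype=float)
    D = ((arr[:, None, :] != arr[None, :, :]) * w).sum(axis=2)
    terms = sorted(index[v] for v in set(observed))
    if len(terms) < 2:
        return 0.0, [nodes[i] for i in terms]
    t0, rest = terms[0], terms[1:]
    t = len(rest)
    full = (1 << t) - 1
    n = len(nodes)
    dp = np.full((1 << t, n), np.inf)
    merged: Dict[int, "np.ndarray"] = {}
    for i, term in enumerate(rest):
        dp[1 << i] = D[term]
    for S in range(1, full + 1):
        if S & (S - 1) == 0:
            continue
        best = np.full(n, np.inf)
        S1 = (S - 1) & S
        while S1:
            S2 = S ^ S1
            if S1 <= S2:
                np.minimum(best, dp[S1] + dp[S2], out=best)
            S1 = (S1 - 1) & S
        merged[S] = best
        dp[S] = (best[None, :] + D).min(axis=1)

    used = set(terms)

    def walk(S: int, v: int) -> None:
        if S & (S - 1) == 0:
            used.add(rest[S.bit_length() - 1])
            return
        u = int(np.argmin(merged[S] + D[:, v]))
        used.add(u)
        S1 = (S - 1) & S
        while S1:
            S2 = S ^ S1
            if S1 <= S2 and dp[S1][u] + dp[S2][u] <= merged[S][u] + 1e-9:
                walk(S1, u)
                walk(S2, u)
                return
            S1 = (S1 - 1) & S
        raise AssertionError("Steiner backtrack failed")  # pragma: no cover

    walk(full, t0)
    return float(dp[full][t0]), [nodes[i] for i in sorted(used)]


def build_mj_network(profiles: Sequence[VariantProfile], epsilon: int = 0,
                     site_weights: Optional[Sequence[float]] = None,
                     hotspots: Optional[HotspotList] = None,
                     force: bool = False) -> HaplotypeNetwork:
    """Build the median-joining network of a set of profiles."""
    carriers, sites = encode_profiles(profiles, hotspots)
    if len(sites) > MAX_SEGREGATING_SITES and not force:
        raise MtFounderError(
            f"{len(sites)} segregating sites exceed the supported "
            f"{MAX_SEGREGATING_SITES}; split the panel by clade or pass "
            f"force=True")
    if len(carriers) < 1:
        raise MtFounderError("need at least one haplotype")
    weights = tuple(site_weights) if site_weights is not None else (1.0,) * len(sites)

    observed = sorted(carriers)
    nodes: List[Vector] = list(observed)
    medians: set = set()

    def mst_length(node_list: Sequence[Vector]) -> float:
        g = nx.Graph()
        g.add_nodes_from(node_list)
        for a, b in itertools.combinations(sorted(node_list), 2):
            g.add_edge(a, b, weight=_distance(a, b, weights))
        if g.number_of_edges() == 0:
            return 0.0
        mst = nx.minimum_spanning_tree(g, weight="weight")
        return sum(d["weight"] for *_, d in mst.edges(data=True))

    exact = (len(sites) <= EXACT_SITE_LIMIT
             and len(observed) <= EXACT_TERMINAL_LIMIT
             and epsilon == 0
             and all(w == 1.0 for w in weights)
             and len(observed) >= 2)
    if exact:
        # exact construction: the full median closure contains every
        # maximum-parsimony tree of binary data; prune it to the node
        # set of one canonical minimum Steiner tree
        closure = _median_closure(observed)
        _, nodes = _steiner_nodes(observed, closure, weights)
        return _assemble(carriers, nodes, sites, weights, epsilon)

    # heuristic path: repeatedly add every novel median vector of a
    # connected triple (u; v, w with v, w both linked to u), bounded to
    # keep pathological inputs finite
    node_cap = max(4 * len(observed), len(observed) + 64)
    for _ in range(32):
        edges = _msn_edges(nodes, weights, epsilon)
        adj: Dict[Vector, set] = {v: set() for v in nodes}
        for a, b, _ in edges:
            adj[a].add(b)
            adj[b].add(a)
        fresh = set()
        for u in sorted(nodes):
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                m = _median(u, v, w)
                if m not in carriers and m not in medians and m not in fresh:
                    fresh.add(m)
        if not fresh or len(nodes) + len(fresh) > node_cap:
            break
        for m in sorted(fresh):
            medians.add(m)
            nodes.append(m)

    # prune latent vectors whose removal does not lengthen the network
    changed = True
    while changed:
        changed = False
        base_len = mst_length(nodes)
        for m in sorted(medians):
            rest = [v for v in nodes if v != m]
            if mst_length(rest) <= base_len + 1e-9:
                medians.discard(m)
                nodes.remove(m)
                changed = True
                break

    return _assemble(carriers, nodes, sites, weights, epsilon)


def _assemble(carriers: Dict[Vector, List[VariantProfile]],
              nodes: Sequence[Vector], sites: Tuple[Site, ...],
              weights: Tuple[float, ...], epsilon: int) -> HaplotypeNetwork:
    graph = nx.Graph()
    for v in nodes:
        if v in carriers:
            pops = Counter(p.population for p in carriers[v])
            graph.add_node(v, kind="observed",
                           carriers=tuple(p.sample_id for p in carriers[v]),
                           multiplicity=len(carriers[v]),
                           populations=dict(pops))
        else:
            graph.add_node(v, kind="median", carriers=(), multiplicity=0,
                           populations={})
    for a, b, d in _msn_edges(nodes, weights, epsilon):
        graph.add_edge(a, b, weight=d, variants=_diff_sites(a, b, sites))
    return HaplotypeNetwork(graph=graph, sites=sites, weights=weights,
                            epsilon=epsilon)


# ---------------------------------------------------------------------------
# Parsimony tree extraction

def extract_parsimony_tree(network: HaplotypeNetwork,
                           root: VariantProfile,
                           hotspots: Optional[HotspotList] = None
                           ) -> nx.DiGraph:
    """Extract a rooted minimum spanning (parsimony) tree from a network.

    The root haplotype is located (or inserted) in the network; the
    minimum spanning tree is taken with canonical tie-breaking and
    oriented away from the root. Each edge carries ``label``: the variant
    strings of the sites changing on that branch, with changes that
    restore the root's state rendered as ``@position`` (back mutations).
    """
    hs = hotspots.positions if hotspots else frozenset()
    root_states = frozenset(root.substitution_state(hs).items())
    root_vec = tuple(1 if s in root_states else 0 for s in network.sites)

    graph = network.graph.copy()
    if root_vec not in graph:
        graph.add_node(root_vec, kind="root", carriers=(), multiplicity=0,
                       populations={})
        for v in sorted(n for n in graph.nodes if n != root_vec):
            graph.add_edge(root_vec, v,
                           weight=_distance(root_vec, v, network.weights),
                           variants=_diff_sites(root_vec, v, network.sites))

    # deterministic MST: sort edges by (weight, endpoints)
    mst = nx.Graph()
    mst.add_nodes_from(graph.nodes(data=True))
    parent = {v: v for v in graph.nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b, d in sorted(graph.edges(data=True),
                          key=lambda e: (e[2]["weight"], sorted((e[0], e[1])))):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
            mst.add_edge(a, b, **d)

    if not nx.is_connected(mst):
        raise MtFounderError("network is not connected; cannot extract a tree")

    tree = nx.bfs_tree(mst, root_vec)
    for u, v in tree.edges:
        labels = []
        for x, y, (pos, alt), r in zip(u, v, network.sites, root_vec):
            if x == y:
                continue
            if y == r:  # branch restores the root's state: back mutation
                labels.append(f"@{pos}")
            elif y == 1:
                labels.append(f"{pos}{alt}")
            else:       # loses a derived allele the root never carried
                labels.append(f"@{pos}")
        tree.edges[u, v]["label"] = labels
        tree.edges[u, v]["weight"] = mst.edges[u, v]["weight"]
    for v, data in mst.nodes(data=True):
        tree.nodes[v].update(data)
    return tree


def tree_length(tree: nx.DiGraph) -> float:
    return sum(d["weight"] for *_, d in tree.edges(data=True))


def tree_to_newick(tree: nx.DiGraph) -> str:
    """Serialise an extracted tree to Newick; median vectors become
    unlabeled internal nodes, observed nodes are named by their carriers."""
    roots = [v for v in tree if tree.in_degree(v) == 0]
    if len(roots) != 1:
        raise MtFounderError("tree must have exactly one root")

    def name(v) -> str:
        carriers = tree.nodes[v].get("carriers", ())
        return "|".join(carriers) if carriers else ""

    def render(v) -> str:
        kids = sorted(tree.successors(v))
        label = name(v)
        if not kids:
            return f"{label}:{0}" if False else label
        inner = ",".join(
            f"{render(k)}:{tree.edges[v, k]['weight']:g}" for k in kids)
        return f"({inner}){label}"

    return render(roots[0]) + ";"


def render_network(network_or_tree, gml_path=None, figure_path=None,
                   newick_path=None) -> None:
    """Write a network/tree to a graph exchange file and a static figure.

    Accepts a :class:`HaplotypeNetwork` or an extracted tree (DiGraph).
    Node size scales with carrier multiplicity; node colour follows the
    dominant population label.
    """
    graph = (network_or_tree.graph if isinstance(network_or_tree, HaplotypeNetwork)
             else network_or_tree)

    if gml_path is not None:
        g2 = nx.relabel_nodes(graph, {v: "".join(map(str, v)) for v in graph.nodes})
        for _, d in g2.nodes(data=True):
            d["carriers"] = ",".join(d.get("carriers", ()))
            d["populations"] = ";".join(
                f"{k}:{v}" for k, v in d.get("populations", {}).items())
        for *_, d in g2.edges(data=True):
            if "variants" in d:
                d["variants"] = ",".join(d["variants"])
            if "label" in d:
                d["label"] = ",".join(d["label"])
        nx.write_gml(g2, gml_path)

    if newick_path is not None and not isinstance(network_or_tree, HaplotypeNetwork):
        with open(newick_path, "w") as fh:
            fh.write(tree_to_newick(network_or_tree) + "\n")

    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        undirected = graph.to_undirected() if graph.is_directed() else graph
        pos = nx.spring_layout(undirected, seed=7)
        pops = sorted({p for _, d in undirected.nodes(data=True)
                       for p in d.get("populations", {})})
        palette = plt.cm.tab10.colors
        colors = []
        sizes = []
        for _, d in undirected.nodes(data=True):
            mult = d.get("multiplicity", 0)
            sizes.append(60 + 120 * mult)
            popd = d.get("populations", {})
            if popd:
                top = max(sorted(popd), key=lambda k: popd[k])
                colors.append(palette[pops.index(top) % len(palette)])
            else:
                colors.append("lightgrey")
        fig, ax = plt.subplots(figsize=(6, 5))
        nx.draw_networkx(undirected, pos=pos, ax=ax, with_labels=False,
                         node_size=sizes, node_color=colors, edge_color="grey")
        ax.set_axis_off()
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
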