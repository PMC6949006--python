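"""Median-joining haplotype networks.

The construction follows Bandelt-style median joining as popularised by
the Network software: (1) build the epsilon-relaxed minimum spanning
network over the observed haplotypes — every link whose cost exceeds the
pair's connection threshold (the minimax path cost, i.e. the level at
which the pair first becomes connected in Kruskal's construction) by at
most epsilon; with epsilon = 0 this is exactly the union of all minimum
spanning trees; (2) repeatedly add median (consensus) vectors of
mutually connected triplets when they reduce the total network cost, then
prune uninformative medians, to a fixed point.

Distances are mutational steps: substitution columns plus maximal
gap-run events, the same metric used for haplotype comparisons elsewhere
in the package.  All tie-breaking is deterministic, ordered by
(weight, lexicographic node id).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .haplotypes import Haplotype, mutational_distance


class UsageError(ValueError):
    pass


@dataclass
class MJNetwork:
    """Haplotype network with observed and median nodes.

    Nodes are (node_id, kind, sequence, count_by_role); edges carry the
    mutational-step weight of their endpoint sequences.
    """

    graph: nx.Graph
    epsilon: int = 0
    truncated: bool = False  # median cap reached before convergence

    @property
    def nodes(self) -> list[tuple[str, str, str, dict[str, int]]]:
        return [
            (n, d["kind"], d["sequence"], d.get("count_by_role", {}))
            for n, d in sorted(self.graph.nodes(data=True))
        ]

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, d["weight"]))
        return sorted(out)

    def observed_ids(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"
        )


def distance_matrix(haps: list[Haplotype]) -> np.ndarray:
    """Symmetric integer matrix of pairwise mutational steps."""
    if not haps:
        raise UsageError("need at least one haplotype")
    n = len(haps)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = mutational_distance(haps[i].sequence, haps[j].sequence)
            m[i, j] = m[j, i] = d
    return m


def _connection_thresholds(ids: list[str], dist: dict[tuple[str, str], int]) -> dict:
    """Minimax path cost for each pair: the Kruskal level at which the pair
    first becomes connected.  Computed on an MST and verified cheap (n small)."""
    g = nx.Graph()
    g.add_nodes_from(ids)
    for (u, v), d in dist.items():
        g.add_edge(u, v, weight=d)
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    thresh: dict[tuple[str, str], int] = {}
    for u, v in itertools.combinations(sorted(ids), 2):
        path = nx.shortest_path(mst, u, v)
        mx = max(
            mst[a][b]["weight"] for a, b in zip(path, path[1:])
        )
        thresh[(u, v)] = mx
    return thresh


def _msn_graph(
    sequences: dict[str, str], epsilon: int
) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network over node sequences."""
    ids = sorted(sequences)
    dist = {
        (u, v): mutational_distance(sequences[u], sequences[v])
        for u, v in itertools.combinations(ids, 2)
    }
    g = nx.Graph()
    g.add_nodes_from(ids)
    if len(ids) == 1:
        return g
    thresh = _connection_thresholds(ids, dist)
    for (u, v), d in sorted(dist.items(), key=lambda kv: (kv[1], kv[0])):
        if d <= thresh[(u, v)] + epsilon:
            g.add_edge(u, v, weight=d)
    return g


def minimum_spanning_network(haps: list[Haplotype], epsilon: int = 0) -> MJNetwork:
    """Build the epsilon-relaxed minimum spanning network (no medians yet)."""
    if epsilon < 0:
        raise UsageError("epsilon must be >= 0")
    if not haps:
        raise UsageError("need at least one haplotype")
    sequences = {h.hap_id: h.sequence for h in haps}
    g = _msn_graph(sequences, epsilon)
    for h in haps:
        g.nodes[h.hap_id]["kind"] = "observed"
        g.nodes[h.hap_id]["sequence"] = h.sequence
        g.nodes[h.hap_id]["count_by_role"] = dict(h.count_by_role)
    return MJNetwork(graph=g, epsilon=epsilon)


def _median_candidates(sa: str, sb: str, sc: str) -> list[str]:
    """Median vectors of a triplet: per-column majority; columns where all
    three states differ expand to the full quasi-median set."""
    cols: list[tuple[str, ...]] = []
    for x, y, z in zip(sa, sb, sc):
        states = (x, y, z)
        counts = {s: states.count(s) for s in set(states)}
        best = max(counts.values())
        if best >= 2:
            maj = max(counts, key=lambda s: (counts[s], s))
            cols.append((maj,))
        else:
            cols.append(tuple(sorted(set(states))))
    # cap the per-triplet expansion; low-divergence data never hits this
    n_comb = 1
    for c in cols:
        n_comb *= len(c)
        if n_comb > 64:
            cols = [(c[0],) for c in cols]
            break
    return ["".join(choice) for choice in itertools.product(*cols)]


def _total_cost(sequences: dict[str, str]) -> int:
    """Cost of a network over these nodes: weight of its minimum spanning tree."""
    ids = sorted(sequences)
    if len(ids) < 2:
        return 0
    g = nx.Graph()
    for u, v in itertools.combinations(ids, 2):
        g.add_edge(u, v, weight=mutational_distance(sequences[u], sequences[v]))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))


def quasi_median_closure(
    network: MJNetwork, haps: list[Haplotype], max_medians: int = 100
) -> MJNetwork:
    """Iteratively add cost-reducing median vectors and prune, to a fixed point.

    Median nodes of degree <= 2 that lie on no shortest observed-observed
    path are pruned after every round.  The total number of medians is
    capped (default 100); hitting the cap sets ``truncated``.
    """
    epsilon = network.epsilon
    sequences = {n: d["sequence"] for n, d in network.graph.nodes(data=True)}
    observed = set(network.observed_ids())
    n_median = 0
    truncated = False

    for _ in range(50):  # fixed-point iteration bound
        g = _msn_graph(sequences, epsilon)
        base_cost = _total_cost(sequences)
        # candidate medians from mutually connected triplets
        candidates: list[tuple[int, str]] = []
        seen = set(sequences.values())
        for u, v, w in itertools.combinations(sorted(g.nodes), 3):
            if not (g.has_edge(u, v) and g.has_edge(u, w) and g.has_edge(v, w)):
                continue
            for med in _median_candidates(
                sequences[u], sequences[v], sequences[w]
            ):
                if med in seen:
                    continue
                cost = _total_cost({**sequences, "__cand__": med})
                if cost < base_cost:
                    candidates.append((cost, med))
        if not candidates:
            break
        # add the single best median per round (deterministic), then repeat
        candidates.sort(key=lambda t: (t[0], t[1]))
        cost, med = candidates[0]
        if n_median >= max_medians:
            truncated = True
            break
        n_median += 1
        sequences[f"mv{n_median}"] = med
        # prune uninformative medians
        sequences = _prune(sequences, observed, epsilon)
    else:
        truncated = True

    g = _msn_graph(sequences, epsilon)
    for n in g.nodes:
        g.nodes[n]["sequence"] = sequences[n]
        if n in observed:
            src = next(h for h in haps if h.hap_id == n)
            g.nodes[n]["kind"] = "observed"
            g.nodes[n]["count_by_role"] = dict(src.count_by_role)
        else:
            g.nodes[n]["kind"] = "median"
            g.nodes[n]["count_by_role"] = {}
    return MJNetwork(graph=g, epsilon=epsilon, truncated=truncated)


def _prune(
    sequences: dict[str, str], observed: set[str], epsilon: int
) -> dict[str, str]:
    """Drop median nodes of degree <= 2 lying on no shortest observed pair path."""
    while True:
        g = _msn_graph(sequences, epsilon)
        keep = set(observed)
        for u, v in itertools.combinations(sorted(observed), 2):
            for path in nx.all_shortest_paths(g, u, v, weight="weight"):
                keep.update(path)
        removable = [
            n
            for n in sorted(sequences)
            if n not in keep and g.degree(n) <= 2
        ]
        if not removable:
            return sequences
        sequences = {k: v for k, v in sequences.items() if k != removable[0]}


def median_joining_network(
    haps: list[Haplotype], epsilon: int = 0, max_medians: int = 100
) -> MJNetwork:
    """Full MJ construction: MSN then quasi-median closure."""
    msn = minimum_spanning_network(haps, epsilon)
    if len(haps) < 3:
        return msn
    return quasi_median_closure(msn, haps, max_medians)


def export_network(network: MJNetwork, path_prefix: str) -> tuple[str, str]:
    """Write GraphML and a TSV edge list; returns the two paths.

    Node attributes: kind, per-role counts (pie-chart-ready); edge
    attribute: weight (mutational steps).
    """
    g = nx.Graph()
    for node_id, kind, seq, counts in network.nodes:
        g.add_node(
            node_id,
            kind=kind,
            sequence=seq,
            count_parent_a=counts.get("parent_a", 0),
            count_parent_b=counts.get("parent_b", 0),
            count_hybrid=counts.get("hybrid", 0),
        )
    for u, v, w in network.edges:
        g.add_edge(u, v, weight=int(w))
    graphml_path = f"{path_prefix}.graphml"
    tsv_path = f"{path_prefix}_edges.tsv"
    nx.write_graphml(g, graphml_path)
    with open(tsv_path, "w") as fh:
        fh.write("node1\tnode2\tweight\n")
        for u, v, w in network.edges:
            fh.write(f"{u}\t{v}\t{w}\n")
    return graphml_path, tsv_path


def plot_network(network: MJNetwork, path: str) -> None:
    """Static plot: nodes scaled by total frequency, coloured by role mix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = network.graph
    pos = nx.spring_layout(g, seed=0, weight=None)
    fig, ax = plt.subplots(figsize=(6, 6))
    for n, d in g.nodes(data=True):
        counts = d.get("count_by_role", {})
        total = sum(counts.values())
        size = 80 + 40 * total
        color = (
            "lightgray"
            if d["kind"] == "median"
            else (
                "gold"
                if counts.get("hybrid", 0)
                else ("tab:blue" if counts.get("parent_a", 0) else "tab:red")
            )
        )
        ax.scatter(*pos[n], s=size, c=color, zorder=2, edgecolors="k")
        ax.annotate(n, pos[n], fontsize=7, ha="center", va="bottom")
    for u, v, d in g.edges(data=True):
        x = [pos[u][0], pos[v][0]]
        y = [pos[u][1], pos[v][1]]
        ax.plot(x, y, "k-", lw=0.8, zorder=1)
        if d["weight"] > 1:
            ax.annotate(
                str(d["weight"]),
                ((x[0] + x[1]) / 2, (y[0] + y[1]) / 2),
                fontsize=7,
                color="darkgreen",
            )
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
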