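"""DPClus density-periphery graph clustering and pathway enrichment.

DPClus grows clusters from high-degree seeds, admitting neighbours in
priority order as long as two criteria hold: the extended cluster's density
d = 2|E|/(|N|(|N|-1)) stays at or above ``d_in``, and the entering node's
cluster property cp = (edges into the cluster) / (d * |cluster|) is at
least ``cp_in``. In overlapping mode an emitted cluster only surrenders its
internal edges, so periphery nodes can join later clusters — the behaviour
that suits overlapping metabolic pathways; non-overlapping mode removes the
nodes outright.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import Network


def cluster_density(g: nx.Graph, nodes) -> float:
    """2|E|/(|N|(|N|-1)) within ``nodes`` (1.0 for a single node, by convention)."""
    k = len(nodes)
    if k < 2:
        return 1.0
    e = g.subgraph(nodes).number_of_edges()
    return 2.0 * e / (k * (k - 1))


@dataclass
class ClusterSet:
    clusters: list[tuple]       # sorted node tuples
    densities: list[float]
    overlapping: bool
    d_in: float
    cp_in: float
    #: frozen working-graph edge sets at each cluster's extraction (audit)
    working_edges: list[frozenset] | None = None

    def __len__(self) -> int:
        return len(self.clusters)

    def membership(self) -> pd.DataFrame:
        rows = [(i + 1, node) for i, cl in enumerate(self.clusters) for node in cl]
        return pd.DataFrame(rows, columns=["cluster", "node"])


def dpclus(net: Network | nx.Graph, d_in: float = 0.5, cp_in: float = 0.5,
           overlapping: bool = True) -> ClusterSet:
    """Iterative seed-and-extend clustering of a simple undirected graph.

    Seeds are the highest-degree nodes of the working graph (ties broken by
    node id); extension admits, repeatedly, the highest-priority neighbour
    (most edges into the cluster, then most shared neighbours with the
    cluster periphery, then highest degree, then id) that keeps
    density >= d_in and has cluster property >= cp_in, until none qualifies.
    Repeats until the working graph has no edges. Every emitted cluster has
    size >= 2 and density >= d_in.
    """
    if not (0 < d_in <= 1 and 0 < cp_in <= 1):
        raise ValueError("d_in and cp_in must be in (0, 1]")
    g = (net.graph if isinstance(net, Network) else net).copy()
    clusters: list[tuple] = []
    densities: list[float] = []
    working_edges: list[frozenset] = []

    while g.number_of_edges() > 0:
        snapshot = frozenset(frozenset(e) for e in g.edges)
        seed = min(g.nodes, key=lambda v: (-g.degree(v), str(v)))
        cluster = {seed}
        internal = 0
        while True:
            candidates = {}
            for member in cluster:
                for nb in g.neighbors(member):
                    if nb not in cluster:
                        candidates[nb] = candidates.get(nb, 0) + 1
            if not candidates:
                break
            # cohesion tie-break: candidates sharing neighbours with the
            # cluster's periphery beat equally-connected bridge nodes
            cand_set = set(candidates)
            common = {v: sum(1 for nb in g.neighbors(v)
                             if nb in cand_set and nb != v)
                      for v in candidates}
            order = sorted(candidates,
                           key=lambda v: (-candidates[v], -common[v],
                                          -g.degree(v), str(v)))
            size = len(cluster)
            d_k = 2.0 * internal / (size * (size - 1)) if size > 1 else 1.0
            admitted = None
            for cand in order:
                e_nk = candidates[cand]
                new_density = 2.0 * (internal + e_nk) / ((size + 1) * size)
                if new_density < d_in:
                    continue
                if size > 1:
                    cp = e_nk / (d_k * size)
                    if cp < cp_in:
                        continue
                admitted = cand
                break
            if admitted is None:
                break
            cluster.add(admitted)
            internal += candidates[admitted]
        if len(cluster) >= 2:
            clusters.append(tuple(sorted(cluster, key=str)))
            densities.append(2.0 * internal / (len(cluster) * (len(cluster) - 1)))
            working_edges.append(snapshot)
        if overlapping:
            g.remove_edges_from(list(g.subgraph(cluster).edges))
        else:
            g.remove_nodes_from(cluster)
        g.remove_nodes_from([v for v in list(g.nodes) if g.degree(v) == 0])

    return ClusterSet(clusters, densities, overlapping, d_in, cp_in, working_edges)


ENRICH_COLUMNS = ["cluster", "pathway", "cluster_size", "pathway_size",
                  "overlap", "universe", "p", "q"]


def enrich(clusters: ClusterSet, annotation, universe=None) -> pd.DataFrame:
    """Hypergeometric pathway over-representation per (cluster, pathway).

    ``annotation`` maps metabolite -> iterable of pathway ids (or is a
    pathway -> member-set mapping; detected by value types against the
    universe). The one-sided upper-tail p uses pathway and cluster sizes
    restricted to the universe; BH is applied across all tested pairs.
    Pathways with no member in the universe are skipped.
    """
    members: set = set()
    for cl in clusters.clusters:
        members |= set(cl)
    universe = set(universe) if universe is not None else members
    if not members <= universe:
        raise ValueError("universe must contain all clustered nodes")

    pathway_members: dict[str, set] = {}
    if isinstance(annotation, Mapping) and annotation:
        sample_val = next(iter(annotation.values()))
        keys_look_like_items = set(annotation) & universe
        if keys_look_like_items:
            for item, pws in annotation.items():
                if item not in universe:
                    continue
                pws = [pws] if isinstance(pws, str) else pws
                for pw in pws:
                    if pw:
                        pathway_members.setdefault(pw, set()).add(item)
        else:
            for pw, its in annotation.items():
                pathway_members[pw] = set(its) & universe
        del sample_val
    else:
        raise ValueError("annotation must be a mapping")
    pathway_members = {pw: its for pw, its in pathway_members.items() if its}

    n_univ = len(universe)
    rows = []
    for ci, cl in enumerate(clusters.clusters, start=1):
        cset = set(cl) & universe
        for pw, pset in sorted(pathway_members.items()):
            k = len(cset & pset)
            p = float(stats.hypergeom.sf(k - 1, n_univ, len(pset), len(cset)))
            rows.append((ci, pw, len(cset), len(pset), k, n_univ, min(p, 1.0), np.nan))
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
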