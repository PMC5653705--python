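"""Metabolite correlation structure: Spearman matrices, heat-map ordering,
PCA summaries, thresholded networks and the threshold-sweep diagnostics.

Correlations are Spearman with average ranks on pairwise-complete samples
(floor of 4 shared observations per pair); significance is the t
approximation with BH correction over all unique pairs. A network keeps the
edges with |Rs| at or above a threshold (default 0.5) that are also
BH-significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .types import CorrelationMatrix, MetaboliteMatrix

log = logging.getLogger(__name__)

MIN_SHARED_SAMPLES = 4


def _values_of(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, MetaboliteMatrix) else matrix


def _spearman_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t approximation, elementwise."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(n >= MIN_SHARED_SAMPLES, p, np.nan)


def spearman_matrix(matrix, min_samples: int = MIN_SHARED_SAMPLES) -> CorrelationMatrix:
    """All-pairs Spearman correlation on pairwise-complete observations.

    Pairs sharing fewer than ``min_samples`` observations are reported NaN
    and excluded from the BH family.
    """
    df = _values_of(matrix)
    cols = list(df.columns)
    m = len(cols)
    x = df.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    n_shared = obs.T.astype(int) @ obs.astype(int)

    if obs.all():
        ranks = np.apply_along_axis(stats.rankdata, 0, x)
        rs = np.corrcoef(ranks, rowvar=False)
        # constant columns give NaN rows; keep them NaN
    else:
        rs = np.full((m, m), np.nan)
        for i in range(m):
            rs[i, i] = 1.0
            for j in range(i + 1, m):
                share = obs[:, i] & obs[:, j]
                if share.sum() < min_samples:
                    continue
                ri = stats.rankdata(x[share, i])
                rj = stats.rankdata(x[share, j])
                if ri.std() == 0 or rj.std() == 0:
                    continue
                rs[i, j] = rs[j, i] = np.corrcoef(ri, rj)[0, 1]
    np.fill_diagonal(rs, 1.0)
    rs = np.clip(rs, -1.0, 1.0)

    p_raw = _spearman_p(rs, n_shared)
    np.fill_diagonal(p_raw, np.nan)
    p_bh = np.full_like(p_raw, np.nan)
    iu = np.triu_indices(m, k=1)
    flat = p_raw[iu]
    ok = ~np.isnan(flat)
    if ok.any():
        adj = np.full(flat.shape, np.nan)
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        p_bh[iu] = adj
        p_bh[(iu[1], iu[0])] = adj

    idx = pd.Index(cols)
    return CorrelationMatrix(
        rs=pd.DataFrame(rs, index=idx, columns=idx),
        p_raw=pd.DataFrame(p_raw, index=idx, columns=idx),
        p_bh=pd.DataFrame(p_bh, index=idx, columns=idx),
        n_obs=pd.DataFrame(n_shared, index=idx, columns=idx),
    )


def hierarchical_order(corr: CorrelationMatrix, linkage: str = "average"):
    """Agglomerative clustering on distance 1 - Rs; returns (leaf order, Z).

    Variables with any missing correlation are dropped with a warning before
    clustering. ``Z`` is the scipy linkage matrix for dendrogram export.
    """
    rs = corr.rs
    bad = rs.isna().any(axis=1)
    if bad.any():
        log.warning("hierarchical_order: dropping %d variables with missing correlations",
                    int(bad.sum()))
        rs = rs.loc[~bad, ~bad.to_numpy()]
    d = 1.0 - rs.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize against fp noise
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    order = [rs.columns[i] for i in hierarchy.leaves_list(z)]
    return order, z


@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # variables x components (orthonormal)
    explained_fraction: np.ndarray


def pca_summary(matrix) -> PcaResult:
    """Column-centered SVD principal components of a complete matrix."""
    df = _values_of(matrix)
    if len(df) < 2:
        raise ValueError("PCA needs at least 2 samples")
    if df.isna().any().any():
        raise ValueError("PCA requires a complete (imputed) matrix")
    x = df.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    frac = s**2 / (s**2).sum() if (s**2).sum() > 0 else np.zeros_like(s)
    comps = [f"PC{i + 1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(u * s, index=df.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=df.columns, columns=comps),
        explained_fraction=frac,
    )


@dataclass
class Network:
    """Thresholded correlation graph (undirected, |Rs| edge weights)."""

    graph: nx.Graph
    threshold: float
    fdr_level: float | None

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(corr: CorrelationMatrix, threshold: float = 0.5,
                  fdr_level: float | None = 0.05, absolute: bool = True) -> Network:
    """Edges where |Rs| >= threshold (signed Rs if ``absolute=False``) and,
    when ``fdr_level`` is set, p_BH < fdr_level. All variables stay as nodes."""
    rs = corr.rs.to_numpy()
    p_bh = corr.p_bh.to_numpy()
    cols = list(corr.rs.columns)
    g = nx.Graph()
    g.add_nodes_from(cols)
    m = len(cols)
    for i in range(m):
        for j in range(i + 1, m):
            r = rs[i, j]
            if np.isnan(r):
                continue
            strength = abs(r) if absolute else r
            if strength < threshold:
                continue
            if fdr_level is not None:
                q = p_bh[i, j]
                if np.isnan(q) or q >= fdr_level:
                    continue
            g.add_edge(cols[i], cols[j], weight=abs(r), rs=float(r))
    return Network(g, threshold, fdr_level)


SWEEP_STATS = ["density", "clustering_coefficient", "average_degree",
               "average_path_length", "n_components", "n_edges"]


def _graph_stats(g: nx.Graph) -> dict:
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0 or e == 0:
        return dict(density=0.0, clustering_coefficient=0.0, average_degree=0.0,
                    average_path_length=np.nan, n_components=0 if n == 0 else n,
                    n_edges=0)
    comps = list(nx.connected_components(g))
    # path length averaged within components, weighted by node-pair counts
    num = den = 0.0
    for comp in comps:
        k = len(comp)
        if k < 2:
            continue
        sub = g.subgraph(comp)
        num += nx.average_shortest_path_length(sub) * k * (k - 1) / 2
        den += k * (k - 1) / 2
    return dict(
        density=nx.density(g),
        clustering_coefficient=nx.average_clustering(g),
        average_degree=2.0 * e / n,
        average_path_length=num / den if den else np.nan,
        n_components=len(comps),
        n_edges=e,
    )


def property_sweep(values: pd.DataFrame, thresholds=None, n_random: int = 100,
                   seed: int | None = None) -> pd.DataFrame:
    """Network statistics vs correlation threshold, observed and randomized.

    For each threshold the |Rs|-thresholded graph (no FDR gate, so threshold
    0 gives the complete graph) is summarized by six statistics; the same is
    done for ``n_random`` data randomizations in which every column is
    permuted independently (destroying correlation, preserving marginals),
    and the randomized statistics are averaged. Empty graphs report 0 for
    counts/density and NaN for path length.
    """
    values = _values_of(values)
    if values.isna().any().any():
        raise ValueError("property_sweep requires a complete matrix")
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.01), 10)
    rng = np.random.default_rng(seed)
    ranks = np.apply_along_axis(stats.rankdata, 0, values.to_numpy(dtype=float))
    cols = list(values.columns)

    def curves(rank_mat, kind):
        rs = np.corrcoef(rank_mat, rowvar=False)
        np.fill_diagonal(rs, 0.0)
        rows = []
        for thr in thresholds:
            g = nx.Graph()
            g.add_nodes_from(cols)
            ii, jj = np.where(np.triu(np.abs(rs) >= thr, k=1))
            g.add_edges_from((cols[i], cols[j]) for i, j in zip(ii, jj))
            rows.append({"kind": kind, "threshold": float(thr), **_graph_stats(g)})
        return pd.DataFrame(rows)

    observed = curves(ranks, "observed")
    randoms = []
    for _ in range(n_random):
        shuffled = np.column_stack([rng.permutation(ranks[:, j])
                                    for j in range(ranks.shape[1])])
        randoms.append(curves(shuffled, "random"))
    random_mean = (
        pd.concat(randoms).groupby("threshold", as_index=False)[SWEEP_STATS].mean()
    )
    random_mean.insert(0, "kind", "random_mean")
    return pd.concat([observed, random_mean], ignore_index=True)
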