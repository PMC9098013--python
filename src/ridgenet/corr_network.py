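"""STOCSY-style correlation network for metabolite annotation.

Multiplet components of one compound rise and fall together, so their
time-series intensities are near-perfectly rank-correlated.  Concatenating
each feature's (gap-filled) intensities across experiments in a fixed
experiment order, taking Spearman correlations between all pairs, keeping
the largest fraction (default top 10%, signed) as edges, and partitioning
the resulting graph with the Markov Clustering Algorithm groups multiplets
of one compound into clusters ready for spectral-database lookup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .ridge_io import RidgeCollection, FeatureMatchTable

__all__ = [
    "CorrelationNetwork",
    "concatenated_intensities",
    "spearman_matrix",
    "threshold_top_fraction",
    "mcl_cluster",
    "cluster_report",
]


@dataclass
class CorrelationNetwork:
    node_ids: list[str]
    edges: list[tuple[int, int, float]]          # (i, j, spearman rho), i < j
    node_meta: dict[str, dict] = field(default_factory=dict)
    cluster_labels: dict[str, int] = field(default_factory=dict)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for nid in self.node_ids:
            g.add_node(nid, **self.node_meta.get(nid, {}))
        for i, j, rho in self.edges:
            g.add_edge(self.node_ids[i], self.node_ids[j], rho=float(rho))
        return g

    def write_graphml(self, path) -> None:
        g = self.to_graph()
        for nid, c in self.cluster_labels.items():
            g.nodes[nid]["cluster"] = int(c)
        for n, data in g.nodes(data=True):
            for k in list(data):
                if data[k] is None:
                    del data[k]
        nx.write_graphml(g, path)

    def write_edge_list(self, path) -> None:
        rows = [
            {"node_i": self.node_ids[i], "node_j": self.node_ids[j], "rho": rho}
            for i, j, rho in self.edges
        ]
        pd.DataFrame(rows, columns=["node_i", "node_j", "rho"]).to_csv(
            path, sep="\t", index=False
        )


def concatenated_intensities(
    coll: RidgeCollection,
    match_table: FeatureMatchTable,
) -> tuple[list[str], np.ndarray, dict[str, dict]]:
    """Concatenate each matched feature's intensities across experiments.

    Experiments are taken in sorted id order; only groups observed in every
    experiment contribute (equal concatenated lengths).  Returns node ids
    (``g<group_id>``), the (n_nodes, total_time) intensity matrix, and node
    metadata (mean ppm, compound, annotation status).
    """
    exp_ids = sorted(coll.experiments)
    node_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta: dict[str, dict] = {}
    for g in match_table.groups:
        by_exp = {e: f for e, f in g.members}
        if set(exp_ids) - set(by_exp):
            continue
        series = [coll.experiments[e].ridges[by_exp[e]].intensity_trace for e in exp_ids]
        cat = np.concatenate(series)
        if np.isnan(cat).any():
            continue
        nid = f"g{g.group_id}"
        node_ids.append(nid)
        rows.append(cat)
        levels = [
            coll.experiments[e].ridges[by_exp[e]].annotation.confidence_level
            for e, f in g.members
            if coll.experiments[e].ridges[by_exp[e]].annotation is not None
        ]
        meta[nid] = {
            "mean_ppm": g.representative_ppm,
            "compound": g.compound,
            "level": max(levels) if levels else None,
        }
    return node_ids, np.vstack(rows) if rows else np.empty((0, 0)), meta


def spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rho of rows, average ranks on ties.

    Rows with zero variance get NaN correlations (they stay in the network
    as isolated nodes).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n == 0:
        return np.empty((0, 0))
    rho = stats.spearmanr(X.T).statistic if n > 2 else None
    if n <= 2:
        rho = np.ones((n, n))
        if n == 2:
            r = stats.spearmanr(X[0], X[1]).statistic
            rho[0, 1] = rho[1, 0] = r
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    np.fill_diagonal(rho, 1.0)
    return rho


def threshold_top_fraction(
    corr: np.ndarray,
    node_ids: list[str] | None = None,
    fraction: float = 0.10,
    node_meta: dict[str, dict] | None = None,
    absolute: bool = False,
) -> CorrelationNetwork:
    """Keep the top ``fraction`` of pairs ranked by correlation.

    Ranking is by signed rho by default — multiplets of one compound
    co-vary positively; set ``absolute=True`` to rank by |rho|.  The number
    of retained edges is ceil(fraction * n_pairs).  Undefined (NaN)
    correlations are never retained.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    pairs = [
        (i, j, corr[i, j])
        for i in range(n)
        for j in range(i + 1, n)
        if not math.isnan(corr[i, j])
    ]
    n_keep = math.ceil(fraction * (n * (n - 1) // 2))
    key = (lambda p: abs(p[2])) if absolute else (lambda p: p[2])
    pairs.sort(key=lambda p: (-key(p), p[0], p[1]))
    return CorrelationNetwork(
        node_ids=list(node_ids),
        edges=pairs[:n_keep],
        node_meta=dict(node_meta or {}),
    )


def mcl_cluster(
    net: CorrelationNetwork,
    granularity: float = 5.0,
    expansion: int = 2,
    prune: float = 1e-8,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> dict[str, int]:
    """Markov clustering of the correlation network.

    Classic MCL on the edge-weight matrix: add a self-loop per node with
    weight equal to its maximum incident weight (regularization), normalize
    columns to a stochastic matrix, then alternate expansion (matrix power)
    and inflation (entrywise power ``granularity``, renormalize), pruning
    entries below ``prune``, until the iterate is idempotent within ``tol``.
    Clusters are read off the attractors (nodes with positive diagonal
    mass); negative retained correlations are clipped to zero for the
    transition matrix.  Deterministic for a fixed node order; cluster ids
    are assigned by smallest member index.  Singletons keep their own
    cluster label.
    """
    n = len(net.node_ids)
    labels: dict[str, int] = {}
    if n == 0:
        return labels
    W = np.zeros((n, n))
    for i, j, rho in net.edges:
        w = max(rho, 0.0)
        W[i, j] = W[j, i] = w
    diag = W.max(axis=0)
    diag[diag <= 0] = 1.0  # isolated nodes: unit self-loop
    np.fill_diagonal(W, diag)

    M = W / W.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        M2 = np.linalg.matrix_power(M, expansion)
        M2 = M2**granularity
        M2[M2 < prune] = 0.0
        colsum = M2.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M2 /= colsum
        if np.max(np.abs(M2 - M)) < tol:
            M = M2
            break
        M = M2
    else:
        raise RuntimeError(
            f"MCL did not converge in {max_iter} iterations "
            f"(residual {np.max(np.abs(M2 - M)):.2e})"
        )

    # attractors have positive diagonal mass; each attractor's row spans its
    # cluster, and overlapping attractor rows are merged
    attractors = np.flatnonzero(np.diag(M) > prune)
    assigned = np.full(n, -1)
    clusters: list[set[int]] = []
    for a in attractors:
        members = set(np.flatnonzero(M[a] > prune)) | {int(a)}
        merged = None
        for c in clusters:
            if c & members:
                c |= members
                merged = c
                break
        if merged is None:
            clusters.append(members)
    # repeated merge pass in case a later attractor bridged two clusters
    changed = True
    while changed:
        changed = False
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                if clusters[x] & clusters[y]:
                    clusters[x] |= clusters[y]
                    del clusters[y]
                    changed = True
                    break
            if changed:
                break
    for c in clusters:
        for m in c:
            assigned[m] = min(c)
    for i in range(n):
        if assigned[i] < 0:
            assigned[i] = i
    # relabel 0..K-1 in order of smallest member
    remap = {old: new for new, old in enumerate(sorted(set(assigned)))}
    for i, nid in enumerate(net.node_ids):
        labels[nid] = remap[int(assigned[i])]
    net.cluster_labels = labels
    return labels


def cluster_report(net: CorrelationNetwork, min_size: int = 2) -> pd.DataFrame:
    """Per-cluster summary for manual database lookup.

    One row per cluster of size >= ``min_size``: sorted member ppm list and
    member counts by annotation status — annotated (confident prior
    annotation), consistent (matches a known compound's reference peaks but
    overlapped), unannotated.  When every annotated member agrees on one
    compound, that name is propagated as the cluster label.
    """
    if not net.cluster_labels:
        raise ValueError("run mcl_cluster first")
    by_cluster: dict[int, list[str]] = {}
    for nid, c in net.cluster_labels.items():
        by_cluster.setdefault(c, []).append(nid)
    rows = []
    for c in sorted(by_cluster):
        members = by_cluster[c]
        if len(members) < min_size:
            continue
        ppms = sorted(
            net.node_meta.get(m, {}).get("mean_ppm")
            for m in members
            if net.node_meta.get(m, {}).get("mean_ppm") is not None
        )
        n_annot = n_consistent = n_unannot = 0
        compounds = set()
        for m in members:
            meta = net.node_meta.get(m, {})
            comp, level = meta.get("compound"), meta.get("level")
            if comp and (level or 3) >= 3:
                n_annot += 1
                compounds.add(comp)
            elif comp:
                n_consistent += 1
                compounds.add(comp)
            else:
                n_unannot += 1
        rows.append(
            {
                "cluster_id": c,
                "size": len(members),
                "ppm_list": ",".join(f"{p:.4f}" for p in ppms),
                "n_annotated": n_annot,
                "n_consistent": n_consistent,
                "n_unannotated": n_unannot,
                "compound": compounds.pop() if len(compounds) == 1 else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size", "ppm_list",
            "n_annotated", "n_consistent", "n_unannotated", "compound",
        ],
    )


def n_multinode_clusters(labels: dict[str, int]) -> int:
    """Count clusters with at least two members (singletons excluded)."""
    counts: dict[int, int] = {}
    for c in labels.values():
        counts[c] = counts.get(c, 0) + 1
    return sum(1 for v in counts.values() if v >= 2)
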