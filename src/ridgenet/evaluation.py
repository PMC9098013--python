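"""Scoring inferred networks and clusters against benchmark ground truth.

Edge inference is scored at the *compound* level: predicted signal-level
edges are collapsed to unique compound pairs through the signal map, and

    precision = N_tp / N_pp        recall = N_tp / N_cp

where N_pp counts predicted compound pairs, N_tp those that are true
edges, and N_cp the conditional positives — true edges with both endpoint
compounds observable (edges touching an unobservable compound cannot be
recovered and are excluded from recall's denominator).

Cluster recovery is scored at the *signal* level with the match ratio: for
each true cluster (expressed as all signals of its observable member
compounds), the estimated cluster with the largest overlap is selected and

    R = N_overlap / N_cluster

with N_cluster the selected estimated cluster's size.  The random baseline
is the expected match ratio of uniformly random signal groups of the
observed estimated-cluster sizes (Monte Carlo).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark_sim import GroundTruthNetwork, SimulatedDataset
from .kinetic_network import FunctionalNetwork

__all__ = [
    "EvalReport",
    "edge_precision_recall",
    "cluster_match_ratio",
    "random_baseline",
    "evaluate_dataset",
    "benchmark_report",
]


@dataclass
class EvalReport:
    n_tp: int
    n_pp: int
    n_cp: int
    precision: float | None          # None when N_pp = 0 (undefined)
    recall: float
    match_ratios: list[float] = field(default_factory=list)
    random_baselines: list[float] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def collapse_to_compound_pairs(
    edges: set[frozenset], signal_to_compound: dict[str, int]
) -> set[frozenset]:
    """Map signal-level edges to unique compound pairs; self-pairs (two
    signals of one compound) are dropped."""
    out: set[frozenset] = set()
    for e in edges:
        a, b = tuple(e)
        ca, cb = signal_to_compound[a], signal_to_compound[b]
        if ca != cb:
            out.add(frozenset((ca, cb)))
    return out


def edge_precision_recall(
    predicted: FunctionalNetwork,
    truth: GroundTruthNetwork,
    signal_to_compound: dict[str, int],
    observable: np.ndarray,
) -> tuple[float | None, float, dict[str, int]]:
    pred_pairs = collapse_to_compound_pairs(predicted.edge_set(), signal_to_compound)
    cond_pos = {
        e for e in truth.adjacency if all(observable[n] for n in e)
    }
    n_pp = len(pred_pairs)
    n_tp = len(pred_pairs & cond_pos)
    n_cp = len(cond_pos)
    precision = n_tp / n_pp if n_pp else None
    recall = n_tp / n_cp if n_cp else 0.0
    return precision, recall, {"n_tp": n_tp, "n_pp": n_pp, "n_cp": n_cp}


def cluster_match_ratio(
    estimated_labels: dict[str, int],
    true_compounds: set[int],
    signal_to_compound: dict[str, int],
    observable: np.ndarray,
) -> float:
    """Best-overlap match ratio of one true cluster, at signal level.

    Ties in overlap resolve to the larger estimated cluster, then to the
    smaller cluster id.  No estimated clusters -> 0.
    """
    true_signals = {
        s for s, c in signal_to_compound.items() if c in true_compounds and observable[c]
    }
    clusters: dict[int, set[str]] = {}
    for s, cid in estimated_labels.items():
        clusters.setdefault(cid, set()).add(s)
    if not clusters or not true_signals:
        return 0.0
    best = max(
        clusters.items(),
        key=lambda kv: (len(kv[1] & true_signals), len(kv[1]), -kv[0]),
    )
    return len(best[1] & true_signals) / len(best[1])


def random_baseline(
    true_cluster_size: int,
    n_observed_signals: int,
    cluster_sizes: list[int],
    seed: int = 0,
    n_draws: int = 10_000,
) -> float:
    """Expected match ratio of random signal groups, by Monte Carlo.

    Groups of the observed estimated-cluster sizes are drawn uniformly
    without replacement from the observed signals; for each draw the best
    group is selected the same way as for estimated clusters and its match
    ratio recorded.  For a single group of size g the expectation is the
    hypergeometric mean overlap m*g/M divided by g, i.e. m/M.
    """
    if true_cluster_size == 0:
        return 0.0
    if true_cluster_size >= n_observed_signals:
        return 1.0
    rng = np.random.default_rng(seed)
    m, M = true_cluster_size, n_observed_signals
    sizes = [min(s, M) for s in cluster_sizes if s > 0] or [1]
    ratios = np.empty(n_draws)
    for i in range(n_draws):
        perm = rng.permutation(M)
        best_overlap, best_size = -1, 1
        start = 0
        for g in sizes:
            grp = perm[start : start + g] if start + g <= M else rng.permutation(M)[:g]
            start += g
            overlap = int((grp < m).sum())
            if (overlap, g) > (best_overlap, best_size):
                best_overlap, best_size = overlap, g
        ratios[i] = best_overlap / best_size
    return float(ratios.mean())


def evaluate_dataset(
    dataset: SimulatedDataset,
    predicted: FunctionalNetwork,
    estimated_labels: dict[str, int] | None = None,
    seed: int = 0,
    metadata: dict | None = None,
) -> EvalReport:
    """Full scoring of one benchmark run: edges plus per-true-cluster
    match ratios and their random baselines."""
    s2c = dataset.signal_to_compound()
    precision, recall, counts = edge_precision_recall(
        predicted, dataset.truth, s2c, dataset.observable
    )
    match_ratios: list[float] = []
    baselines: list[float] = []
    if estimated_labels is not None:
        observed_signals = {s for s, c in s2c.items() if dataset.observable[c]}
        sizes: dict[int, int] = {}
        for s, cid in estimated_labels.items():
            sizes[cid] = sizes.get(cid, 0) + 1
        size_list = sorted(sizes.values(), reverse=True)
        for true_cluster in dataset.truth.true_clusters():
            match_ratios.append(
                cluster_match_ratio(estimated_labels, true_cluster, s2c, dataset.observable)
            )
            true_sig = sum(
                1 for s, c in s2c.items() if c in true_cluster and dataset.observable[c]
            )
            baselines.append(
                random_baseline(
                    true_sig, len(observed_signals), size_list, seed=seed, n_draws=2000
                )
            )
    return EvalReport(
        n_tp=counts["n_tp"],
        n_pp=counts["n_pp"],
        n_cp=counts["n_cp"],
        precision=precision,
        recall=recall,
        match_ratios=match_ratios,
        random_baselines=baselines,
        metadata=metadata or {},
    )


def benchmark_study(
    seed: int,
    n_networks: int = 5,
    condition_levels: tuple[int, ...] = (2, 4, 8),
    n_nodes: int = 30,
    cluster_sizes: tuple[int, ...] = (12, 6, 6),
    redundant_signals: bool = False,
    prescreen_k: int = 10,
    dense_factor: int = 2,
) -> pd.DataFrame:
    """The full simulate → infer → cluster → score study, aggregated.

    Simulates ``n_networks`` random clustered mass-action systems, infers
    and clusters the functional network at each condition-count level
    (condition sets are nested, so levels are paired per network), and
    returns the aggregate table from :func:`benchmark_report`.  The
    default scale (30 nodes, clusters 12/6/6, five networks) is the
    package's standard demonstration configuration.
    """
    from . import benchmark_sim, kinetic_network

    config = benchmark_sim.SimulationConfig(redundant_signals=redundant_signals)
    runs: list[tuple[int, EvalReport]] = []
    for i in range(n_networks):
        for n_cond in condition_levels:
            ds = benchmark_sim.generate_benchmark_network(
                n_nodes, cluster_sizes, n_cond, seed + 7919 * i, config
            )
            env_data = kinetic_network.prepare_environments(
                ds.environments, dense_factor=dense_factor
            )
            net = kinetic_network.infer_network(env_data, prescreen_k=prescreen_k)
            labels = kinetic_network.community_cluster(net)
            runs.append(
                (
                    n_cond,
                    evaluate_dataset(
                        ds, net, labels, seed=seed,
                        metadata={"network": i, "n_conditions": n_cond},
                    ),
                )
            )
    return benchmark_report(runs)


def benchmark_report(runs: list[tuple[int, EvalReport]]) -> pd.DataFrame:
    """Aggregate mean and two standard errors versus condition count.

    ``runs`` is a list of (n_conditions, report).  Undefined precisions are
    dropped from their aggregates.
    """
    rows = []
    by_cond: dict[int, list[EvalReport]] = {}
    for n_cond, rep in runs:
        by_cond.setdefault(n_cond, []).append(rep)

    def mean_se(vals: list[float]) -> tuple[float, float]:
        arr = np.array(vals, dtype=float)
        if arr.size == 0:
            return float("nan"), float("nan")
        se = 2 * arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
        return float(arr.mean()), float(se)

    n_clusters = max(
        (len(r.match_ratios) for reps in by_cond.values() for r in reps), default=0
    )
    for n_cond in sorted(by_cond):
        reps = by_cond[n_cond]
        mp, sp = mean_se([r.precision for r in reps if r.precision is not None])
        mr, sr = mean_se([r.recall for r in reps])
        row = {
            "n_conditions": n_cond,
            "mean_precision": mp,
            "se2_precision": sp,
            "mean_recall": mr,
            "se2_recall": sr,
        }
        for c in range(n_clusters):
            mm, sm = mean_se([r.match_ratios[c] for r in reps if len(r.match_ratios) > c])
            mb, _ = mean_se([r.random_baselines[c] for r in reps if len(r.random_baselines) > c])
            row[f"mean_R_c{c + 1}"] = mm
            row[f"se2_R_c{c + 1}"] = sm
            row[f"baseline_c{c + 1}"] = mb
        rows.append(row)
    return pd.DataFrame(rows)
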