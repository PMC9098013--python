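"""Stability-based inference of a functional network from metabolic dynamics.

The model class links one feature's *rate of change* to other features'
concentrations: dX_T/dt = f(X_S), with the same dependency required to
hold across experimental conditions (environments).  For each target
feature, candidate models with at most two terms — single covariates or
pairwise interaction products — over a prescreened covariate set are
scored by leave-one-environment-out prediction: fit a linear
derivative-mode regression on the held-in environments, integrate the
fitted derivative along the held-out environment's grid from the observed
initial value, and measure the normalized mean squared error against the
held-out smoothed trajectory.  Lower scores mean models that are both
predictive and stable across conditions.  A covariate's importance is its
best score over models containing it; its significance comes from a
one-sided rank-sum comparison of scores of containing vs non-containing
models, and covariates with p < alpha become (undirected) edges.

Communities in the resulting network are found by greedy modularity
maximization, and edge/cluster stability is assessed by bootstrapping
replicate curves within each environment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from networkx.algorithms import community as nx_community
from scipy import stats

from . import fda_smooth
from .ridge_io import Experiment, RidgeCollection, TimeGrid

__all__ = [
    "EnvironmentData",
    "CandidateModel",
    "FunctionalNetwork",
    "prepare_environments",
    "prescreen",
    "enumerate_models",
    "score_model",
    "rank_variables",
    "infer_network",
    "community_cluster",
    "bootstrap_support",
]


# ---------------------------------------------------------------------------
# Data preparation: smoothed values and derivatives per environment


@dataclass
class EnvironmentData:
    """Smoothed curves of one environment (condition), replicates pooled.

    ``values`` and ``derivs`` are (n_replicates, n_features, n_grid) arrays
    of smoothed concentrations and their first derivatives on the
    environment's evaluation grid.
    """

    environment_id: str
    feature_ids: list[str]
    grid: np.ndarray
    values: np.ndarray
    derivs: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    def resample_replicates(self, rep_idx: np.ndarray) -> "EnvironmentData":
        """Per-feature replicate resample: rep_idx is (n_features,) of
        replicate indices; feature f's curve is taken from replicate
        rep_idx[f] (complete time series resampled per feature)."""
        f = np.arange(len(self.feature_ids))
        vals = self.values[rep_idx, f, :][None, ...]
        ders = self.derivs[rep_idx, f, :][None, ...]
        return EnvironmentData(self.environment_id, self.feature_ids, self.grid, vals, ders)


def _smooth_experiment(
    exp: Experiment, feature_ids: list[str], dense_factor: int, lam: float | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    grid = exp.grid
    lo, hi = grid.domain
    dense = np.linspace(lo, hi, dense_factor * (len(grid) - 1) + 1)
    basis = fda_smooth.default_basis(grid)
    vals = np.empty((len(feature_ids), dense.size))
    ders = np.empty_like(vals)
    for i, fid in enumerate(feature_ids):
        y = exp.ridges[fid].intensity_trace
        if np.isnan(y).any():
            raise ValueError(f"feature {fid!r} has gaps; gap-fill first")
        if lam is None:
            fit = fda_smooth.select_lambda(y, grid, basis)
        else:
            fit = fda_smooth.penalized_fit(y, grid, basis, lam)
        vals[i] = fit(dense)
        ders[i] = fit(dense, deriv=1)
    return dense, vals, ders


def prepare_environments(
    environments: dict[str, list[Experiment]],
    dense_factor: int = 2,
    lam: float | None = None,
) -> list[EnvironmentData]:
    """Smooth every replicate of every environment onto a dense grid.

    Feature sets must agree across all experiments.  ``lam=None`` selects
    the penalty per curve by GCV.
    """
    env_data = []
    feature_ids: list[str] | None = None
    for env_id in sorted(environments):
        reps = environments[env_id]
        if not reps:
            raise ValueError(f"environment {env_id!r} has no replicates")
        fids = sorted(reps[0].ridges)
        if feature_ids is None:
            feature_ids = fids
        elif fids != feature_ids:
            raise ValueError("feature sets differ across environments")
        grids = [r.grid.times for r in reps]
        if not all(np.array_equal(g, grids[0]) for g in grids):
            raise ValueError(f"replicate grids differ within environment {env_id!r}")
        all_vals, all_ders = [], []
        for rep in reps:
            dense, vals, ders = _smooth_experiment(rep, feature_ids, dense_factor, lam)
            all_vals.append(vals)
            all_ders.append(ders)
        env_data.append(
            EnvironmentData(env_id, feature_ids, dense, np.array(all_vals), np.array(all_ders))
        )
    return env_data


# ---------------------------------------------------------------------------
# Candidate models


@dataclass(frozen=True)
class CandidateModel:
    """<= 2 terms; each term is a 1- or 2-covariate product.

    The target itself may appear in a term: mass-action consumption makes
    most derivatives depend on the target's own level, and allowing a
    self-term frees the other term to capture a genuine parent.  Self-terms
    never produce edges.
    """

    target: str
    terms: tuple[tuple[str, ...], ...]
    score: float = np.inf

    def __post_init__(self) -> None:
        if len(self.terms) > 2:
            raise ValueError("at most two terms per model")

    @property
    def covariates(self) -> frozenset[str]:
        """Covariates eligible for edges (the target excluded)."""
        return frozenset(c for t in self.terms for c in t if c != self.target)

    def reduced(self, cov: str) -> "CandidateModel":
        """The same model with covariate ``cov`` ablated from its terms."""
        terms = []
        for t in self.terms:
            rest = tuple(c for c in t if c != cov)
            if rest:
                terms.append(rest)
        return CandidateModel(self.target, tuple(terms))


def prescreen(
    target: str,
    env_data: list[EnvironmentData],
    k: int = 20,
) -> list[str]:
    """Rank covariates by pooled |corr(dX_T/dt, X_s)| and keep the top k."""
    fids = env_data[0].feature_ids
    ti = fids.index(target)
    dvals = np.concatenate([e.derivs[:, ti, :].ravel() for e in env_data])
    scores = []
    for si, s in enumerate(fids):
        if s == target:
            continue
        xs = np.concatenate([e.values[:, si, :].ravel() for e in env_data])
        if np.std(xs) == 0 or np.std(dvals) == 0:
            c = 0.0
        else:
            c = abs(float(np.corrcoef(dvals, xs)[0, 1]))
        scores.append((s, c))
    scores.sort(key=lambda t: (-t[1], t[0]))
    return [s for s, _ in scores[:k]]


def enumerate_models(
    target: str,
    covariates: list[str],
    max_terms: int = 2,
    interactions: bool = True,
    include_self: bool = False,
) -> list[CandidateModel]:
    """All models with <= max_terms terms over the covariate pool.

    Terms are single covariates and, when ``interactions`` is on, pairwise
    products X_s * X_u.  Multi-term models combine single-covariate terms;
    an interaction product occupies a model on its own (two covariates is
    already the complexity cap).  ``include_self`` adds the target to the
    pool so consumption terms can be represented.
    """
    pool = ([target] if include_self else []) + [c for c in covariates if c != target]
    singles: list[tuple[str, ...]] = [(c,) for c in pool]
    models: list[CandidateModel] = []
    for r in range(1, max_terms + 1):
        for combo in itertools.combinations(singles, r):
            models.append(CandidateModel(target, combo))
    if interactions:
        for a, b in itertools.combinations(pool, 2):
            models.append(CandidateModel(target, ((a, b),)))
    return models


# ---------------------------------------------------------------------------
# Scoring


def _term_matrix(env: EnvironmentData, rep: int, terms) -> np.ndarray:
    """Design columns (n_grid, n_terms) for one replicate: products of the
    member covariates' smoothed values."""
    fidx = {f: i for i, f in enumerate(env.feature_ids)}
    cols = []
    for term in terms:
        col = np.ones(env.grid.size)
        for c in term:
            col = col * env.values[rep, fidx[c], :]
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((env.grid.size, 0))


def _integrate_rate(grid: np.ndarray, rate: np.ndarray, x0: float, refine: int = 4) -> np.ndarray:
    """Trajectory x(t) = x0 + int rate dt on ``grid``.

    The fitted rate does not depend on x itself, so fixed-step RK4 on a
    ``refine``-times finer grid reduces to composite quadrature of the
    linearly interpolated rate; cumulative trapezoid on the refined grid is
    that quadrature.
    """
    fine = np.linspace(grid[0], grid[-1], refine * (grid.size - 1) + 1)
    rate_fine = np.interp(fine, grid, rate)
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate_fine[1:] + rate_fine[:-1]) * np.diff(fine))]
    )
    return x0 + cum[:: refine]


def score_model_per_env(
    model: CandidateModel,
    env_data: list[EnvironmentData],
    refine: int = 4,
) -> np.ndarray:
    """Vector of per-environment stability scores.

    The model's coefficients are estimated *once* by regressing the
    target's smoothed derivative on the term columns pooled over all
    environments and replicates (with intercept) — the stability
    assumption made explicit: one set of kinetics must serve every
    condition.  Each environment is then scored by integrating the fitted
    derivative along its grid from each replicate's observed initial
    value and taking the mean squared error against the smoothed
    trajectory, normalized by the target's variance in that environment.
    0 means the integrated model reproduces the environment's trajectory
    exactly; a model whose true relationship shifts between conditions
    scores poorly in most of them.  Singular designs score +inf.
    """
    if len(env_data) < 2:
        raise ValueError("stability scoring requires >= 2 environments")
    fids = env_data[0].feature_ids
    ti = fids.index(model.target)
    rows_X, rows_y = [], []
    for env in env_data:
        for rep in range(env.n_replicates):
            T = _term_matrix(env, rep, model.terms)
            rows_X.append(np.column_stack([np.ones(env.grid.size), T]))
            rows_y.append(env.derivs[rep, ti, :])
    X = np.vstack(rows_X)
    yv = np.concatenate(rows_y)
    beta, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    if rank < X.shape[1]:
        return np.full(len(env_data), np.inf)
    scores = []
    for env in env_data:
        errs = []
        target_var = float(np.var(env.values[:, ti, :]))
        scale = float(np.mean(env.values[:, ti, :] ** 2))
        if target_var <= 1e-12 * max(scale, 1e-300):
            # (near-)constant target: judge by absolute error instead
            target_var = 1.0
        for rep in range(env.n_replicates):
            T = _term_matrix(env, rep, model.terms)
            rate = beta[0] + T @ beta[1:]
            traj = _integrate_rate(env.grid, rate, env.values[rep, ti, 0], refine)
            errs.append(float(np.mean((traj - env.values[rep, ti, :]) ** 2)))
        scores.append(np.mean(errs) / target_var)
    return np.asarray(scores)


def score_model(
    model: CandidateModel,
    env_data: list[EnvironmentData],
    refine: int = 4,
) -> float:
    """Mean of the per-environment stability scores (lower is better)."""
    return float(np.mean(score_model_per_env(model, env_data, refine)))


@dataclass
class EdgeScore:
    target: str
    covariate: str
    importance: float
    p_value: float


def stability_edge_scores(
    target: str,
    models: list[CandidateModel],
    env_scores: np.ndarray,
    top_frac: float = 0.05,
    min_top: int = 5,
    dominance: float = 0.1,
) -> list[EdgeScore]:
    """Covariate significance from the stability ranking of models.

    For every environment the candidate models are ranked by that
    environment's score and the top ``q`` inspected; a covariate's
    evidence is the number of top models containing it, *averaged over
    environments*.  Averaging rewards covariates near the top of every
    condition's ranking and discounts ones that dominate a single
    environment.  Because the per-environment rankings share one pooled
    fit, the averaged count is compared against the null of a single
    ranking: p = P[X >= x̄] for X ~ hypergeometric(N models, K
    containing, q drawn), linearly interpolated between the integers
    bracketing x̄ — a deliberately conservative calibration whose
    false-positive rate falls as the rankings concentrate with added
    conditions.

    Rank statistics cannot see score *magnitudes*, so a single decisively
    dominant model (typical for noiseless, identifiable systems) is
    handled separately: if the best model containing the covariate beats
    the best model without it by a factor ``1/dominance`` in *every*
    environment, the covariate is promoted (reported p = 1/N).  Importance
    is the covariate's best median score.
    """
    S = np.asarray(env_scores, dtype=float)
    N, E = S.shape
    if N != len(models):
        raise ValueError("env_scores rows must match the model list")
    q = max(min_top, int(np.ceil(top_frac * N)))
    consensus = np.median(S, axis=1)
    tops = [set(np.argsort(S[:, e], kind="stable")[:q].tolist()) for e in range(E)]
    covs = sorted({c for m in models for c in m.covariates})
    out = []
    for c in covs:
        mask = np.array([c in m.covariates for m in models])
        K = int(mask.sum())
        if K == 0 or K == N:
            out.append(EdgeScore(target, c, float("inf"), 1.0))
            continue
        xbar = float(
            np.mean([sum(1 for i in top if mask[i]) for top in tops])
        )
        lo = int(np.floor(xbar))
        frac = xbar - lo
        p = float(
            (1 - frac) * stats.hypergeom.sf(lo - 1, N, K, q)
            + frac * stats.hypergeom.sf(lo, N, K, q)
        )
        with np.errstate(invalid="ignore"):
            best_with = S[mask].min(axis=0)       # per environment
            best_without = S[~mask].min(axis=0)
        decisive = bool(
            np.all(np.isfinite(best_with))
            and np.all(best_with <= dominance * best_without)
            and np.any(best_without > 0)
        )
        if decisive:
            p = min(p, 1.0 / N)
        importance = float(consensus[mask].min())
        out.append(EdgeScore(target, c, importance, p))
    return out


def rank_variables(
    target: str,
    scored: list[CandidateModel],
    min_group: int = 3,
) -> list[EdgeScore]:
    """Importance and significance per covariate from the model score table.

    importance = best (lowest) score among models containing the covariate;
    p_value = one-sided Mann–Whitney rank-sum test that containing models
    score lower than non-containing models.  Fewer than ``min_group``
    models on either side gives p = 1 (insufficient evidence).
    """
    all_scores = np.array([m.score for m in scored])
    finite = np.isfinite(all_scores)
    covs = sorted({c for m in scored for c in m.covariates})
    out = []
    for cov in covs:
        mask = np.array([cov in m.covariates for m in scored])
        with_c = all_scores[mask & finite]
        without_c = all_scores[~mask & finite]
        importance = float(with_c.min()) if with_c.size else float("inf")
        if with_c.size < min_group or without_c.size < min_group:
            p = 1.0
        else:
            p = float(
                stats.mannwhitneyu(with_c, without_c, alternative="less").pvalue
            )
        out.append(EdgeScore(target, cov, importance, p))
    return out


# ---------------------------------------------------------------------------
# Network assembly


@dataclass
class FunctionalNetwork:
    node_ids: list[str]
    edges: dict[frozenset, dict] = field(default_factory=dict)
    cluster_labels: dict[str, int] = field(default_factory=dict)
    cocluster_frequency: np.ndarray | None = None

    def add_edge(self, a: str, b: str, importance: float, p_value: float) -> None:
        key = frozenset((a, b))
        prev = self.edges.get(key)
        if prev is None or p_value < prev["p_value"]:
            self.edges[key] = {
                "importance": importance,
                "p_value": p_value,
                "support": None,
                "supported": None,
            }

    def edge_set(self) -> set[frozenset]:
        return set(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for key, attrs in self.edges.items():
            a, b = sorted(key)
            g.add_edge(a, b, **{k: v for k, v in attrs.items() if v is not None})
        return g

    def write_graphml(self, path) -> None:
        g = self.to_graph()
        for nid, c in self.cluster_labels.items():
            g.nodes[nid]["cluster"] = int(c)
        nx.write_graphml(g, path)

    def write_clusters(self, path) -> None:
        rows = [
            {"feature_id": nid, "cluster_id": c}
            for nid, c in sorted(self.cluster_labels.items())
        ]
        pd.DataFrame(rows, columns=["feature_id", "cluster_id"]).to_csv(
            path, sep="\t", index=False
        )

    def write_cocluster_matrix(self, path) -> None:
        if self.cocluster_frequency is None:
            raise ValueError("no bootstrap cocluster matrix available")
        pd.DataFrame(
            self.cocluster_frequency, index=self.node_ids, columns=self.node_ids
        ).to_csv(path)


def infer_network(
    env_data: list[EnvironmentData],
    alpha: float = 0.05,
    max_terms: int = 2,
    prescreen_k: int = 20,
    interactions: bool = True,
    refine: int = 4,
    ranking: str = "stability",
    include_self: bool = True,
) -> FunctionalNetwork:
    """Edge inference over all targets.

    For each feature as target: prescreen covariates, enumerate <=2-term
    candidate models (with interactions, and by default the target's own
    level as an allowed term), score each model by leave-one-environment-
    out prediction, rank covariates, and keep covariates with p < alpha.
    Target->covariate pairs are merged into an undirected edge set; an
    interaction term contributes an edge from the target to each covariate
    of the product.

    ``ranking`` selects the covariate significance statistic:
    ``"stability"`` (default) tests over-representation among the top
    models of every environment's ranking; ``"ranksum"`` compares mean
    scores of containing vs non-containing models with a one-sided
    Mann–Whitney test.
    """
    if len(env_data) < 2:
        raise ValueError("stability requires multiple conditions")
    if ranking not in ("stability", "ranksum"):
        raise ValueError(f"unknown ranking {ranking!r}")
    fids = env_data[0].feature_ids
    net = FunctionalNetwork(node_ids=list(fids))
    for target in fids:
        pool = prescreen(target, env_data, prescreen_k)
        models = enumerate_models(target, pool, max_terms, interactions, include_self)
        S = np.vstack([score_model_per_env(m, env_data, refine) for m in models])
        if ranking == "stability":
            edge_scores = stability_edge_scores(target, models, S)
        else:
            scored = [
                CandidateModel(m.target, m.terms, float(np.mean(s)))
                for m, s in zip(models, S)
            ]
            edge_scores = rank_variables(target, scored)
        for es in edge_scores:
            if es.p_value < alpha:
                net.add_edge(es.target, es.covariate, es.importance, es.p_value)
    return net


def community_cluster(net: FunctionalNetwork) -> dict[str, int]:
    """Greedy modularity communities of the unweighted topology.

    Agglomerative merging by best modularity gain until no merge improves
    modularity; isolated nodes come out as singletons.  Cluster ids are
    assigned by each community's smallest member id, making the labeling
    deterministic.
    """
    g = net.to_graph()
    nontrivial = [n for n in g if g.degree(n) > 0]
    labels: dict[str, int] = {}
    if nontrivial:
        sub = g.subgraph(nontrivial)
        comms = nx_community.greedy_modularity_communities(sub, weight=None)
        comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
        for cid, comm in enumerate(comms):
            for n in comm:
                labels[n] = cid
    next_id = len(set(labels.values()))
    for n in sorted(set(g) - set(labels)):
        labels[n] = next_id
        next_id += 1
    net.cluster_labels = labels
    return labels


def bootstrap_support(
    env_data: list[EnvironmentData],
    B: int = 100,
    seed: int = 0,
    support_cutoff: float = 0.40,
    alpha: float = 0.05,
    max_terms: int = 2,
    prescreen_k: int = 20,
    interactions: bool = True,
    refine: int = 4,
    base_net: FunctionalNetwork | None = None,
) -> FunctionalNetwork:
    """Bootstrap edge support and cocluster frequency.

    In each of ``B`` iterations, every feature independently draws one
    complete replicate curve (with replacement) per environment; the
    network is re-inferred and re-clustered on the resampled data.  Edge
    support is the fraction of iterations containing the edge;
    cocluster_frequency[i, j] is the fraction of iterations in which i and
    j share a community (diagonal defined as 1).  Edges of the base network
    with support >= ``support_cutoff`` are flagged supported.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if any(e.n_replicates < 1 for e in env_data):
        raise ValueError("each environment needs at least one replicate")
    rng = np.random.default_rng(seed)
    fids = env_data[0].feature_ids
    n = len(fids)
    if base_net is None:
        base_net = infer_network(
            env_data, alpha, max_terms, prescreen_k, interactions, refine
        )
        community_cluster(base_net)
    edge_counts: dict[frozenset, int] = {}
    cocluster = np.zeros((n, n))
    for _ in range(B):
        resampled = []
        for env in env_data:
            rep_idx = rng.integers(0, env.n_replicates, size=n)
            resampled.append(env.resample_replicates(rep_idx))
        bnet = infer_network(resampled, alpha, max_terms, prescreen_k, interactions, refine)
        labels = community_cluster(bnet)
        for key in bnet.edge_set():
            edge_counts[key] = edge_counts.get(key, 0) + 1
        lab = np.array([labels[f] for f in fids])
        cocluster += (lab[:, None] == lab[None, :]).astype(float)
    cocluster /= B
    np.fill_diagonal(cocluster, 1.0)
    out = FunctionalNetwork(node_ids=list(fids), cluster_labels=dict(base_net.cluster_labels))
    for key, attrs in base_net.edges.items():
        support = edge_counts.get(key, 0) / B
        out.edges[key] = {
            **attrs,
            "support": support,
            "supported": support >= support_cutoff,
        }
    out.cocluster_frequency = cocluster
    return out
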