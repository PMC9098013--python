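"""Benchmark generator: random clustered networks with mass-action dynamics.

Ground-truth networks are Erdős–Rényi-with-communities graphs: every node
pair gains an edge with a global probability, and pairs inside the same
planted cluster additionally with a higher within-cluster probability
(union of the two draws).  Each edge becomes either a chemical reaction or
a regulatory assignment; dynamics follow sums of regulated mass actions,

    dX_T/dt = sum_j s_j k_j* prod_h X_h ,   k* = k prod_r X_r^alpha_r

with stoichiometric factors s in {-1, +1}, rate constants k ~ U(0, 1),
regulator exponents alpha in {-1, +1}, optional reversibility, and a
fraction of reactions merged pairwise into two-reactant reactions.
Trajectories under per-condition U(0, 1) initial values are decorated the
way real NMR data is degraded: redundant signals per compound (multiplet
analogy), additive Gaussian noise scaled to each feature's dynamic range,
three replicates, and 50% random observability.  The output is packaged in
the ridge-table data model so every downstream module consumes it
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .ridge_io import Experiment, Ridge, RidgeCollection, TimeGrid

__all__ = [
    "GroundTruthNetwork",
    "Reaction",
    "SimulationConfig",
    "SimulatedDataset",
    "random_cluster_graph",
    "build_kinetics",
    "simulate",
    "add_noise",
    "add_redundant_signals",
    "mask_observability",
    "generate_benchmark",
]

CONC_FLOOR = 1e-6  # inside rate evaluation: keeps X_r^-1 regulators finite


@dataclass
class GroundTruthNetwork:
    n_nodes: int
    cluster_sizes: tuple[int, ...]
    adjacency: set[frozenset]                  # undirected edges {i, j}
    cluster_labels: dict[int, int | None]      # node -> cluster index or None

    def true_clusters(self) -> list[set[int]]:
        out: list[set[int]] = [set() for _ in self.cluster_sizes]
        for node, c in self.cluster_labels.items():
            if c is not None:
                out[c].add(node)
        return out


@dataclass(frozen=True)
class Reaction:
    reactants: tuple[int, ...]                       # 1-2 consumed nodes (s = -1)
    products: tuple[int, ...]                        # produced nodes (s = +1)
    k: float
    regulators: tuple[tuple[int, int], ...] = ()     # (node, alpha in {-1,+1})


@dataclass
class SimulationConfig:
    t_max: float = 5.0
    t_step: float = 0.2
    replicates: int = 3
    noise_coefficient: float = 0.02
    noise_floor: float = 1e-7
    redundancy_max: int = 5
    redundancy_factor_range: tuple[float, float] = (0.3, 3.0)
    observable_fraction: float = 0.5
    p_regulation: float = 0.2
    p_reversible: float = 0.3
    merge_fraction: float = 0.2
    redundant_signals: bool = True

    @property
    def grid(self) -> np.ndarray:
        n = int(round(self.t_max / self.t_step)) + 1
        return np.linspace(0.0, self.t_max, n)


@dataclass
class SimulatedDataset:
    truth: GroundTruthNetwork
    reactions: list[Reaction]
    signal_map: dict[int, list[tuple[str, float]]]   # node -> [(signal_id, factor)]
    observable: np.ndarray                           # bool per node
    collection: RidgeCollection = field(default_factory=RidgeCollection)
    environments: dict[str, list[Experiment]] = field(default_factory=dict)

    def signal_to_compound(self) -> dict[str, int]:
        return {sid: node for node, sigs in self.signal_map.items() for sid, _ in sigs}


def random_cluster_graph(
    n: int = 100,
    sizes: tuple[int, ...] = (40, 20, 20),
    p_in: float = 0.15,
    p_global: float = 0.015,
    seed: int | np.random.Generator = 0,
) -> GroundTruthNetwork:
    """Random graph with planted clusters.

    An edge appears between any pair with probability ``p_global`` and,
    independently, between same-cluster pairs with probability ``p_in``;
    the union of the two draws gives within-cluster edge probability
    1 - (1 - p_in)(1 - p_global).  Nodes beyond the listed cluster sizes
    remain unclustered background.
    """
    if sum(sizes) > n:
        raise ValueError("cluster sizes exceed node count")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels: dict[int, int | None] = {i: None for i in range(n)}
    start = 0
    for c, size in enumerate(sizes):
        for i in range(start, start + size):
            labels[i] = c
        start += size
    edges: set[frozenset] = set()
    for i in range(n):
        for j in range(i + 1, n):
            hit = rng.random() < p_global
            if labels[i] is not None and labels[i] == labels[j]:
                hit = hit or (rng.random() < p_in)
            if hit:
                edges.add(frozenset((i, j)))
    return GroundTruthNetwork(n, tuple(sizes), edges, labels)


def build_kinetics(
    graph: GroundTruthNetwork,
    seed: int | np.random.Generator = 0,
    p_regulation: float = 0.2,
    p_reversible: float = 0.3,
    merge_fraction: float = 0.2,
) -> list[Reaction]:
    """Turn graph edges into a regulated mass-action reaction system.

    Each edge independently becomes a reaction (probability
    1 - p_regulation) with uniformly random direction, or a regulatory
    assignment: one endpoint (uniform) regulates a random reaction incident
    to the other with exponent alpha in {-1, +1}.  Reactions are reversible
    with probability ``p_reversible`` (the reverse gets its own rate
    constant).  A ``merge_fraction`` of the single-reactant reactions is
    pairwise merged into two-reactant reactions.  All k ~ U(0, 1).
    Regulation edges whose partner node has no incident reaction fall back
    to plain reactions so that every graph edge shapes the dynamics.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    edge_list = sorted(tuple(sorted(e)) for e in graph.adjacency)
    reaction_edges, regulation_edges = [], []
    for e in edge_list:
        (regulation_edges if rng.random() < p_regulation else reaction_edges).append(e)

    reactions: list[Reaction] = []
    for u, v in reaction_edges:
        if rng.random() < 0.5:
            u, v = v, u
        reactions.append(Reaction((u,), (v,), float(rng.uniform(0, 1))))
        if rng.random() < p_reversible:
            reactions.append(Reaction((v,), (u,), float(rng.uniform(0, 1))))

    # merge a fraction of single-reactant reactions pairwise
    n_merge_pairs = int(merge_fraction * len(reactions) / 2)
    if n_merge_pairs > 0:
        idx = rng.permutation(len(reactions))[: 2 * n_merge_pairs]
        merged_away = set()
        merged: list[Reaction] = []
        for a, b in zip(idx[0::2], idx[1::2]):
            ra, rb = reactions[a], reactions[b]
            reactants = tuple(sorted(set(ra.reactants + rb.reactants)))[:2]
            products = tuple(sorted(set(ra.products + rb.products)))
            merged.append(Reaction(reactants, products, float(rng.uniform(0, 1))))
            merged_away |= {int(a), int(b)}
        reactions = [r for i, r in enumerate(reactions) if i not in merged_away] + merged

    # regulation assignment on the assembled reaction list
    incident: dict[int, list[int]] = {}
    for ri, r in enumerate(reactions):
        for node in r.reactants + r.products:
            incident.setdefault(node, []).append(ri)
    regs: dict[int, list[tuple[int, int]]] = {}
    for u, v in regulation_edges:
        regulator, partner = (u, v) if rng.random() < 0.5 else (v, u)
        targets = incident.get(partner, [])
        if not targets:
            if rng.random() < 0.5:
                regulator, partner = partner, regulator
            reactions.append(Reaction((regulator,), (partner,), float(rng.uniform(0, 1))))
            continue
        ri = int(targets[rng.integers(len(targets))])
        alpha = 1 if rng.random() < 0.5 else -1
        regs.setdefault(ri, []).append((regulator, alpha))
    for ri, r in regs.items():
        old = reactions[ri]
        reactions[ri] = Reaction(
            old.reactants, old.products, old.k, old.regulators + tuple(r)
        )
    return reactions


def _rhs(reactions: list[Reaction], n: int):
    def f(_t: float, x: np.ndarray) -> np.ndarray:
        xe = np.maximum(x, CONC_FLOOR)
        dx = np.zeros(n)
        for r in reactions:
            rate = r.k
            for h in r.reactants:
                rate *= xe[h]
            for node, alpha in r.regulators:
                rate *= xe[node] ** alpha
            for h in r.reactants:
                dx[h] -= rate
            for p in r.products:
                dx[p] += rate
        return dx

    return f


def simulate(
    reactions: list[Reaction],
    initial: np.ndarray,
    grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the system on ``grid``; returns (n_nodes, n_times).

    Uses the stiff-capable LSODA integrator; concentrations are clipped at
    0 on output (rate evaluation floors them at 1e-6 so inverse regulators
    stay finite).
    """
    initial = np.asarray(initial, dtype=float)
    if np.any(initial < 0):
        raise ValueError("initial values must be non-negative")
    n = initial.size
    sol = solve_ivp(
        _rhs(reactions, n),
        (grid[0], grid[-1]),
        initial,
        t_eval=grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return np.clip(sol.y, 0.0, None)


def add_noise(
    X: np.ndarray,
    rng: np.random.Generator,
    coefficient: float = 0.02,
    floor: float = 1e-7,
) -> np.ndarray:
    """Y = X + N(0, a) with a = coefficient * sd(X) + floor per feature.

    sd(X) is each feature's standard deviation over its own noiseless
    trajectory, so the noise level tracks the feature's dynamic range;
    draws are independent per time point.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=-1, keepdims=True)
    a = coefficient * sd + floor
    return X + rng.normal(0.0, 1.0, size=X.shape) * a


def add_redundant_signals(
    X: np.ndarray,
    rng: np.random.Generator,
    max_signals: int = 5,
    factor_range: tuple[float, float] = (0.3, 3.0),
) -> tuple[np.ndarray, list[tuple[int, float]]]:
    """Expand compounds into multiplet-like redundant signals.

    Per compound, N_S ~ U{1..max_signals} copies are emitted, each the
    compound trajectory times an independent U(factor_range) factor.
    Returns the expanded (n_signals, n_times) array and a parent list of
    (compound index, factor) per signal.
    """
    rows, parents = [], []
    for c in range(X.shape[0]):
        n_s = int(rng.integers(1, max_signals + 1))
        for _ in range(n_s):
            factor = float(rng.uniform(*factor_range))
            rows.append(X[c] * factor)
            parents.append((c, factor))
    return np.vstack(rows), parents


def mask_observability(
    n: int, rng: np.random.Generator, fraction: float = 0.5
) -> np.ndarray:
    """Uniformly random boolean mask with exactly floor(fraction * n) True."""
    k = int(fraction * n)
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:k]] = True
    return mask


def _signal_ppm(node: int, sig_index: int, n: int) -> float:
    # deterministic synthetic chemical shifts: signals of one compound sit
    # within 0.005 ppm of each other, compounds 10/n ppm apart
    return 10.0 * (node + 1) / n + 0.001 * sig_index


def generate_benchmark_network(
    n_nodes: int,
    cluster_sizes: tuple[int, ...],
    n_conditions: int,
    seed: int,
    config: SimulationConfig | None = None,
    p_in: float = 0.15,
    p_global: float = 0.015,
    max_attempts: int = 5,
) -> SimulatedDataset:
    """One benchmark network end to end: graph -> kinetics -> per-condition
    initial values -> ODE trajectories -> redundant signals -> noise x
    replicates -> observability mask, packaged as a RidgeCollection.

    An occasional pathological reaction system fails to integrate; such a
    draw is regenerated from an offset seed (up to ``max_attempts``).
    """
    config = config or SimulationConfig()
    grid = config.grid
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        # independent streams: structure is shared across condition counts,
        # and condition c is identical whether 2 or 8 conditions are drawn,
        # so sweeps over n_conditions are paired on the same systems
        rng = np.random.default_rng([seed, attempt])
        graph = random_cluster_graph(n_nodes, cluster_sizes, p_in, p_global, rng)
        reactions = build_kinetics(
            graph, rng, config.p_regulation, config.p_reversible, config.merge_fraction
        )
        try:
            trajectories = [
                simulate(
                    reactions,
                    np.random.default_rng([seed, attempt, 1, c]).uniform(0, 1, n_nodes),
                    grid,
                )
                for c in range(n_conditions)
            ]
        except RuntimeError as err:
            last_err = err
            continue

        # one shared signal expansion and observability mask per network
        if config.redundant_signals:
            n_sigs = rng.integers(1, config.redundancy_max + 1, size=n_nodes)
        else:
            n_sigs = np.ones(n_nodes, dtype=int)
        factors = [
            [float(rng.uniform(*config.redundancy_factor_range)) for _ in range(int(k))]
            if config.redundant_signals
            else [1.0]
            for k in n_sigs
        ]
        observable = mask_observability(n_nodes, rng, config.observable_fraction)
        signal_map: dict[int, list[tuple[str, float]]] = {}
        for node in range(n_nodes):
            signal_map[node] = [
                (f"s{node:03d}_{j}", factors[node][j]) for j in range(int(n_sigs[node]))
            ]

        dataset = SimulatedDataset(
            truth=graph,
            reactions=reactions,
            signal_map=signal_map,
            observable=observable,
        )
        tg = TimeGrid(grid)
        for cond in range(n_conditions):
            env_id = f"cond{cond}"
            X = trajectories[cond]
            env_exps = []
            for rep in range(config.replicates):
                exp = Experiment(
                    experiment_id=f"{env_id}_rep{rep}",
                    grid=tg,
                    condition={"environment": env_id, "replicate": str(rep)},
                )
                for node in range(n_nodes):
                    if not observable[node]:
                        continue
                    for j, (sig_id, factor) in enumerate(signal_map[node]):
                        y = add_noise(
                            (X[node] * factor)[None, :],
                            rng,
                            config.noise_coefficient,
                            config.noise_floor,
                        )[0]
                        ppm = np.full(grid.size, _signal_ppm(node, j, n_nodes))
                        exp.add(
                            Ridge(
                                feature_id=sig_id,
                                experiment_id=exp.experiment_id,
                                ppm_trace=ppm,
                                intensity_trace=y,
                            )
                        )
                dataset.collection.add(exp)
                env_exps.append(exp)
            dataset.environments[env_id] = env_exps
        return dataset
    raise RuntimeError(
        f"benchmark generation failed after {max_attempts} attempts: {last_err}"
    )


def generate_benchmark(
    n_networks: int,
    n_conditions: int,
    seed: int = 0,
    n_nodes: int = 100,
    cluster_sizes: tuple[int, ...] = (40, 20, 20),
    config: SimulationConfig | None = None,
) -> list[SimulatedDataset]:
    """A list of independent benchmark networks with their simulated data."""
    return [
        generate_benchmark_network(
            n_nodes, cluster_sizes, n_conditions, seed + 7919 * i, config
        )
        for i in range(n_networks)
    ]
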