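"""Functional principal component analysis of smoothed ridge curves.

Each standardized, smoothed intensity curve is evaluated on a dense grid
(default 4x the sampling density); the sample covariance surface of these
evaluations is symmetrized with trapezoid quadrature weights so that the
eigenfunctions come out orthonormal in the L2 inner product:

    integral xi_i(t) xi_j(t) dt = delta_ij

Eigenvalues are the variances captured per component, variance fractions
their share of the total, and scores the L2 projections of the centered
curves onto the eigenfunctions.  The eigenfunction sign is fixed so that
the component correlates positively with an increasing linear trend — with
this convention, curves of metabolites that are produced over time score
positive on a "rising" component and consumed metabolites score negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fda_smooth
from .ridge_io import RidgeCollection, TimeGrid, FeatureMatchTable

__all__ = ["FPCAModel", "standardize", "fit_fpca", "harmonic_effect", "pooled_fpca"]


def standardize(curves: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Center and scale each row to mean 0, sample sd 1 over its time points.

    Rows with zero variance are rejected — flag and exclude them upstream.
    """
    curves = np.asarray(curves, dtype=float)
    mu = curves.mean(axis=-1, keepdims=True)
    sd = curves.std(axis=-1, ddof=ddof, keepdims=True)
    if np.any(sd <= 0):
        raise ValueError("zero-variance curve cannot be standardized")
    return (curves - mu) / sd


def trapezoid_weights(t: np.ndarray) -> np.ndarray:
    """Quadrature weights w with sum(w * f) ~= integral f dt on grid t."""
    t = np.asarray(t, dtype=float)
    w = np.zeros_like(t)
    w[0] = (t[1] - t[0]) / 2
    w[-1] = (t[-1] - t[-2]) / 2
    w[1:-1] = (t[2:] - t[:-2]) / 2
    return w


@dataclass
class FPCAModel:
    grid: np.ndarray                    # dense evaluation times
    mean_curve: np.ndarray              # values on grid
    eigenfunctions: np.ndarray          # (n_components, n_grid), L2-orthonormal
    eigenvalues: np.ndarray             # variance per component, non-increasing
    variance_fraction: np.ndarray       # eigenvalue / total variance
    scores: np.ndarray                  # (n_curves, n_components)
    labels: list[dict] = field(default_factory=list)  # per-curve metadata

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def reconstruct(self, i: int) -> np.ndarray:
        """mean + sum_k score_ik * xi_k — complete within quadrature error."""
        return self.mean_curve + self.scores[i] @ self.eigenfunctions


def fit_fpca(
    curve_values: np.ndarray,
    grid: np.ndarray,
    n_components: int | None = None,
    labels: list[dict] | None = None,
) -> FPCAModel:
    """Eigen-decompose the sample covariance of curves evaluated on ``grid``.

    ``curve_values`` is (n_curves, n_grid).  The covariance C(s,t) is
    discretized with trapezoid weights W; the symmetric eigenproblem of
    W^1/2 C W^1/2 gives eigenfunctions orthonormal under the quadrature
    inner product.  Scores are integral (x_i - mean) xi_k dt.  If
    ``n_components`` is None, the smallest K with cumulative variance
    fraction >= 99% is retained.
    """
    X = np.asarray(curve_values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 curves")
    grid = np.asarray(grid, dtype=float)
    n_curves, n_grid = X.shape
    if grid.size != n_grid:
        raise ValueError("grid length mismatch")

    mean_curve = X.mean(axis=0)
    Xc = X - mean_curve
    C = (Xc.T @ Xc) / (n_curves - 1)

    w = trapezoid_weights(grid)
    sw = np.sqrt(w)
    M = sw[:, None] * C * sw[None, :]
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    max_k = min(n_curves, n_grid)
    evals = evals[:max_k]
    evecs = evecs[:, :max_k]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)

    if n_components is None:
        csum = np.cumsum(fractions)
        n_components = int(np.searchsorted(csum, 0.99) + 1)
    if n_components > max_k:
        n_components = max_k
    evals = evals[:n_components]
    fractions = fractions[:n_components]
    # back-transform to functions orthonormal in L2
    with np.errstate(divide="ignore", invalid="ignore"):
        xis = np.where(sw[:, None] > 0, evecs[:, :n_components] / sw[:, None], 0.0).T

    # sign convention: positive projection on the increasing linear trend
    tc = grid - np.average(grid, weights=w)
    for k in range(n_components):
        if np.sum(w * xis[k] * tc) < 0:
            xis[k] = -xis[k]

    scores = (Xc * w) @ xis.T
    return FPCAModel(
        grid=grid,
        mean_curve=mean_curve,
        eigenfunctions=xis,
        eigenvalues=evals,
        variance_fraction=fractions,
        scores=scores,
        labels=labels or [],
    )


def harmonic_effect(model: FPCAModel, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean curve +/- sqrt(eigenvalue_k) * eigenfunction_k.

    The standard visualization of what a component *does*: the pair of
    curves a typical positive- and negative-scoring feature would follow.
    """
    if not 0 <= k < model.n_components:
        raise ValueError("component index out of range")
    delta = np.sqrt(model.eigenvalues[k]) * model.eigenfunctions[k]
    return model.mean_curve + delta, model.mean_curve - delta


def smooth_and_evaluate(
    intensities: np.ndarray,
    grid: TimeGrid,
    dense_factor: int = 4,
    lam: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize, smooth (GCV by default) and evaluate curves densely.

    Returns (dense_grid, values (n_curves, n_dense)).
    """
    X = standardize(np.atleast_2d(np.asarray(intensities, dtype=float)))
    lo, hi = grid.domain
    n_dense = dense_factor * (len(grid) - 1) + 1
    dense = np.linspace(lo, hi, n_dense)
    out = np.empty((X.shape[0], n_dense))
    basis = fda_smooth.default_basis(grid)
    for i, y in enumerate(X):
        if lam is None:
            fit = fda_smooth.select_lambda(y, grid, basis)
        else:
            fit = fda_smooth.penalized_fit(y, grid, basis, lam)
        out[i] = fit(dense)
    return dense, out


def fpca_experiment(
    experiment,
    n_components: int | None = None,
    dense_factor: int = 4,
) -> FPCAModel:
    """FPCA of one experiment's ridges: standardize, smooth, decompose."""
    ridges = [r for r in experiment.ridges.values()
              if np.nanstd(r.intensity_trace) > 0]
    X = np.vstack([r.intensity_trace for r in ridges])
    if np.isnan(X).any():
        raise ValueError("gap-fill ridges before FPCA")
    dense, vals = smooth_and_evaluate(X, experiment.grid, dense_factor)
    labels = [
        {
            "experiment_id": experiment.experiment_id,
            "feature_id": r.feature_id,
            "compound": r.compound,
            "labeled": r.labeled,
            **experiment.condition,
        }
        for r in ridges
    ]
    return fit_fpca(vals, dense, n_components, labels)


def pooled_fpca(
    collection: RidgeCollection,
    match_table: FeatureMatchTable | None = None,
    n_components: int | None = None,
    n_grid: int = 101,
    dense_factor: int = 4,
) -> FPCAModel:
    """Joint FPCA across experiments and conditions.

    Experiment durations differ, so each experiment's time axis is rescaled
    to [0, 1] before smoothing; all curves are then resampled onto one
    shared dense grid and decomposed together.  Score rows carry
    experiment/condition/labeling metadata so one compound's trajectories
    can be compared across conditions.  Experiments with fewer than 4 time
    points are excluded.
    """
    shared = np.linspace(0.0, 1.0, n_grid)
    rows: list[np.ndarray] = []
    labels: list[dict] = []
    group_of: dict[tuple[str, str], int] = (
        match_table.member_to_group() if match_table else {}
    )
    for exp in collection.experiments.values():
        t = exp.grid.times
        if t.size < 4:
            continue
        unit = (t - t[0]) / (t[-1] - t[0])
        grid01 = TimeGrid(unit)
        basis = fda_smooth.default_basis(grid01)
        for ridge in exp.ridges.values():
            y = ridge.intensity_trace
            if np.isnan(y).any() or np.std(y) <= 0:
                continue
            ys = standardize(y[None, :])[0]
            fit = fda_smooth.select_lambda(ys, grid01, basis)
            rows.append(fit(shared))
            labels.append(
                {
                    "experiment_id": exp.experiment_id,
                    "feature_id": ridge.feature_id,
                    "compound": ridge.compound,
                    "labeled": ridge.labeled,
                    "group_id": group_of.get((exp.experiment_id, ridge.feature_id)),
                    **exp.condition,
                }
            )
    return fit_fpca(np.vstack(rows), shared, n_components, labels)
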