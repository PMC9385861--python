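"""Dissimilarity, ordination and permutation inference.

Bray-Curtis dissimilarities between sample profiles, non-metric
multidimensional scaling (NMDS), distance-based redundancy analysis
(db-RDA: principal-coordinate decomposition followed by redundancy analysis
on predictor variables, with a permutation test on the pseudo-F), and a
Procrustes congruence test between two ordination configurations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import smacof

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "ConstrainedResult",
    "ProcrustesResult",
    "bray_curtis",
    "pcoa_decomposition",
    "nmds",
    "dbrda",
    "procrustes_test",
]


def bray_curtis(matrix: pd.DataFrame, samples_as: str = "columns") -> DistanceMatrix:
    """Bray-Curtis dissimilarities between sample profiles.

    ``matrix`` is a features x samples table by default (``samples_as=
    "rows"`` transposes). Profiles must be non-negative with positive sums.
    """
    if samples_as == "columns":
        prof = matrix.T
    elif samples_as == "rows":
        prof = matrix
    else:
        raise ValueError("samples_as must be 'columns' or 'rows'")
    x = prof.to_numpy(float)
    if (x < 0).any():
        raise ValueError("negative entries in profiles")
    sums = x.sum(axis=1)
    dead = [str(prof.index[i]) for i in np.flatnonzero(sums <= 0)]
    if dead:
        raise ValueError(f"zero-sum samples: {dead}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in prof.index])


@dataclass
class OrdinationResult:
    """Sample configuration from an (N)MDS run."""

    coordinates: pd.DataFrame  # samples x axes, centered
    stress: float | None  # Kruskal stress-1 (NMDS)
    eigenvalues: np.ndarray | None
    converged: bool
    seed: int | None


@dataclass
class ConstrainedResult:
    """db-RDA summary."""

    explained_fraction: float
    pseudo_F: float
    p_value: float | None
    n_permutations: int
    rank: int
    total_inertia: float
    constrained_inertia: float
    dropped_negative_inertia: float
    seed: int | None


@dataclass
class ProcrustesResult:
    m2: float
    p_value: float | None
    n_permutations: int
    seed: int | None


def pcoa_decomposition(d: DistanceMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Principal-coordinate (classical scaling) decomposition.

    Returns (coordinates for positive eigenvalues, positive eigenvalues
    descending, summed magnitude of dropped negative eigenvalues).
    """
    dm = d.data
    n = dm.shape[0]
    a = -0.5 * dm ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-8 * max(abs(evals[0]), 1.0))
    pos = evals > tol
    neg_sum = float(-evals[evals < -tol].sum())
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    return coords, evals[pos], neg_sum


def nmds(d: DistanceMatrix, k: int = 2, n_starts: int = 20, seed: int | None = None,
         max_iter: int = 500, tol: float = 1e-6) -> OrdinationResult:
    """Non-metric MDS by stress majorization with monotone regression.

    Runs one start initialized from classical scaling plus ``n_starts - 1``
    random starts, and keeps the configuration with the lowest Kruskal
    stress-1. Non-convergence flags the result instead of raising.
    """
    n = d.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} samples for k={k} axes")
    if k >= n - 1:
        warnings.warn(f"k={k} with n={n} samples is degenerate (stress ~ 0 always)",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    dm = d.data
    inits: list[np.ndarray] = []
    coords0, _, _ = pcoa_decomposition(d)
    if coords0.shape[1] >= k:
        inits.append(coords0[:, :k])
    while len(inits) < max(1, n_starts):
        inits.append(rng.standard_normal((n, k)))
    best = None
    for init in inits:
        coords, stress, n_iter = smacof(
            dm, metric=False, n_components=k, init=init, n_init=1,
            max_iter=max_iter, eps=tol, random_state=0,
            normalized_stress=True, return_n_iter=True)
        if best is None or stress < best[1]:
            best = (coords, stress, n_iter)
    coords, stress, n_iter = best
    coords = coords - coords.mean(axis=0)
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(d.ids),
                                 columns=[f"NMDS{i + 1}" for i in range(k)]),
        stress=float(stress),
        eigenvalues=None,
        converged=bool(n_iter < max_iter),
        seed=seed,
    )


def dbrda(d: DistanceMatrix, predictors: pd.DataFrame, n_perm: int = 9999,
          seed: int | None = None) -> ConstrainedResult:
    """Distance-based redundancy analysis with a permutation test.

    The dissimilarity matrix is decomposed into principal coordinates
    (negative eigenvalues dropped and recorded); the coordinates are then
    regressed on the standardized predictors. ``explained_fraction`` is
    constrained over total inertia; the p-value permutes sample rows of the
    predictor table. Collinear predictors are handled by pseudo-inverse.
    """
    ids = list(d.ids)
    missing = [s for s in ids if s not in predictors.index]
    if missing:
        raise ValueError(f"predictors missing samples: {missing}")
    x = predictors.loc[ids].to_numpy(float)
    if np.isnan(x).any():
        raise ValueError("predictors contain missing values")
    n = len(ids)
    if n <= x.shape[1] + 1:
        warnings.warn("more predictors than samples-2; model is saturated", stacklevel=2)
    y, evals, neg_sum = pcoa_decomposition(d)
    total = float(evals.sum())

    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=0)) / sd
    rank = int(np.linalg.matrix_rank(xs))
    if rank < xs.shape[1]:
        warnings.warn(f"collinear predictors (rank {rank} < {xs.shape[1]}); "
                      "using pseudo-inverse", stacklevel=2)

    def stats(xmat: np.ndarray) -> tuple[float, float]:
        fitted = xmat @ np.linalg.pinv(xmat) @ y
        constrained = float((fitted ** 2).sum())
        residual = max(total - constrained, 0.0)
        df_res = max(n - 1 - rank, 1)
        f = (constrained / rank) / (residual / df_res) if residual > 0 else np.inf
        return constrained, f

    constrained, f_obs = stats(xs)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            _, f_perm = stats(xs[rng.permutation(n)])
            if f_perm >= f_obs:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
    return ConstrainedResult(
        explained_fraction=constrained / total if total > 0 else 0.0,
        pseudo_F=f_obs,
        p_value=p,
        n_permutations=n_perm,
        rank=rank,
        total_inertia=total,
        constrained_inertia=constrained,
        dropped_negative_inertia=neg_sum,
        seed=seed,
    )


def procrustes_test(a: OrdinationResult, b: OrdinationResult, n_perm: int = 9999,
                    seed: int | None = None) -> ProcrustesResult:
    """Procrustes congruence of two configurations.

    Both configurations are scaled to unit total variance (symmetric
    scaling); m^2 is the residual sum of squares after optimal translation,
    rotation and scaling of ``b`` onto ``a``. The p-value counts row
    permutations of ``b`` achieving m^2 at most the observed value.
    """
    if list(a.coordinates.index) != list(b.coordinates.index):
        raise ValueError("configurations must cover the same samples in the same order")
    if a.coordinates.shape[1] != b.coordinates.shape[1]:
        raise ValueError("configurations must have the same dimensionality")
    xa = a.coordinates.to_numpy(float)
    xb = b.coordinates.to_numpy(float)
    _, _, m2 = _scipy_procrustes(xa, xb)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        n = xa.shape[0]
        hits = 0
        for _ in range(n_perm):
            _, _, m2p = _scipy_procrustes(xa, xb[rng.permutation(n)])
            if m2p <= m2:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
    return ProcrustesResult(m2=float(m2), p_value=p, n_permutations=n_perm, seed=seed)
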