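"""Non-metric multidimensional scaling and Procrustes/PROTEST comparisons.

NMDS follows Kruskal's alternating scheme: pool-adjacent-violators monotone
regression of configuration distances on the observed dissimilarities
(weak/primary tie handling) alternated with quasi-Newton configuration
updates of stress-1.  Multiple random starts plus one PCoA-seeded start;
the lowest-stress solution is returned, centred and rotated to principal
axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression, minimize

from .exceptions import ValidationError
from .transforms import DissimilarityMatrix, bray_curtis, hellinger, pcoa


@dataclass
class NmdsResult:
    labels: list[str]
    coordinates: np.ndarray  # samples x k, centred, principal-axis rotated
    stress: float  # Kruskal stress-1 of the best start
    n_starts: int
    converged: bool
    best_start_seed: int
    stress_histories: list[np.ndarray] = field(repr=False, default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def _disparities(dist: np.ndarray, order: np.ndarray, tie_sorter: np.ndarray) -> np.ndarray:
    """Monotone (weak-tie) fit of configuration distances to dissimilarity order."""
    # primary ties: within tied blocks of delta, distances sorted ascending
    idx = order[tie_sorter]
    fit = isotonic_regression(dist[idx]).x
    out = np.empty_like(dist)
    out[idx] = fit
    return out


def _stress(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = np.sum(dist**2)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def _stress_grad(x: np.ndarray, dhat: np.ndarray, n: int, k: int):
    """Squared stress-1 and its gradient for a fixed set of disparities."""
    xm = x.reshape(n, k)
    diff = xm[:, None, :] - xm[None, :, :]
    dmat = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(n, k=1)
    dist = dmat[iu]
    a = np.sum((dist - dhat) ** 2)
    b = np.sum(dist**2)
    if b <= 0:
        return 0.0, np.zeros_like(x)
    s2 = a / b
    # d(s2)/d(dist) per pair
    gd = (2 * (dist - dhat) * b - a * 2 * dist) / b**2
    coef = np.zeros((n, n))
    coef[iu] = gd / np.maximum(dist, 1e-12)
    coef = coef + coef.T
    grad = (coef.sum(axis=1)[:, None] * xm) - coef @ xm
    return s2, grad.ravel()


def _single_start(
    delta: np.ndarray,
    x0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, list[float], bool]:
    n, k = x0.shape
    order = np.argsort(delta, kind="stable")
    x = x0.copy()
    iu = np.triu_indices(n, k=1)
    history: list[float] = []
    converged = False
    prev = np.inf
    for _ in range(max_iter):
        dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))[iu]
        # weak ties: stable sort of distances inside tied delta blocks
        tie_sorter = np.lexsort((dist[order], delta[order]))
        dhat = _disparities(dist, order, tie_sorter)
        res = minimize(
            _stress_grad,
            x.ravel(),
            args=(dhat, n, k),
            jac=True,
            method="L-BFGS-B",
            options=dict(maxiter=50, gtol=1e-10),
        )
        x = res.x.reshape(n, k)
        dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))[iu]
        tie_sorter = np.lexsort((dist[order], delta[order]))
        dhat = _disparities(dist, order, tie_sorter)
        s = _stress(dist, dhat)
        history.append(s)
        if prev - s < tol * max(prev, 1e-12):
            converged = True
            break
        prev = s
    return x, history[-1] if history else 0.0, history, converged


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> NmdsResult:
    """NMDS minimizing Kruskal stress-1 over *n_starts* configurations.

    One start is PCoA-seeded; the rest are uniform random.  Stress within a
    start is non-increasing by construction (monotone regression and the
    configuration update each cannot increase it).
    """
    n = d.n
    if k >= n - 1:
        raise ValidationError(f"k={k} requires at least {k + 2} samples, got {n}")
    delta = d.condensed()
    if np.allclose(delta, delta[0]):
        warnings.warn("all dissimilarities equal; NMDS solution is degenerate", stacklevel=2)
    rng = np.random.default_rng(seed)
    best = None
    histories = []
    for start in range(n_starts):
        start_seed = int(rng.integers(2**32))
        if start == 0:
            p = pcoa(d)
            x0 = np.zeros((n, k))
            take = min(k, p.coordinates.shape[1])
            x0[:, :take] = p.coordinates[:, :take]
            if take < k:
                x0[:, take:] = np.random.default_rng(start_seed).uniform(-1e-4, 1e-4, (n, k - take))
        else:
            x0 = np.random.default_rng(start_seed).uniform(-1, 1, (n, k))
        x, stress, history, converged = _single_start(delta, x0, max_iter, tol)
        histories.append(np.asarray(history))
        if best is None or stress < best[1]:
            best = (x, stress, start_seed, converged)
    x, stress, best_seed, converged = best
    x = x - x.mean(axis=0)
    # principal-axis rotation for cross-run comparability
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    return NmdsResult(list(d.labels), x, stress, n_starts, converged, best_seed, histories)


@dataclass
class ProcrustesResult:
    m2: float  # symmetric Procrustes statistic in [0, 1]
    correlation: float  # sqrt(1 - m2)
    rotation_applied: str
    p_value: float | None = None
    n_perm: int | None = None


def _procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    ssx = np.sum(xc**2)
    ssy = np.sum(yc**2)
    if ssx <= 0 or ssy <= 0:
        raise ValidationError("degenerate (zero-variance) configuration")
    s = np.linalg.svd(xc.T @ yc, compute_uv=False)
    m2 = 1.0 - s.sum() ** 2 / (ssx * ssy)
    return float(min(max(m2, 0.0), 1.0))


def procrustes(x, y, symmetric: bool = True) -> ProcrustesResult:
    """Least-squares superimposition of two configurations.

    Both configurations are centred and (symmetric mode) scaled to unit
    sum of squares; the optimal rotation comes from the SVD of the
    cross-product.  m2 = 1 - (sum of singular values)^2 and the Procrustes
    correlation is sqrt(1 - m2).
    """
    x = _coords(x)
    y = _coords(y)
    if x.shape != y.shape:
        raise ValidationError(f"configuration shapes differ: {x.shape} vs {y.shape}")
    m2 = _procrustes_m2(x, y)
    desc = "centred, unit-scaled, SVD rotation" if symmetric else "centred, SVD rotation + LS scaling"
    return ProcrustesResult(m2, float(np.sqrt(1.0 - m2)), desc)


def _coords(x) -> np.ndarray:
    if isinstance(x, NmdsResult):
        return np.asarray(x.coordinates, dtype=float)
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def protest(
    x,
    y,
    n_perm: int = 1000,
    seed: int | None = None,
    symmetric: bool = True,
) -> ProcrustesResult:
    """Procrustes randomization test: permute rows of y, p = (b+1)/(m+1)."""
    xa = _coords(x)
    ya = _coords(y)
    if xa.shape[0] < 4:
        raise ValidationError("protest requires >= 4 samples")
    res = procrustes(xa, ya, symmetric=symmetric)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(ya.shape[0])
        m2p = _procrustes_m2(xa, ya[perm])
        hits += np.sqrt(1.0 - m2p) >= res.correlation - 1e-12
    res.p_value = float((hits + 1) / (n_perm + 1))
    res.n_perm = n_perm
    return res


def rank_consistency(
    tables: dict,
    d_builder=None,
    k: int = 2,
    n_starts: int = 20,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise Procrustes/PROTEST between NMDS solutions per taxonomic level.

    *tables* maps level name -> OtuTable (same samples).  Bonferroni
    factor equals the number of level pairs.
    """
    if len(tables) < 2:
        raise ValidationError("rank_consistency requires >= 2 levels")
    if d_builder is None:
        d_builder = lambda t: bray_curtis(hellinger(t), labels=t.sample_ids)
    rng = np.random.default_rng(seed)
    nmds_seed = int(rng.integers(2**32))  # shared: identical levels match exactly
    levels = list(tables)
    ref = tables[levels[0]].sample_ids
    ords = {}
    for lev in levels:
        t = tables[lev]
        if t.sample_ids != ref:
            raise ValidationError(f"level {lev!r} has different samples")
        if t.n_samples < 4:
            raise ValidationError(f"level {lev!r} has < 4 samples")
        ords[lev] = nmds(d_builder(t), k=k, n_starts=n_starts, seed=nmds_seed)
    pairs = list(combinations(levels, 2))
    rows = []
    for a, b in pairs:
        res = protest(ords[a], ords[b], n_perm=n_perm, seed=int(rng.integers(2**32)))
        rows.append(
            dict(level_a=a, level_b=b, correlation=res.correlation, m2=res.m2,
                 p=res.p_value, p_bonferroni=min(1.0, res.p_value * len(pairs)),
                 stress_a=ords[a].stress, stress_b=ords[b].stress)
        )
    return pd.DataFrame(rows)
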