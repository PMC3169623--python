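"""Diversity, rank-sum comparison, ANOSIM and multivariate dispersion."""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, rankdata

from .exceptions import ValidationError
from .transforms import DissimilarityMatrix, gower_eig

#: exact Mann-Whitney enumeration is used when the smaller group has at most
#: this many observations (and full enumeration when ties make the standard
#: null distribution invalid)
EXACT_MW_THRESHOLD = 8
_MAX_ENUMERATION = 500_000


def inverse_simpson(counts) -> float:
    """Inverse Simpson diversity 1 / sum(p_i^2); 1 for a single taxon."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValidationError("inverse_simpson: zero total count")
    p = c / total
    return float(1.0 / np.sum(p**2))


def inverse_simpson_per_sample(table) -> pd.Series:
    vals = [inverse_simpson(row) for row in table.counts]
    return pd.Series(vals, index=table.sample_ids, name="inverse_simpson")


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test with mid-rank ties.

    Small samples (min n <= 8) get an exact p: the standard no-tie null
    when the data are tie-free, otherwise full enumeration of label
    assignments on the observed mid-ranks (falling back to the corrected
    normal approximation when enumeration would be too large).  Larger
    samples use the tie- and continuity-corrected normal approximation.
    Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n2 = x.size, y.size
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if np.ptp(pooled) == 0:
        return u1, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = min(n1, n2) <= EXACT_MW_THRESHOLD
    if small and not has_ties:
        return u1, float(mannwhitneyu(x, y, alternative=alternative, method="exact").pvalue)
    if small and math.comb(n1 + n2, n1) <= _MAX_ENUMERATION:
        return u1, _exact_mw_enumeration(ranks, n1, alternative)
    return u1, float(
        mannwhitneyu(
            x, y, alternative=alternative, method="asymptotic", use_continuity=True
        ).pvalue
    )


def _exact_mw_enumeration(ranks: np.ndarray, n1: int, alternative: str) -> float:
    n = ranks.size
    mu = n1 * (n + 1) / 2.0
    t_obs = ranks[:n1].sum()
    count = total = 0
    eps = 1e-9
    for idx in combinations(range(n), n1):
        t = ranks[list(idx)].sum()
        total += 1
        if alternative == "two-sided":
            count += abs(t - mu) >= abs(t_obs - mu) - eps
        elif alternative == "greater":
            count += t >= t_obs - eps
        else:
            count += t <= t_obs + eps
    return count / total


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_perm: int
    group_sizes: dict[str, int]


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def _within_mask_condensed(groups: np.ndarray) -> np.ndarray:
    n = groups.size
    iu = np.triu_indices(n, k=1)
    return groups[iu[0]] == groups[iu[1]]


def anosim(
    d: DissimilarityMatrix,
    groups,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AnosimResult:
    """Analysis of similarities: rank-based between/within group contrast.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise dissimilarities, mid-ranked.  The p-value uses
    the (b+1)/(m+1) permutation convention on group-label permutations.
    """
    groups = _align_groups(d, groups)
    sizes = pd.Series(groups).value_counts()
    if len(sizes) < 2:
        raise ValidationError("anosim requires >= 2 groups")
    if (sizes < 2).any():
        raise ValidationError(f"anosim group of size 1: {sizes[sizes < 2].index.tolist()}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    ranks = rankdata(d.condensed())
    garr = np.asarray(groups)
    within = _within_mask_condensed(garr)
    if within.all() or not within.any():
        raise ValidationError("degenerate grouping")
    r_obs = _anosim_r(ranks, within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(garr)
        hits += _anosim_r(ranks, _within_mask_condensed(perm)) >= r_obs - 1e-12
    p = (hits + 1) / (n_perm + 1)
    return AnosimResult(r_obs, float(p), n_perm, sizes.to_dict())


def _align_groups(d: DissimilarityMatrix, groups) -> list:
    if isinstance(groups, pd.Series):
        missing = [s for s in d.labels if s not in groups.index]
        if missing:
            raise ValidationError(f"samples without group label: {missing[:5]}")
        return list(groups.reindex(d.labels))
    groups = list(groups)
    if len(groups) != d.n:
        raise ValidationError("groups length does not match matrix")
    return groups


def pairwise_anosim(
    d: DissimilarityMatrix,
    groups,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """ANOSIM on every group pair; Bonferroni factor = number of pairs."""
    groups = pd.Series(_align_groups(d, groups), index=d.labels)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValidationError("pairwise_anosim requires >= 2 groups")
    pairs = list(combinations(levels, 2))
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        ids = [s for s in d.labels if groups[s] in (a, b)]
        res = anosim(d.submatrix(ids), groups.loc[ids], n_perm=n_perm,
                     seed=int(rng.integers(2**32)))
        rows.append(
            dict(group_a=a, group_b=b, R=res.R, p=res.p_value,
                 p_bonferroni=min(1.0, res.p_value * len(pairs)))
        )
    return pd.DataFrame(rows)


@dataclass
class DispersionResult:
    distances: pd.Series  # per-sample distance to own group centroid
    group_means: pd.Series
    comparisons: pd.DataFrame  # pair, U, p, p_bonferroni


def beta_dispersion(d: DissimilarityMatrix, groups) -> DispersionResult:
    """Distance of each sample to its group centroid in PCoA space.

    Positive- and negative-eigenvalue axes are embedded separately and
    the squared distance is the positive part minus the negative part
    (truncated at zero), following the standard multivariate-dispersion
    construction for semi-metric dissimilarities.  Group comparisons use
    Mann-Whitney with Bonferroni over pairs.
    """
    groups = pd.Series(_align_groups(d, groups), index=d.labels)
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValidationError(f"dispersion group of size 1: {sizes[sizes < 2].index.tolist()}")
    w, v = gower_eig(d)
    tol = 1e-8 * max(abs(w[0]), abs(w[-1]), 1e-300)
    pos = w > tol
    neg = w < -tol
    xpos = v[:, pos] * np.sqrt(w[pos])
    xneg = v[:, neg] * np.sqrt(-w[neg])
    dist = np.empty(d.n)
    garr = groups.to_numpy()
    for g in sizes.index:
        mask = garr == g
        cp = xpos[mask].mean(axis=0)
        cn = xneg[mask].mean(axis=0) if xneg.size else np.zeros(0)
        d2 = ((xpos[mask] - cp) ** 2).sum(axis=1)
        if xneg.size:
            d2 = d2 - ((xneg[mask] - cn) ** 2).sum(axis=1)
        dist[mask] = np.sqrt(np.maximum(d2, 0.0))
    distances = pd.Series(dist, index=d.labels, name="dist_to_centroid")
    group_means = distances.groupby(groups).mean()
    pairs = list(combinations(sorted(sizes.index), 2))
    rows = []
    for a, b in pairs:
        u, p = mann_whitney(distances[garr == a], distances[garr == b])
        rows.append(dict(group_a=a, group_b=b, U=u, p=p,
                         p_bonferroni=min(1.0, p * len(pairs))))
    return DispersionResult(distances, group_means, pd.DataFrame(rows))
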