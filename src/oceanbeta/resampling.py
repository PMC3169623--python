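"""Resampling procedures: shared-OTU estimation, balanced-group ANOSIM,
cell-density weight sensitivity, and singleton/presence-absence robustness."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .group_stats import AnosimResult, anosim
from .ordination import nmds, protest
from .tables_io import OtuTable, remove_singletons
from .transforms import bray_curtis, hellinger, presence_absence


def _group_series(table: OtuTable, groups) -> pd.Series:
    if isinstance(groups, pd.Series):
        g = groups.reindex(table.sample_ids)
        if g.isna().any():
            raise ValidationError("every sample needs a group label")
        return g
    groups = list(groups)
    if len(groups) != table.n_samples:
        raise ValidationError("groups length does not match table")
    return pd.Series(groups, index=table.sample_ids)


@dataclass
class SharedOtuResult:
    """Mean/sd shared-OTU counts and percentages per group pair."""

    table: pd.DataFrame  # pair, mean_shared, sd_shared, mean_pct, sd_pct
    n_iterations: int
    design: str
    denominator: str


def _rarefy(pooled: np.ndarray, depth: int, rng) -> np.ndarray:
    total = int(pooled.sum())
    if depth >= total:
        return pooled
    return rng.multivariate_hypergeometric(pooled, depth)


def shared_otus(
    table: OtuTable,
    groups,
    n_iter: int = 100,
    design: str = "equal_samples",
    denominator: str = "union",
    seed: int | None = None,
) -> SharedOtuResult:
    """Resampled shared-OTU counts between every pair of groups.

    Each iteration draws min-group-size samples per group without
    replacement (``equal_sequences`` additionally rarefies each drawn
    group's pooled counts to the smaller group total), then counts OTUs
    present in both groups.  Percentage = shared / denominator x 100 with
    denominator ``union`` (distinct OTUs in the pair, default), ``min`` or
    ``mean`` of the two group OTU counts.
    """
    if design not in ("equal_samples", "equal_sequences"):
        raise ValueError("design must be equal_samples or equal_sequences")
    if denominator not in ("union", "min", "mean"):
        raise ValueError("denominator must be union, min or mean")
    g = _group_series(table, groups)
    sizes = g.value_counts()
    if len(sizes) < 2:
        raise ValidationError("shared_otus requires >= 2 groups")
    if (sizes < 2).any():
        raise ValidationError(f"group too small: {sizes[sizes < 2].index.tolist()}")
    rng = np.random.default_rng(seed)
    garr = g.to_numpy()
    rows = []
    for a, b in combinations(sorted(sizes.index), 2):
        ia = np.flatnonzero(garr == a)
        ib = np.flatnonzero(garr == b)
        m = min(ia.size, ib.size)
        shared_counts = np.empty(n_iter)
        shared_pcts = np.empty(n_iter)
        for it in range(n_iter):
            sa = rng.choice(ia, m, replace=False)
            sb = rng.choice(ib, m, replace=False)
            pa = table.counts[sa].sum(axis=0)
            pb = table.counts[sb].sum(axis=0)
            if design == "equal_sequences":
                depth = int(min(pa.sum(), pb.sum()))
                pa = _rarefy(pa, depth, rng)
                pb = _rarefy(pb, depth, rng)
            in_a = pa > 0
            in_b = pb > 0
            n_shared = int((in_a & in_b).sum())
            if denominator == "union":
                denom = int((in_a | in_b).sum())
            elif denominator == "min":
                denom = int(min(in_a.sum(), in_b.sum()))
            else:
                denom = (int(in_a.sum()) + int(in_b.sum())) / 2.0
            shared_counts[it] = n_shared
            shared_pcts[it] = 100.0 * n_shared / denom if denom else 0.0
        rows.append(
            dict(
                group_a=a,
                group_b=b,
                mean_shared=shared_counts.mean(),
                sd_shared=shared_counts.std(ddof=1) if n_iter > 1 else 0.0,
                mean_pct=shared_pcts.mean(),
                sd_pct=shared_pcts.std(ddof=1) if n_iter > 1 else 0.0,
            )
        )
    return SharedOtuResult(pd.DataFrame(rows), n_iter, design, denominator)


@dataclass
class BalancedAnosimResult:
    r_values: np.ndarray
    p_values: np.ndarray
    n_per_group: int
    n_perm: int

    @property
    def r_min(self) -> float:
        return float(self.r_values.min())

    @property
    def r_max(self) -> float:
        return float(self.r_values.max())

    @property
    def r_mean(self) -> float:
        return float(self.r_values.mean())

    def fraction_significant(self, alpha: float = 0.05) -> float:
        return float((self.p_values <= alpha).mean())


def balanced_anosim(
    table: OtuTable,
    groups,
    n_per_group: int = 140,
    n_iter: int = 1000,
    n_perm: int = 100,
    seed: int | None = None,
) -> BalancedAnosimResult:
    """Equal-group-size ANOSIM simulation.

    Each iteration samples *n_per_group* samples per group without
    replacement, rebuilds the Hellinger/Bray-Curtis matrix on the subset
    and reruns ANOSIM.
    """
    g = _group_series(table, groups)
    sizes = g.value_counts()
    too_small = sizes[sizes < n_per_group]
    if len(too_small):
        raise ValidationError(
            f"groups smaller than n_per_group={n_per_group}: "
            f"{too_small.index.tolist()}"
        )
    rng = np.random.default_rng(seed)
    garr = g.to_numpy()
    ids = np.asarray(table.sample_ids)
    rs = np.empty(n_iter)
    ps = np.empty(n_iter)
    for it in range(n_iter):
        chosen = np.concatenate(
            [
                rng.choice(np.flatnonzero(garr == lev), n_per_group, replace=False)
                for lev in sorted(sizes.index)
            ]
        )
        sub = table.select_samples(ids[chosen])
        d = bray_curtis(hellinger(sub), labels=sub.sample_ids)
        res = anosim(d, g.loc[sub.sample_ids], n_perm=n_perm, seed=int(rng.integers(2**32)))
        rs[it] = res.R
        ps[it] = res.p_value
    return BalancedAnosimResult(rs, ps, n_per_group, n_perm)


def weight_sensitivity(
    table: OtuTable,
    groups,
    weights=(0.1, 0.316, 1.0, 3.16, 10.0),
    n_perm: int = 1000,
    seed: int | None = None,
    transform: str = "raw",
) -> pd.DataFrame:
    """ANOSIM separation as one realm's counts are up/down-weighted.

    The weight multiplies the counts of the first (sorted) group before
    any transformation.  ``transform='raw'`` feeds the weighted counts
    straight into Bray-Curtis (weights are visible); ``'hellinger'``
    standardizes per sample first, which makes the pipeline scale
    invariant so R(w) is constant -- useful as a control.  The same
    ANOSIM seed is used for every weight, so w = 1 reproduces the
    unweighted analysis exactly.
    """
    g = _group_series(table, groups)
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValidationError("weight_sensitivity requires exactly two groups")
    if any(w <= 0 for w in weights):
        raise ValidationError("weights must be > 0")
    if transform not in ("raw", "hellinger"):
        raise ValueError("transform must be raw or hellinger")
    target = (g == levels[0]).to_numpy()
    anosim_seed = int(np.random.default_rng(seed).integers(2**32))
    rows = []
    for w in weights:
        m = table.counts.astype(float).copy()
        m[target] *= float(w)
        mat = hellinger(m) if transform == "hellinger" else m
        d = bray_curtis(mat, labels=table.sample_ids)
        res = anosim(d, g, n_perm=n_perm, seed=anosim_seed)
        rows.append(dict(weight=float(w), R=res.R, p=res.p_value))
    return pd.DataFrame(rows)


def robustness_procrustes(
    table: OtuTable,
    seed: int | None = None,
    k: int = 2,
    n_starts: int = 20,
    n_perm: int = 999,
) -> pd.DataFrame:
    """Procrustes correlation of the full-data NMDS against two variants:
    singleton-free and presence/absence."""
    if table.n_samples < 4:
        raise ValidationError("robustness_procrustes requires >= 4 samples")
    rng = np.random.default_rng(seed)
    nmds_seed = int(rng.integers(2**32))  # shared: identical variants match exactly

    def ordinate(mat):
        d = bray_curtis(mat, labels=table.sample_ids)
        return nmds(d, k=k, n_starts=n_starts, seed=nmds_seed)

    full = ordinate(hellinger(table))
    nosingle_t = remove_singletons(table)
    if nosingle_t.n_otus == 0:
        raise ValidationError("table is all singletons; nothing left after removal")
    variants = {
        "no_singletons": ordinate(hellinger(nosingle_t)),
        # presence/absence runs through the same standardization pipeline,
        # so an already-binary table reproduces the full analysis exactly
        "presence_absence": ordinate(hellinger(presence_absence(table))),
    }
    rows = []
    for name, ordn in variants.items():
        res = protest(full, ordn, n_perm=n_perm, seed=int(rng.integers(2**32)))
        rows.append(
            dict(
                comparison=f"full_vs_{name}",
                correlation=res.correlation,
                m2=res.m2,
                p=res.p_value,
            )
        )
    return pd.DataFrame(rows)
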