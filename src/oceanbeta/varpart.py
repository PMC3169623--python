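"""Redundancy analysis, db-RDA, adjusted R2 and 2-4 set variation partitioning."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .tables_io import SampleMetadata
from .transforms import DissimilarityMatrix, great_circle, pcoa


@dataclass
class RdaStats:
    r2: float
    adj_r2: float
    pseudo_f: float
    rank: int


def _design_matrix(x) -> np.ndarray:
    if x is None:
        return np.zeros((0, 0))
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def _prune_columns(x: np.ndarray, warn: bool = True) -> np.ndarray:
    """Drop constant and linearly dependent columns (QR pivoting)."""
    if x.size == 0:
        return x.reshape(x.shape[0], 0)
    xc = x - x.mean(axis=0)
    keep_nonconst = np.ptp(x, axis=0) > 0
    xc = xc[:, keep_nonconst]
    if xc.shape[1] == 0:
        return xc
    q, r, piv = _qr_pivot(xc)
    tol = max(xc.shape) * np.finfo(float).eps * abs(r[0, 0]) if r.size else 0.0
    rank = int(np.sum(np.abs(np.diag(r)) > tol))
    if rank < xc.shape[1] and warn:
        warnings.warn(
            f"design: dropped {xc.shape[1] - rank} collinear column(s)",
            stacklevel=3,
        )
    keep = np.sort(piv[:rank])
    return xc[:, keep]


def _qr_pivot(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, mode="economic", pivoting=True)
    return q, r, piv


def rda_r2(y, x) -> RdaStats:
    """Redundancy analysis fit: R2, adjusted R2 and pseudo-F of y ~ x.

    y is column-centred internally; x is centred and pruned to full column
    rank.  adjusted R2 = 1 - (1 - R2)(n - 1)/(n - m - 1) with m = rank(x).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    ss_total = float(np.sum(yc**2))
    xm = _prune_columns(_design_matrix(x), warn=False)
    m = xm.shape[1]
    if m == 0:
        return RdaStats(0.0, 0.0, float("nan"), 0)
    if n <= m + 1:
        raise ValidationError(f"rda needs n > m + 1 (n={n}, m={m})")
    if ss_total <= 0:
        raise ValidationError("response has zero variance")
    q, _ = np.linalg.qr(xm)
    fitted = q @ (q.T @ yc)
    ss_fit = float(np.sum(fitted**2))
    r2 = ss_fit / ss_total
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    f = (ss_fit / m) / ((ss_total - ss_fit) / (n - m - 1))
    return RdaStats(r2, adj, f, m)


def db_rda_r2(d: DissimilarityMatrix, x) -> RdaStats:
    """Distance-based RDA: RDA on the positive-axis PCoA embedding of d."""
    coords = pcoa(d, negative_eig="keep_positive").coordinates
    return rda_r2(coords, x)


def _response_matrix(y_or_d) -> np.ndarray:
    if isinstance(y_or_d, DissimilarityMatrix):
        return pcoa(y_or_d, negative_eig="keep_positive").coordinates
    y = np.asarray(y_or_d, dtype=float)
    return y[:, None] if y.ndim == 1 else y


@dataclass
class PartialTestResult:
    pure_adj_r2: float
    pseudo_f: float
    p_value: float
    rank_x: int
    rank_z: int


def partial_test(
    y_or_d,
    x,
    z=None,
    n_perm: int = 1000,
    seed: int | None = None,
    scheme: str = "freedman_lane",
) -> PartialTestResult:
    """Permutation test of the pure effect of x conditioned on z.

    The statistic is the partial pseudo-F of x after z.  Under
    ``freedman_lane`` the reduced-model (y ~ z) residuals are permuted and
    added back to the reduced-model fit; ``raw`` permutes y rows directly.
    p = (b + 1)/(m + 1).  The pure adjusted R2 is
    adjR2(x union z) - adjR2(z).
    """
    if scheme not in ("freedman_lane", "raw"):
        raise ValueError("scheme must be 'freedman_lane' or 'raw'")
    y = _response_matrix(y_or_d)
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    xm = _prune_columns(_design_matrix(x), warn=False)
    zm = _prune_columns(_design_matrix(z), warn=False) if z is not None else np.zeros((n, 0))
    mx_cols = xm.shape[1]
    if mx_cols == 0:
        raise ValidationError("empty focal design")
    both = np.hstack([zm, xm]) if zm.shape[1] else xm
    both_p = _prune_columns(both, warn=False)
    mz = zm.shape[1]
    mfull = both_p.shape[1]
    mx = mfull - mz
    if mx <= 0:
        warnings.warn("focal set collinear with conditioning set; pure effect is empty",
                      stacklevel=2)
        return PartialTestResult(0.0, float("nan"), 1.0, 0, mz)

    def partial_f(resp: np.ndarray) -> float:
        if mz:
            qz, _ = np.linalg.qr(zm)
            r = resp - qz @ (qz.T @ resp)
        else:
            r = resp
        qf, _ = np.linalg.qr(both_p)
        fit_full = qf @ (qf.T @ resp)
        ss_res_full = float(np.sum((resp - fit_full) ** 2))
        if mz:
            ss_x_after_z = float(np.sum(fit_full**2)) - float(
                np.sum((qz @ (qz.T @ resp)) ** 2)
            )
        else:
            ss_x_after_z = float(np.sum(fit_full**2))
        dfe = n - mfull - 1
        return (ss_x_after_z / mx) / (ss_res_full / dfe)

    f_obs = partial_f(yc)
    rng = np.random.default_rng(seed)
    if mz:
        qz, _ = np.linalg.qr(zm)
        fit_z = qz @ (qz.T @ yc)
        resid_z = yc - fit_z
    else:
        fit_z = np.zeros_like(yc)
        resid_z = yc
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if scheme == "freedman_lane":
            ystar = fit_z + resid_z[perm]
        else:
            ystar = yc[perm]
        hits += partial_f(ystar - ystar.mean(axis=0)) >= f_obs - 1e-12
    p = (hits + 1) / (n_perm + 1)
    adj_both = rda_r2(yc, both_p).adj_r2
    adj_z = rda_r2(yc, zm).adj_r2 if mz else 0.0
    return PartialTestResult(float(adj_both - adj_z), float(f_obs), float(p), mx, mz)


@dataclass
class VarpartResult:
    """Venn decomposition of adjusted R2 over 2-4 explanatory sets."""

    set_names: list[str]
    fractions: dict[frozenset, float]  # exactly-these-sets Venn cells
    full_adj_r2: float
    unexplained: float
    pure_tests: pd.DataFrame  # set, pure_adj_r2, pseudo_f, p

    def pure(self, name: str) -> float:
        return self.fractions[frozenset([name])]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fraction": "+".join(sorted(k)), "n_sets": len(k), "adj_r2": v}
            for k, v in sorted(self.fractions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        rows.append({"fraction": "unexplained", "n_sets": 0, "adj_r2": self.unexplained})
        return pd.DataFrame(rows)


def variation_partition(
    y_or_d,
    sets: dict,
    n_perm: int = 1000,
    seed: int | None = None,
    scheme: str = "freedman_lane",
) -> VarpartResult:
    """Partition explained variance among 2-4 explanatory sets.

    Adjusted R2 is computed for every non-empty union of sets and the
    Venn cells are recovered by inclusion-exclusion; cells may be
    negative (adjusted-R2 artefact) and are reported as-is.  Only pure
    (single-set) cells are permutation-tested; shared cells are deduced
    numerically and therefore untestable.
    """
    names = list(sets)
    k = len(names)
    if not 1 <= k <= 4:
        raise ValidationError("variation_partition supports 1-4 sets")
    y = _response_matrix(y_or_d)
    mats = {nm: _prune_columns(_design_matrix(sets[nm]), warn=True) for nm in names}
    empty = [nm for nm, m in mats.items() if m.shape[1] == 0]
    if empty:
        raise ValidationError(f"explanatory set(s) with no usable columns: {empty}")

    def adj_of(subset: frozenset) -> float:
        if not subset:
            return 0.0
        xm = np.hstack([mats[nm] for nm in names if nm in subset])
        return rda_r2(y, xm).adj_r2

    all_sets = frozenset(names)
    subsets = [frozenset(c) for r in range(k + 1) for c in combinations(names, r)]
    a = {s: adj_of(s) for s in subsets}
    full = a[all_sets]
    # g(V) = variance of cells fully inside V = A(full) - A(full \ V)
    g = {s: full - a[all_sets - s] for s in subsets}
    fractions: dict[frozenset, float] = {}
    for t in subsets:
        if not t:
            continue
        val = 0.0
        for r in range(len(t) + 1):
            for v in combinations(t, r):
                val += (-1) ** (len(t) - r) * g[frozenset(v)]
        fractions[t] = val

    rng = np.random.default_rng(seed)
    rows = []
    for nm in names:
        others = [mats[o] for o in names if o != nm]
        zm = np.hstack(others) if others else None
        res = partial_test(y, mats[nm], zm, n_perm=n_perm,
                           seed=int(rng.integers(2**32)), scheme=scheme)
        rows.append(dict(set=nm, pure_adj_r2=res.pure_adj_r2,
                         pseudo_f=res.pseudo_f, p=res.p_value))
    return VarpartResult(names, fractions, float(full), float(1.0 - full),
                         pd.DataFrame(rows))


def build_design(
    meta: SampleMetadata,
    spatial_axes: str = "all_positive",
    k_spatial: int = 2,
    productivity: str = "both",
) -> dict:
    """Assemble the four explanatory sets from classified metadata.

    ecosystem: dummy-coded ecosystem type (reference level dropped);
    space: PCoA axes of great-circle distances plus water depth;
    time: days since earliest sampling; productivity: Longhurst
    productivity index and/or fisheries yield class.
    """
    if spatial_axes not in ("all_positive", "first_k", "depth_only"):
        raise ValueError("spatial_axes must be all_positive, first_k or depth_only")
    if productivity not in ("both", "longhurst", "fisheries"):
        raise ValueError("productivity must be both, longhurst or fisheries")
    cls = meta.classify()
    eco = pd.get_dummies(cls["ecosystem"], prefix="eco", drop_first=True).astype(float)
    if eco.shape[1] == 0:
        warnings.warn("single ecosystem level; ecosystem set is empty", stacklevel=2)
    depth = meta.frame["water_depth"].rename("water_depth").to_frame()
    if spatial_axes == "depth_only":
        space = depth
    else:
        geo = pcoa(great_circle(meta), negative_eig="keep_positive")
        coords = geo.to_frame()
        if spatial_axes == "first_k":
            coords = coords.iloc[:, :k_spatial]
        coords.index = meta.frame.index
        space = pd.concat([coords, depth], axis=1)
    time_col = meta.days_since_earliest().astype(float).to_frame()
    if time_col["time_days"].nunique() == 1:
        warnings.warn("all samples share one date; time column dropped", stacklevel=2)
        time_col = time_col.iloc[:, :0]
    prod_cols = []
    if productivity in ("both", "longhurst"):
        prod_cols.append(meta.frame["longhurst_productivity"].astype(float))
    if productivity in ("both", "fisheries"):
        prod_cols.append(meta.frame["fisheries_class"].astype(float))
    prod = pd.concat(prod_cols, axis=1)
    return {"ecosystem": eco, "space": space, "time": time_col, "productivity": prod}
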