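"""Abundance standardizations, dissimilarities, geodesic distances and PCoA."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import ValidationError
from .tables_io import OtuTable, SampleMetadata

EARTH_RADIUS_KM = 6371.0


@dataclass
class DissimilarityMatrix:
    """Symmetric, zero-diagonal, non-negative pairwise dissimilarities."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("matrix is not symmetric (tol 1e-12)")
        if v.size and v.min() < 0:
            raise ValidationError("negative dissimilarities")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def submatrix(self, ids: Sequence[str]) -> "DissimilarityMatrix":
        idx = {s: i for i, s in enumerate(self.labels)}
        rows = [idx[s] for s in ids]
        return DissimilarityMatrix([self.labels[r] for r in rows], self.values[np.ix_(rows, rows)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        self.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy())


@dataclass
class PcoaResult:
    """Principal coordinates: centred sample scores plus eigenvalue diagnostics."""

    labels: list[str]
    coordinates: np.ndarray  # samples x retained axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    prop_explained: np.ndarray  # per retained axis, relative to positive sum

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def _as_matrix(t) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(t, OtuTable):
        return t.counts.astype(float), list(t.sample_ids)
    return np.asarray(t, dtype=float), None


def hellinger(t) -> np.ndarray:
    """Hellinger standardization: sqrt of per-sample relative abundance."""
    m, _ = _as_matrix(t)
    totals = m.sum(axis=1)
    if (totals <= 0).any():
        raise ValidationError("hellinger: sample with zero total")
    return np.sqrt(m / totals[:, None])


def presence_absence(t) -> np.ndarray:
    m, _ = _as_matrix(t)
    return (m > 0).astype(float)


def bray_curtis(m, labels: Sequence[str] | None = None) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    m, inferred = _as_matrix(m)
    labels = list(labels) if labels is not None else inferred
    if labels is None:
        labels = [str(i) for i in range(m.shape[0])]
    if (m < 0).any():
        raise ValidationError("bray_curtis requires non-negative entries")
    if (m.sum(axis=1) == 0).any():
        raise ValidationError("bray_curtis undefined for all-zero samples")
    d = squareform(pdist(m, metric="braycurtis"))
    return DissimilarityMatrix(labels, d)


def great_circle(meta, labels: Sequence[str] | None = None) -> DissimilarityMatrix:
    """Haversine great-circle distances in km (mean Earth radius 6371.0 km)."""
    if isinstance(meta, SampleMetadata):
        lat = meta.frame["latitude"].to_numpy(float)
        lon = meta.frame["longitude"].to_numpy(float)
        labels = meta.sample_ids
    else:
        lat, lon = (np.asarray(a, dtype=float) for a in meta)
        if labels is None:
            labels = [str(i) for i in range(lat.size)]
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    return DissimilarityMatrix(list(labels), d)


def gower_eig(d: DissimilarityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the Gower-centred matrix, descending order."""
    a = -0.5 * d.values**2
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    w, v = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def pcoa(d: DissimilarityMatrix, negative_eig: str = "keep_positive") -> PcoaResult:
    """Principal coordinates analysis of a dissimilarity matrix.

    ``keep_positive`` retains axes with eigenvalue > 1e-8 x the leading
    eigenvalue; ``lingoes`` applies the additive constant correction first
    so all axes become non-negative.
    """
    if negative_eig not in ("keep_positive", "lingoes"):
        raise ValueError("negative_eig must be 'keep_positive' or 'lingoes'")
    w, v = gower_eig(d)
    if negative_eig == "lingoes" and w[-1] < -1e-12:
        c = -w[-1]
        d2 = d.values**2 + 2 * c
        np.fill_diagonal(d2, 0.0)
        corrected = DissimilarityMatrix(d.labels, np.sqrt(d2))
        w, v = gower_eig(corrected)
    lead = max(w[0], 0.0)
    if lead <= 0:
        # degenerate all-zero matrix: single trivial axis
        coords = np.zeros((d.n, 1))
        return PcoaResult(list(d.labels), coords, w, np.array([0.0]))
    keep = w > 1e-8 * lead
    coords = v[:, keep] * np.sqrt(w[keep])
    coords -= coords.mean(axis=0)
    pos_sum = w[w > 0].sum()
    return PcoaResult(list(d.labels), coords, w, w[keep] / pos_sum)
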