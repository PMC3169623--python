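"""Data model and I/O for OTU count tables, sample metadata and taxonomies.

The table model is deliberately simple: an :class:`OtuTable` is a dense
samples x OTUs integer matrix with label vectors, metadata is a validated
:class:`pandas.DataFrame` wrapper, and taxonomy is a rank-prefix lineage
table.  All on-disk formats are plain TSV (tab-separated, UTF-8, header
row); a dense BIOM-style JSON table is accepted read-only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ClassificationError, FormatError, ValidationError

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
UNASSIGNED = "UNASSIGNED"

PELAGIC = "pelagic"
BENTHIC = "benthic"

#: canonical (realm, ecosystem) ordering used for summary tables
GROUP_ORDER = (
    (PELAGIC, "coastal"),
    (PELAGIC, "surface_open_ocean"),
    (PELAGIC, "deep_open_ocean"),
    (PELAGIC, "vent"),
    (PELAGIC, "anoxic"),
    (BENTHIC, "coastal"),
    (BENTHIC, "deep_seafloor"),
    (BENTHIC, "vent"),
)

REQUIRED_METADATA_COLUMNS = (
    "latitude",
    "longitude",
    "water_depth",
    "distance_to_coast",
    "sample_depth_kind",
    "special_habitat",
    "date",
    "longhurst_productivity",
    "fisheries_class",
)

#: boundary thresholds (nautical miles / metres); coastal is strictly below,
#: deep uses >= so the classification partitions every valid sample
COASTAL_NMI = 200.0
DEEP_M = 200.0


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate {what} ids: {dupes[:5]}")
    bad = [i for i in ids if "." in i]
    if bad:
        raise FormatError(f"'.' is forbidden in {what} ids: {bad[:5]}")
    return ids


class OtuTable:
    """Dense samples x OTUs table of non-negative integer counts."""

    def __init__(
        self,
        sample_ids: Sequence[str],
        otu_ids: Sequence[str],
        counts,
        validate: bool = True,
    ):
        self.sample_ids = [str(s) for s in sample_ids]
        self.otu_ids = [str(o) for o in otu_ids]
        counts = np.asarray(counts)
        if validate:
            self.sample_ids = _check_ids(self.sample_ids, "sample")
            self.otu_ids = _check_ids(self.otu_ids, "OTU")
            if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
                raise ValidationError(
                    f"counts shape {counts.shape} does not match "
                    f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
                )
            if counts.size and not np.issubdtype(counts.dtype, np.integer):
                rounded = np.rint(counts)
                if not np.allclose(counts, rounded, atol=1e-9):
                    raise ValidationError("counts must be integers")
                counts = rounded
            counts = counts.astype(np.int64, copy=False)
            if counts.size and counts.min() < 0:
                raise ValidationError("counts must be >= 0")
            empty = np.flatnonzero(counts.sum(axis=1) == 0)
            if empty.size:
                names = [self.sample_ids[i] for i in empty[:5]]
                raise ValidationError(f"samples with zero total count: {names}")
        self.counts = counts.astype(np.int64, copy=False)

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def otu_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, validate: bool = True) -> "OtuTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(), validate=validate)

    def select_samples(self, ids: Iterable[str]) -> "OtuTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in ids]
        sub = self.counts[rows]
        keep = sub.sum(axis=0) > 0
        return OtuTable(
            [self.sample_ids[r] for r in rows],
            [o for o, k in zip(self.otu_ids, keep) if k],
            sub[:, keep],
            validate=False,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"OtuTable({self.n_samples} samples x {self.n_otus} OTUs)"


@dataclass
class SampleMetadata:
    """Validated per-sample metadata indexed by sample id.

    Unknown columns are preserved untouched as opaque covariates.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        for col, lo, hi in (
            ("latitude", -90.0, 90.0),
            ("longitude", -180.0, 180.0),
        ):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad = df.index[vals.isna()][0]
                raise ValidationError(f"unparseable {col} for sample {bad!r}")
            if ((vals < lo) | (vals > hi)).any():
                bad = df.index[(vals < lo) | (vals > hi)][0]
                raise ValidationError(
                    f"{col} out of range [{lo}, {hi}] for sample {bad!r}"
                )
            df[col] = vals.astype(float)
        for col in ("water_depth", "distance_to_coast"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any() or (vals < 0).any():
                bad = df.index[vals.isna() | (vals < 0)][0]
                raise ValidationError(f"invalid {col} for sample {bad!r}")
            df[col] = vals.astype(float)
        try:
            df["date"] = pd.to_datetime(df["date"], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"unparseable date in metadata: {exc}") from exc
        for col, allowed in (
            ("sample_depth_kind", {"water", "sediment"}),
            ("special_habitat", {"none", "vent", "anoxic"}),
        ):
            bad = set(df[col].astype(str)) - allowed
            if bad:
                raise ValidationError(f"invalid {col} values: {sorted(bad)}")
            df[col] = df[col].astype(str)
        for col in ("longhurst_productivity", "fisheries_class"):
            df[col] = pd.to_numeric(df[col]).astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def require_samples(self, ids: Iterable[str]) -> None:
        missing = [s for s in ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing[:5]}")

    def days_since_earliest(self) -> pd.Series:
        d = self.frame["date"]
        return (d - d.min()).dt.days.rename("time_days")

    def subset(self, ids: Iterable[str]) -> "SampleMetadata":
        self.require_samples(ids)
        return SampleMetadata(self.frame.loc[list(ids)].copy())

    def classify(self) -> pd.DataFrame:
        """Ecosystem/realm assignment for every sample (columns: ecosystem, realm)."""
        rows = {
            s: classify_ecosystem(self.frame.loc[s]) for s in self.frame.index
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=["ecosystem", "realm"])


def classify_ecosystem(rec: Mapping) -> tuple[str, str]:
    """Assign (ecosystem, realm) from one metadata record.

    Rules: special habitats (vent, anoxic) override the depth/distance
    thresholds.  Realm is benthic iff the sample is a sediment sample.
    Water: coastal below 200 nmi and 200 m; >=200 m is deep open ocean,
    otherwise surface open ocean.  Sediment: coastal below 200 m, else
    deep seafloor.  Thresholds: coastal strictly <, deep >=, so the
    classification is total.
    """
    try:
        kind = str(rec["sample_depth_kind"])
        special = str(rec["special_habitat"])
        dist = float(rec["distance_to_coast"])
        depth = float(rec["water_depth"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ClassificationError(f"missing/invalid classification field: {exc}") from exc
    if kind not in ("water", "sediment"):
        raise ClassificationError(f"unknown sample_depth_kind {kind!r}")
    realm = BENTHIC if kind == "sediment" else PELAGIC
    if special == "vent":
        return "vent", realm
    if special == "anoxic":
        return "anoxic", realm
    if special != "none":
        raise ClassificationError(f"unknown special_habitat {special!r}")
    if realm == PELAGIC:
        if depth >= DEEP_M:
            return "deep_open_ocean", realm
        if dist < COASTAL_NMI:
            return "coastal", realm
        return "surface_open_ocean", realm
    return ("coastal" if depth < DEEP_M else "deep_seafloor"), realm


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read a samples x OTUs count table (TSV, or dense BIOM-style JSON)."""
    if format == "tsv":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        _check_ids(header, "OTU")  # before pandas mangles duplicates
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        df.columns = [str(c) for c in df.columns]
        df.index = [str(i) for i in df.index]
        return OtuTable.from_frame(df)
    if format == "biom_dense":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") != "dense":
            raise FormatError("only dense BIOM-style JSON is supported")
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        data = np.asarray(doc["data"])
        # BIOM orientation is observations x samples; normalize
        return OtuTable(sample_ids, otu_ids, data.T)
    raise ValueError(f"unknown format {format!r}")


def write_otu_table(table: OtuTable, path) -> None:
    table.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("metadata must have a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.frame.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.rename_axis("sample_id").to_csv(path, sep="\t")


@dataclass
class TaxonomyTable:
    """Lineage table: one row per OTU, columns are the six ranks.

    Prefix annotation is enforced: once a rank is UNASSIGNED, every rank
    below it is UNASSIGNED as well.  Violating rows are repaired by
    truncation on construction (with a warning).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        missing = [r for r in RANKS if r not in df.columns]
        if missing:
            raise FormatError(f"taxonomy missing rank columns: {missing}")
        if df.index.has_duplicates:
            raise FormatError("duplicate otu ids in taxonomy")
        df[list(RANKS)] = df[list(RANKS)].astype(str)
        vals = df[list(RANKS)].to_numpy()
        unass = vals == UNASSIGNED
        # repair: everything below the first UNASSIGNED becomes UNASSIGNED
        seen = np.zeros(len(df), dtype=bool)
        repaired = 0
        for j in range(len(RANKS)):
            bad = seen & ~unass[:, j]
            repaired += int(bad.sum())
            vals[seen, j] = UNASSIGNED
            seen |= unass[:, j]
        if repaired:
            warnings.warn(
                f"taxonomy: repaired {repaired} rank entries below an "
                "UNASSIGNED rank (truncated to UNASSIGNED)",
                stacklevel=2,
            )
            df[list(RANKS)] = vals

    def assigned_at(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.frame[rank] != UNASSIGNED

    def names_at(self, rank: str) -> pd.Series:
        return self.frame[rank]


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "otu_id" not in df.columns:
        raise FormatError("taxonomy must have an otu_id column")
    return TaxonomyTable(df.set_index("otu_id"))


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.frame.rename_axis("otu_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# table operations
# ---------------------------------------------------------------------------

def aggregate_by_rank(
    table: OtuTable,
    taxonomy: TaxonomyTable,
    rank: str,
    missing: str = "drop",
) -> tuple[OtuTable, dict]:
    """Sum OTU counts by taxon name at *rank*.

    OTUs unassigned at *rank* are excluded from the aggregated table but
    tallied in the report.  OTUs absent from the taxonomy are treated as
    unassigned when ``missing='drop'`` (a warning is emitted), or raise
    when ``missing='error'``.

    Returns the aggregated table (taxa as columns) and a report dict with
    OTU/sequence assignment fractions.
    """
    if rank not in RANKS[1:]:
        raise ValueError(f"rank must be one of {RANKS[1:]}, got {rank!r}")
    absent = [o for o in table.otu_ids if o not in taxonomy.frame.index]
    if absent:
        if missing == "error":
            raise ValidationError(f"OTUs missing from taxonomy: {absent[:5]}")
        warnings.warn(
            f"{len(absent)} OTUs missing from taxonomy; treated as unassigned",
            stacklevel=2,
        )
    names = {}
    for o in table.otu_ids:
        if o in taxonomy.frame.index:
            n = taxonomy.frame.at[o, rank]
            names[o] = None if n == UNASSIGNED else n
        else:
            names[o] = None
    assigned_mask = np.array([names[o] is not None for o in table.otu_ids])
    total_seqs = int(table.counts.sum())
    assigned_seqs = int(table.counts[:, assigned_mask].sum())
    report = {
        "rank": rank,
        "n_otus": table.n_otus,
        "n_otus_assigned": int(assigned_mask.sum()),
        "otu_fraction_assigned": float(assigned_mask.mean()) if table.n_otus else 0.0,
        "n_sequences": total_seqs,
        "n_sequences_assigned": assigned_seqs,
        "sequence_fraction_assigned": assigned_seqs / total_seqs if total_seqs else 0.0,
    }
    if not assigned_mask.any():
        warnings.warn(f"no OTUs assigned at rank {rank!r}", stacklevel=2)
        agg = OtuTable(table.sample_ids, [], np.zeros((table.n_samples, 0), dtype=np.int64), validate=False)
        return agg, report
    taxa = sorted({names[o] for o in table.otu_ids if names[o] is not None})
    col = {t: j for j, t in enumerate(taxa)}
    out = np.zeros((table.n_samples, len(taxa)), dtype=np.int64)
    for i, o in enumerate(table.otu_ids):
        n = names[o]
        if n is not None:
            out[:, col[n]] += table.counts[:, i]
    agg = OtuTable(table.sample_ids, taxa, out, validate=False)
    return agg, report


def mean_composition(
    table: OtuTable,
    groups: pd.Series,
    top_n: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean and sd of per-sample relative abundances.

    With *top_n*, only the globally most abundant *top_n* taxa are kept and
    the remainder is pooled into an ``other`` column.  Returns
    ``(means, sds)`` frames of shape groups x taxa; sd is the sample
    standard deviation (0 for singleton groups).
    """
    groups = groups.reindex(table.sample_ids)
    if groups.isna().any():
        raise ValidationError("every sample needs a group label")
    rel = table.counts / table.sample_sums[:, None]
    df = pd.DataFrame(rel, index=table.sample_ids, columns=table.otu_ids)
    if top_n is not None and top_n < df.shape[1]:
        order = df.mean(axis=0).sort_values(ascending=False)
        keep = list(order.index[:top_n])
        other = df.drop(columns=keep).sum(axis=1)
        df = df[keep]
        df["other"] = other
    means = df.groupby(groups).mean()
    sds = df.groupby(groups).std(ddof=1).fillna(0.0)
    if (means.index.value_counts() == 0).any() or means.empty:
        raise ValidationError("empty group in mean_composition")
    return means, sds


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs whose total count across the whole dataset is exactly 1."""
    keep = table.otu_sums != 1
    return OtuTable(
        table.sample_ids,
        [o for o, k in zip(table.otu_ids, keep) if k],
        table.counts[:, keep],
        validate=False,
    )


@dataclass
class SummaryTable:
    """Per-(realm, ecosystem) sample/sequence/OTU/singleton bookkeeping."""

    frame: pd.DataFrame  # index (realm, ecosystem) incl. totals rows

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t")

    def grand_total(self, column: str) -> int:
        return int(self.frame.loc[("all", "grand_total"), column])


def summarize_dataset(
    table: OtuTable,
    meta: SampleMetadata,
    singleton_scope: str = "dataset",
) -> SummaryTable:
    """Build the per-ecosystem summary (sample/sequence/OTU/singleton counts).

    Singletons are defined dataset-wide (total abundance exactly 1) and
    attributed to the group holding the single occurrence.  The
    experimental ``singleton_scope='group'`` recomputes singleton status
    within each group instead.
    """
    if singleton_scope not in ("dataset", "group"):
        raise ValueError("singleton_scope must be 'dataset' or 'group'")
    meta.require_samples(table.sample_ids)
    cls = meta.classify().loc[table.sample_ids]
    singleton_global = table.otu_sums == 1

    rows = []
    index = []
    order = [g for g in GROUP_ORDER] + sorted(
        set(zip(cls["realm"], cls["ecosystem"])) - set(GROUP_ORDER)
    )
    for realm, eco in order:
        mask = ((cls["realm"] == realm) & (cls["ecosystem"] == eco)).to_numpy()
        if not mask.any():
            continue
        sub = table.counts[mask]
        present = sub.sum(axis=0) > 0
        if singleton_scope == "dataset":
            n_single = int((singleton_global & present).sum())
        else:
            n_single = int((sub.sum(axis=0) == 1).sum())
        rows.append(
            dict(
                n_samples=int(mask.sum()),
                n_sequences=int(sub.sum()),
                n_otus=int(present.sum()),
                n_singleton_otus=n_single,
            )
        )
        index.append((realm, eco))
    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["realm", "ecosystem"]))
    for realm in (PELAGIC, BENTHIC):
        if realm not in df.index.get_level_values(0):
            continue
        mask = (cls["realm"] == realm).to_numpy()
        sub = table.counts[mask]
        present = sub.sum(axis=0) > 0
        if singleton_scope == "dataset":
            n_single = int((singleton_global & present).sum())
        else:
            n_single = int((sub.sum(axis=0) == 1).sum())
        df.loc[(realm, "total"), :] = [
            int(mask.sum()), int(sub.sum()), int(present.sum()), n_single,
        ]
    df.loc[("all", "grand_total"), :] = [
        table.n_samples,
        int(table.counts.sum()),
        int((table.otu_sums > 0).sum()),
        int(singleton_global.sum()) if singleton_scope == "dataset"
        else int((table.otu_sums == 1).sum()),
    ]
    return SummaryTable(df.astype(int))
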