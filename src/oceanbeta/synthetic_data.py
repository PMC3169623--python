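"""Synthetic marine community generator.

Produces OTU tables, metadata and taxonomies with the statistical
structure the downstream analyses assume: two realm pools with a small
fixed overlap, heavy-tailed (singleton-rich) abundance distributions, a
more even benthic realm, multiplicative ecosystem/productivity/time
effects and a spatially autocorrelated field with realm-specific decay
ranges.  Counts are multinomial draws at a negative-binomially
distributed sequencing depth.  Everything is reproducible from a single
seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .tables_io import (
    BENTHIC,
    PELAGIC,
    RANKS,
    UNASSIGNED,
    OtuTable,
    SampleMetadata,
    TaxonomyTable,
    write_metadata,
    write_otu_table,
    write_taxonomy,
)
from .transforms import great_circle

DEFAULT_GROUP_SIZES = {
    (PELAGIC, "coastal"): 40,
    (PELAGIC, "surface_open_ocean"): 30,
    (PELAGIC, "deep_open_ocean"): 30,
    (PELAGIC, "vent"): 10,
    (PELAGIC, "anoxic"): 10,
    (BENTHIC, "coastal"): 40,
    (BENTHIC, "deep_seafloor"): 35,
    (BENTHIC, "vent"): 10,
}

DEFAULT_ASSIGNED_FRACTIONS = {
    "phylum": 0.23,
    "class": 0.20,
    "order": 0.18,
    "family": 0.17,
    "genus": 0.16,
}


@dataclass
class SimulationParams:
    """Knobs of the community generator (all effects act on log abundance)."""

    n_otus_pool: int = 5000
    realm_overlap: float = 0.07
    n_samples: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    abundance_model: str = "lognormal"  # or "logseries"
    abundance_shape: float = 3.0  # lognormal sigma / logseries p
    sequencing_depth: float = 2000.0
    depth_dispersion: float | None = 5.0  # None -> fixed depth
    evenness_contrast: float = 2.0  # benthic shape softened by this factor
    shared_abundance_boost: float = 3.0  # log-scale boost of shared OTUs
    spatial_decay_range: dict = field(
        default_factory=lambda: {PELAGIC: 8000.0, BENTHIC: 2000.0}
    )
    spatial_effect_size: float = 0.5
    n_spatial_factors: int = 2
    sample_noise: float = 2.0  # per-(sample, OTU) lognormal overdispersion sd
    occupancy_exponent: float = 20.0  # abundance-occupancy coupling; 0 = all present
    occupancy_floor: float = 0.015  # satellite taxa: minimum per-sample presence rate
    presence_floor_reads: float = 0.3  # expected reads an occurrence contributes at least
    satellite_cap_reads: float = 0.5  # satellite occurrences stay near detection limit
    ecosystem_effect_size: float = 1.0
    productivity_effect_size: float = 0.3
    time_effect_size: float = 0.1
    singleton_target: float = 0.5
    assigned_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_ASSIGNED_FRACTIONS)
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("realm_overlap", "singleton_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.sequencing_depth < 1:
            raise ValidationError("sequencing_depth must be >= 1")
        if self.abundance_model not in ("lognormal", "logseries"):
            raise ValidationError("abundance_model must be lognormal or logseries")
        if self.abundance_model == "logseries" and not 0 < self.abundance_shape < 1:
            raise ValidationError("logseries shape must be in (0, 1)")
        if self.n_otus_pool < 4:
            raise ValidationError("n_otus_pool too small")


@dataclass
class GroundTruth:
    """Latent quantities recorded during generation."""

    seed: int
    pools: dict  # realm -> list of otu ids; plus "shared"
    sample_table: pd.DataFrame  # realm, ecosystem, productivity latent, time
    effect_sizes: dict
    expected_composition: pd.DataFrame | None = None  # samples x pool OTUs
    spatial_factors: dict | None = None  # realm -> (samples x factors)

    def to_json(self, path) -> None:
        doc = {
            "seed": self.seed,
            "pools": self.pools,
            "effect_sizes": self.effect_sizes,
            "samples": {
                s: {
                    k: (v if not isinstance(v, (np.floating, np.integer)) else v.item())
                    for k, v in rec.items()
                }
                for s, rec in self.sample_table.to_dict(orient="index").items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _base_abundance(model: str, shape: float, n: int, rng) -> np.ndarray:
    """Unnormalized per-OTU base abundances on the log scale."""
    if model == "lognormal":
        return rng.normal(0.0, shape, n)
    # logseries: heavy-tailed integer weights, log-transformed
    draws = stats.logser.rvs(shape, size=n, random_state=rng)
    return np.log(draws.astype(float))


def _spatial_field(dist_km: np.ndarray, rng, range_km: float, n_factors: int) -> np.ndarray:
    cov = np.exp(-dist_km / range_km)
    cov += 1e-8 * np.eye(cov.shape[0])
    chol = np.linalg.cholesky(cov)
    return chol @ rng.normal(size=(cov.shape[0], n_factors))


def _sample_locations(realm: str, eco: str, n: int, rng) -> pd.DataFrame:
    lat = rng.uniform(-65.0, 65.0, n)
    lon = rng.uniform(-180.0, 180.0, n)
    if eco == "coastal":
        dist = rng.uniform(5.0, 150.0, n)
        depth = rng.uniform(1.0, 150.0, n)
    elif eco == "surface_open_ocean":
        dist = rng.uniform(250.0, 2500.0, n)
        depth = rng.uniform(1.0, 150.0, n)
    elif eco == "deep_open_ocean":
        dist = rng.uniform(250.0, 2500.0, n)
        depth = rng.uniform(300.0, 4000.0, n)
    elif eco == "deep_seafloor":
        dist = rng.uniform(250.0, 2500.0, n)
        depth = rng.uniform(500.0, 5000.0, n)
    elif eco in ("vent", "anoxic"):
        dist = rng.uniform(50.0, 1500.0, n)
        depth = rng.uniform(300.0, 3000.0, n)
    else:
        raise ValidationError(f"unknown ecosystem {eco!r}")
    if realm == BENTHIC and eco == "coastal":
        depth = rng.uniform(5.0, 150.0, n)
    special = {"vent": "vent", "anoxic": "anoxic"}.get(eco, "none")
    kind = "sediment" if realm == BENTHIC else "water"
    return pd.DataFrame(
        dict(
            latitude=lat,
            longitude=lon,
            water_depth=depth,
            distance_to_coast=dist,
            sample_depth_kind=kind,
            special_habitat=special,
        )
    )


def _taxonomy(otu_ids: list[str], assigned: dict, rng) -> TaxonomyTable:
    """Nested hierarchical lineages with per-rank unassigned truncation."""
    n = len(otu_ids)
    shape = {"phylum": 10, "class": 3, "order": 3, "family": 2, "genus": 2}
    codes = {}
    parent = np.zeros(n, dtype=int)
    for rank in RANKS[1:]:
        idx = rng.integers(0, shape[rank], n)
        parent = parent * shape[rank] + idx
        codes[rank] = parent.copy()
    # names encode the nesting: Phy03_C1_O2 ...
    prefixes = {"phylum": "Phy", "class": "C", "order": "O", "family": "F", "genus": "G"}
    name_at = {}
    running = ["" for _ in range(n)]
    for rank in RANKS[1:]:
        local = codes[rank] - (codes[rank] // shape[rank]) * shape[rank]
        names = []
        for i in range(n):
            running[i] = (
                f"{prefixes[rank]}{local[i] + 1:02d}"
                if rank == "phylum"
                else f"{running[i]}_{prefixes[rank]}{local[i] + 1}"
            )
            names.append(running[i])
        name_at[rank] = names
    u = rng.uniform(size=n)
    frame = pd.DataFrame(index=pd.Index(otu_ids, name="otu_id"))
    frame["domain"] = "Bacteria"
    for rank in RANKS[1:]:
        thresh = assigned.get(rank, 0.0)
        frame[rank] = [
            name_at[rank][i] if u[i] < thresh else UNASSIGNED for i in range(n)
        ]
    return TaxonomyTable(frame)


@dataclass
class SimulatedDataset:
    table: OtuTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    truth: GroundTruth

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_otu_table(self.table, f"{outdir}/otu_table.tsv")
        write_metadata(self.metadata, f"{outdir}/metadata.tsv")
        write_taxonomy(self.taxonomy, f"{outdir}/taxonomy.tsv")
        self.truth.to_json(f"{outdir}/ground_truth.json")


def generate_community(params: SimulationParams) -> SimulatedDataset:
    """Draw one synthetic dataset; identical params + seed give identical output."""
    rng = np.random.default_rng(params.seed)
    n_pool = params.n_otus_pool
    n_shared = int(round(params.realm_overlap * n_pool))
    n_excl = n_pool - n_shared
    n_pel_only = n_excl // 2
    otu_ids = [f"OTU_{i + 1:06d}" for i in range(n_pool)]
    shared_ids = otu_ids[:n_shared]
    pel_ids = otu_ids[: n_shared + n_pel_only]
    ben_ids = shared_ids + otu_ids[n_shared + n_pel_only :]
    pool_idx = {
        PELAGIC: np.arange(n_shared + n_pel_only),
        BENTHIC: np.concatenate(
            [np.arange(n_shared), np.arange(n_shared + n_pel_only, n_pool)]
        ),
    }

    # realm-specific base abundances (benthic shape softened -> more even)
    shape = {
        PELAGIC: params.abundance_shape,
        BENTHIC: (
            params.abundance_shape / params.evenness_contrast
            if params.abundance_model == "lognormal"
            else params.abundance_shape ** params.evenness_contrast
        ),
    }
    base = {}
    occupancy = {}
    satellite = {}
    for realm in (PELAGIC, BENTHIC):
        logab = _base_abundance(params.abundance_model, shape[realm], pool_idx[realm].size, rng)
        # keep shared OTUs abundant at the same z-score position regardless
        # of the realm's evenness (shape) setting
        boost = params.shared_abundance_boost
        if params.abundance_model == "lognormal" and params.abundance_shape > 0:
            boost *= shape[realm] / params.abundance_shape
        logab[: n_shared] += boost
        base[realm] = logab
        # abundance-occupancy relationship: rare OTUs occur in few samples
        u = (stats.rankdata(logab) - 0.5) / logab.size
        occupancy[realm] = np.clip(
            u ** params.occupancy_exponent, params.occupancy_floor, 1.0
        )
        satellite[realm] = u ** params.occupancy_exponent <= params.occupancy_floor

    # samples + metadata
    meta_parts = []
    sample_groups = []
    for (realm, eco), n in params.n_samples.items():
        if n <= 0:
            continue
        part = _sample_locations(realm, eco, n, rng)
        meta_parts.append(part)
        sample_groups += [(realm, eco)] * n
    meta_df = pd.concat(meta_parts, ignore_index=True)
    n_samples = len(meta_df)
    meta_df.index = pd.Index(
        [f"S{i + 1:04d}" for i in range(n_samples)], name="sample_id"
    )
    realms = np.array([g[0] for g in sample_groups])
    ecos = np.array([g[1] for g in sample_groups])

    prod_latent = rng.normal(size=n_samples)
    meta_df["longhurst_productivity"] = np.digitize(prod_latent, [-1.0, -0.3, 0.3, 1.0]) + 1
    meta_df["fisheries_class"] = (
        np.digitize(prod_latent + rng.normal(scale=0.5, size=n_samples), [-1.0, -0.3, 0.3, 1.0]) + 1
    )
    days = rng.integers(0, 731, n_samples)
    meta_df["date"] = [str(date(2003, 1, 1) + timedelta(days=int(x))) for x in days]
    metadata = SampleMetadata(meta_df)
    time_std = (days - days.mean()) / max(days.std(), 1e-9)

    # latent effect loadings
    eco_load = {
        (realm, eco): rng.normal(size=n_pool)
        for (realm, eco) in sorted(set(sample_groups))
    }
    prod_load = rng.normal(size=n_pool)
    time_load = rng.normal(size=n_pool)

    spatial = np.zeros((n_samples, params.n_spatial_factors))
    spat_load = rng.normal(size=(params.n_spatial_factors, n_pool))
    spatial_factors = {}
    if params.spatial_effect_size > 0 and params.spatial_decay_range:
        geo = great_circle(
            (meta_df["latitude"].to_numpy(), meta_df["longitude"].to_numpy())
        ).values
        for realm in (PELAGIC, BENTHIC):
            rng_km = params.spatial_decay_range.get(realm)
            mask = realms == realm
            if rng_km is None or not mask.any():
                continue
            spatial[mask] = _spatial_field(
                geo[np.ix_(mask, mask)], rng, rng_km, params.n_spatial_factors
            )
            spatial_factors[realm] = spatial[mask].copy()

    # expected compositions and counts
    counts = np.zeros((n_samples, n_pool), dtype=np.int64)
    expected = np.zeros((n_samples, n_pool))
    for i in range(n_samples):
        realm = realms[i]
        idx = pool_idx[realm]
        logw = base[realm].copy()
        logw += params.ecosystem_effect_size * eco_load[(realm, ecos[i])][idx]
        logw += params.productivity_effect_size * prod_latent[i] * prod_load[idx]
        logw += params.time_effect_size * time_std[i] * time_load[idx]
        logw += params.spatial_effect_size * (spatial[i] @ spat_load[:, idx])
        if params.sample_noise > 0:
            # evenness contrast softens the full benthic dispersion, noise
            # included, so the favoured realm is reliably more even
            noise_sd = params.sample_noise
            if realm == BENTHIC and params.evenness_contrast > 0:
                noise_sd /= params.evenness_contrast
            logw += noise_sd * rng.normal(size=idx.size)
        w = np.exp(logw - logw.max())
        if params.occupancy_exponent > 0:
            present = rng.random(idx.size) < occupancy[realm]
            if not present.any():
                present[np.argmax(w)] = True
            w = w * present
        p = w / w.sum()
        if params.presence_floor_reads > 0:
            # an occurrence implies a detectable population near the
            # detection limit: floor the expected read contribution of
            # present OTUs, cap satellite occurrences, then renormalize
            floor = params.presence_floor_reads / params.sequencing_depth
            cap = params.satellite_cap_reads / params.sequencing_depth
            p = np.where((p > 0) & (p < floor), floor, p)
            sat = satellite[realm] & (p > 0)
            p[sat] = np.clip(p[sat], floor, max(cap, floor))
            p = p / p.sum()
        expected[i, idx] = p
        if params.depth_dispersion is None:
            depth = int(params.sequencing_depth)
        else:
            lam = rng.gamma(
                params.depth_dispersion,
                params.sequencing_depth / params.depth_dispersion,
            )
            depth = max(1, int(rng.poisson(lam)))
        counts[i, idx] = rng.multinomial(depth, p)

    observed = counts.sum(axis=0) > 0
    table = OtuTable(
        list(meta_df.index),
        [o for o, k in zip(otu_ids, observed) if k],
        counts[:, observed],
        validate=False,
    )
    taxonomy = _taxonomy(otu_ids, params.assigned_fractions, rng)
    truth = GroundTruth(
        seed=params.seed,
        pools={PELAGIC: pel_ids, BENTHIC: ben_ids, "shared": shared_ids},
        sample_table=pd.DataFrame(
            dict(
                realm=realms,
                ecosystem=ecos,
                productivity_latent=prod_latent,
                time_days=days,
            ),
            index=meta_df.index,
        ),
        effect_sizes=dict(
            ecosystem=params.ecosystem_effect_size,
            productivity=params.productivity_effect_size,
            time=params.time_effect_size,
            spatial=params.spatial_effect_size,
        ),
        expected_composition=pd.DataFrame(expected, index=meta_df.index, columns=otu_ids),
        spatial_factors=spatial_factors or None,
    )
    return SimulatedDataset(table, metadata, taxonomy, truth)


def singleton_fraction(table: OtuTable) -> float:
    """Fraction of OTUs occurring exactly once in the whole table."""
    if table.n_otus == 0:
        return 0.0
    return float((table.otu_sums == 1).mean())


@dataclass
class CalibrationReport:
    target: float
    realized: float
    shape: float
    n_iterations: int
    converged: bool
    message: str = ""


def calibrate_singletons(
    params: SimulationParams,
    target: float | None = None,
    tol: float = 0.05,
    max_iter: int = 20,
) -> CalibrationReport:
    """Bisection on the abundance-model shape to hit a singleton fraction.

    The realized dataset-wide singleton fraction increases with tail
    heaviness; the shape parameter is bisected (<= *max_iter* steps) until
    the realized fraction is within *tol* of the target.  If the target is
    unreachable at the given sequencing depth the best achieved value is
    returned with a warning.
    """
    from dataclasses import replace

    target = params.singleton_target if target is None else target
    if params.abundance_model == "lognormal":
        lo, hi = 0.3, 8.0
    else:
        lo, hi = 0.05, 0.999

    def realized(shape: float) -> float:
        t = generate_community(replace(params, abundance_shape=shape)).table
        return singleton_fraction(t)

    f_lo, f_hi = realized(lo), realized(hi)
    best = (lo, f_lo) if abs(f_lo - target) < abs(f_hi - target) else (hi, f_hi)
    n_it = 0
    if not min(f_lo, f_hi) - tol <= target <= max(f_lo, f_hi) + tol:
        msg = (
            f"target {target} outside reachable range "
            f"[{min(f_lo, f_hi):.3f}, {max(f_lo, f_hi):.3f}] at this depth"
        )
        warnings.warn(msg, stacklevel=2)
        return CalibrationReport(target, best[1], best[0], n_it, False, msg)
    increasing = f_hi >= f_lo
    while n_it < max_iter and abs(best[1] - target) > tol:
        mid = (lo + hi) / 2
        f_mid = realized(mid)
        n_it += 1
        if abs(f_mid - target) < abs(best[1] - target):
            best = (mid, f_mid)
        if (f_mid < target) == increasing:
            lo = mid
        else:
            hi = mid
    ok = abs(best[1] - target) <= tol
    if not ok:
        warnings.warn(
            f"singleton calibration stopped at {best[1]:.3f} (target {target})",
            stacklevel=2,
        )
    return CalibrationReport(target, best[1], best[0], n_it, ok)
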