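# oceanbeta

Global beta-diversity analysis of marine bacterial OTU tables: ordination,
group-separation tests, dispersion, shared-OTU resampling, cross-rank
consistency, and variation partitioning of community composition against
ecosystem type, space, time and productivity — plus a synthetic community
generator that reproduces the statistical structure such analyses assume
(two realms sharing <10% of OTUs, ~50% singleton OTUs contributing a tiny
sequence share, a more even and OTU-rich benthic realm, realm-specific
spatial distance decay, and small productivity/time effects), so that
every stage is testable without any external download.

## Layout

| Module | Contents |
|---|---|
| `oceanbeta.tables_io` | `OtuTable` / `SampleMetadata` / `TaxonomyTable` data model, TSV + dense BIOM-JSON readers, ecosystem classification, taxonomic aggregation, singleton filtering, dataset summaries |
| `oceanbeta.synthetic_data` | `SimulationParams`, `generate_community`, singleton-fraction calibration |
| `oceanbeta.transforms` | Hellinger / presence-absence standardization, Bray-Curtis, haversine great-circle distances, PCoA (with Lingoes correction) |
| `oceanbeta.ordination` | NMDS (Kruskal stress-1, monotone regression, 20 starts incl. one PCoA-seeded), Procrustes, PROTEST, cross-rank consistency |
| `oceanbeta.group_stats` | inverse Simpson, Mann-Whitney (exact for small n), ANOSIM + pairwise ANOSIM, distance-to-centroid dispersion |
| `oceanbeta.resampling` | shared-OTU resampling, balanced-group ANOSIM simulation, cell-density weight sensitivity, singleton / presence-absence robustness |
| `oceanbeta.varpart` | RDA, db-RDA, adjusted R², partial (Freedman-Lane) permutation tests, 2–4 set variation partitioning |
| `oceanbeta.cli` | `oceanbeta` command-line pipeline |

## CLI

```sh
# generate a synthetic dataset (OTU table, metadata, taxonomy, ground truth)
oceanbeta simulate --out run/ --seed 0

# individual stages
oceanbeta summarize  --otu-table run/otu_table.tsv --metadata run/metadata.tsv --out run/
oceanbeta ordinate   --otu-table run/otu_table.tsv --out run/ --seed 0
oceanbeta anosim     --otu-table run/otu_table.tsv --metadata run/metadata.tsv --out run/ --by realm
oceanbeta varpart    --otu-table run/otu_table.tsv --metadata run/metadata.tsv --out run/ --realm pelagic

# everything in dependency order (simulate -> summarize -> ordinate ->
# anosim -> dispersion -> shared-otus -> weights -> robustness -> varpart
# -> rank-consistency), with a manifest of seeds and checksums
oceanbeta run-all --out run/ --seed 0
```

Options may also come from a YAML config (`--config cfg.yaml`); explicit
flags win. Ecosystem classification thresholds: *coastal* is strictly
below 200 nautical miles from the coast and 200 m water depth; a value of
exactly 200 falls on the open-ocean/deep side, so every sample
classifies.

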