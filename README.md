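# benthocur

A curation toolkit for georeferenced seafloor-image **metadata**: the
bookkeeping that turns heterogeneous benthic survey collections into a
machine-learning-ready compilation. It operates entirely on CSV metadata
tables — never on the images themselves.

Benthic (seafloor) imagery is collected by towed cameras, drop cameras,
divers, AUVs and ROVs. Video-derived collections are massively redundant:
consecutive frames centimetres apart depict the same patch of seabed, and
that same spatial autocorrelation silently leaks information from training
into test data when such collections are split naively. Annotations arrive
in dozens of bespoke vocabularies. `benthocur` addresses all three problems
for anyone assembling benthic image compilations:

- **Density-aware spatial subsampling** (`benthocur.subsampler`) — thins
  each recording site to a target count by greedily walking the
  chronologically ordered track and keeping images a separation distance
  Δ apart, escalating Δ = 1.25 m through ×{1, 2, 3, 4, 6, 8, 10, 12, 14, 16}
  (up to 20 m) until the kept count would fall below the target. Targets
  scale with detected structure: 250 per *pseudo-site* (single-linkage
  clusters ≥ 1000 m apart) plus 50 per extra *subsite* (clusters ≥ 100 m
  apart). Sites with fewer than 40 images per pseudo-site are exempt;
  unlocated sites fall back to every-*n*-th selection.
- **Leakage-aware train/test partitioning** (`benthocur.partitioner`) —
  grows the two partitions image by image under prioritized per-label
  rules (≥ 2 train samples; ≥ 50 % train; ≥ 15 % test; ≤ 35 % test), a 50 m
  exclusion radius between partitions, and closest-decile spatial growth,
  so partitions expand outwards from seed locations. Remaining images go
  to test iff within 50 m of a test image. Runs independently per
  environmental stratum (e.g. Ecological Marine Unit).
- **Hierarchical CATAMI label translation** (`benthocur.catami`) — a model
  of the CATAMI classification scheme (Biota / Substrate / Bedforms /
  Relief plus an Anthropogenic extension), table-driven translation of
  bespoke source labels into scheme paths with WoRMS AphiaIDs, rollup
  counting at any depth, and per-stratum censuses.
- **Schema I/O and geometry** (`benthocur.metadata_io`, `benthocur.geo`) —
  strict CSV schema validation, site-mean coordinate imputation, UTC
  datetime normalization with precision tags, the 512-px shortest-side
  resize rule, haversine geometry, threshold clustering, neighbour indices
  and regular-raster joins (nearest-stratum, bilinear depth).
- **Synthetic surveys** (`benthocur.synthgen`) — deterministic generators
  for transects, station grids, multi-cluster and unlocated sites, and
  imbalanced multi-label annotation layouts with known ground truth, so
  every pipeline stage is testable without downloading anything.

## Worked example

```python
import pandas as pd
from benthocur import partitioner, subsampler
from benthocur.synthgen import LabelRecipe, SurveyRecipe, gen_site, gen_partition_study

# a dense 2000-frame video transect, frames ~0.4 m apart
site = gen_site(SurveyRecipe(kind="transect", n=2000, spacing_m=0.4,
                             jitter_sd_m=0.05, seed=7))
kept, reports = subsampler.subsample_compilation(site)
print(reports[("synthetic", "site_0")].to_dict())
# {'n_out': 332, 'target': 250, 'delta': 2.5, 'method': 'spatial',
#  'n_pseudosites': 1, 'n_subsites': 1}
```

The site is a single pseudo-site with no extra subsites, so the target is
the base 250. At Δ = 2.5 m the greedy pass keeps 332 images (≥ 250); at the
next schedule step Δ = 3.75 m it would fall below target, so 2.5 m is the
chosen separation — 2000 redundant frames become 332 representative ones.

```python
records = gen_partition_study(n_images=5000, label_recipe=LabelRecipe(seed=1))
result = partitioner.partition_stratum(records,
                                       partitioner.PartitionConfig(seed=1))
print(result.n_train, result.n_test, len(result.violations),
      len(partitioner.leakage_report(result, records)))
# 4000 1000 0 0
```

Five thousand images bearing 30 Zipf-imbalanced CATAMI labels are split
80 % / 20 % train/test with zero exclusion-zone violations and an empty
leakage report: no test image lies within 50 m of a train image, and every
label meets its minimum-train, minimum-test and maximum-test constraints
(see `result.ledger`).

A thin CLI wraps the library:

```sh
benthocur simulate --recipe recipe.yaml --output synthetic.csv
benthocur subsample --input meta.csv --output kept.csv --report report.json
benthocur partition --input labelled.csv --output split.csv --seed 42
benthocur run --config pipeline.yaml --outdir out/   # validate → … → stats
```

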