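# Methods

This note documents the procedures `benthocur` implements, the parameters
that matter, the numerical choices made where the design was genuinely
open, and what the synthetic-data generators do and do not emulate.

## Geometry

All distances are great-circle (haversine) distances on a sphere of radius
R = 6 371 000 m. At the scales the toolkit reasons about — 0.625 m removal
radii to 1000 m cluster gaps — the discrepancy between the sphere and the
WGS 84 ellipsoid (≲ 0.3 %) is far below GPS positioning error, so no
ellipsoidal geodesics are used. Radius queries and nearest-cell joins go
through a ball tree with the haversine metric; the test suite pins the tree
to exact agreement with full brute-force scans at all the radii the
pipeline uses (0.625, 50, 100, 1000 m).

Pseudo-sites and subsites are single-linkage clusters: connected components
of the graph linking point pairs strictly closer than the threshold
(1000 m and 100 m respectively). Single linkage is the construction that
guarantees the defining property — distinct clusters are pairwise at least
the threshold apart at their closest points. Cluster ids are canonicalized
by order of first appearance, making them invariant to point order up to
relabelling.

The geographic mean centre is the arithmetic mean of latitudes and of
longitudes. This is the convention appropriate for site-scale extents; it
is not antimeridian-safe, so point sets whose longitudes span more than
180° are rejected rather than silently averaged across the wrap.

Grid joins address raster cells by their centre coordinates. Stratum
assignment takes the nearest non-missing cell centre by great-circle
distance; depth interpolation is standard bilinear interpolation in
lat/lon space over the four surrounding cell values, where a masked corner
is an error unless it carries zero interpolation weight (points exactly on
a node or edge).

## Spatial subsampling

The target count for a site is

    target = 250 × n_pseudosites + 50 × (n_subsites − n_pseudosites),

i.e. 250 per pseudo-site plus 50 for each subsite beyond them. The subsite
increment is read as applying to *additional* subsites: a single contiguous
site (one pseudo-site, one subsite) has target 250, and one extra
≥ 100 m-separated image group adds exactly 50. Counting all subsites
instead would make the minimal site's target 300 and the base target 250
unreachable, so the additional-subsites reading is adopted.

One spacing pass at separation Δ over a chronologically ordered, located
track:

1. keep the first image;
2. scan forward through not-yet-removed images for the first at least Δ
   from the last image kept;
3. keep that image or the not-removed image scanned over immediately
   before it, whichever is closer to being exactly Δ away — ties keep the
   later image (maintains forward progress, deterministic);
4. remove, among the images still to be considered, all within Δ/2 of the
   image just kept;
5. repeat from step 2; the scan never restarts, and when the predecessor
   was the one kept, the boundary-crossing candidate itself remains to be
   considered;
6. finally keep the last image iff it is at least Δ/2 from every kept
   image.

"Previous image" in step 3 means the predecessor *within the current
scan*; when the scan finds its boundary-crossing image immediately, there
is no predecessor and the candidate is kept. Step 4's removal is
prospective only — images already scanned past are never retroactively
removed.

A consequence worth knowing: every kept image after the first is protected
by a removal pass, so consecutive keeps are at least Δ/2 apart — *except*
pairs involving the very first image, around which no removal ever runs. A
step-3 predecessor pick near the start of a track can therefore sit closer
than Δ/2 to image 0. The property tests assert the separation for all
removal-protected pairs, and exact equivalence with an independently coded
transcription of the six steps covers the full behaviour.

Escalation evaluates the pass at Δ = 1.25 m scaled by 1, 2, 3, 4, 6, 8,
10, 12, 14, 16 (so up to 20 m) and selects the largest Δ whose kept count
still meets the target; the schedule is evaluated exhaustively rather than
assuming monotonicity of kept counts in Δ. If even the base Δ undershoots
the target the site is returned unthinned. Sites with fewer than
40 images per pseudo-site are exempt and pass through bit-identically.
Sites lacking coordinates for any image cannot be thinned spatially and
keep every n-th image chronologically, n = max(1, ⌊N/target⌋) (the floor
rule keeps at least the target when N ≥ target).

Collection order is (datetime, filename) when every record of a site has a
datetime; if any datetime is missing, the site's input file order is
retained — interleaving sorted and unsorted rows has no defensible
semantics.

## Train/test partitioning

The unit of work is one environmental stratum (the `emu` column by
default); censuses and targets are recomputed within each stratum and
records with missing stratum ids run as a dedicated "unknown" stratum.
Per-stratum RNG seeds derive from the global seed XOR a CRC-32 of the
stratum id, so results are reproducible and strata are independent.

For a stratum with per-label counts c:

- global test target T = round-half-up of min(0.15 × max c, 0.35 × median
  c), floor 1, where the median is the lower median of the count multiset;
- per label: train minimum max(2, ⌈0.50 c⌉); test minimum
  min(⌈0.15 c⌉, T) clamped to the cap; test cap ⌊0.35 c⌋.

Rounding direction follows the "at least"/"no more than" wording: minima
round up, the cap rounds down; for tiny labels whose 15 % minimum would
exceed their 35 % cap, the minimum is clamped to the cap.

The greedy loop scans the priorities in their stated order — seed-train
(rule 1), 50 %-train (rule 2), 15 %-test (rule 3) — for the most urgent
unmet per-label deficit, breaking ties by the fewest remaining
*allocatable* images (unassigned bearers not excluded by the 50 m zone
count as unallocatable) and then lexicographically. Rule 4 (the 35 % cap)
acts as a guard during image selection for test: candidates whose
assignment would push any of their labels over cap are avoided while a
cap-safe candidate exists. Image selection itself prefers the nearest
⌈10 %⌉ of label-bearers within 50 m of the growing target partition
(uniform draw), else a uniform draw among bearers more than 50 m from the
opposite partition, else — only when needed to satisfy the minima — a
uniform draw among all remaining bearers with the exclusion-zone violation
logged together with the constraint that forced it.

Remaining images are assigned in one pass: test iff within 50 m of an
image in the test partition *as it stands when the loop ends*, else train.
The snapshot reading keeps the remainder rule order-independent and
prevents remainder images from chaining each other into test through a
dense transect; the alternative sequential reading floods entire tracks
into test and makes the result depend on row order.

The per-label ledger records counts, targets and four satisfaction flags
(seed-train, 50 %-train, 15 %-test, 35 %-cap); the leakage report lists
every test image within 50 m of a train image with its cause (a logged
forced violation, or adjacency created by the remainder rule).

## CATAMI scheme and translation

The scheme is a five-branch forest — Biota, Substrate, Bedforms, Relief,
and an Anthropogenic branch for man-made objects — serialized as a flat
text file of " > "-delimited paths (the delimiter carries spaces because
node names such as "High (>3m)" contain bare ">"). The packaged fixture is
a minimal, user-extensible core covering the depth-2 substrate classes and
the nodes used by the packaged translation table; it is not a full
reproduction of the scheme. Extensions (e.g. morphospecies detail) are
added only when supported by strictly more than 10 samples and carry an
`extension` provenance tag.

Translation is table-driven: (dataset, original label) rows map to one or
more scheme paths with optional qualifiers, bleached/dead/colour modifiers
and a WoRMS AphiaID. One original label may yield annotations in several
branches (a combined substrate-plus-biota label produces both). Unmapped
labels are returned as explicit findings, never dropped. WoRMS mapping is
offline by design — reproducibility without a live registry. Percent-cover
source labels collapse to presence/absence.

Rollup counts add each annotation to its node and every ancestor up to the
branch root, so a node's count equals its children's counts plus
annotations recorded exactly at it.

## Metadata schema and imputation

Tables are UTF-8, comma-separated, RFC 4180-quoted CSV with the exact
compilation column names; missing values are empty strings. Coordinates
are WGS 84 decimal degrees; datetimes are `YYYY-MM-DD HH:mm:ss`, assumed
UTC when no zone is indicated and converted to UTC otherwise. Partial
datetimes are completed (missing month/day → 01, missing time → 00:00:00)
and the finest component actually present is recorded in a separate
precision tag rather than in the schema column, which has a fixed format.
Missing coordinates are imputed as the site's geographic mean centre when
the site has at least one located image; the operation is idempotent and
flags what it touched. Numeric precision is emitted in full on export; no
rounding convention is imposed.

The resize rule maps (w, h) to dimensions whose shortest side is exactly
512 px, scaling both sides equally and rounding to the nearest integer —
but images whose shortest side is already at most 512 × 1.1 are left
unchanged. The 10 % tolerance is one-sided: the rule never upscales.

## Synthetic data

`gen_site` produces transects (points along a line at fixed spacing with
Gaussian jitter — the spatially autocorrelated, video-derived case),
station scatters, multi-cluster sites with metre-specified gaps, and
unlocated sites; datetimes increase strictly. Metre offsets become degrees
via the spherical small-offset approximation (1° latitude =
πR/180 ≈ 111 195 m, longitude scaled by cos φ), accurate to well under a
millimetre at site scale. Everything is deterministic given the recipe
seed.

`gen_labelled_compilation` scatters a Zipf-imbalanced label inventory
(default: 30 labels spanning all four core branches, exponent 1.2,
multi-label rate 0.3) over station sites, with rare labels confined to few
sites (one site plus a radius cap reproduces the fully clumped case). At
most one label per branch is placed on an image, so multi-label images
combine labels across branches — matching the one-row-per-image labelled
schema.

`gen_partition_study` is the canonical *feasible* fixture for partitioning
studies: labels are split into a frequent and a rare half and matched into
cross-branch pairs; each pair owns a dedicated block of ten tight
(σ = 6 m), well-separated (400 m) station sites, with the rare label
riding on an evenly spread subset of the primary's images. Co-occurring
labels thus share sites and images while distinct pairs share neither, so
greedy growth always leaves whole train-free sites for test seeding. This
is the regime in which the partitioning procedure is *exact*: all
constraints satisfiable with zero exclusion-zone violations. Real
compilations are messier — labels co-occur across arbitrary sites — and
there the procedure degrades gracefully into logged violations and a
non-empty leakage report rather than failing.

What passing tests on these generators show: the algorithms implement
their stated rules exactly, honour their guarantees on separable data, and
degrade as documented on inseparable data. What they do not show:
performance on real surveys' label noise, positional error correlated
along tracks, or datasets whose spatial structure differs qualitatively
from clustered stations and linear transects.

## Problem sizes and determinism

The test suite exercises the spacing oracle on 100 randomized fixtures of
200–2000 points across transect, loop and clustered geometries at all ten
schedule deltas; the partitioner constraint suite uses 5000-image,
30-label compilations over three seeds. All randomness flows from explicit
integer seeds (numpy `default_rng`); reruns with the same configuration
are byte-identical, and the pipeline manifest records version, config
hash, seed and per-stage counts needed to reproduce a run.
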