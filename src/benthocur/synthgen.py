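"""Synthetic survey-metadata generator with known ground truth.

Emulates the spatial and label structure of real benthic image surveys so
the subsampler and partitioner are testable without any downloads: dense
transect tracks (sub-metre spacing with GPS-like jitter), sparse station
sites, multi-cluster sites with large gaps, unlocated sites, and imbalanced
Zipf-distributed multi-label annotations that clump in space.

Everything is deterministic for a fixed seed.  Local metre offsets are
converted to degrees with the spherical small-offset approximation
(dlat = m / (pi R / 180); dlon additionally scaled by 1/cos(lat)), which is
accurate to well under a millimetre at site scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from . import geo
from .metadata_io import DATETIME_FORMAT, LABELLED_COLUMNS, UNLABELLED_COLUMNS

SITE_KINDS = ("transect", "stations", "multi_cluster", "unlocated")


def _offset_deg(lat0: float, east_m, north_m) -> tuple[np.ndarray, np.ndarray]:
    """Convert local metre offsets to (lat, lon) degrees around lat0."""
    dlat = np.asarray(north_m, dtype=float) / geo.METRES_PER_DEGREE
    dlon = (np.asarray(east_m, dtype=float)
            / (geo.METRES_PER_DEGREE * np.cos(np.radians(lat0))))
    return dlat, dlon


@dataclass(frozen=True)
class SurveyRecipe:
    kind: str = "transect"
    n: int = 200
    spacing_m: float = 0.5          # along-track spacing / station scatter sd
    jitter_sd_m: float = 0.05       # positional jitter per image
    cluster_offsets_m: tuple[float, ...] = (0.0,)  # eastward cluster centres
    start_lat: float = 44.5
    start_lon: float = -63.5
    start_datetime: str = "2019-06-01 08:00:00"
    interval_s: float = 2.0
    dataset: str = "synthetic"
    site: str = "site_0"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in SITE_KINDS:
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.spacing_m < 0 or self.jitter_sd_m < 0:
            raise ValueError("spacing and jitter must be non-negative")


def gen_site(recipe: SurveyRecipe) -> pd.DataFrame:
    """Generate one site's image records (unlabelled schema).

    transect: points along a west-east line at ``spacing_m`` with Gaussian
    jitter.  stations: Gaussian scatter (sd ``spacing_m``) around the start.
    multi_cluster: ``n`` split evenly over tight clusters centred at the
    eastward ``cluster_offsets_m``.  unlocated: coordinates left empty.
    Datetimes increase strictly by ``interval_s``.
    """
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n
    if recipe.kind == "transect":
        east = np.arange(n) * recipe.spacing_m
        north = np.zeros(n)
    elif recipe.kind == "stations":
        east = rng.normal(0.0, recipe.spacing_m, size=n)
        north = rng.normal(0.0, recipe.spacing_m, size=n)
    elif recipe.kind == "multi_cluster":
        centres = np.asarray(recipe.cluster_offsets_m, dtype=float)
        which = np.sort(np.arange(n) % len(centres))
        east = centres[which]
        north = np.zeros(n)
    else:  # unlocated
        east = north = None
    if east is not None and recipe.jitter_sd_m > 0:
        east = east + rng.normal(0.0, recipe.jitter_sd_m, size=n)
        north = north + rng.normal(0.0, recipe.jitter_sd_m, size=n)

    t0 = datetime.strptime(recipe.start_datetime, DATETIME_FORMAT)
    times = [(t0 + timedelta(seconds=i * recipe.interval_s)
              ).strftime(DATETIME_FORMAT) for i in range(n)]
    images = [f"{recipe.site}_{i:05d}.jpg" for i in range(n)]
    df = pd.DataFrame({
        "url": [f"https://data.invalid/{recipe.dataset}/{recipe.site}/{im}"
                for im in images],
        "source": "synthetic",
        "dataset": recipe.dataset,
        "site": recipe.site,
        "image": images,
        "latitude": np.nan,
        "longitude": np.nan,
        "datetime": times,
    })
    if east is not None:
        dlat, dlon = _offset_deg(recipe.start_lat, east, north)
        df["latitude"] = recipe.start_lat + dlat
        df["longitude"] = recipe.start_lon + dlon
    return df[UNLABELLED_COLUMNS]


def gen_compilation(recipes) -> pd.DataFrame:
    """Concatenate several sites into one metadata table."""
    return pd.concat([gen_site(r) for r in recipes], ignore_index=True)


# default 30-label inventory drawn from the packaged scheme: spans all four
# core branches so multi-label images combine labels across branches
DEFAULT_INVENTORY: tuple[str, ...] = (
    "Substrate > Unconsolidated (soft) > Sand / mud (<1mm)",
    "Biota > Macroalgae",
    "Substrate > Consolidated (hard) > Rock",
    "Biota > Sponges",
    "Substrate > Unconsolidated (soft) > Pebble / gravel",
    "Biota > Seagrasses",
    "Substrate > Consolidated (hard) > Boulders",
    "Biota > Cnidaria > Corals",
    "Substrate > Consolidated (hard) > Cobbles",
    "Biota > Worms > Polychaetes",
    "Bedforms > Ripples",
    "Biota > Echinoderms > Sea stars",
    "Relief > Flat",
    "Biota > Molluscs > Bivalves",
    "Bedforms > None",
    "Biota > Worms > Polychaetes > Tube worms",
    "Relief > Low (<1m)",
    "Biota > Cnidaria > Corals > Stony corals",
    "Substrate > Unconsolidated (soft) > Sand / mud (<1mm) > Mud / silt (<64um)",
    "Biota > Ascidians",
    "Bedforms > Waves",
    "Biota > Bryozoa",
    "Relief > Moderate (1-3m)",
    "Biota > Crustacea",
    "Substrate > Unconsolidated (soft) > Sand / mud (<1mm) > Sand (no shell fragments)",
    "Biota > Fishes",
    "Relief > High (>3m)",
    "Biota > Echinoderms > Sea urchins",
    "Substrate > Consolidated (hard)",
    "Biota > Molluscs > Gastropods",
)


def station_grid_recipes(n_sites: int = 120, per_site: int = 45,
                         scatter_sd_m: float = 6.0,
                         site_spacing_m: float = 400.0,
                         start_lat: float = 44.5, start_lon: float = -63.5,
                         seed: int = 0) -> list[SurveyRecipe]:
    """Canonical feasible survey layout for partitioning studies.

    A rectangular grid of tight station sites: within-site scatter well
    under the 50 m exclusion radius, between-site spacing well over it, so
    train/test partitions can always be separated at site granularity.
    """
    ncols = int(np.ceil(np.sqrt(n_sites)))
    dlat = site_spacing_m / geo.METRES_PER_DEGREE
    dlon = site_spacing_m / (geo.METRES_PER_DEGREE
                             * np.cos(np.radians(start_lat)))
    return [SurveyRecipe(kind="stations", n=per_site, spacing_m=scatter_sd_m,
                         jitter_sd_m=0.0,
                         start_lat=start_lat + dlat * (i // ncols),
                         start_lon=start_lon + dlon * (i % ncols),
                         dataset="synthetic", site=f"site_{i:03d}",
                         seed=seed * 100_003 + i)
            for i in range(n_sites)]


@dataclass(frozen=True)
class LabelRecipe:
    inventory: tuple[str, ...] = DEFAULT_INVENTORY
    zipf_exponent: float = 1.2
    multi_label_rate: float = 0.3   # expected extra labels per image
    clump_radius_m: float | None = None  # cap pairwise spread of a label
    clumps_per_label: int | str = "auto"
    min_count: int = 14             # floor on per-label target counts
    seed: int = 0

    def __post_init__(self):
        if not self.inventory:
            raise ValueError("empty label inventory")
        if not 0.0 <= self.multi_label_rate:
            raise ValueError("multi_label_rate must be >= 0")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf exponent must be positive")


def _branch(path: str) -> str:
    return path.split(" > ")[0].strip()


def zipf_counts(n_slots: int, n_labels: int, exponent: float,
                min_count: int) -> np.ndarray:
    """Deterministic per-rank target counts under a Zipf frequency law."""
    w = (np.arange(1, n_labels + 1, dtype=float)) ** (-exponent)
    w /= w.sum()
    c = np.maximum(np.round(n_slots * w).astype(int), min_count)
    return c


def gen_partition_study(n_images: int = 5000,
                        label_recipe: LabelRecipe = LabelRecipe(),
                        sites_per_pair: int = 10,
                        site_spacing_m: float = 400.0,
                        scatter_sd_m: float = 6.0,
                        start_lat: float = 44.5, start_lon: float = -63.5,
                        ) -> pd.DataFrame:
    """Feasible multi-label compilation for train/test partitioning studies.

    Labels are split into primary (the more frequent half of the Zipf
    inventory) and secondary (the rarer half) and matched into pairs across
    different CATAMI branches.  Each pair owns a dedicated block of tight,
    well-separated station sites: every image in the block bears the
    primary label, and the secondary label rides on an evenly spread subset
    of those images.  Because co-occurring labels share sites and images
    while distinct pairs never share either, greedy partition growth always
    leaves whole train-free sites for test seeding — the compilation is
    spatially separable by construction, while still exercising imbalanced
    multi-label dynamics.
    """
    rng = np.random.default_rng(label_recipe.seed)
    labels = list(label_recipe.inventory)
    half = len(labels) // 2
    w = np.arange(1, len(labels) + 1, dtype=float) ** (-label_recipe.zipf_exponent)
    counts = np.maximum(np.round(n_images * w / w[:half].sum()).astype(int),
                        label_recipe.min_count)
    primaries, secondaries = labels[:half], labels[half:]
    # match each primary with an unused secondary of a different branch,
    # most-constrained primary first so a feasible matching is found
    pairs: list[tuple[int, int]] = []
    unused = list(range(len(secondaries)))
    todo = list(range(len(primaries)))
    while todo:
        options = {i: [j for j in unused
                       if _branch(secondaries[j]) != _branch(primaries[i])]
                   for i in todo}
        i = min(todo, key=lambda i: len(options[i]))
        if not options[i]:
            raise ValueError("inventory cannot be branch-matched into pairs")
        j = options[i][0]
        unused.remove(j)
        todo.remove(i)
        pairs.append((i, j))
    pairs.sort()

    n_prim = counts[:half].copy()
    n_prim[0] += n_images - n_prim.sum()    # exact total; absorb in the top
    branch_col = {"Biota": "catami_biota", "Substrate": "catami_substrate",
                  "Bedforms": "catami_bedforms", "Relief": "catami_relief"}
    frames = []
    site_no = 0
    ncols = int(np.ceil(np.sqrt(half * sites_per_pair)))
    dlat = site_spacing_m / geo.METRES_PER_DEGREE
    dlon = site_spacing_m / (geo.METRES_PER_DEGREE
                             * np.cos(np.radians(start_lat)))
    for i, j in pairs:
        prim, sec = primaries[i], secondaries[half * 0 + j]
        n_pair = int(n_prim[i])
        c_sec = int(min(counts[half + j], n_pair))
        base, extra = divmod(n_pair, sites_per_pair)
        site_sizes = [base + (1 if s < extra else 0)
                      for s in range(sites_per_pair)]
        # water-fill the secondary quota evenly over the pair's sites
        sec_quota = [0] * sites_per_pair
        placed = 0
        while placed < c_sec:
            progressed = False
            for s in range(sites_per_pair):
                if placed < c_sec and sec_quota[s] < site_sizes[s]:
                    sec_quota[s] += 1
                    placed += 1
                    progressed = True
            if not progressed:
                break
        for s in range(sites_per_pair):
            n_site = site_sizes[s]
            if n_site == 0:
                continue
            rec = SurveyRecipe(
                kind="stations", n=n_site, spacing_m=scatter_sd_m,
                jitter_sd_m=0.0,
                start_lat=start_lat + dlat * (site_no // ncols),
                start_lon=start_lon + dlon * (site_no % ncols),
                dataset="synthetic", site=f"site_{site_no:03d}",
                seed=int(label_recipe.seed) * 100_003 + site_no)
            site_no += 1
            df = gen_site(rec)
            for col in LABELLED_COLUMNS:
                if col not in df.columns:
                    df[col] = ""
            df[branch_col[_branch(prim)]] = prim
            n_sec_here = sec_quota[s]
            if n_sec_here:
                rows = rng.choice(n_site, size=n_sec_here, replace=False)
                df.iloc[rows, df.columns.get_loc(branch_col[_branch(sec)])] = sec
            df["original_label"] = (
                df[branch_col[_branch(prim)]].astype(str) + ";"
                + df[branch_col[_branch(sec)]].astype(str)).str.rstrip(";")
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[LABELLED_COLUMNS]


def gen_labelled_compilation(survey_recipes, label_recipe: LabelRecipe,
                             ) -> pd.DataFrame:
    """Labelled synthetic compilation: every image gets >= 1 CATAMI label.

    Per-label counts follow the Zipf law of the recipe (rank-frequency
    monotone non-increasing by construction).  Each label is placed on a
    limited set of sites — few sites for rare labels — so labels clump in
    space; with ``clumps_per_label = 1`` and a ``clump_radius_m`` a rare
    label's images all fall within that radius of a centre image.  At most
    one label per CATAMI branch is placed on an image, so multi-label
    images combine labels across branches.
    """
    rng = np.random.default_rng(label_recipe.seed)
    table = gen_compilation(survey_recipes)
    n = len(table)
    labels = list(label_recipe.inventory)
    n_slots = int(round(n * (1.0 + label_recipe.multi_label_rate)))
    targets = zipf_counts(n_slots, len(labels), label_recipe.zipf_exponent,
                          label_recipe.min_count)

    sites = table["site"].to_numpy()
    site_ids = pd.unique(sites)
    site_rows = {s: np.flatnonzero(sites == s) for s in site_ids}
    lat = pd.to_numeric(table["latitude"], errors="coerce").to_numpy()
    lon = pd.to_numeric(table["longitude"], errors="coerce").to_numpy()

    # per-image, per-branch occupancy: one label of each branch max
    occupied: dict[tuple[int, str], bool] = {}
    realized_prev = n + 1
    label_of: list[list[str]] = [[] for _ in range(n)]

    for rank, (label, want) in enumerate(zip(labels, targets)):
        branch = _branch(label)
        want = int(min(want, realized_prev))  # keep rank-frequency monotone
        if label_recipe.clumps_per_label == "auto":
            k = int(np.clip(int(np.ceil(want / 4)), 16, len(site_ids)))
        else:
            k = int(label_recipe.clumps_per_label)
        k = max(1, min(k, len(site_ids)))
        chosen = rng.choice(site_ids, size=k, replace=False)
        pool = np.concatenate([site_rows[s] for s in chosen])
        if label_recipe.clump_radius_m is not None and k == 1:
            centre = int(rng.choice(pool))
            d = np.atleast_1d(geo.haversine_m(lat[centre], lon[centre],
                                              lat[pool], lon[pool]))
            pool = pool[d <= label_recipe.clump_radius_m]
        max_per_image = 1 if label_recipe.multi_label_rate == 0 else 4
        free = np.array([i for i in pool
                         if not occupied.get((i, branch))
                         and len(label_of[int(i)]) < max_per_image])
        take = min(want, free.size)
        picks = rng.choice(free, size=take, replace=False) if take else []
        for i in picks:
            occupied[(int(i), branch)] = True
            label_of[int(i)].append(label)
        realized_prev = len(picks)

    # guarantee every image bears at least one label (use the top label)
    top, top_branch = labels[0], _branch(labels[0])
    for i in range(n):
        if not label_of[i]:
            label_of[i].append(top)
            occupied[(i, top_branch)] = True

    branch_col = {"Biota": "catami_biota", "Substrate": "catami_substrate",
                  "Bedforms": "catami_bedforms", "Relief": "catami_relief"}
    out = table.copy()
    for col in LABELLED_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    for i in range(n):
        for label in label_of[i]:
            out.iat[i, out.columns.get_loc(branch_col[_branch(label)])] = label
        out.iat[i, out.columns.get_loc("original_label")] = ";".join(label_of[i])
    return out[LABELLED_COLUMNS]
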