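"""Density-aware spatial subsampling of per-site image series.

Dense survey data (e.g. frames extracted from towed-camera or AUV video)
is spatially redundant: consecutive images a fraction of a metre apart
depict nearly the same patch of seafloor.  This module thins each site to a
target count by greedily walking the chronologically ordered track and
keeping images roughly a separation distance delta apart, escalating delta
through a fixed schedule until the kept count would fall below the site's
target.

Targets scale with detected spatial structure: a base of 250 images per
pseudo-site (clusters >= 1000 m apart) plus 50 for each additional subsite
(clusters >= 100 m apart).  Sites with fewer than 40 images per pseudo-site
are exempt, and sites lacking per-image coordinates fall back to keeping
every n-th image chronologically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo

SCALE_FACTORS = (1, 2, 3, 4, 6, 8, 10, 12, 14, 16)


@dataclass(frozen=True)
class SubsampleConfig:
    base_target: int = 250
    subsite_increment: int = 50
    min_per_pseudosite: int = 40
    base_delta: float = 1.25
    scale_factors: tuple[int, ...] = SCALE_FACTORS
    max_delta: float = 20.0
    pseudosite_threshold: float = geo.PSEUDOSITE_THRESHOLD_M
    subsite_threshold: float = geo.SUBSITE_THRESHOLD_M

    def __post_init__(self):
        if min(self.base_target, self.subsite_increment,
               self.min_per_pseudosite) <= 0:
            raise ValueError("counts must be positive")
        if self.base_delta <= 0 or self.max_delta <= 0:
            raise ValueError("deltas must be positive")
        if abs(self.base_delta * max(self.scale_factors) - self.max_delta) > 1e-9:
            raise ValueError("base_delta * max(scale_factors) must equal max_delta")

    @property
    def delta_schedule(self) -> list[float]:
        return [self.base_delta * f for f in self.scale_factors]


@dataclass
class SubsampleResult:
    kept: list[int]
    delta: float | None          # None means "no spatial thinning applied"
    target: int
    method: str                  # spatial | every_nth | exempt
    n_pseudosites: int = 1
    n_subsites: int = 1

    def to_dict(self) -> dict:
        return {"n_out": len(self.kept), "target": self.target,
                "delta": self.delta, "method": self.method,
                "n_pseudosites": self.n_pseudosites,
                "n_subsites": self.n_subsites}


def site_target(n_pseudosites: int, n_subsites: int,
                cfg: SubsampleConfig = SubsampleConfig()) -> int:
    """Target image count for a site.

    250 per pseudo-site, plus 50 for each subsite beyond the pseudo-sites
    (a single contiguous site gains nothing from the subsite increment).
    """
    if n_pseudosites < 1 or n_subsites < n_pseudosites:
        raise ValueError("need n_subsites >= n_pseudosites >= 1")
    return (cfg.base_target * n_pseudosites
            + cfg.subsite_increment * (n_subsites - n_pseudosites))


def spacing_pass(lat: np.ndarray, lon: np.ndarray, delta: float) -> list[int]:
    """One greedy spacing pass over a chronologically ordered located track.

    Procedure (indices are positions in collection order):

    1. keep the first image;
    2. scan forward through images not yet removed for the first one at
       least ``delta`` from the last image kept;
    3. keep that image or its immediate not-removed predecessor in the scan,
       whichever is closer to being exactly ``delta`` away (ties keep the
       later image);
    4. remove all remaining unscanned images within ``delta/2`` of the image
       just kept;
    5. repeat from step 2 until the scan reaches the end;
    6. finally keep the last image iff it is at least ``delta/2`` from every
       kept image.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    n = lat.size
    if n == 0:
        raise ValueError("empty series")
    if np.isnan(lat).any() or np.isnan(lon).any():
        raise ValueError("spacing_pass requires located records")
    if n == 1:
        return [0]
    half = delta / 2.0
    latr = np.radians(lat)
    lonr = np.radians(lon)
    coslat = np.cos(latr)

    def dist(a: int, b: int) -> float:
        # scalar haversine on precomputed radians (hot path of the scan)
        s = (math.sin((latr[b] - latr[a]) / 2.0) ** 2
             + coslat[a] * coslat[b] * math.sin((lonr[b] - lonr[a]) / 2.0) ** 2)
        return 2.0 * geo.EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(s)))

    removed = np.zeros(n, dtype=bool)
    kept_mask = np.zeros(n, dtype=bool)
    kept = [0]
    kept_mask[0] = True
    last = 0
    i = 1
    while True:
        # step 2: first not-removed image >= delta from the last kept
        prev = -1  # immediate not-removed predecessor within this scan
        cand = -1
        while i < n:
            if removed[i]:
                i += 1
                continue
            if dist(last, i) >= delta:
                cand = i
                break
            prev = i
            i += 1
        if cand < 0:
            break
        # step 3: candidate vs its predecessor, closest to exactly delta
        # (ties keep the later image, i.e. the candidate)
        choice = cand
        if prev >= 0 and (abs(dist(last, prev) - delta)
                          < abs(dist(last, cand) - delta)):
            choice = prev
        kept.append(choice)
        kept_mask[choice] = True
        last = choice
        # scanning never restarts: when the predecessor was kept, the
        # candidate itself is still to be considered
        i = cand if choice == prev else cand + 1
        # step 4: drop remaining images to consider within delta/2 of the keep
        if i < n:
            s = (np.sin((latr[i:] - latr[choice]) / 2.0) ** 2
                 + coslat[choice] * coslat[i:]
                 * np.sin((lonr[i:] - lonr[choice]) / 2.0) ** 2)
            d_rest = 2.0 * geo.EARTH_RADIUS_M * np.arcsin(
                np.sqrt(np.clip(s, 0.0, 1.0)))
            removed[i:] |= d_rest < half
    # step 6: add the last image if >= delta/2 from all kept images
    lastidx = n - 1
    if not kept_mask[lastidx]:
        d = np.atleast_1d(geo.haversine_m(lat[lastidx], lon[lastidx],
                                          lat[kept], lon[kept]))
        if (d >= half).all():
            kept.append(lastidx)
    return sorted(kept)


def every_nth_pass(n_records: int, target: int) -> list[int]:
    """Keep every n-th image, n = max(1, floor(N / target))."""
    if target < 1:
        raise ValueError("target must be >= 1")
    if n_records < 1:
        raise ValueError("empty series")
    n = max(1, n_records // target)
    return list(range(0, n_records, n))


def escalate_subsample(lat, lon, target: int,
                       cfg: SubsampleConfig = SubsampleConfig()) -> SubsampleResult:
    """Pick the largest schedule delta whose spacing pass keeps >= target.

    Evaluates the spacing pass at every delta in the schedule (1.25 m scaled
    by 1, 2, 3, 4, 6, 8, 10, 12, 14, 16) and selects the largest separation
    distance that does not reduce the kept count below the target.  If even
    the base delta undershoots the target, the site is returned unthinned
    (delta ``None``).
    """
    lat = np.asarray(lat, dtype=float)
    n = lat.size
    best: tuple[float, list[int]] | None = None
    for delta in cfg.delta_schedule:  # exhaustive: counts need not be monotone
        kept = spacing_pass(lat, lon, delta)
        if len(kept) >= target:
            best = (delta, kept)
    if best is None:
        return SubsampleResult(kept=list(range(n)), delta=None,
                               target=target, method="spatial")
    return SubsampleResult(kept=best[1], delta=best[0],
                           target=target, method="spatial")


def order_site(df: pd.DataFrame) -> pd.DataFrame:
    """Collection (chronological) order for one site's records.

    Sorted by (datetime, image filename) when every record has a datetime;
    if any datetime is missing the input file order is retained.
    """
    if "datetime" in df.columns:
        dt = df["datetime"].astype(str)
        if (dt != "").all() and not dt.isna().any():
            key = df.assign(_dt=dt, _im=df["image"].astype(str))
            return key.sort_values(["_dt", "_im"], kind="stable").drop(
                columns=["_dt", "_im"])
    return df


def subsample_site(df: pd.DataFrame,
                   cfg: SubsampleConfig = SubsampleConfig()) -> SubsampleResult:
    """Route one site's ordered records to the appropriate subsampling path."""
    lat = pd.to_numeric(df["latitude"], errors="coerce").to_numpy()
    lon = pd.to_numeric(df["longitude"], errors="coerce").to_numpy()
    n = len(df)
    located = n > 0 and not (np.isnan(lat).any() or np.isnan(lon).any())
    if not located:
        target = site_target(1, 1, cfg)
        if n < cfg.min_per_pseudosite:
            return SubsampleResult(list(range(n)), None, target, "exempt")
        return SubsampleResult(every_nth_pass(n, target), None, target,
                               "every_nth")
    n_pseudo = geo.count_pseudosites(lat, lon)
    n_sub = geo.count_subsites(lat, lon)
    target = site_target(n_pseudo, n_sub, cfg)
    if n < cfg.min_per_pseudosite * n_pseudo:
        return SubsampleResult(list(range(n)), None, target, "exempt",
                               n_pseudo, n_sub)
    res = escalate_subsample(lat, lon, target, cfg)
    res.n_pseudosites = n_pseudo
    res.n_subsites = n_sub
    return res


def subsample_compilation(df: pd.DataFrame,
                          cfg: SubsampleConfig = SubsampleConfig(),
                          site_columns: tuple[str, str] = ("dataset", "site"),
                          ) -> tuple[pd.DataFrame, dict[tuple, SubsampleResult]]:
    """Subsample every (dataset, site) group of a metadata table.

    Returns the kept rows (input column set and within-site order preserved)
    and a per-site :class:`SubsampleResult` report.  Per-site failures are
    recorded as ``method="error"`` results rather than aborting the run.
    """
    reports: dict[tuple, SubsampleResult] = {}
    pieces = []
    for key, group in df.groupby(list(site_columns), sort=False):
        ordered = order_site(group)
        try:
            res = subsample_site(ordered, cfg)
        except Exception as exc:  # pragma: no cover - defensive per-site guard
            res = SubsampleResult(list(range(len(ordered))), None, 0, "error")
            res.error = str(exc)  # type: ignore[attr-defined]
        reports[key] = res
        pieces.append(ordered.iloc[res.kept])
    out = pd.concat(pieces) if pieces else df.iloc[0:0]
    return out, reports
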