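"""Spatially-aware, label-stratified train/test partitioning.

Benthic image labels are multi-label and heavily imbalanced, and images a
few metres apart depict the same patch of seafloor, so a naive random split
both starves rare labels and leaks spatial information from train to test.
The partitioner grows the two partitions greedily, one image at a time:

1. ensure at least two samples of every label can go to train;
2. ensure at least 50% of every label's samples can go to train without
   using samples within 50 m of a test sample;
3. ensure at least 15% of every label's samples can go to test without
   using samples within 50 m of a train sample;
4. ensure no more than 35% of any label's samples end up in test;
5. ties between labels are broken by the fewest remaining allocatable
   images (then lexicographically).

Images are drawn preferentially from the closest 10% of label-bearers near
the growing target partition, so partitions expand spatially outwards from
random seed locations.  Images violating the 50 m exclusion zone are used
only when needed to satisfy the minimum populations, and every such
violation is logged.  Remaining images go to test iff within 50 m of a test
image, else to train.  The whole procedure runs independently per
environmental stratum (e.g. per Ecological Marine Unit).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geo
from .metadata_io import CATAMI_COLUMNS


@dataclass(frozen=True)
class PartitionConfig:
    test_frac_of_max: float = 0.15
    test_frac_cap: float = 0.35
    train_min_frac: float = 0.50
    train_min_count: int = 2
    exclusion_radius_m: float = 50.0
    closest_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for f in (self.test_frac_of_max, self.test_frac_cap,
                  self.train_min_frac, self.closest_frac):
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must lie strictly in (0, 1)")
        if self.exclusion_radius_m <= 0:
            raise ValueError("exclusion radius must be positive")


def image_labels(records: pd.DataFrame) -> tuple[list[list[str]], list[int]]:
    """Per-image label lists from the four CATAMI columns.

    Returns (labels per row, positional indices of rows with no label).
    """
    n = len(records)
    labels: list[list[str]] = [[] for _ in range(n)]
    for col in CATAMI_COLUMNS:
        if col not in records.columns:
            continue
        vals = records[col].astype(str).to_numpy()
        for i, v in enumerate(vals):
            if v and v != "nan":
                labels[i].append(v)
    unlabelled = [i for i, ls in enumerate(labels) if not ls]
    return labels, unlabelled


def label_census(records: pd.DataFrame) -> dict[str, int]:
    """Per-label image counts; a k-label image adds 1 to each of k counts."""
    labels, _ = image_labels(records)
    census: dict[str, int] = {}
    for ls in labels:
        for lab in ls:
            census[lab] = census.get(lab, 0) + 1
    return census


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def test_target(census: dict[str, int],
                cfg: PartitionConfig = PartitionConfig()) -> int:
    """Global per-label test-sample target.

    The smaller of 15% of the most frequent label's count and 35% of the
    median label's count (lower median of the count multiset), rounded half
    up with a floor of one sample.
    """
    if not census:
        raise ValueError("empty census")
    counts = sorted(census.values())
    median = counts[(len(counts) - 1) // 2]  # lower median
    raw = min(cfg.test_frac_of_max * max(counts),
              cfg.test_frac_cap * median)
    return max(1, _round_half_up(raw))


@dataclass
class PartitionResult:
    assignments: pd.Series            # "train"/"test" per input row
    ledger: pd.DataFrame              # per-label satisfaction bookkeeping
    violations: list[dict] = field(default_factory=list)
    unlabelled_rows: list = field(default_factory=list)

    @property
    def n_train(self) -> int:
        return int((self.assignments == "train").sum())

    @property
    def n_test(self) -> int:
        return int((self.assignments == "test").sum())


class _StratumState:
    """Mutable assignment state for one stratum's greedy partitioning."""

    def __init__(self, lat, lon, labels, cfg: PartitionConfig):
        self.lat = np.asarray(lat, dtype=float)
        self.lon = np.asarray(lon, dtype=float)
        self.n = self.lat.size
        self.labels = labels
        self.cfg = cfg
        self.assigned = np.full(self.n, "", dtype=object)
        self.dist_to = {"train": np.full(self.n, np.inf),
                        "test": np.full(self.n, np.inf)}
        self.members: dict[str, np.ndarray] = {}
        for i, ls in enumerate(labels):
            for lab in ls:
                self.members.setdefault(lab, []).append(i)  # type: ignore
        self.members = {k: np.asarray(v, dtype=int)
                        for k, v in self.members.items()}
        self.n_part = {"train": {k: 0 for k in self.members},
                       "test": {k: 0 for k in self.members}}

    def assign(self, i: int, partition: str) -> None:
        if self.assigned[i]:
            raise RuntimeError(f"image {i} already assigned")
        self.assigned[i] = partition
        for lab in self.labels[i]:
            self.n_part[partition][lab] += 1
        if np.isfinite(self.lat[i]):
            d = np.atleast_1d(geo.haversine_m(self.lat[i], self.lon[i],
                                              self.lat, self.lon))
            np.minimum(self.dist_to[partition], d,
                       out=self.dist_to[partition])

    def unassigned_members(self, label: str) -> np.ndarray:
        m = self.members[label]
        return m[self.assigned[m] == ""]

    def allocatable(self, label: str, partition: str) -> int:
        """Unassigned bearers not excluded by the 50 m zone for partition."""
        other = "test" if partition == "train" else "train"
        cand = self.unassigned_members(label)
        return int((self.dist_to[other][cand]
                    > self.cfg.exclusion_radius_m).sum())


def select_image(label: str, partition: str, state: _StratumState,
                 cfg: PartitionConfig, rng: np.random.Generator,
                 allow_violation: bool = True) -> tuple[int | None, dict | None]:
    """Choose the image of ``label`` to add to ``partition``.

    Prefers the closest ceil(10%) of unassigned label-bearers within 50 m of
    the growing target partition; otherwise a uniform draw among bearers at
    least 50 m from the opposite partition; otherwise (only when needed for
    the minimum populations) a uniform draw among all remaining bearers,
    with the violation recorded.  Returns (row index or None, violation or
    None).
    """
    cand = state.unassigned_members(label)
    if cand.size == 0:
        raise ValueError(f"no unassigned image bears label {label!r}")
    other = "test" if partition == "train" else "train"
    r = cfg.exclusion_radius_m
    if partition == "test":
        # priority-4 guard: avoid pushing any label of the image over its
        # 35% test cap, unless no candidate is cap-safe
        caps = _caps(state, cfg)
        safe_cap = np.array([all(
            state.n_part["test"][lab] + 1 <= caps[lab]
            for lab in state.labels[i]) for i in cand])
        if safe_cap.any():
            cand = cand[safe_cap]
    d_target = state.dist_to[partition][cand]
    near = cand[d_target <= r]
    if near.size:
        order = np.argsort(state.dist_to[partition][near], kind="stable")
        pool = near[order[:math.ceil(cfg.closest_frac * near.size)]]
        return int(rng.choice(pool)), None
    safe = cand[state.dist_to[other][cand] > r]
    if safe.size:
        return int(rng.choice(safe)), None
    if not allow_violation:
        return None, None
    pick = int(rng.choice(cand))
    return pick, {"row": pick, "label": label, "partition": partition,
                  "nearest_opposite_m": float(state.dist_to[other][pick])}


def _needs(state: _StratumState, cfg: PartitionConfig, target: int):
    """Per-label (train_seed, train_min, test_min, test_cap) requirement."""
    out = {}
    for lab, m in state.members.items():
        c = m.size
        train_seed = min(cfg.train_min_count, c)
        train_min = min(max(train_seed, math.ceil(cfg.train_min_frac * c)), c)
        cap = math.floor(cfg.test_frac_cap * c)
        test_min = min(math.ceil(cfg.test_frac_of_max * c), target, cap)
        out[lab] = (train_seed, train_min, test_min, cap)
    return out


def _caps(state: _StratumState, cfg: PartitionConfig) -> dict[str, int]:
    if not hasattr(state, "_cap_cache"):
        state._cap_cache = {lab: math.floor(cfg.test_frac_cap * m.size)
                            for lab, m in state.members.items()}
    return state._cap_cache


def assign_remainder(state: _StratumState, cfg: PartitionConfig) -> None:
    """Unassigned images: test iff within 50 m of a test image, else train.

    Evaluated against the test set as it stands when the greedy loop ends
    (a snapshot, so remainder images do not chain each other into test);
    the outcome is therefore independent of processing order.
    """
    rest = np.flatnonzero(state.assigned == "")
    near_test = state.dist_to["test"][rest] <= cfg.exclusion_radius_m
    for i, to_test in zip(rest, near_test):
        state.assign(int(i), "test" if to_test else "train")


def partition_stratum(records: pd.DataFrame,
                      cfg: PartitionConfig = PartitionConfig(),
                      rng: np.random.Generator | None = None,
                      ) -> PartitionResult:
    """Partition the labelled records of one stratum.

    Iteratively scans the four ensure-rules in priority order for the most
    urgent unmet per-label deficit, breaks ties by the fewest remaining
    allocatable images then lexicographic label, assigns one image via
    :func:`select_image`, and repeats until every satisfiable deficit is
    met; the remainder rule completes the assignment.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels, unlabelled = image_labels(records)
    if len(records) == 0:
        return PartitionResult(pd.Series(dtype=object),
                               _empty_ledger())
    lat = pd.to_numeric(records["latitude"], errors="coerce").to_numpy()
    lon = pd.to_numeric(records["longitude"], errors="coerce").to_numpy()
    state = _StratumState(lat, lon, labels, cfg)
    census = {lab: m.size for lab, m in state.members.items()}
    target = test_target(census, cfg) if census else 0
    needs = _needs(state, cfg, target)
    violations: list[dict] = []
    dead: set[tuple[str, str]] = set()  # (label, partition) unsatisfiable

    while census:
        step = None
        # priority scan 1 -> 3 (rule 4 acts as a guard inside select_image)
        for pri, (part, slot) in enumerate(
                [("train", 0), ("train", 1), ("test", 2)]):
            cands = []
            for lab, (seed_n, train_min, test_min, _cap) in needs.items():
                want = (seed_n, train_min, test_min)[pri]
                have = state.n_part[part][lab]
                if have >= want or (lab, part) in dead:
                    continue
                if state.unassigned_members(lab).size == 0:
                    dead.add((lab, part))
                    continue
                cands.append(lab)
            if cands:
                # rule 5 tie-break: fewest allocatable, then lexicographic
                cands.sort(key=lambda lab: (state.allocatable(lab, part), lab))
                step = (cands[0], part)
                break
        if step is None:
            break
        lab, part = step
        pick, viol = select_image(lab, part, state, cfg, rng)
        state.assign(pick, part)
        if viol is not None:
            viol["constraint"] = _constraint_name(state, needs, lab, part)
            violations.append(viol)

    assign_remainder(state, cfg)

    ledger = _build_ledger(state, needs, target)
    assignments = pd.Series(state.assigned, index=records.index, dtype=object)
    return PartitionResult(assignments, ledger, violations,
                           [records.index[i] for i in unlabelled])


def _constraint_name(state, needs, lab, part) -> str:
    seed_n, train_min, test_min, _ = needs[lab]
    if part == "train":
        if state.n_part["train"][lab] < seed_n:
            return "train-minimum-two"
        return "train-50-percent"
    return "test-15-percent"


def _empty_ledger() -> pd.DataFrame:
    return pd.DataFrame(columns=["label", "count", "n_train", "n_test",
                                 "target_test", "train_min_met",
                                 "train_frac_met", "test_min_met",
                                 "test_cap_ok"])


def _build_ledger(state: _StratumState, needs, target: int) -> pd.DataFrame:
    rows = []
    for lab in sorted(state.members):
        c = state.members[lab].size
        seed_n, train_min, test_min, cap = needs[lab]
        n_tr = state.n_part["train"][lab]
        n_te = state.n_part["test"][lab]
        rows.append({"label": lab, "count": c, "n_train": n_tr,
                     "n_test": n_te, "target_test": test_min,
                     "train_min_met": n_tr >= seed_n,
                     "train_frac_met": n_tr >= train_min,
                     "test_min_met": n_te >= test_min,
                     "test_cap_ok": n_te <= cap})
    return pd.DataFrame(rows) if rows else _empty_ledger()


def _stratum_seed(global_seed: int, stratum) -> int:
    return (int(global_seed) ^ zlib.crc32(str(stratum).encode())) % (2 ** 31)


def partition_dataset(records: pd.DataFrame,
                      cfg: PartitionConfig = PartitionConfig(),
                      stratum_column: str = "emu") -> PartitionResult:
    """Run :func:`partition_stratum` independently per stratum value.

    Censuses and test targets are recomputed within each stratum; records
    with a missing stratum id are routed to a dedicated ``unknown`` stratum.
    Results are concatenated and a global ledger (per stratum, per label)
    produced.
    """
    if stratum_column in records.columns:
        strat = records[stratum_column].astype(object)
        strat = strat.where(~pd.isna(strat), "")
        strat = strat.map(lambda v: "unknown" if str(v).strip() == ""
                          else str(v))
    else:
        strat = pd.Series("unknown", index=records.index)
    assignments = pd.Series("", index=records.index, dtype=object)
    ledgers, violations, unlabelled = [], [], []
    for value in sorted(strat.unique()):
        sub = records[strat == value]
        sub_cfg = PartitionConfig(
            test_frac_of_max=cfg.test_frac_of_max,
            test_frac_cap=cfg.test_frac_cap,
            train_min_frac=cfg.train_min_frac,
            train_min_count=cfg.train_min_count,
            exclusion_radius_m=cfg.exclusion_radius_m,
            closest_frac=cfg.closest_frac,
            seed=_stratum_seed(cfg.seed, value))
        res = partition_stratum(sub, sub_cfg)
        assignments[res.assignments.index] = res.assignments
        led = res.ledger.copy()
        led.insert(0, "stratum", value)
        ledgers.append(led)
        violations.extend(res.violations)
        unlabelled.extend(res.unlabelled_rows)
    ledger = (pd.concat(ledgers, ignore_index=True)
              if ledgers else _empty_ledger())
    return PartitionResult(assignments, ledger, violations, unlabelled)


def leakage_report(result: PartitionResult, records: pd.DataFrame,
                   cfg: PartitionConfig = PartitionConfig()) -> list[dict]:
    """Every test image within 50 m of a train image, with its cause.

    Entries carry the forcing constraint when the greedy loop logged one,
    else they are marked ``remainder-rule adjacency``.
    """
    lat = pd.to_numeric(records["latitude"], errors="coerce").to_numpy()
    lon = pd.to_numeric(records["longitude"], errors="coerce").to_numpy()
    part = result.assignments.reindex(records.index).to_numpy()
    train = np.flatnonzero(part == "train")
    test = np.flatnonzero(part == "test")
    report = []
    if train.size == 0 or test.size == 0:
        return report
    ok = np.isfinite(lat[train]) & np.isfinite(lon[train])
    train = train[ok]
    if train.size == 0:
        return report
    idx = geo.NeighbourIndex(lat[train], lon[train])
    causes = {}
    for v in result.violations:
        causes[v["row"]] = v.get("constraint", "forced")
    for i in test:
        if not np.isfinite(lat[i]):
            continue
        hits = idx.query_radius(lat[i], lon[i], cfg.exclusion_radius_m)
        if hits.size:
            report.append({
                "row": int(i),
                "nearest_train_row": int(train[hits[0]]),
                "distance_m": float(geo.haversine_m(
                    lat[i], lon[i], lat[train[hits[0]]], lon[train[hits[0]]])),
                "cause": causes.get(int(i), "remainder-rule adjacency")})
    return report
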