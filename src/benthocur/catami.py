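"""Hierarchical CATAMI label scheme, bespoke-label translation, and rollups.

CATAMI is a hierarchical, image-oriented classification scheme for benthic
imagery.  The hierarchy is a forest of five branches — Biota, Substrate,
Bedforms, Relief, plus an Anthropogenic branch for man-made objects such as
trash or cables — whose nodes may be annotated at any level of detail.
Bespoke source-dataset labels are translated to CATAMI paths through a
table; taxonomic biota labels additionally carry a WoRMS AphiaID (stable
integer taxon identifiers from the World Register of Marine Species),
table-driven so no live registry queries are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

BRANCH_ROOTS = ("Biota", "Substrate", "Bedforms", "Relief", "Anthropogenic")

PATH_SEP = " > "

#: a scheme extension node needs strictly more than this many samples
EXTENSION_MIN_SAMPLES = 10


class SchemeError(ValueError):
    """Raised for malformed scheme files (orphans, duplicates, bad roots)."""


@dataclass
class CatamiNode:
    path: str
    name: str
    parent: str | None           # parent path, None for branch roots
    provenance: str = "core-v1.4"
    children: list[str] = field(default_factory=list)


class CatamiTree:
    """Forest of CATAMI nodes keyed by full " > "-delimited path."""

    def __init__(self):
        self.nodes: dict[str, CatamiNode] = {}
        for root in BRANCH_ROOTS:
            self.nodes[root] = CatamiNode(root, root, None)

    def add_path(self, path: str, provenance: str = "core-v1.4") -> CatamiNode:
        """Add a node (and require its parent to already exist)."""
        parts = [p.strip() for p in str(path).split(PATH_SEP)]
        path = PATH_SEP.join(parts)
        if path in self.nodes:
            return self.nodes[path]
        if len(parts) == 1:
            raise SchemeError(f"unknown branch root {path!r}")
        parent = PATH_SEP.join(parts[:-1])
        if parent not in self.nodes:
            raise SchemeError(f"orphan path {path!r}: parent {parent!r} "
                              "not in scheme")
        node = CatamiNode(path, parts[-1], parent, provenance)
        self.nodes[path] = node
        self.nodes[parent].children.append(path)
        return node

    def __contains__(self, path: str) -> bool:
        return self.normalize(path) in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    @staticmethod
    def normalize(path: str) -> str:
        # the hierarchy delimiter is " > " with spaces; a bare ">" may occur
        # inside node names such as "High (>3m)"
        return PATH_SEP.join(p.strip() for p in str(path).split(PATH_SEP))

    def branch(self, path: str) -> str:
        return self.normalize(path).split(PATH_SEP)[0]

    def depth(self, path: str) -> int:
        return len(self.normalize(path).split(PATH_SEP))

    def ancestors(self, path: str) -> list[str]:
        """All ancestor paths from the branch root down to the node itself."""
        parts = self.normalize(path).split(PATH_SEP)
        return [PATH_SEP.join(parts[:k]) for k in range(1, len(parts) + 1)]


def load_scheme(source=None) -> CatamiTree:
    """Load a scheme file: one " > "-delimited path per line, optionally
    followed by a tab and a provenance tag.  Parents must appear before
    children (any order of sibling subtrees is fine because every prefix of
    a listed path must itself be listed).  Defaults to the packaged minimal
    core-v1.4 fixture.

    Lines starting with ``#`` and blank lines are ignored.
    """
    if source is None:
        text = (resources.files("benthocur") / "data" /
                "catami_scheme.txt").read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    tree = CatamiTree()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        path, _, prov = line.partition("\t")
        norm = tree.normalize(path)
        if norm in tree.nodes and norm not in BRANCH_ROOTS:
            raise SchemeError(f"duplicate path at line {lineno}: {norm!r}")
        tree.add_path(path, prov.strip() or "core-v1.4")
    return tree


def extend_scheme(tree: CatamiTree, new_paths: dict[str, int],
                  ) -> tuple[CatamiTree, list[dict]]:
    """Add extension child nodes for sufficiently supported new labels.

    A child is added iff its supporting sample count is strictly greater
    than 10 (systematic extensions only); refusals and duplicates are
    reported, not raised.  Parents must already exist.
    """
    findings = []
    for path, count in new_paths.items():
        norm = tree.normalize(path)
        if norm in tree.nodes:
            findings.append({"path": norm, "action": "duplicate",
                             "count": count})
            continue
        if count > EXTENSION_MIN_SAMPLES:
            tree.add_path(norm, provenance="extension")
            findings.append({"path": norm, "action": "added", "count": count})
        else:
            findings.append({"path": norm, "action": "refused",
                             "count": count})
    return tree, findings


@dataclass
class CatamiAnnotation:
    branch: str
    path: str
    qualifiers: str | None = None
    bleached: int | None = None
    dead: int | None = None
    colour: str | None = None
    aphia_id: int | None = None
    row_frac: float | None = None
    col_frac: float | None = None


TRANSLATION_COLUMNS = ["dataset", "original_label", "branch", "path",
                       "qualifiers", "bleached", "dead", "colour", "aphia_id"]


class TranslationTable:
    """Maps (dataset, original label) to one or more CATAMI annotations.

    One original label may expand to multiple annotations (e.g. a combined
    "mud and tube worms" label yields both a substrate and a biota path).
    Rows with dataset ``*`` apply to any dataset.
    """

    def __init__(self, rows: pd.DataFrame, tree: CatamiTree):
        missing = [c for c in TRANSLATION_COLUMNS if c not in rows.columns]
        if missing:
            raise SchemeError(f"translation table missing columns: {missing}")
        self.rows = rows
        self.tree = tree
        for i, path in rows["path"].items():
            if tree.normalize(path) not in tree.nodes:
                raise SchemeError(
                    f"translation row {i}: path {path!r} not in scheme")
        aph = pd.to_numeric(rows["aphia_id"].replace("", pd.NA),
                            errors="coerce")
        if (aph.dropna() <= 0).any():
            raise SchemeError("aphia_id must be a positive integer")

    @classmethod
    def load(cls, source=None, tree: CatamiTree | None = None) -> "TranslationTable":
        if tree is None:
            tree = load_scheme()
        if source is None:
            src = (resources.files("benthocur") / "data" /
                   "translation_table.csv")
            with resources.as_file(src) as p:
                rows = pd.read_csv(p, dtype=str, keep_default_na=False)
        else:
            rows = pd.read_csv(source, dtype=str, keep_default_na=False)
        return cls(rows, tree)

    def translate(self, original: str, dataset: str = "*",
                  ) -> tuple[list[CatamiAnnotation], list[dict]]:
        """All annotations mapped from an original label.

        Unmapped labels come back as explicit ``untranslated`` findings in
        the second return value; they are never silently dropped.
        """
        rows = self.rows
        hit = rows[(rows["original_label"] == str(original))
                   & rows["dataset"].isin([dataset, "*"])]
        if hit.empty:
            return [], [{"kind": "untranslated", "dataset": dataset,
                         "original_label": original}]
        anns = []
        for _, r in hit.iterrows():
            path = self.tree.normalize(r["path"])
            anns.append(CatamiAnnotation(
                branch=self.tree.branch(path), path=path,
                qualifiers=r["qualifiers"] or None,
                bleached=int(float(r["bleached"])) if r["bleached"] else None,
                dead=int(float(r["dead"])) if r["dead"] else None,
                colour=r["colour"] or None,
                aphia_id=int(float(r["aphia_id"])) if r["aphia_id"] else None))
        return anns, []


def translate(original: str, table: TranslationTable, tree: CatamiTree,
              dataset: str = "*") -> tuple[list[CatamiAnnotation], list[dict]]:
    """Module-level convenience wrapper around TranslationTable.translate."""
    assert table.tree is tree or set(tree.nodes) >= {
        tree.normalize(p) for p in table.rows["path"]}
    return table.translate(original, dataset)


def rollup_counts(paths, tree: CatamiTree, depth: int | None = None,
                  ) -> dict[str, int]:
    """Hierarchical counts: each annotation counts at its node and at every
    ancestor up to its branch root.  ``depth`` truncates reporting (1 =
    branch roots only); counts at deeper nodes still roll up into their
    reported ancestors.
    """
    counts: dict[str, int] = {}
    for path in paths:
        norm = tree.normalize(path)
        if norm not in tree.nodes:
            raise SchemeError(f"annotation path {norm!r} not in scheme")
        for anc in tree.ancestors(norm):
            counts[anc] = counts.get(anc, 0) + 1
    if depth is not None:
        counts = {p: c for p, c in counts.items() if tree.depth(p) <= depth}
    return counts


def census_by_stratum(records: pd.DataFrame, stratum_column: str = "emu",
                      ) -> pd.DataFrame:
    """Per-stratum image and annotation counts with fractions summing to 1.

    Records missing a stratum id are pooled into an ``unknown`` row.  The
    annotation count sums presences across the four CATAMI branch columns.
    """
    from .metadata_io import CATAMI_COLUMNS
    strat = records.get(stratum_column, pd.Series("", index=records.index))
    strat = strat.astype(object).where(~pd.isna(strat), "")
    strat = strat.map(lambda v: "unknown" if str(v).strip() == ""
                      else (str(int(v)) if isinstance(v, float) else str(v)))
    n_ann = pd.Series(0, index=records.index)
    for col in CATAMI_COLUMNS:
        if col in records.columns:
            n_ann = n_ann + (records[col].astype(str) != "").astype(int)
    out = pd.DataFrame({"stratum": strat, "n_annotations": n_ann})
    g = out.groupby("stratum").agg(n_images=("stratum", "size"),
                                   n_annotations=("n_annotations", "sum"))
    g["image_fraction"] = g["n_images"] / g["n_images"].sum()
    g["annotation_fraction"] = (g["n_annotations"] / g["n_annotations"].sum()
                                if g["n_annotations"].sum() else 0.0)
    return g.reset_index()
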