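"""Command-line interface and end-to-end pipeline orchestration.

Subcommands: ``validate``, ``translate``, ``subsample``, ``partition``,
``stats``, ``simulate``, ``run``.  All tabular I/O follows the compilation
CSV schema; structured logs go to stderr, data only to files.  All
randomness flows from a single global seed.
"""

from __future__ import annotations

import hashlib
import json
import sys


import click
import pandas as pd
import yaml

from . import __version__, catami, metadata_io, partitioner, subsampler, synthgen


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


@click.group()
@click.version_option(__version__)
def cli():
    """Curation toolkit for georeferenced seafloor-image metadata."""


@cli.command()
@click.option("--input", "input_", required=True, type=click.Path(exists=True))
@click.option("--labelled", is_flag=True, default=False)
@click.option("--report", type=click.Path(), default=None,
              help="write findings as JSON lines")
def validate(input_, labelled, report):
    """Quality-control checks on a metadata CSV."""
    df = metadata_io.read_records(input_, labelled=labelled,
                                  strict_ranges=False)
    rep = metadata_io.validate_records(df, labelled=labelled)
    if report:
        with open(report, "w") as fh:
            fh.write(rep.to_jsonl())
    _log(f"{len(df)} records, {len(rep)} findings")
    sys.exit(0 if rep.ok else 1)


@cli.command()
@click.option("--input", "input_", required=True, type=click.Path(exists=True))
@click.option("--output", required=True, type=click.Path())
@click.option("--scheme", type=click.Path(exists=True), default=None)
@click.option("--table", type=click.Path(exists=True), default=None)
def translate(input_, output, scheme, table):
    """Translate original labels to CATAMI columns via a translation table."""
    df = metadata_io.read_records(input_)
    tree = catami.load_scheme(scheme)
    ttable = catami.TranslationTable.load(table, tree)
    out, findings = translate_table(df, ttable)
    metadata_io.write_records(out, output)
    _log(f"translated {len(df)} records; {len(findings)} untranslated labels")


def translate_table(df: pd.DataFrame, table: catami.TranslationTable,
                    ) -> tuple[pd.DataFrame, list[dict]]:
    """Fill catami_*/aphia_id columns from each record's original_label."""
    out = df.copy()
    for col in metadata_io.LABELLED_EXTRA_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    branch_col = {"Biota": "catami_biota", "Substrate": "catami_substrate",
                  "Bedforms": "catami_bedforms", "Relief": "catami_relief",
                  "Anthropogenic": "catami_qualifiers"}
    findings: list[dict] = []
    for i in out.index:
        orig = str(out.at[i, "original_label"]) if "original_label" in out else ""
        if not orig:
            continue
        anns, missed = table.translate(orig, str(out.at[i, "dataset"]))
        findings.extend(missed)
        for ann in anns:
            out.at[i, branch_col[ann.branch]] = ann.path
            if ann.aphia_id is not None:
                out.at[i, "aphia_id"] = ann.aphia_id
            if ann.bleached is not None:
                out.at[i, "bleached"] = ann.bleached
            if ann.dead is not None:
                out.at[i, "dead"] = ann.dead
            if ann.colour is not None:
                out.at[i, "colour_qualifier"] = ann.colour
    return out, findings


@cli.command()
@click.option("--input", "input_", required=True, type=click.Path(exists=True))
@click.option("--output", required=True, type=click.Path())
@click.option("--report", type=click.Path(), default=None)
@click.option("--base-target", default=250, show_default=True)
@click.option("--base-delta", default=1.25, show_default=True)
@click.option("--max-delta", default=20.0, show_default=True)
def subsample(input_, output, report, base_target, base_delta, max_delta):
    """Density-aware per-site spatial subsampling."""
    df = metadata_io.read_records(input_)
    cfg = subsampler.SubsampleConfig(base_target=base_target,
                                     base_delta=base_delta,
                                     max_delta=max_delta)
    kept, reports = subsampler.subsample_compilation(df, cfg)
    metadata_io.write_records(kept, output)
    if report:
        payload = {"|".join(map(str, k)): dict(v.to_dict(), n_in=int(
            (df["dataset"].astype(str) + "|" + df["site"].astype(str))
            .eq("|".join(map(str, k))).sum()))
            for k, v in reports.items()}
        with open(report, "w") as fh:
            json.dump(payload, fh, indent=1)
    _log(f"kept {len(kept)} of {len(df)} images over {len(reports)} sites")


@cli.command()
@click.option("--input", "input_", required=True, type=click.Path(exists=True))
@click.option("--output", required=True, type=click.Path())
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--radius", default=50.0, show_default=True)
@click.option("--test-frac-of-max", default=0.15, show_default=True)
@click.option("--test-cap", default=0.35, show_default=True)
@click.option("--stratum-column", default="emu", show_default=True)
@click.option("--report", type=click.Path(), default=None)
def partition(input_, output, seed, radius, test_frac_of_max, test_cap,
              stratum_column, report):
    """Leakage-aware label-stratified train/test partitioning."""
    df = metadata_io.read_records(input_, labelled=True)
    cfg = partitioner.PartitionConfig(test_frac_of_max=test_frac_of_max,
                                      test_frac_cap=test_cap,
                                      exclusion_radius_m=radius, seed=seed)
    res = partitioner.partition_dataset(df, cfg, stratum_column)
    out = df.copy()
    out["partition"] = res.assignments
    metadata_io.write_records(out, output)
    if report:
        with open(report, "w") as fh:
            json.dump({"ledger": res.ledger.to_dict(orient="records"),
                       "violations": res.violations,
                       "n_train": res.n_train, "n_test": res.n_test},
                      fh, indent=1)
    _log(f"train {res.n_train} / test {res.n_test}; "
         f"{len(res.violations)} exclusion-zone violations")


@cli.command()
@click.option("--input", "input_", required=True, type=click.Path(exists=True))
@click.option("--labelled", is_flag=True, default=False)
@click.option("--output", type=click.Path(), default=None)
@click.option("--stratum-column", default="emu", show_default=True)
def stats(input_, labelled, output, stratum_column):
    """Label and stratum distribution summaries."""
    df = metadata_io.read_records(input_, labelled=labelled)
    summary = catami.census_by_stratum(df, stratum_column)
    if output:
        summary.to_csv(output, index=False)
    else:
        _log(summary.to_string(index=False))


@cli.command()
@click.option("--recipe", required=True, type=click.Path(exists=True),
              help="YAML survey/label recipe")
@click.option("--output", required=True, type=click.Path())
def simulate(recipe, output):
    """Generate a synthetic compilation from a YAML recipe file."""
    with open(recipe) as fh:
        spec = yaml.safe_load(fh)
    surveys = [synthgen.SurveyRecipe(**r) for r in spec.get("surveys", [])]
    if "labels" in spec:
        lab = spec["labels"]
        if "inventory" in lab:
            lab["inventory"] = tuple(lab["inventory"])
        df = synthgen.gen_labelled_compilation(surveys,
                                               synthgen.LabelRecipe(**lab))
    else:
        df = synthgen.gen_compilation(surveys)
    metadata_io.write_records(df, output)
    _log(f"wrote {len(df)} synthetic records")


def run_pipeline(config: dict, outdir) -> dict:
    """Execute validate -> translate -> subsample -> partition -> stats.

    Stages may be skipped via ``config["stages"]``.  Returns (and writes) a
    manifest recording the toolkit version, a hash of the configuration,
    the global seed and per-stage record counts; the manifest suffices to
    reproduce the run.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages",
                        ["validate", "translate", "subsample", "partition",
                         "stats"])
    seed = int(config.get("seed", 0))
    labelled = bool(config.get("labelled", True))
    df = metadata_io.read_records(config["input"], labelled=labelled)
    manifest = {"version": __version__, "seed": seed,
                "config_hash": hashlib.sha256(
                    json.dumps(config, sort_keys=True).encode()).hexdigest(),
                "stages": []}

    def record(stage, n_in, n_out, **extra):
        manifest["stages"].append(dict(stage=stage, n_in=n_in, n_out=n_out,
                                       **extra))

    if "validate" in stages:
        rep = metadata_io.validate_records(df, labelled=labelled)
        (outdir / "validation.jsonl").write_text(rep.to_jsonl())
        if not rep.ok and config.get("strict", False):
            raise RuntimeError(f"validation failed with {len(rep)} findings")
        record("validate", len(df), len(df), findings=len(rep))
    if "translate" in stages:
        tree = catami.load_scheme(config.get("scheme"))
        table = catami.TranslationTable.load(config.get("translation_table"),
                                             tree)
        df, missed = translate_table(df, table)
        record("translate", len(df), len(df), untranslated=len(missed))
    if "subsample" in stages:
        n_in = len(df)
        df, reports = subsampler.subsample_compilation(
            df, subsampler.SubsampleConfig(**config.get("subsample", {})))
        record("subsample", n_in, len(df), n_sites=len(reports))
    if "partition" in stages:
        cfg = partitioner.PartitionConfig(seed=seed,
                                          **config.get("partition", {}))
        res = partitioner.partition_dataset(
            df, cfg, config.get("stratum_column", "emu"))
        df = df.copy()
        df["partition"] = res.assignments
        (outdir / "partition_ledger.json").write_text(json.dumps(
            {"ledger": res.ledger.to_dict(orient="records"),
             "violations": res.violations}, indent=1))
        record("partition", len(df), len(df), n_train=res.n_train,
               n_test=res.n_test)
    if "stats" in stages:
        summary = catami.census_by_stratum(
            df, config.get("stratum_column", "emu"))
        summary.to_csv(outdir / "stats.csv", index=False)
        record("stats", len(df), len(summary))
    metadata_io.write_records(df, outdir / "output.csv")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


@cli.command(name="run")
@click.option("--config", required=True, type=click.Path(exists=True))
@click.option("--outdir", required=True, type=click.Path())
@click.option("--seed", default=None, type=int,
              help="override the config seed")
def run_cmd(config, outdir, seed):
    """Run the full pipeline from a YAML config."""
    with open(config) as fh:
        cfg = yaml.safe_load(fh)
    if seed is not None:
        cfg["seed"] = seed
    try:
        manifest = run_pipeline(cfg, outdir)
    except Exception as exc:
        _log(f"pipeline failed: {exc}")
        raise SystemExit(1)
    _log(json.dumps(manifest["stages"], indent=1))
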