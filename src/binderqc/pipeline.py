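"""End-to-end orchestration: simulate -> features -> screen -> filter -> evaluate.

Every run writes its resolved configuration, per-stage outputs and a
manifest with package version and seeds, so a rerun with the same config
is byte-identical for the deterministic stages. The ``reproduce_zenodo``
entry point re-analyzes a user-supplied local copy of the released
competition dataset and tabulates computed vs. published summary numbers;
it never downloads anything.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from binderqc import io as bqio
from binderqc.filters import FilterSpec, apply_filter, evaluate_filter
from binderqc.predict import cv_feature_ranking
from binderqc.screen import summarize_by_team, test_enrichment
from binderqc.seqfeats import compute_feature_table, write_feature_schema
from binderqc.simulate import SimConfig, generate_designs, simulate_screen, write_fixture

logger = logging.getLogger("binderqc")

ALL_STAGES = ("simulate", "features", "screen", "filter", "evaluate")


class SchemaError(ValueError):
    """Raised when an input dataset does not match the expected schema."""


@dataclass
class RunConfig:
    """Serializable configuration of a pipeline run."""

    outdir: str = "binderqc_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: dict = field(default_factory=dict)        # SimConfig field overrides
    filter_spec: dict = field(default_factory=dict)  # FilterSpec field overrides
    min_reads: int = 25
    cv_folds: int = 5
    hit_denominator: str = "retained"

    def sim_config(self) -> SimConfig:
        cfg = SimConfig(**self.sim)
        cfg.seed = self.seed
        return cfg

    def spec(self) -> FilterSpec:
        return FilterSpec(**self.filter_spec)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages on a synthetic cohort.

    Stage outputs land in ``config.outdir``; a ``manifest.json`` lists every
    produced file plus the package version and seed, and the resolved config
    is copied next to it. Later stages require the earlier ones (within the
    same run or a previous run in the same directory).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.resolved.yaml")
    import binderqc

    manifest: dict = {
        "binderqc_version": binderqc.__version__,
        "seed": config.seed,
        "stages": {},
    }

    def _require(path: Path, stage: str, needed_by: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage '{needed_by}' needs output {path.name} of stage '{stage}'; "
                f"run it first or include it in stages"
            )
        return path

    designs = truth = counts = None
    if "simulate" in config.stages:
        sim_cfg = config.sim_config()
        designs, truth = generate_designs(sim_cfg)
        counts = simulate_screen(designs, sim_cfg)
        paths = write_fixture(designs, counts, outdir)
        truth.to_csv(outdir / "truth.tsv", sep="\t")
        paths["truth"] = outdir / "truth.tsv"
        manifest["stages"]["simulate"] = {k: str(v) for k, v in paths.items()}
        logger.info("simulate: %d designs", len(designs))

    if "features" in config.stages:
        proteins = bqio.read_fasta(_require(outdir / "protein.fasta", "simulate", "features"))
        dnas = bqio.read_fasta(_require(outdir / "dna.fasta", "simulate", "features"))
        ss = bqio.read_ss(outdir / "ss.tsv") if (outdir / "ss.tsv").exists() else None
        table = compute_feature_table(
            [(design_id, proteins[design_id], dnas[design_id]) for design_id in proteins],
            ss=ss,
        )
        bqio.write_table(table, outdir / "features.tsv")
        write_feature_schema(outdir / "features.schema.json")
        manifest["stages"]["features"] = {
            "features": str(outdir / "features.tsv"),
            "schema": str(outdir / "features.schema.json"),
        }
        logger.info("features: %d rows", len(table))

    if "screen" in config.stages:
        cm = bqio.read_counts(_require(outdir / "counts.tsv", "simulate", "screen"))
        results = test_enrichment(cm, min_reads=config.min_reads)
        results.to_csv(outdir / "results.tsv", sep="\t")
        meta_path = outdir / "metadata.tsv"
        if meta_path.exists():
            team = summarize_by_team(results, bqio.read_metadata(meta_path))
            team.to_csv(outdir / "team_summary.tsv", sep="\t")
        manifest["stages"]["screen"] = {"results": str(outdir / "results.tsv")}
        logger.info(
            "screen: %d recovered, %d enriched",
            int(results["recovered"].sum()),
            int((results["category"] == "enriched").sum()),
        )

    if "filter" in config.stages:
        feats = bqio.read_table(_require(outdir / "features.tsv", "features", "filter"))
        results = pd.read_csv(
            _require(outdir / "results.tsv", "screen", "filter"), sep="\t", index_col=0
        )
        report = apply_filter(feats, config.spec())
        report.to_csv(outdir / "filter_report.tsv", sep="\t")
        metrics = evaluate_filter(report, results, hit_denominator=config.hit_denominator)
        with open(outdir / "filter_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
        manifest["stages"]["filter"] = {
            "report": str(outdir / "filter_report.tsv"),
            "metrics": str(outdir / "filter_metrics.json"),
        }
        logger.info("filter: removed %d of %d", metrics["n_removed"], metrics["n_total"])

    if "evaluate" in config.stages:
        feats = bqio.read_table(_require(outdir / "features.tsv", "features", "evaluate"))
        results = pd.read_csv(
            _require(outdir / "results.tsv", "screen", "evaluate"), sep="\t", index_col=0
        )
        feats = feats.set_index("design_id").loc[results.index]
        ranking = cv_feature_ranking(
            feats, results["recovered"].astype(int), k=config.cv_folds, seed=config.seed
        )
        ranking.to_csv(outdir / "feature_ranking.tsv", sep="\t", index=False)
        manifest["stages"]["evaluate"] = {"ranking": str(outdir / "feature_ranking.tsv")}
        logger.info("evaluate: top feature %s", ranking.iloc[0]["feature"] if len(ranking) else "n/a")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


# Published dataset-level summary statistics of the 12,000-design screen,
# used only to tabulate computed-vs-printed deltas in reproduce_zenodo.
REFERENCE_STATS: dict[str, float] = {
    "n_designs": 12000,
    "pct_detected": 98.3,
    "pct_recovered": 56.8,
    "n_hits": 707,
    "pct_hits": 5.9,
    "pct_recovered_after_filter": 81.2,
    "pct_hits_after_filter": 7.6,
    "pct_recovered_after_cys_filter": 72.6,
    "pct_hits_after_cys_filter": 10.6,
    "n_removed_by_filter": 4600,
}


def reproduce_zenodo(archive_path: str | Path, config: RunConfig | None = None):
    """Re-analyze a local copy of the released competition dataset.

    ``archive_path`` must be a directory containing at least ``counts.tsv``
    (design x replicate schema of :mod:`binderqc.io`) plus optionally
    ``metadata.tsv``, ``protein.fasta``/``dna.fasta`` and ``ss.tsv`` for the
    filter-stage comparisons. Returns a DataFrame with columns
    {metric, computed, printed, delta}, or None (with a log message) when
    the path does not exist. Schema problems raise :class:`SchemaError`
    itemizing what is missing; value mismatches never raise.
    """
    config = config or RunConfig()
    archive = Path(archive_path)
    if not archive.exists():
        logger.warning("archive %s not found; skipping dataset reproduction", archive)
        return None

    counts_path = archive / "counts.tsv"
    if not counts_path.exists():
        raise SchemaError(f"expected file missing from archive: {counts_path.name}")
    try:
        cm = bqio.read_counts(counts_path)
    except ValueError as exc:
        raise SchemaError(f"counts.tsv: {exc}") from exc
    missing_cols = [
        cond for cond in ("cd20pos", "cd20neg") if not cm.replicates(cond)
    ]
    if missing_cols:
        raise SchemaError(f"counts.tsv lacks replicate columns for: {missing_cols}")

    results = test_enrichment(cm, min_reads=config.min_reads)
    computed: dict[str, float] = {
        "n_designs": float(len(results)),
        "pct_recovered": float(results["recovered"].mean() * 100),
        "n_hits": float((results["category"] == "enriched").sum()),
        "pct_hits": float((results["category"] == "enriched").mean() * 100),
    }

    fasta_p, fasta_d = archive / "protein.fasta", archive / "dna.fasta"
    if fasta_p.exists() and fasta_d.exists():
        proteins = bqio.read_fasta(fasta_p)
        dnas = bqio.read_fasta(fasta_d)
        ss = bqio.read_ss(archive / "ss.tsv") if (archive / "ss.tsv").exists() else None
        feats = compute_feature_table(
            [(i, proteins[i], dnas[i]) for i in proteins if i in dnas], ss=ss
        )
        report = apply_filter(feats, config.spec())
        metrics = evaluate_filter(report, results, hit_denominator=config.hit_denominator)
        computed["n_removed_by_filter"] = float(metrics["n_removed"])
        computed["pct_recovered_after_filter"] = metrics["pct_recovered_after"]
        computed["pct_hits_after_filter"] = metrics["pct_hits_after"]
        cys_spec = dataclasses.replace(config.spec(), use_cysteine=True)
        cys_metrics = evaluate_filter(
            apply_filter(feats, cys_spec), results, hit_denominator=config.hit_denominator
        )
        computed["pct_recovered_after_cys_filter"] = cys_metrics["pct_recovered_after"]
        computed["pct_hits_after_cys_filter"] = cys_metrics["pct_hits_after"]

    rows = []
    for metric, printed in REFERENCE_STATS.items():
        if metric not in computed:
            continue
        value = computed[metric]
        rows.append(
            {
                "metric": metric,
                "computed": value,
                "printed": printed,
                "delta": value - printed,
            }
        )
    return pd.DataFrame(rows, columns=["metric", "computed", "printed", "delta"])
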