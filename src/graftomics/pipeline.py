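"""End-to-end orchestration: simulate -> chip-diff -> methylome ->
integrate -> phenotype -> score -> report.

Each stage reads and writes plain TSV under ``RunConfig.outdir`` and the
run finishes with a machine-readable JSON manifest recording the seed,
thresholds and per-stage row counts.  Stage failures abort with a
:class:`PipelineError` naming the stage.  The manifest contains no
timestamps, so identically configured runs are byte-identical.
"""
from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, chip, expression, io, methylome, phenotype, scoring, simulate
from .config import MARKS, RunConfig
from .errors import GraftomicsError, PipelineError

logger = logging.getLogger("graftomics")

ALL_STAGES = ("simulate", "chip", "methylome", "integrate", "phenotype", "score", "report")


def _setup_logging(level: str) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[graftomics %(levelname)s] %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except (GraftomicsError, OSError) as exc:
                raise PipelineError(f"{name}: {exc}") from exc
        return run
    return wrap


@_stage("simulate")
def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    paths = simulate.simulate_all(cfg.sim, out)
    return {"rows": cfg.sim.n_genes, "outputs": sorted(p.name for p in paths.values())}


@_stage("chip")
def stage_chip(cfg: RunConfig, out: Path) -> dict:
    pileups = io.read_tsv(out / "chip_pileups.tsv")
    tracks = io.read_tsv(out / "chip_tracks.tsv")
    genes = io.read_gff3(out / "genes.gff3")
    frames = []
    for mark in MARKS:
        table = chip.enrichment_table(
            pileups[pileups["mark"] == mark],
            fold_cut=cfg.fold_cut, alpha=cfg.alpha, pseudocount=cfg.pseudocount,
        )
        table.insert(1, "mark", mark)
        frames.append(table)
    enrichment = pd.concat(frames, ignore_index=True)
    io.write_tsv(enrichment, out / "chip_enrichment.tsv")
    profile = chip.metagene_from_table(tracks, genes)
    io.write_tsv(profile, out / "metagene_profile.tsv")
    return {"rows": len(enrichment), "outputs": ["chip_enrichment.tsv", "metagene_profile.tsv"]}


@_stage("methylome")
def stage_methylome(cfg: RunConfig, out: Path) -> dict:
    sites = io.read_tsv(out / "methyl_sites.tsv")
    sequences = io.read_fasta(out / "reference.fa")
    genes = io.read_gff3(out / "genes.gff3")
    dmps = methylome.call_dmps(sites, sequences,
                               min_depth=cfg.min_depth, min_fraction=cfg.min_fraction)
    dmgs = methylome.aggregate_dmgs(dmps, genes, flank_bp=cfg.flank_bp,
                                    threshold_k=cfg.dmg_k)
    io.write_tsv(dmps, out / "dmps.tsv")
    io.write_tsv(dmgs, out / "dmgs.tsv")
    return {"rows": len(dmps), "outputs": ["dmps.tsv", "dmgs.tsv"]}


@_stage("integrate")
def stage_integrate(cfg: RunConfig, out: Path) -> dict:
    counts = io.read_tsv(out / "counts.tsv")
    genes = io.read_gff3(out / "genes.gff3")
    enrichment = io.read_tsv(out / "chip_enrichment.tsv")
    dmgs = io.read_tsv(out / "dmgs.tsv")
    term_map = io.read_tsv(out / "term_map.tsv")

    lengths = pd.Series((genes["end"] - genes["start"]).to_numpy(),
                        index=genes["gene_id"])
    expr = expression.expression_table(counts, lengths,
                                       fold_cut=cfg.fold_cut, min_rpkm=cfg.min_rpkm)
    io.write_tsv(expr, out / "expression.tsv")

    k4 = enrichment[enrichment["mark"] == MARKS[0]]
    k27 = enrichment[enrichment["mark"] == MARKS[1]]
    marks = expression.build_mark_assignments(k4, k27, dmgs)
    groups = expression.assign_mark_groups(marks)

    # Venn over the three active-modification gene sets (and implicitly the
    # inactive ones via the mark table); here: K4 hyper / DNA hypo / K27 hypo
    venn_sets = {
        "K4 hyper": set(marks.loc[marks["k4"] == "hyper", "gene_id"]),
        "DNA hypo": set(marks.loc[marks["dna"].isin(["hypo", "both"]), "gene_id"]),
        "K27 hypo": set(marks.loc[marks["k27"] == "hypo", "gene_id"]),
    }
    venn = expression.venn_counts(venn_sets)
    venn_df = pd.DataFrame(
        [{"region": " & ".join(k), "count": v} for k, v in sorted(venn.items())]
    )
    io.write_tsv(venn_df, out / "venn.tsv")

    deg = expr.set_index("gene_id")["class_d0"]
    crosstab = expression.crosstab_marks_by_deg(marks, deg).reset_index()
    io.write_tsv(crosstab, out / "crosstab.tsv")

    table1 = expression.build_table1(k4, k27, dmgs, expr)
    io.write_tsv(table1, out / "table1.tsv")

    universe = set(genes["gene_id"])
    marked = groups["active"] | groups["inactive"]
    enrich = expression.fisher_term_enrichment(marked, universe, term_map,
                                               alpha=cfg.enrichment_alpha)
    io.write_tsv(enrich, out / "term_enrichment.tsv")
    return {
        "rows": len(table1),
        "outputs": ["expression.tsv", "venn.tsv", "crosstab.tsv", "table1.tsv",
                    "term_enrichment.tsv"],
    }


@_stage("phenotype")
def stage_phenotype(cfg: RunConfig, out: Path) -> dict:
    qpcr = io.read_tsv(out / "qpcr.tsv")
    cohort = io.read_tsv(out / "cohort.tsv")
    stats_df = phenotype.qpcr_group_stats(qpcr)
    summary = phenotype.cohort_summary(cohort)
    tests = phenotype.survival_tests(summary)
    io.write_tsv(stats_df, out / "qpcr_stats.tsv")
    io.write_tsv(summary, out / "cohort_summary.tsv")
    io.write_tsv(tests, out / "cohort_tests.tsv")
    return {"rows": len(summary),
            "outputs": ["qpcr_stats.tsv", "cohort_summary.tsv", "cohort_tests.tsv"]}


@_stage("score")
def stage_score(cfg: RunConfig, out: Path) -> dict:
    truth_chip = io.read_tsv(out / "truth_chip.tsv")
    truth_meth = io.read_tsv(out / "truth_methylation.tsv")
    truth_expr = io.read_tsv(out / "truth_expression.tsv")
    enrichment = io.read_tsv(out / "chip_enrichment.tsv")
    dmps = io.read_tsv(out / "dmps.tsv")
    expr = io.read_tsv(out / "expression.tsv")
    scores = {}
    for mark in MARKS:
        scores[f"chip_{mark}"] = scoring.score_chip(
            truth_chip, enrichment[enrichment["mark"] == mark], mark)
    scores["dmp"] = scoring.score_dmps(truth_meth, dmps)
    scores["deg"] = scoring.score_deg(truth_expr, expr)
    frame = scoring.scores_to_frame(scores)
    io.write_tsv(frame, out / "scores.tsv")
    return {"rows": len(frame), "outputs": ["scores.tsv"]}


def run_all(cfg: RunConfig, stages=None) -> dict:
    """Run the pipeline stages in dependency order and write the manifest.

    ``stages`` restricts execution (default: everything); earlier outputs
    must already exist when a stage is skipped.  Returns the manifest.
    """
    _setup_logging(cfg.log_level)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    todo = list(stages) if stages is not None else list(ALL_STAGES)
    unknown = set(todo) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"run-all: unknown stages {sorted(unknown)}")
    runners = {
        "simulate": stage_simulate,
        "chip": stage_chip,
        "methylome": stage_methylome,
        "integrate": stage_integrate,
        "phenotype": stage_phenotype,
        "score": stage_score,
    }
    manifest = {
        "package": "graftomics",
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": cfg.thresholds(),
        "sim": {k: v for k, v in vars(cfg.sim).items()
                if isinstance(v, (int, float, str, bool))},
        "stages": {},
    }
    for name in ALL_STAGES:
        if name == "report" or name not in todo:
            continue
        manifest["stages"][name] = runners[name](cfg, out)
    if "report" in todo:
        io.write_manifest(manifest, out / "manifest.json")
        manifest["stages"]["report"] = {"rows": 1, "outputs": ["manifest.json"]}
        io.write_manifest(manifest, out / "manifest.json")
    return manifest
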