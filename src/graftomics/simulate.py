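"""Synthetic multi-omic data with planted ground truth.

This module generates every input the downstream stages consume — a toy
reference with gene models, per-gene ChIP pile-ups with binned signal
tracks, paired condition site tables obeying conversion chemistry
(an unmethylated cytosine reads as thymine on its own strand, hence
guanine reads as adenine when the cytosine sits on the minus strand),
RNA count matrices, qPCR Ct tables and plant-level survival cohorts —
together with truth tables sufficient to score any caller.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimConfig.seed``; a fixed config therefore yields byte-identical files.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import CONDITIONS, MARKS, TIMEPOINTS, SimConfig
from .errors import ConfigError, CoordinateError
from . import io

BASES = np.array(list("ACGT"))
_OTHER = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])  # non-self base indices

# 5'-anchored body shape for the promoter-peaked (K4-like) mark; the
# repressive (K27-like) mark is uniform across the gene body.
N_FLANK_BINS = 10
N_BODY_BINS = 40


def _rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


# ---------------------------------------------------------------------------
# reference + gene models

def generate_reference(config: SimConfig, rng: np.random.Generator | None = None):
    """Build one linear chromosome with evenly spaced, non-overlapping,
    strand-alternating gene models.

    Returns ``(sequences, genes)`` where sequences is ``{chrom: str}`` and
    genes has columns gene_id, chrom, start, end, strand (0-based
    half-open).  Total length is ``n_genes*gene_length + (n_genes+1)*
    intergenic`` by construction.
    """
    if config.n_genes < 1:
        raise ConfigError("cannot generate a reference with zero genes")
    rng = rng if rng is not None else _rng(config)
    n, glen, ilen = config.n_genes, config.gene_length_bp, config.intergenic_bp
    total = n * glen + (n + 1) * ilen
    p_gc = config.gc_fraction / 2.0
    p_at = (1.0 - config.gc_fraction) / 2.0
    seq_idx = rng.choice(4, size=total, p=[p_at, p_gc, p_gc, p_at])
    seq = "".join(BASES[seq_idx])
    starts = ilen + np.arange(n) * (glen + ilen)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:06d}" for i in range(n)],
            "chrom": "chr1",
            "start": starts,
            "end": starts + glen,
            "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
        }
    )
    return {"chr1": seq}, genes


def cytosine_sites(sequences: dict[str, str]) -> pd.DataFrame:
    """All cytosine sites on both strands, in the plus-strand frame.

    A plus-strand cytosine is a reference C; a minus-strand cytosine is a
    reference G.  Columns: chrom, pos (0-based), ref_base, strand.
    """
    frames = []
    for chrom, seq in sequences.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for ref, strand in ((b"C", "+"), (b"G", "-")):
            pos = np.flatnonzero(arr == ref)
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos, "ref_base": ref.decode(), "strand": strand}
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], ignore_index=True)


# ---------------------------------------------------------------------------
# planted truth

def plant_chip_truth(config: SimConfig, gene_ids, rng: np.random.Generator) -> pd.DataFrame:
    """Assign {hyper, hypo, none} per gene per mark (disjoint, exhaustive)."""
    rows = []
    n = len(gene_ids)
    n_hyper = int(round(config.frac_hyper * n))
    n_hypo = int(round(config.frac_hypo * n))
    for mark in MARKS:
        perm = rng.permutation(n)
        label = np.full(n, "none", dtype=object)
        label[perm[:n_hyper]] = "hyper"
        label[perm[n_hyper:n_hyper + n_hypo]] = "hypo"
        rows.append(pd.DataFrame({"gene_id": gene_ids, "mark": mark, "label": label}))
    return pd.concat(rows, ignore_index=True)


def plant_methylation_truth(
    config: SimConfig, sites: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-site methylation state per condition; a ``dmp_rate`` fraction of
    sites flips state between control and grafted."""
    n = len(sites)
    control = rng.random(n) < config.methylation_rate
    flip = rng.random(n) < config.dmp_rate
    grafted = control ^ flip
    truth = sites.copy()
    truth["state_control"] = np.where(control, "methylated", "unmethylated")
    truth["state_grafted"] = np.where(grafted, "methylated", "unmethylated")
    # a flip away from methylation is a hypo DMP, toward it a hyper DMP
    truth["dmp_direction"] = np.select(
        [flip & control, flip & ~control], ["hypo", "hyper"], default="none"
    )
    return truth


def plant_expression_truth(config: SimConfig, gene_ids, rng: np.random.Generator) -> pd.DataFrame:
    n = len(gene_ids)
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    perm = rng.permutation(n)
    label = np.full(n, "nc", dtype=object)
    label[perm[:n_up]] = "up"
    label[perm[n_up:n_up + n_down]] = "down"
    return pd.DataFrame({"gene_id": gene_ids, "label": label})


# ---------------------------------------------------------------------------
# ChIP pile-ups

def _lognormal_around(mean, cv: float, rng: np.random.Generator, size=None):
    """Mean-preserving lognormal draws with the given coefficient of variation."""
    if cv < 0:
        raise ConfigError("noise CV must be >= 0")
    if cv == 0:
        return np.broadcast_to(np.asarray(mean, dtype=float), size if size else np.shape(mean)).copy()
    sigma = np.sqrt(np.log1p(cv * cv))
    z = rng.standard_normal(size if size else np.shape(mean))
    return np.asarray(mean, dtype=float) * np.exp(sigma * z - sigma * sigma / 2.0)


def _body_shape(mark: str) -> np.ndarray:
    """Relative signal over flank|body|flank bins for one mark."""
    body = np.arange(N_BODY_BINS)
    if mark == MARKS[0]:  # promoter-peaked: maximum near the 5' end of the body
        shape_body = 0.3 + 2.2 * np.exp(-0.5 * ((body - 5.0) / 4.0) ** 2)
        flank = np.full(N_FLANK_BINS, 0.15)
        return np.concatenate([flank, shape_body, flank])
    # uniform throughout
    return np.ones(2 * N_FLANK_BINS + N_BODY_BINS)


def simulate_chip_pileups(
    config: SimConfig,
    chip_truth: pd.DataFrame,
    rng: np.random.Generator,
    genes: pd.DataFrame | None = None,
):
    """Per-gene pile-up values per mark/condition/replicate, plus binned
    signal tracks.

    Hyper genes receive grafted mean = ``chip_effect_fold`` x control mean,
    hypo genes the reciprocal, unaffected genes identical means.  Replicates
    are mean-preserving lognormal with CV ``chip_noise_cv``, so with CV 0
    ratios are exactly the planted fold.

    Returns ``(pileups, tracks)``: a long table (gene_id, mark, cond, rep,
    value) and a long track table (gene_id, mark, bin, value) in genomic
    orientation (minus-strand genes reversed).
    """
    if config.chip_noise_cv < 0:
        raise ConfigError("chip_noise_cv must be >= 0")
    strand = None
    if genes is not None:
        strand = genes.set_index("gene_id")["strand"]
    pile_frames, track_frames = [], []
    for mark in MARKS:
        sub = chip_truth[chip_truth["mark"] == mark].reset_index(drop=True)
        g = len(sub)
        base = config.chip_base_mean * np.exp(
            config.chip_base_sigma * rng.standard_normal(g)
            - config.chip_base_sigma**2 / 2.0
        )
        fold = np.select(
            [sub["label"] == "hyper", sub["label"] == "hypo"],
            [config.chip_effect_fold, 1.0 / config.chip_effect_fold],
            default=1.0,
        )
        means = {"control": base, "grafted": base * fold}
        for cond in CONDITIONS:
            draws = _lognormal_around(
                means[cond][:, None], config.chip_noise_cv, rng,
                size=(g, config.n_replicates),
            )
            for rep in range(config.n_replicates):
                pile_frames.append(
                    pd.DataFrame(
                        {
                            "gene_id": sub["gene_id"],
                            "mark": mark,
                            "cond": cond,
                            "rep": rep + 1,
                            "value": draws[:, rep],
                        }
                    )
                )
        # binned track at the control level (the profile shape is a property
        # of the mark, not of the grafting contrast)
        shape = _body_shape(mark)
        track = base[:, None] * shape[None, :]
        track = _lognormal_around(track, config.chip_noise_cv, rng, size=track.shape)
        if strand is not None:
            minus = (strand.reindex(sub["gene_id"]).to_numpy() == "-")
            track[minus] = track[minus, ::-1]
        nb = track.shape[1]
        track_frames.append(
            pd.DataFrame(
                {
                    "gene_id": np.repeat(sub["gene_id"].to_numpy(), nb),
                    "mark": mark,
                    "bin": np.tile(np.arange(nb), g),
                    "value": track.ravel(),
                }
            )
        )
    return (
        pd.concat(pile_frames, ignore_index=True),
        pd.concat(track_frames, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# methylome site tables

def simulate_methyl_calls(
    config: SimConfig,
    meth_truth: pd.DataFrame,
    sequences: dict[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Replicate base counts per cytosine site per condition.

    Chemistry contract (error rate 0): a methylated plus-strand cytosine is
    read as C and an unmethylated one as T; a methylated minus-strand
    cytosine appears as G in the plus frame and an unmethylated one as A.
    Depth is Poisson(``depth_mean``) per replicate; each read independently
    miscalls to one of the three other bases with ``error_rate``.

    Output columns: chrom, pos (1-based), ref_base, strand, cond, rep,
    nA, nC, nG, nT.
    """
    for chrom, pos in zip(meth_truth["chrom"], meth_truth["pos"]):
        if chrom not in sequences:
            raise CoordinateError(f"site on unknown sequence {chrom!r}")
    lengths = {c: len(s) for c, s in sequences.items()}
    max_len = meth_truth["chrom"].map(lengths)
    if (meth_truth["pos"] < 0).any() or (meth_truth["pos"] >= max_len).any():
        raise CoordinateError("site position outside the reference")

    n = len(meth_truth)
    plus = (meth_truth["strand"] == "+").to_numpy()
    frames = []
    for cond in CONDITIONS:
        meth = (meth_truth[f"state_{cond}"] == "methylated").to_numpy()
        # observed-base index in the plus frame: C=1, T=3, G=2, A=0
        true_base = np.where(plus, np.where(meth, 1, 3), np.where(meth, 2, 0))
        for rep in range(config.n_replicates):
            depth = rng.poisson(config.depth_mean, n)
            if config.error_rate > 0:
                n_err = rng.binomial(depth, config.error_rate)
            else:
                n_err = np.zeros(n, dtype=np.int64)
            counts = np.zeros((n, 4), dtype=np.int64)
            counts[np.arange(n), true_base] = depth - n_err
            if config.error_rate > 0:
                split = rng.multinomial(n_err, [1 / 3, 1 / 3, 1 / 3])
                others = _OTHER[true_base]
                for j in range(3):
                    counts[np.arange(n), others[:, j]] += split[:, j]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": meth_truth["chrom"].to_numpy(),
                        "pos": meth_truth["pos"].to_numpy() + 1,
                        "ref_base": meth_truth["ref_base"].to_numpy(),
                        "strand": meth_truth["strand"].to_numpy(),
                        "cond": cond,
                        "rep": rep + 1,
                        "nA": counts[:, 0],
                        "nC": counts[:, 1],
                        "nG": counts[:, 2],
                        "nT": counts[:, 3],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# RNA counts, qPCR, cohorts

def simulate_counts(
    config: SimConfig,
    expr_truth: pd.DataFrame,
    rng: np.random.Generator,
    noise: bool = True,
) -> pd.DataFrame:
    """Gene count matrix for the four pooled libraries Co/Gr x D0/D3.

    Grafted means are ``deg_fold`` x control for planted-up genes and the
    reciprocal for planted-down genes, at both timepoints (a shared per-gene
    drought factor shifts D3 in both conditions).  Counts are
    gamma-Poisson (negative binomial) with dispersion ``nb_dispersion``;
    with ``noise=False`` the expected values are returned unchanged.
    """
    if config.nb_dispersion < 0:
        raise ConfigError("nb_dispersion must be >= 0")
    g = len(expr_truth)
    base = config.count_base_mean * np.exp(
        config.count_base_sigma * rng.standard_normal(g)
        - config.count_base_sigma**2 / 2.0
    )
    fold = np.select(
        [expr_truth["label"] == "up", expr_truth["label"] == "down"],
        [config.deg_fold, 1.0 / config.deg_fold],
        default=1.0,
    )
    drought = np.exp(0.5 * rng.standard_normal(g))  # shared D3 shift
    means = {
        ("control", "D0"): base,
        ("grafted", "D0"): base * fold,
        ("control", "D3"): base * drought,
        ("grafted", "D3"): base * fold * drought,
    }
    out = pd.DataFrame({"gene_id": expr_truth["gene_id"]})
    for cond in CONDITIONS:
        for tp in TIMEPOINTS:
            m = means[(cond, tp)]
            if not noise:
                vals = m
            elif config.nb_dispersion == 0:
                vals = rng.poisson(m)
            else:
                lam = rng.gamma(1.0 / config.nb_dispersion, m * config.nb_dispersion)
                vals = rng.poisson(lam)
            out[f"{cond}_{tp}"] = vals
    return out


def simulate_qpcr(
    config: SimConfig,
    rng: np.random.Generator,
    gene_ids=None,
    expr_truth: pd.DataFrame | None = None,
):
    """Ct tables with a reference-gene channel (rRNA stand-in).

    The planted relative expression of a gene in a group is ``deg_fold``
    (up), ``1/deg_fold`` (down) or 1 relative to control; pre-drought groups
    are planted at 1.  Returns ``(ct_table, truth)``.
    """
    groups = ("control", "grafted", "pre4d", "pre7d")
    if gene_ids is None:
        gene_ids = ["q%02d" % i for i in range(1, 5)]
    labels = {}
    if expr_truth is not None:
        labels = expr_truth.set_index("gene_id")["label"].to_dict()
    rows, truth_rows = [], []
    for gene in gene_ids:
        lab = labels.get(gene, "up")  # stand-alone qPCR genes default to planted up
        rel_grafted = {"up": config.deg_fold, "down": 1.0 / config.deg_fold}.get(lab, 1.0)
        for group in groups:
            rel = rel_grafted if group == "grafted" else 1.0
            for tp in TIMEPOINTS:
                truth_rows.append(
                    {"gene": gene, "group": group, "timepoint": tp, "rel_expr": rel}
                )
                # rel = 2^-(dct - dct_control); plant control dCT at 5 cycles
                dct = 5.0 - np.log2(rel)
                for rep in range(1, config.n_replicates + 1):
                    ct_ref = config.qpcr_ref_ct + 0.15 * rng.standard_normal()
                    ct_target = ct_ref + dct + config.qpcr_ct_sd * rng.standard_normal()
                    rows.append(
                        {
                            "gene": gene,
                            "group": group,
                            "timepoint": tp,
                            "rep": rep,
                            "ct_target": ct_target,
                            "ct_ref": ct_ref,
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_cohort(config: SimConfig, rng: np.random.Generator):
    """One row per plant with its recovery route.

    Survivors regrow from the apical meristem or (with probability
    ``axillary_fraction``) from an axillary bud; non-survivors have route
    ``none``.  Returns ``(cohort_table, truth)`` where truth records the
    planted survival probabilities.
    """
    rows = []
    for group, n in config.cohort_sizes.items():
        p = config.cohort_survival[group]
        survived = rng.random(n) < p
        axillary = rng.random(n) < config.axillary_fraction
        route = np.where(survived, np.where(axillary, "axillary", "apical"), "none")
        for i in range(n):
            rows.append({"group": group, "plant_id": f"{group}_{i + 1:03d}", "route": route[i]})
    truth = pd.DataFrame(
        [
            {"group": g, "n": n, "survival_prob": config.cohort_survival[g]}
            for g, n in config.cohort_sizes.items()
        ]
    )
    return pd.DataFrame(rows), truth


def simulate_term_map(
    gene_ids, rng: np.random.Generator, n_terms: int = 20, max_terms_per_gene: int = 3
) -> pd.DataFrame:
    """Random gene -> term assignments for the term-enrichment stage."""
    rows = []
    terms = [f"T{j:03d}" for j in range(n_terms)]
    for gid in gene_ids:
        k = rng.integers(1, max_terms_per_gene + 1)
        for t in rng.choice(terms, size=k, replace=False):
            rows.append({"gene_id": gid, "term_id": t})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration

def simulate_all(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic dataset plus truth tables into ``outdir``.

    Deterministic: the same config (including seed) produces byte-identical
    files.  Returns a name -> path mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config)

    sequences, genes = generate_reference(config, rng)
    sites = cytosine_sites(sequences)
    chip_truth = plant_chip_truth(config, genes["gene_id"].tolist(), rng)
    meth_truth = plant_methylation_truth(config, sites, rng)
    expr_truth = plant_expression_truth(config, genes["gene_id"].tolist(), rng)

    pileups, tracks = simulate_chip_pileups(config, chip_truth, rng, genes)
    site_table = simulate_methyl_calls(config, meth_truth, sequences, rng)
    counts = simulate_counts(config, expr_truth, rng)
    qpcr, qpcr_truth = simulate_qpcr(config, rng)
    cohort, cohort_truth = simulate_cohort(config, rng)
    term_map = simulate_term_map(genes["gene_id"].tolist(), rng)

    paths = {
        "reference": outdir / "reference.fa",
        "genes": outdir / "genes.gff3",
        "chip_pileups": outdir / "chip_pileups.tsv",
        "chip_tracks": outdir / "chip_tracks.tsv",
        "methyl_sites": outdir / "methyl_sites.tsv",
        "counts": outdir / "counts.tsv",
        "qpcr": outdir / "qpcr.tsv",
        "cohort": outdir / "cohort.tsv",
        "term_map": outdir / "term_map.tsv",
        "truth_chip": outdir / "truth_chip.tsv",
        "truth_methylation": outdir / "truth_methylation.tsv",
        "truth_expression": outdir / "truth_expression.tsv",
        "truth_qpcr": outdir / "truth_qpcr.tsv",
        "truth_cohort": outdir / "truth_cohort.tsv",
    }
    io.write_fasta(sequences, paths["reference"])
    io.write_gff3(genes, paths["genes"])
    io.write_tsv(pileups, paths["chip_pileups"])
    io.write_tsv(tracks, paths["chip_tracks"])
    io.write_tsv(site_table, paths["methyl_sites"])
    io.write_tsv(counts, paths["counts"])
    io.write_tsv(qpcr, paths["qpcr"])
    io.write_tsv(cohort, paths["cohort"])
    io.write_tsv(term_map, paths["term_map"])
    io.write_tsv(chip_truth, paths["truth_chip"])
    truth_meth_out = meth_truth.copy()
    truth_meth_out["pos"] = truth_meth_out["pos"] + 1  # 1-based on disk
    io.write_tsv(truth_meth_out, paths["truth_methylation"])
    io.write_tsv(expr_truth, paths["truth_expression"])
    io.write_tsv(qpcr_truth, paths["truth_qpcr"])
    io.write_tsv(cohort_truth, paths["truth_cohort"])
    return paths
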