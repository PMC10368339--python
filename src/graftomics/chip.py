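"""Differential histone-mark enrichment from per-gene ChIP pile-ups.

The signal per gene is the mean pile-up over replicates in each condition.
Signed fold enrichment is the grafted/control ratio, reported as ``+r``
for increases and ``-1/r`` for decreases (magnitude always >= 1, zero
difference mapping to +1).  P-values come from a robust normal null fitted
to the log2 ratios over all genes (median centre, MAD spread), chosen
because genuine effects occupy only the tails while the bulk of genes is
approximately lognormal in both conditions.  A gene is called hyper when
its signed fold is >= +2 with p below alpha, hypo when <= -2 with p below
alpha, otherwise ns.  No multiple-testing correction is applied; the
classification threshold is a raw per-gene p-value.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateNullError, InputError

MIN_GENES_FOR_NULL = 50


def fold_enrichment(control_reps, grafted_reps, pseudocount: float = 1.0) -> float:
    """Signed fold enrichment between replicate means.

    ``r = mean(grafted)/mean(control)``; returns ``+r`` if r >= 1 else
    ``-1/r``.  The pseudocount is added to *both* means only when one of
    them is zero, so ordinary positive pile-ups are untouched (10 vs 21
    gives exactly +2.1) while all-zero conditions stay finite.
    """
    c = np.asarray(control_reps, dtype=float)
    g = np.asarray(grafted_reps, dtype=float)
    if c.size == 0 or g.size == 0:
        raise InputError("each condition needs at least one replicate")
    if (c < 0).any() or (g < 0).any():
        raise InputError("pile-up values must be non-negative")
    mc, mg = c.mean(), g.mean()
    if mc == 0.0 or mg == 0.0:
        if pseudocount <= 0:
            raise InputError("undefined ratio: a condition mean is zero and the pseudocount is disabled")
        mc += pseudocount
        mg += pseudocount
    r = mg / mc
    return r if r >= 1.0 else -1.0 / r


def _signed_to_log2(signed_fold: np.ndarray) -> np.ndarray:
    return np.where(signed_fold >= 0, np.log2(signed_fold), -np.log2(-signed_fold))


def fit_null(log2_ratios) -> tuple[float, float]:
    """Robust normal null for log2 ratios: median centre, MAD-scaled spread."""
    x = np.asarray(log2_ratios, dtype=float)
    if x.size < MIN_GENES_FOR_NULL:
        raise InputError(f"null fit needs at least {MIN_GENES_FOR_NULL} genes, got {x.size}")
    mu = float(np.median(x))
    sd = float(stats.median_abs_deviation(x, scale="normal"))
    if sd == 0.0:
        raise DegenerateNullError("all log2 ratios identical: null spread is zero")
    return mu, sd


def pvalues_from_null(log2_ratios, mu: float, sd: float) -> np.ndarray:
    """Two-sided tail probability under the fitted N(mu, sd)."""
    z = (np.asarray(log2_ratios, dtype=float) - mu) / sd
    return 2.0 * stats.norm.sf(np.abs(z))


def fit_null_and_pvalues(signed_folds) -> np.ndarray:
    x = _signed_to_log2(np.asarray(signed_folds, dtype=float))
    mu, sd = fit_null(x)
    return pvalues_from_null(x, mu, sd)


def classify_enrichment(signed_fold: float, p_value: float,
                        fold_cut: float = 2.0, alpha: float = 0.001) -> str:
    if signed_fold >= fold_cut and p_value < alpha:
        return "hyper"
    if signed_fold <= -fold_cut and p_value < alpha:
        return "hypo"
    return "ns"


def enrichment_table(
    pileups: pd.DataFrame,
    fold_cut: float = 2.0,
    alpha: float = 0.001,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene enrichment records for one mark.

    ``pileups`` is long-form with columns gene_id, cond, rep, value (one
    mark at a time; filter first if the table carries a mark column).
    Returns gene_id, mean_control, mean_grafted, signed_fold, p_value,
    class.
    """
    required = {"gene_id", "cond", "rep", "value"}
    if not required.issubset(pileups.columns):
        raise InputError(f"pile-up table must have columns {sorted(required)}")
    means = pileups.pivot_table(index="gene_id", columns="cond", values="value",
                                aggfunc="mean", sort=True)
    for cond in ("control", "grafted"):
        if cond not in means.columns:
            raise InputError(f"pile-up table is missing condition {cond!r}")
    mc = means["control"].to_numpy(dtype=float)
    mg = means["grafted"].to_numpy(dtype=float)
    zero = (mc == 0.0) | (mg == 0.0)
    if zero.any() and pseudocount <= 0:
        raise InputError("undefined ratio for all-zero condition with pseudocount disabled")
    mc_adj = np.where(zero, mc + pseudocount, mc)
    mg_adj = np.where(zero, mg + pseudocount, mg)
    ratio = mg_adj / mc_adj
    signed = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    log2r = np.log2(ratio)
    mu, sd = fit_null(log2r)
    pvals = pvalues_from_null(log2r, mu, sd)
    cls = np.select(
        [(signed >= fold_cut) & (pvals < alpha), (signed <= -fold_cut) & (pvals < alpha)],
        ["hyper", "hypo"],
        default="ns",
    )
    return pd.DataFrame(
        {
            "gene_id": means.index,
            "mean_control": mc,
            "mean_grafted": mg,
            "signed_fold": signed,
            "p_value": pvals,
            "class": cls,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# metagene profile

def _resample(segment: np.ndarray, n_out: int) -> np.ndarray:
    if len(segment) == n_out:
        return segment
    if len(segment) == 0:
        return np.zeros(n_out)
    x_in = (np.arange(len(segment)) + 0.5) / len(segment)
    x_out = (np.arange(n_out) + 0.5) / n_out
    return np.interp(x_out, x_in, segment)


def metagene_profile(
    tracks: np.ndarray,
    strands,
    n_body_bins: int = 40,
    n_flank_bins: int = 10,
    in_flank_bins: int | None = None,
) -> np.ndarray:
    """Across-gene mean signal profile over 5' flank | scaled body | 3' flank.

    ``tracks`` is (genes x bins) in genomic orientation covering
    flank+body+flank; minus-strand genes are reversed so the profile is
    oriented 5'->3'.  Tracks of a different bin count are rescaled per
    segment by linear interpolation (flank share inferred proportionally
    unless ``in_flank_bins`` is given).
    """
    tracks = np.asarray(tracks, dtype=float)
    if tracks.ndim == 1:
        tracks = tracks[None, :]
    if tracks.size == 0 or tracks.shape[0] == 0:
        raise InputError("metagene profile needs at least one gene track")
    strands = np.asarray(list(strands))
    if strands.shape[0] != tracks.shape[0]:
        raise InputError("one strand per gene track is required")
    n_out = 2 * n_flank_bins + n_body_bins
    length = tracks.shape[1]
    if in_flank_bins is None:
        in_flank_bins = int(round(length * n_flank_bins / n_out))
    oriented = np.where((strands == "-")[:, None], tracks[:, ::-1], tracks)
    if length == n_out and in_flank_bins == n_flank_bins:
        resampled = oriented
    else:
        resampled = np.empty((tracks.shape[0], n_out))
        for i, row in enumerate(oriented):
            left, body, right = (
                row[:in_flank_bins],
                row[in_flank_bins:length - in_flank_bins],
                row[length - in_flank_bins:],
            )
            resampled[i] = np.concatenate(
                [
                    _resample(left, n_flank_bins),
                    _resample(body, n_body_bins),
                    _resample(right, n_flank_bins),
                ]
            )
    return resampled.mean(axis=0)


def metagene_from_table(
    tracks: pd.DataFrame,
    genes: pd.DataFrame,
    n_body_bins: int = 40,
    n_flank_bins: int = 10,
) -> pd.DataFrame:
    """Mean profile per mark from a long track table (gene_id, mark, bin, value)."""
    strand = genes.set_index("gene_id")["strand"]
    frames = []
    for mark, sub in tracks.groupby("mark", sort=True):
        wide = sub.pivot(index="gene_id", columns="bin", values="value").sort_index()
        prof = metagene_profile(
            wide.to_numpy(), strand.reindex(wide.index).to_numpy(),
            n_body_bins=n_body_bins, n_flank_bins=n_flank_bins,
        )
        frames.append(pd.DataFrame({"mark": mark, "bin": np.arange(prof.size), "mean_signal": prof}))
    return pd.concat(frames, ignore_index=True)
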