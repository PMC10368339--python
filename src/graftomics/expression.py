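"""RPKM normalisation, fold-change DEG classification and the
multi-mark/expression integration layer.

Expression is classified purely by fold change between grafted and
control (no count-based test): up when the RPKM ratio reaches 2, down
when it falls to 1/2, otherwise no change.  The fold threshold is
*inclusive* — a ratio of exactly 2.0 is "up".  Genes whose maximum RPKM
across all samples in the comparison context stays at or below the
expression floor (default 10) are reported as ``filtered`` rather than
classified.  A pseudocount of 0.01 is applied only when the control RPKM
is exactly zero, so ordinary values are never distorted.

The integration layer groups epigenetic marks into transcription-
promoting ("active": K4 hyper, DNA hypo, K27 hypo) and silencing
("inactive": K4 hypo, DNA hyper, K27 hyper) sets, computes Venn region
counts, cross-tabulates mark classes against DEG direction, joins
everything into per-gene report rows, and provides a one-sided
hypergeometric over-representation test for user-supplied gene -> term
maps.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

EPSILON_ZERO_CONTROL = 0.01
_REL_TOL = 1e-12  # guards binary-representation jitter at exact thresholds


# ---------------------------------------------------------------------------
# RPKM + DEG classification

def rpkm(count: float, gene_length_bp: float, library_total: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_bp <= 0:
        raise InputError("gene length must be positive")
    if library_total <= 0:
        raise InputError("library total must be positive")
    return count * 1e9 / (gene_length_bp * library_total)


def rpkm_matrix(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """RPKM for a gene x sample count matrix (gene_id column + sample columns).

    Library totals are the per-sample column sums.
    """
    lengths = gene_lengths.reindex(counts["gene_id"])
    if lengths.isna().any():
        missing = counts.loc[lengths.isna().to_numpy(), "gene_id"].tolist()[:5]
        raise InputError(f"genes without length annotation: {missing}")
    out = pd.DataFrame({"gene_id": counts["gene_id"]})
    for col in counts.columns.drop("gene_id"):
        total = counts[col].sum()
        out[col] = counts[col].to_numpy() * 1e9 / (lengths.to_numpy() * total)
    return out


def classify_deg(
    rpkm_control: float,
    rpkm_grafted: float,
    fold_cut: float = 2.0,
    min_rpkm: float = 10.0,
    context_max_rpkm: float | None = None,
) -> str:
    """Fold-change class of one gene at one timepoint.

    ``context_max_rpkm`` is the gene's maximum RPKM across every sample of
    the comparison (defaults to the two values given); at or below
    ``min_rpkm`` the gene is ``filtered``.  Thresholds are inclusive.
    """
    if rpkm_control < 0 or rpkm_grafted < 0:
        raise InputError("RPKM values must be non-negative")
    ctx = max(rpkm_control, rpkm_grafted) if context_max_rpkm is None else context_max_rpkm
    if ctx <= min_rpkm:
        return "filtered"
    if rpkm_control == 0.0:
        ratio = (rpkm_grafted + EPSILON_ZERO_CONTROL) / (rpkm_control + EPSILON_ZERO_CONTROL)
    else:
        ratio = rpkm_grafted / rpkm_control
    if ratio >= fold_cut * (1.0 - _REL_TOL):
        return "up"
    if ratio <= (1.0 / fold_cut) * (1.0 + _REL_TOL):
        return "down"
    return "nc"


def expression_table(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    fold_cut: float = 2.0,
    min_rpkm: float = 10.0,
) -> pd.DataFrame:
    """Per-gene expression records from a gene x 4-sample count matrix.

    Expects sample columns control_D0, control_D3, grafted_D0, grafted_D3.
    The expression filter uses the max RPKM across all four samples.
    """
    needed = {"gene_id", "control_D0", "control_D3", "grafted_D0", "grafted_D3"}
    if not needed.issubset(counts.columns):
        raise InputError(f"count matrix must have columns {sorted(needed)}")
    rp = rpkm_matrix(counts[list(needed)], gene_lengths)
    ctx = rp[["control_D0", "control_D3", "grafted_D0", "grafted_D3"]].max(axis=1)
    out = pd.DataFrame(
        {
            "gene_id": rp["gene_id"],
            "rpkm_co_d0": rp["control_D0"],
            "rpkm_co_d3": rp["control_D3"],
            "rpkm_gr_d0": rp["grafted_D0"],
            "rpkm_gr_d3": rp["grafted_D3"],
        }
    )
    for tp in ("d0", "d3"):
        out[f"class_{tp}"] = [
            classify_deg(c, g, fold_cut=fold_cut, min_rpkm=min_rpkm, context_max_rpkm=m)
            for c, g, m in zip(out[f"rpkm_co_{tp}"], out[f"rpkm_gr_{tp}"], ctx)
        ]
    return out


# ---------------------------------------------------------------------------
# mark integration

ACTIVE_RULES = (("k4", "hyper"), ("dna", "hypo"), ("k27", "hypo"))
INACTIVE_RULES = (("k4", "hypo"), ("dna", "hyper"), ("k27", "hyper"))


def build_mark_assignments(
    k4: pd.DataFrame, k27: pd.DataFrame, dmg: pd.DataFrame
) -> pd.DataFrame:
    """Join per-mark enrichment classes and DMG directions per gene.

    ``k4``/``k27`` are enrichment tables (gene_id, class); ``dmg`` has
    gene_id, n_hyper, n_hypo.  The DNA column is hyper / hypo / both /
    none.
    """
    genes = sorted(
        set(k4["gene_id"]) | set(k27["gene_id"]) | set(dmg["gene_id"])
    )
    out = pd.DataFrame({"gene_id": genes})
    for name, table in (("k4", k4), ("k27", k27)):
        cls = table.set_index("gene_id")["class"].reindex(genes).fillna("ns")
        out[name] = cls.replace({"ns": "none"}).to_numpy()
    d = dmg.set_index("gene_id").reindex(genes)
    n_hyper = pd.to_numeric(d["n_hyper"], errors="coerce").fillna(0).to_numpy()
    n_hypo = pd.to_numeric(d["n_hypo"], errors="coerce").fillna(0).to_numpy()
    out["dna"] = np.select(
        [(n_hyper > 0) & (n_hypo > 0), n_hyper > 0, n_hypo > 0],
        ["both", "hyper", "hypo"],
        default="none",
    )
    return out


def assign_mark_groups(marks: pd.DataFrame) -> dict[str, set]:
    """Split marked genes into active and inactive modification groups.

    Active marks promote transcription (K4 hyper, DNA hypo, K27 hypo);
    inactive marks silence (K4 hypo, DNA hyper, K27 hyper).  A gene whose
    DNA column is ``both`` belongs to both groups.
    """
    groups: dict[str, set] = {"active": set(), "inactive": set()}
    for col, direction in ACTIVE_RULES:
        vals = marks[col]
        sel = (vals == direction) | ((col == "dna") & (vals == "both"))
        groups["active"].update(marks.loc[sel, "gene_id"])
    for col, direction in INACTIVE_RULES:
        vals = marks[col]
        sel = (vals == direction) | ((col == "dna") & (vals == "both"))
        groups["inactive"].update(marks.loc[sel, "gene_id"])
    return groups


def venn_counts(sets: dict[str, set]) -> dict[tuple, int]:
    """Exclusive region counts for 2 or 3 named sets.

    Keys are sorted name tuples; the region for ``("A", "B")`` counts
    elements in A and B but not in any other set.  Region counts sum to
    the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise InputError("venn_counts supports exactly 2 or 3 sets")
    names = sorted(sets)
    counts = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            counts[tuple(combo)] = len(inside - outside)
    return counts


def crosstab_marks_by_deg(
    marks: pd.DataFrame, deg_classes: pd.Series, deg_values: tuple = ("up", "down")
) -> pd.DataFrame:
    """Counts of genes per (mark class x DEG class) cell.

    Rows are K4 hyper/hypo, K27 hyper/hypo, DNA hyper/hypo; a gene with
    DNA ``both`` contributes to both DNA rows.  ``deg_classes`` maps
    gene_id -> up/down/nc/filtered; only ``deg_values`` columns are
    reported.
    """
    rows = []
    specs = [("K4", "k4"), ("K27", "k27"), ("DNA", "dna")]
    for label, col in specs:
        for direction in ("hyper", "hypo"):
            sel = (marks[col] == direction) | ((col == "dna") & (marks[col] == "both"))
            genes = marks.loc[sel, "gene_id"]
            cls = deg_classes.reindex(genes)
            rows.append(
                {"mark_class": f"{label} {direction}",
                 **{v: int((cls == v).sum()) for v in deg_values}}
            )
    return pd.DataFrame(rows).set_index("mark_class")


def fisher_term_enrichment(
    gene_set: set, universe: set, term_map: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term.

    ``term_map`` has columns gene_id, term_id.  For a term covering K of
    the N universe genes with k hits in the n-gene query set,
    ``p = P(X >= k)`` for X ~ Hypergeom(N, K, n).  No multiple-testing
    correction: enriched terms are those with raw p below ``alpha``.
    """
    if not universe:
        raise InputError("the gene universe must not be empty")
    if not set(gene_set) <= set(universe):
        raise InputError("gene_set must be a subset of the universe")
    tm = term_map[term_map["gene_id"].isin(universe)]
    n_universe = len(universe)
    n_set = len(gene_set)
    rows = []
    for term, sub in tm.groupby("term_id", sort=True):
        members = set(sub["gene_id"])
        k_term = len(members)
        k_hit = len(members & gene_set)
        p = float(stats.hypergeom.sf(k_hit - 1, n_universe, k_term, n_set))
        rows.append(
            {
                "term_id": term,
                "n_term": k_term,
                "n_overlap": k_hit,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=["term_id", "n_term", "n_overlap", "p_value"])
    out["enriched"] = out["p_value"] < alpha
    return out


# ---------------------------------------------------------------------------
# integrated per-gene report

_MARK_LABELS = {"k4": "H3K4me3", "k27": "H3K27me3", "dna": "DNAmeth"}


def build_table1(
    k4: pd.DataFrame,
    k27: pd.DataFrame,
    dmg: pd.DataFrame,
    expression: pd.DataFrame,
    annotations: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Integrated per-gene report joining marks, DMP counts and expression.

    One row per marked gene: the epigenetic mark(s), the signed fold
    enrichment (histone marks) or signed DMP summary (DNA methylation),
    the four RPKM values and both fold-change classes.  Genes without
    expression records keep the row with ``NA`` markers.
    """
    marks = build_mark_assignments(k4, k27, dmg)
    marks = marks[(marks[["k4", "k27", "dna"]] != "none").any(axis=1)]
    folds = {
        "k4": k4.set_index("gene_id")["signed_fold"] if "signed_fold" in k4 else None,
        "k27": k27.set_index("gene_id")["signed_fold"] if "signed_fold" in k27 else None,
    }
    summaries = dmg.set_index("gene_id")["summary"] if "summary" in dmg else None
    expr = expression.set_index("gene_id") if len(expression) else pd.DataFrame()
    rows = []
    for rec in marks.itertuples(index=False):
        mark_bits, value_bits = [], []
        for col in ("k4", "k27", "dna"):
            val = getattr(rec, col)
            if val == "none":
                continue
            label = "hyper / hypo" if val == "both" else val
            mark_bits.append(f"{_MARK_LABELS[col]} {label}")
            if col == "dna":
                value_bits.append(str(summaries.get(rec.gene_id, "NA")) if summaries is not None else "NA")
            else:
                f = folds[col]
                value_bits.append(f"{f.get(rec.gene_id):.1f}" if f is not None and rec.gene_id in f.index else "NA")
        row = {
            "gene_id": rec.gene_id,
            "annotation": (annotations or {}).get(rec.gene_id, "NA"),
            "epigenetic_mark": "; ".join(mark_bits),
            "fold_enrichment_or_dmps": "; ".join(value_bits),
        }
        if rec.gene_id in expr.index:
            e = expr.loc[rec.gene_id]
            row.update(
                rpkm_co_d0=e["rpkm_co_d0"], rpkm_co_d3=e["rpkm_co_d3"],
                rpkm_gr_d0=e["rpkm_gr_d0"], rpkm_gr_d3=e["rpkm_gr_d3"],
                fc_d0=e["class_d0"], fc_d3=e["class_d3"],
            )
        else:
            row.update(rpkm_co_d0="NA", rpkm_co_d3="NA", rpkm_gr_d0="NA",
                       rpkm_gr_d3="NA", fc_d0="NA", fc_d3="NA")
        rows.append(row)
    cols = ["gene_id", "annotation", "epigenetic_mark", "fold_enrichment_or_dmps",
            "rpkm_co_d0", "rpkm_co_d3", "rpkm_gr_d0", "rpkm_gr_d3", "fc_d0", "fc_d3"]
    return pd.DataFrame(rows, columns=cols)
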