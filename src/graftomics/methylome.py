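"""Conversion-as-variant differential methylation calling.

Under conversion chemistry (bisulfite or enzymatic), an unmethylated
cytosine is sequenced as thymine on its own strand; a cytosine sitting on
the minus strand therefore appears in the plus frame as a reference G read
as A when unmethylated and as G when methylated.  Comparing the consensus
allele between two conditions at every cytosine site turns methylation
differences into apparent C->T / G->A variants:

* control reads C (or G on a minus-strand cytosine) and grafted reads
  T (or A)  ->  the site lost methylation in grafted: a **hypo** DMP;
* the reverse pattern  ->  a **hyper** DMP.

Sites are annotated with their plant methylation context — CG, CHG or CHH,
where H is any base other than G, read 5'->3' on the cytosine's own
strand — and aggregated to differentially methylated genes (DMGs) by
counting DMPs of each direction inside every gene interval.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import CoordinateError, InputError, SiteTypeError

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASE_COLS = ["nA", "nC", "nG", "nT"]
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# per-site primitives

def consensus_allele(base_counts, min_depth: int = 5, min_fraction: float = 0.9) -> str:
    """Pooled consensus base, or ``"ambiguous"``.

    ``base_counts`` maps base -> count (replicates already pooled, or a
    sequence of such mappings to pool here).  The consensus is the modal
    base when its pooled fraction reaches ``min_fraction`` and pooled depth
    reaches ``min_depth``.
    """
    if isinstance(base_counts, dict):
        base_counts = [base_counts]
    pooled = {b: 0 for b in "ACGT"}
    for rep in base_counts:
        for b, c in rep.items():
            if c < 0:
                raise InputError("base counts must be non-negative")
            pooled[b] += c
    depth = sum(pooled.values())
    if depth < min_depth or depth == 0:
        return "ambiguous"
    best = max(pooled, key=pooled.get)
    if pooled[best] / depth < min_fraction:
        return "ambiguous"
    return best


def methylation_state(ref_base: str, cytosine_strand: str, allele: str) -> str:
    """Decode an observed consensus allele into a methylation state.

    Plus-strand cytosine: C -> methylated, T -> unmethylated.  Minus-strand
    cytosine (reference G in the plus frame): G -> methylated,
    A -> unmethylated.  Any other allele is uninformative.
    """
    if cytosine_strand == "+":
        if ref_base != "C":
            raise SiteTypeError("a plus-strand cytosine site must have reference base C")
        return {"C": "methylated", "T": "unmethylated"}.get(allele, "uninformative")
    if cytosine_strand == "-":
        if ref_base != "G":
            raise SiteTypeError("a minus-strand cytosine site must have reference base G")
        return {"G": "methylated", "A": "unmethylated"}.get(allele, "uninformative")
    raise SiteTypeError(f"invalid cytosine strand {cytosine_strand!r}")


def call_dmp(control_state: str, grafted_state: str) -> str:
    """Direction of a differential methylation position, or ``"none"``.

    Methylated in control and unmethylated in grafted is a loss of
    methylation by grafting (hypo); the reverse is a gain (hyper).
    Uninformative inputs yield ``"none"`` (skipped, not an error).
    """
    if control_state == "methylated" and grafted_state == "unmethylated":
        return "hypo"
    if control_state == "unmethylated" and grafted_state == "methylated":
        return "hyper"
    return "none"


def classify_context(sequence: str, pos: int, cytosine_strand: str) -> str:
    """CG / CHG / CHH context of the cytosine at ``pos`` (0-based).

    The two bases 3' of the cytosine are read on the cytosine's own strand
    (reverse complement for minus-strand cytosines).  A truncated
    neighbourhood yields ``"NA"``.
    """
    n = len(sequence)
    if not 0 <= pos < n:
        raise CoordinateError(f"position {pos} outside sequence of length {n}")
    if cytosine_strand == "+":
        if pos + 2 >= n:
            return "NA" if pos + 1 >= n else ("CG" if sequence[pos + 1] == "G" else "NA")
        nxt1, nxt2 = sequence[pos + 1], sequence[pos + 2]
    elif cytosine_strand == "-":
        if pos - 2 < 0:
            if pos - 1 < 0:
                return "NA"
            return "CG" if _COMPLEMENT[sequence[pos - 1]] == "G" else "NA"
        nxt1 = _COMPLEMENT[sequence[pos - 1]]
        nxt2 = _COMPLEMENT[sequence[pos - 2]]
    else:
        raise SiteTypeError(f"invalid cytosine strand {cytosine_strand!r}")
    if nxt1 == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


# ---------------------------------------------------------------------------
# vectorised table operations

def _pool_and_decode(sites: pd.DataFrame, min_depth: int, min_fraction: float) -> pd.DataFrame:
    """Pool replicate counts per site per condition and decode states."""
    required = {"chrom", "pos", "ref_base", "strand", "cond", *_BASE_COLS}
    if not required.issubset(sites.columns):
        raise InputError(f"site table must have columns {sorted(required)}")
    pooled = sites.groupby(["chrom", "pos", "ref_base", "strand", "cond"], as_index=False)[
        _BASE_COLS
    ].sum()
    counts = pooled[_BASE_COLS].to_numpy()
    depth = counts.sum(axis=1)
    top = counts.max(axis=1)
    allele = _BASES[counts.argmax(axis=1)]
    ok = (depth >= min_depth) & (top >= min_fraction * depth) & (depth > 0)
    allele = np.where(ok, allele, "ambiguous")
    plus = pooled["strand"].to_numpy() == "+"
    meth = (plus & (allele == "C")) | (~plus & (allele == "G"))
    unmeth = (plus & (allele == "T")) | (~plus & (allele == "A"))
    pooled["depth"] = depth
    pooled["allele"] = allele
    pooled["state"] = np.select([meth, unmeth], ["methylated", "unmethylated"],
                                default="uninformative")
    return pooled


def _context_vector(sequences: dict[str, str], chroms, pos0, strands) -> np.ndarray:
    out = np.empty(len(pos0), dtype=object)
    for chrom in pd.unique(chroms):
        seq = sequences.get(chrom)
        if seq is None:
            raise CoordinateError(f"site on unknown sequence {chrom!r}")
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        mask = chroms == chrom
        p = pos0[mask]
        s = strands[mask]
        n = len(seq)
        res = np.full(p.shape, "NA", dtype=object)
        step = np.where(s == "+", 1, -1)
        p1 = p + step
        p2 = p + 2 * step
        in1 = (p1 >= 0) & (p1 < n)
        in2 = (p2 >= 0) & (p2 < n)
        b1 = np.full(p.shape, "N", dtype="U1")
        b2 = np.full(p.shape, "N", dtype="U1")
        b1[in1] = arr[p1[in1]]
        b2[in2] = arr[p2[in2]]
        # minus-strand cytosines read the complement of upstream plus bases
        comp = np.vectorize(_COMPLEMENT.get)
        minus = s == "-"
        if minus.any():
            b1[minus] = comp(b1[minus])
            b2[minus] = comp(b2[minus])
        res[in1 & (b1 == "G")] = "CG"
        res[in1 & in2 & (b1 != "G") & (b2 == "G")] = "CHG"
        res[in1 & in2 & (b1 != "G") & (b2 != "G")] = "CHH"
        out[mask] = res
    return out


def call_dmps(
    sites: pd.DataFrame,
    sequences: dict[str, str],
    min_depth: int = 5,
    min_fraction: float = 0.9,
) -> pd.DataFrame:
    """Call DMPs from a paired-condition site table.

    ``sites`` carries per-replicate base counts per cytosine site per
    condition (columns chrom, pos 1-based, ref_base, strand, cond, rep,
    nA, nC, nG, nT).  Replicates are pooled before consensus; sites that
    are ambiguous or uninformative in either condition are skipped.

    Returns one row per DMP: chrom, pos (1-based), strand, context,
    direction.
    """
    pooled = _pool_and_decode(sites, min_depth, min_fraction)
    wide = pooled.pivot(index=["chrom", "pos", "ref_base", "strand"],
                        columns="cond", values="state")
    for cond in ("control", "grafted"):
        if cond not in wide.columns:
            raise InputError(f"site table is missing condition {cond!r}")
    wide = wide.reset_index()
    ctrl = wide["control"].to_numpy()
    graf = wide["grafted"].to_numpy()
    direction = np.select(
        [
            (ctrl == "methylated") & (graf == "unmethylated"),
            (ctrl == "unmethylated") & (graf == "methylated"),
        ],
        ["hypo", "hyper"],
        default="none",
    )
    dmp = wide.loc[direction != "none", ["chrom", "pos", "ref_base", "strand"]].copy()
    dmp["direction"] = direction[direction != "none"]
    pos0 = dmp["pos"].to_numpy() - 1
    dmp["context"] = _context_vector(
        sequences, dmp["chrom"].to_numpy(), pos0, dmp["strand"].to_numpy()
    )
    return dmp[["chrom", "pos", "strand", "context", "direction"]].reset_index(drop=True)


def dmg_summary(n_hyper: int, n_hypo: int) -> str:
    """Human-readable signed DMP summary: ``+11``, ``-2`` or ``1 / -2``."""
    if n_hyper and n_hypo:
        return f"{n_hyper} / -{n_hypo}"
    if n_hyper:
        return f"+{n_hyper}"
    return f"-{n_hypo}"


def aggregate_dmgs(
    dmps: pd.DataFrame,
    genes: pd.DataFrame,
    flank_bp: int = 0,
    threshold_k: int = 1,
    mode: str = "per-direction",
) -> pd.DataFrame:
    """Count DMPs per gene interval and emit differentially methylated genes.

    A gene qualifies when ``n_hyper >= k`` or ``n_hypo >= k``
    (``mode="per-direction"``, the default) or when ``|n_hyper - n_hypo|
    >= k`` (``mode="net"``).  Gene intervals are the annotated bodies
    extended by ``flank_bp`` on both sides; a DMP inside two overlapping
    genes is counted once in each.
    """
    if mode not in ("per-direction", "net"):
        raise InputError(f"unknown DMG mode {mode!r}")
    if threshold_k < 1:
        raise InputError("threshold_k must be >= 1")
    records = []
    by_chrom = {
        (chrom, direction): np.sort(sub["pos"].to_numpy())
        for (chrom, direction), sub in dmps.groupby(["chrom", "direction"])
    }
    for row in genes.itertuples(index=False):
        lo = row.start + 1 - flank_bp  # 1-based inclusive interval
        hi = row.end + flank_bp
        counts = {}
        for direction in ("hyper", "hypo"):
            pos = by_chrom.get((row.chrom, direction))
            if pos is None:
                counts[direction] = 0
            else:
                counts[direction] = int(
                    np.searchsorted(pos, hi, side="right") - np.searchsorted(pos, lo, side="left")
                )
        n_hyper, n_hypo = counts["hyper"], counts["hypo"]
        if mode == "per-direction":
            qualifies = n_hyper >= threshold_k or n_hypo >= threshold_k
        else:
            qualifies = abs(n_hyper - n_hypo) >= threshold_k
        if qualifies:
            records.append(
                {
                    "gene_id": row.gene_id,
                    "n_hyper": n_hyper,
                    "n_hypo": n_hypo,
                    "summary": dmg_summary(n_hyper, n_hypo),
                }
            )
    return pd.DataFrame(records, columns=["gene_id", "n_hyper", "n_hypo", "summary"])
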