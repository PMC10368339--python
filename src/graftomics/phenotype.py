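"""qPCR relative expression, exact small-sample tests and cohort survival.

Relative expression uses the single-delta 2^-dCt form with a housekeeping
reference channel.  Group comparisons in 3-vs-3 designs use an exact
Mann-Whitney U obtained by enumerating every assignment of the pooled
ranks (with midranks for ties) — note that with three replicates per group
the smallest attainable two-sided p is 0.1, so a Welch t-test p-value is
reported alongside.  Survival is summarised per cohort (recovery via the
apical meristem or an axillary bud counts as survival) and compared
between groups with a Pearson chi-square on the 2x2 table, continuity
correction off by default.
"""
from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

MAX_EXACT_TOTAL = 12


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """2^-(Ct_target - Ct_reference)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise InputError("Ct values must be finite")
    return 2.0 ** (-(ct_target - ct_reference))


def mann_whitney_exact(group_a, group_b, alternative: str = "two-sided"):
    """Exact Mann-Whitney U by full enumeration of rank assignments.

    Returns ``(u, p)`` where ``u`` is the U statistic of ``group_a``.  The
    p-value enumerates all C(n, n_a) assignments of the pooled midranks,
    so it is exact with or without ties.  Two-sided p is the probability
    of a U at least as far from its mean as observed.  Restricted to
    total sample sizes <= 12 (the exact-enumeration regime).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    n = a.size + b.size
    if n > MAX_EXACT_TOTAL:
        raise InputError(f"exact enumeration restricted to total n <= {MAX_EXACT_TOTAL}")
    if alternative not in ("two-sided", "less", "greater"):
        raise InputError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    na = a.size
    offset = na * (na + 1) / 2.0
    u_obs = ranks[:na].sum() - offset
    us = np.array(
        [ranks[list(idx)].sum() - offset for idx in combinations(range(n), na)]
    )
    mu = na * b.size / 2.0
    tol = 1e-9
    if alternative == "two-sided":
        p = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - tol))
    elif alternative == "less":
        p = float(np.mean(us <= u_obs + tol))
    else:
        p = float(np.mean(us >= u_obs - tol))
    return float(u_obs), p


def welch_t(group_a, group_b) -> float:
    """Two-sided Welch t-test p-value (companion to the exact U test)."""
    res = stats.ttest_ind(np.asarray(group_a, float), np.asarray(group_b, float),
                          equal_var=False)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


# ---------------------------------------------------------------------------
# survival

def survival_rate(n: int, survivors_apical: int, survivors_axillary: int = 0) -> float:
    """Percent survival of a cohort."""
    if n <= 0:
        raise InputError("cohort size must be positive")
    if survivors_apical < 0 or survivors_axillary < 0:
        raise InputError("survivor counts must be non-negative")
    total = survivors_apical + survivors_axillary
    if total > n:
        raise InputError("survivors exceed cohort size")
    return 100.0 * total / n


def display_percent(rate: float) -> str:
    """Whole-percent display string, rounding half up (56.25 -> '56%')."""
    return f"{int(Decimal(repr(rate)).quantize(Decimal('1'), rounding=ROUND_HALF_UP))}%"


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False):
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]].

    Continuity correction is off by default.  Returns ``(statistic, p)``;
    a zero row or column marginal makes the test undefined.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise InputError("all cells must be non-negative")
    if table.sum() < 1:
        raise InputError("the table must contain at least one observation")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise InputError("undefined test: a row or column marginal is zero")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group survival summary from a plant-level table.

    ``cohort`` has columns group, plant_id, route with route in
    {apical, axillary, none}.
    """
    needed = {"group", "plant_id", "route"}
    if not needed.issubset(cohort.columns):
        raise InputError(f"cohort table must have columns {sorted(needed)}")
    bad = set(cohort["route"]) - {"apical", "axillary", "none"}
    if bad:
        raise InputError(f"unknown recovery routes: {sorted(bad)}")
    rows = []
    for group, sub in cohort.groupby("group", sort=True):
        n = len(sub)
        apical = int((sub["route"] == "apical").sum())
        axillary = int((sub["route"] == "axillary").sum())
        rate = survival_rate(n, apical, axillary)
        rows.append(
            {
                "group": group,
                "n": n,
                "survivors_apical": apical,
                "survivors_axillary": axillary,
                "survival_rate": round(rate, 2),
                "display": display_percent(rate),
            }
        )
    return pd.DataFrame(rows)


def survival_tests(summary: pd.DataFrame, control: str = "control",
                   yates: bool = False) -> pd.DataFrame:
    """Chi-square of each treated group against the control cohort."""
    idx = summary.set_index("group")
    if control not in idx.index:
        raise InputError(f"no control group {control!r} in the summary")
    ctrl = idx.loc[control]
    c_surv = int(ctrl["survivors_apical"] + ctrl["survivors_axillary"])
    c_dead = int(ctrl["n"]) - c_surv
    rows = []
    for group, row in idx.iterrows():
        if group == control:
            continue
        surv = int(row["survivors_apical"] + row["survivors_axillary"])
        dead = int(row["n"]) - surv
        try:
            statistic, p = chi_square_2x2(c_surv, c_dead, surv, dead, yates=yates)
        except InputError:
            statistic, p = float("nan"), float("nan")
        rows.append({"group": group, "chi_square": statistic, "p_value": p})
    return pd.DataFrame(rows, columns=["group", "chi_square", "p_value"])


# ---------------------------------------------------------------------------
# qPCR tables

def qpcr_relative_expression(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Add delta_ct and rel_expr columns to a Ct table."""
    needed = {"gene", "group", "timepoint", "rep", "ct_target", "ct_ref"}
    if not needed.issubset(qpcr.columns):
        raise InputError(f"qPCR table must have columns {sorted(needed)}")
    out = qpcr.copy()
    if not np.isfinite(out[["ct_target", "ct_ref"]].to_numpy()).all():
        raise InputError("Ct values must be finite")
    out["delta_ct"] = out["ct_target"] - out["ct_ref"]
    out["rel_expr"] = 2.0 ** (-out["delta_ct"])
    return out


def qpcr_group_stats(qpcr: pd.DataFrame, control: str = "control") -> pd.DataFrame:
    """Mean relative expression per gene/group/timepoint plus exact
    Mann-Whitney and Welch t p-values against the control group.

    Both p-values are reported side by side because with three replicates
    per group the exact test cannot fall below p = 0.1.
    """
    rel = qpcr_relative_expression(qpcr)
    rows = []
    for (gene, tp), sub in rel.groupby(["gene", "timepoint"], sort=True):
        ctrl_vals = sub.loc[sub["group"] == control, "rel_expr"].to_numpy()
        if ctrl_vals.size == 0:
            raise InputError(f"no control replicates for gene {gene!r} at {tp}")
        for group, gsub in sub.groupby("group", sort=True):
            vals = gsub["rel_expr"].to_numpy()
            row = {
                "gene": gene,
                "timepoint": tp,
                "group": group,
                "mean_rel_expr": float(vals.mean()),
                "n": int(vals.size),
            }
            if group != control:
                u, p_exact = mann_whitney_exact(vals, ctrl_vals)
                row["mw_exact_p"] = p_exact
                row["welch_t_p"] = welch_t(vals, ctrl_vals)
            else:
                row["mw_exact_p"] = float("nan")
                row["welch_t_p"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
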