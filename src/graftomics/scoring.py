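"""Scoring of pipeline calls against planted synthetic truth.

Every synthetic dataset ships with truth tables; these helpers compute
precision, recall, F1 and confusion tables per stage so that the caller
chain (chip classes, DMPs, DMGs, DEG classes) can be validated end to
end.  Undefined ratios (e.g. precision with no positive calls) are
reported as NaN, never silently as 0 or 1.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ScoringError


def precision_recall(called: set, truth: set) -> dict:
    """Set-based precision/recall/F1; NaN where the denominator is empty."""
    tp = len(called & truth)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    if called and truth and tp:
        f1 = 2 * precision * recall / (precision + recall)
    elif called and truth:
        f1 = 0.0
    else:
        f1 = float("nan")
    return {"tp": tp, "n_called": len(called), "n_truth": len(truth),
            "precision": precision, "recall": recall, "f1": f1}


def confusion_table(y_true: pd.Series, y_pred: pd.Series, labels=None) -> pd.DataFrame:
    """Truth x prediction counts over a shared key index."""
    orphans = y_pred.index.difference(y_true.index)
    if len(orphans):
        raise ScoringError(f"calls with no matching truth keys: {list(orphans[:5])}")
    aligned = y_pred.reindex(y_true.index)
    if labels is None:
        labels = sorted(set(y_true) | set(aligned.dropna()))
    table = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(y_true, aligned):
        if pd.isna(p):
            continue
        table.loc[t, p] += 1
    table.index.name = "truth"
    table.columns.name = "called"
    return table


def score_labels(truth: pd.DataFrame, calls: pd.DataFrame, key: str,
                 truth_col: str, call_col: str, positive_labels) -> dict:
    """Per-label precision/recall plus a confusion table for label calls."""
    t = truth.set_index(key)[truth_col]
    c = calls.set_index(key)[call_col]
    orphan = c.index.difference(t.index)
    if len(orphan):
        raise ScoringError(f"calls for unknown {key}s: {list(orphan[:5])}")
    out = {"confusion": confusion_table(t, c)}
    for label in positive_labels:
        called = set(c.index[c == label])
        truthset = set(t.index[t == label])
        out[label] = precision_recall(called, truthset)
    return out


def score_chip(truth_chip: pd.DataFrame, enrichment: pd.DataFrame, mark: str) -> dict:
    """Score hyper/hypo calls of one mark against planted chip truth."""
    truth = truth_chip[truth_chip["mark"] == mark]
    calls = enrichment.copy()
    calls["class"] = calls["class"].replace({"ns": "none"})
    return score_labels(truth, calls, "gene_id", "label", "class", ("hyper", "hypo"))


def score_dmps(truth_methylation: pd.DataFrame, dmps: pd.DataFrame) -> dict:
    """Score DMP calls keyed by (chrom, pos, strand, direction).

    ``truth_methylation`` uses 1-based positions (as written to disk) with
    a ``dmp_direction`` column; planted flips are the positives.
    """
    def keys(df, direction_col):
        sub = df[df[direction_col] != "none"]
        return set(zip(sub["chrom"], sub["pos"], sub["strand"], sub[direction_col]))

    site_universe = set(zip(truth_methylation["chrom"], truth_methylation["pos"],
                            truth_methylation["strand"]))
    called_sites = set(zip(dmps["chrom"], dmps["pos"], dmps["strand"]))
    orphan = called_sites - site_universe
    if orphan:
        raise ScoringError(f"DMP calls at unknown sites: {sorted(orphan)[:5]}")
    out = {"overall": precision_recall(keys(dmps, "direction"),
                                       keys(truth_methylation, "dmp_direction"))}
    for direction in ("hyper", "hypo"):
        called = {k for k in keys(dmps, "direction") if k[3] == direction}
        truthset = {k for k in keys(truth_methylation, "dmp_direction") if k[3] == direction}
        out[direction] = precision_recall(called, truthset)
    return out


def score_deg(truth_expression: pd.DataFrame, expression: pd.DataFrame,
              class_col: str = "class_d0") -> dict:
    """Score D0 DEG classes against planted expression truth.

    ``filtered`` calls are mapped to ``nc`` before comparison: the
    expression floor is an analysis choice, not a planted state.
    """
    calls = expression[["gene_id", class_col]].copy()
    calls[class_col] = calls[class_col].replace({"filtered": "nc"})
    return score_labels(truth_expression, calls, "gene_id", "label", class_col,
                        ("up", "down"))


def scores_to_frame(scores: dict) -> pd.DataFrame:
    """Flatten nested stage -> label -> metrics dicts into a tidy table."""
    rows = []
    for stage, by_label in scores.items():
        for label, metrics in by_label.items():
            if label == "confusion":
                continue
            rows.append({"stage": stage, "label": label, **metrics})
    return pd.DataFrame(rows)
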