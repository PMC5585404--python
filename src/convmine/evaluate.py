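"""Recovery metrics of a pipeline run against a study's planted truth.

Used for validating the method on synthetic studies: precision/recall/F1 of
the common signature, of each conversion-specific signature and of DE-TF
recovery, plus the top-k hit rate of the planted master regulators in the
out-degree rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from convmine.pipeline import StudyResult
from convmine.simulate import GroundTruth


def precision_recall_f1(predicted: set, truth: set) -> tuple[float, float, float]:
    """Standard set-overlap metrics; vacuous cases score 1.0 when both sets
    are empty and 0.0 when only one is."""
    if not predicted and not truth:
        return 1.0, 1.0, 1.0
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth) if truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    return precision, recall, f1


@dataclass
class RecoveryMetrics:
    table: pd.DataFrame           # one row per evaluated quantity
    master_tf_top_k_hits: float   # fraction of planted DE-TFs in their ranking's top k

    def f1(self, what: str) -> float:
        row = self.table[self.table["quantity"] == what]
        if row.empty:
            raise KeyError(f"no metric {what!r}")
        return float(row["f1"].iloc[0])


def evaluate_against_truth(
    result: StudyResult, truth: GroundTruth, top_k: int = 5
) -> RecoveryMetrics:
    """Score every recovered quantity of a synthetic study against its truth."""
    measured = set(result.table.genes)
    if not truth.universe >= measured:
        raise ValueError("study gene universe does not match the truth's")
    rows = []

    true_common = {(g, "up") for g in truth.common_up} | {(g, "down") for g in truth.common_down}
    p, r, f1 = precision_recall_f1(set(result.common_full), true_common)
    rows.append(("common_signature", p, r, f1))
    p, r, f1 = precision_recall_f1(set(result.common_strict), true_common)
    rows.append(("common_signature_strict", p, r, f1))

    for conv, (up, down) in sorted(truth.specific.items()):
        true_spec = {(g, "up") for g in up} | {(g, "down") for g in down}
        pred = {(c.gene, c.direction) for c in result.specific.get(conv, [])}
        p, r, f1 = precision_recall_f1(pred, true_spec)
        rows.append((f"specific:{conv}", p, r, f1))

    for conv, merged in sorted(result.merged.items()):
        planted = truth.planted_de(conv)
        pred = {(g, d) for g, d in merged.degs.items()}
        p, r, f1 = precision_recall_f1(pred, set(planted.items()))
        rows.append((f"degs:{conv}", p, r, f1))

    hits = total = 0
    for conv, cg in sorted(result.grns.items()):
        true_tfs = set(truth.de_tfs.get(conv, frozenset()))
        p, r, f1 = precision_recall_f1(set(cg.de_tfs), true_tfs)
        rows.append((f"de_tfs:{conv}", p, r, f1))
        top = set(cg.ranking.top(top_k))
        for tf in true_tfs:
            total += 1
            hits += tf in top

    table = pd.DataFrame(rows, columns=["quantity", "precision", "recall", "f1"])
    hit_rate = hits / total if total else 1.0
    return RecoveryMetrics(table=table, master_tf_top_k_hits=hit_rate)


def grn_edge_f1(result: StudyResult, truth: GroundTruth, db) -> dict[str, float]:
    """Per-conversion F1 of recovered GRN edges against the planted wiring."""
    out = {}
    for conv, cg in sorted(result.grns.items()):
        _, _, f1 = precision_recall_f1(cg.grn.edges, truth.grn_edges(conv, db))
        out[conv] = f1
    return out
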