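"""Cross-dataset consensus on direction calls.

Robustness in multi-dataset conversion studies comes from vote counting:
a gene is accepted when it shows the same direction of differential
expression in at least ``min_same`` of the datasets in scope — e.g. 8 of the
9 fibroblast-panel datasets for the common signature, 2 of 3 (with no
opposite call allowed in the third) within the endothelial and cardiomyocyte
conversions, and 3 of 4 for pre-B→macrophage. An optional per-dataset fold
change gate (1.5 by default for the strict tier) further restricts the
supporting datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from convmine.diffexpr import DEResult, UP, DOWN, NONE

log = logging.getLogger(__name__)

_OPPOSITE = {UP: DOWN, DOWN: UP}


@dataclass
class DirectionTable:
    """Genes × datasets matrix of direction calls, the substrate of voting.

    ``calls``: DataFrame of {'up','down','none'}, index genes, columns
    dataset ids. ``conversions``: dataset id → conversion name. ``fc``:
    optional parallel DataFrame of linear fold changes.
    """

    calls: pd.DataFrame
    conversions: dict[str, str]
    fc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.to_numpy())) - {UP, DOWN, NONE}
        if bad:
            raise ValueError(f"invalid direction values {bad}")
        missing = [d for d in self.calls.columns if d not in self.conversions]
        if missing:
            raise ValueError(f"datasets without a conversion label: {missing}")
        if self.fc is not None and (
            list(self.fc.index) != list(self.calls.index)
            or list(self.fc.columns) != list(self.calls.columns)
        ):
            raise ValueError("fc matrix must be aligned with calls")

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.calls.columns)

    def datasets_of(self, conversion: str) -> list[str]:
        ids = [d for d in self.calls.columns if self.conversions[d] == conversion]
        if not ids:
            raise KeyError(f"unknown conversion {conversion!r}")
        return ids

    @classmethod
    def from_results(
        cls, results: Sequence[DEResult], conversions: dict[str, str]
    ) -> "DirectionTable":
        """Assemble the table from per-dataset DE results on the shared
        gene set (intersection, original order of the first dataset)."""
        genes = results[0].table.index
        for r in results[1:]:
            genes = genes.intersection(r.table.index, sort=False)
        calls = pd.DataFrame(
            {r.dataset_id: r.directions.loc[genes] for r in results}, index=genes
        )
        fc = pd.DataFrame(
            {r.dataset_id: r.fc_linear.loc[genes] for r in results}, index=genes
        )
        return cls(calls=calls, conversions=dict(conversions), fc=fc)


@dataclass(frozen=True)
class VoteRule:
    """``min_same`` datasets must agree on a direction; ``forbid_opposite``
    additionally rejects genes with any opposite call; ``fc_min``, when set,
    requires every *supporting* dataset to reach that linear fold-change
    magnitude."""

    min_same: int
    forbid_opposite: bool = False
    fc_min: float | None = None

    def __post_init__(self) -> None:
        if self.min_same < 1:
            raise ValueError("min_same must be >= 1")
        if self.fc_min is not None and self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")


def _fc_magnitude(fc: float) -> float:
    return max(fc, 1.0 / fc)


def vote(
    calls_for_gene: Sequence[str],
    rule: VoteRule,
    fcs: Sequence[float] | None = None,
) -> str:
    """Consensus direction for one gene across the datasets in scope.

    Returns ``d`` in {up, down} iff at least ``rule.min_same`` datasets call
    ``d``, no dataset calls the opposite when ``rule.forbid_opposite``, and
    every supporting dataset passes ``rule.fc_min`` when set. If both
    directions qualify (possible only when min_same <= n/2) the gene is
    returned as none and logged — ties are not contemplated by the voting
    scheme.
    """
    if len(calls_for_gene) == 0:
        raise ValueError("empty call list")
    if rule.min_same > len(calls_for_gene):
        return NONE
    winners = []
    for d in (UP, DOWN):
        idx = [i for i, c in enumerate(calls_for_gene) if c == d]
        if len(idx) < rule.min_same:
            continue
        if rule.forbid_opposite and any(c == _OPPOSITE[d] for c in calls_for_gene):
            continue
        if rule.fc_min is not None:
            if fcs is None:
                raise ValueError("rule has fc_min but no fold changes supplied")
            if any(_fc_magnitude(fcs[i]) < rule.fc_min for i in idx):
                continue
        winners.append(d)
    if len(winners) == 2:
        log.warning("both directions qualify under min_same=%d; returning none", rule.min_same)
        return NONE
    return winners[0] if winners else NONE


def _vote_frame(
    calls: pd.DataFrame, fc: pd.DataFrame | None, rule: VoteRule
) -> pd.Series:
    """Vectorized `vote` over all genes of a calls matrix."""
    arr = calls.to_numpy()
    n_up = (arr == UP).sum(axis=1)
    n_down = (arr == DOWN).sum(axis=1)
    up_ok = n_up >= rule.min_same
    down_ok = n_down >= rule.min_same
    if rule.forbid_opposite:
        up_ok &= n_down == 0
        down_ok &= n_up == 0
    if rule.fc_min is not None:
        if fc is None:
            raise ValueError("rule has fc_min but table has no fold changes")
        mag = np.maximum(fc.to_numpy(), 1.0 / fc.to_numpy())
        weak = mag < rule.fc_min
        up_ok &= ~((arr == UP) & weak).any(axis=1)
        down_ok &= ~((arr == DOWN) & weak).any(axis=1)
    tie = up_ok & down_ok
    if tie.any():
        log.warning("%d genes qualify in both directions; returned as none", int(tie.sum()))
    out = np.where(up_ok & ~tie, UP, np.where(down_ok & ~tie, DOWN, NONE))
    return pd.Series(out, index=calls.index, dtype=object)


@dataclass
class ConversionDegs:
    """Conversion-level DEG calls: consensus direction per gene plus a
    representative linear fold change (geometric mean over the datasets
    supporting the consensus; the single dataset's value for one-dataset
    conversions)."""

    conversion: str
    direction: pd.Series
    fc: pd.Series

    @property
    def degs(self) -> pd.Series:
        """Only the called genes (direction != none), sorted by symbol."""
        d = self.direction[self.direction != NONE]
        return d.sort_index()

    def gene_set(self) -> frozenset[str]:
        return frozenset(self.degs.index)


def merge_conversion(table: DirectionTable, conversion: str, rule: VoteRule) -> ConversionDegs:
    """Merge a conversion's datasets into one DEG list.

    Single-dataset conversions pass their calls through unchanged;
    multi-dataset conversions apply :func:`vote` per gene.
    """
    ids = table.datasets_of(conversion)
    calls = table.calls[ids]
    fc = table.fc[ids] if table.fc is not None else None
    if len(ids) == 1:
        direction = calls[ids[0]].copy()
        rep_fc = fc[ids[0]].copy() if fc is not None else pd.Series(np.nan, index=calls.index)
    else:
        direction = _vote_frame(calls, fc, rule)
        if fc is not None:
            support = (calls.to_numpy() == direction.to_numpy()[:, None]) & (
                direction.to_numpy()[:, None] != NONE
            )
            logfc = np.log(fc.to_numpy())
            with np.errstate(invalid="ignore"):
                mean_log = np.where(
                    support.any(axis=1),
                    (logfc * support).sum(axis=1) / np.maximum(support.sum(axis=1), 1),
                    np.nan,
                )
            rep_fc = pd.Series(np.exp(mean_log), index=calls.index)
        else:
            rep_fc = pd.Series(np.nan, index=calls.index)
    n = int((direction != NONE).sum())
    log.info("conversion %s: %d datasets -> %d DEGs", conversion, len(ids), n)
    return ConversionDegs(conversion=conversion, direction=direction, fc=rep_fc)


def common_signature(
    table: DirectionTable,
    rule: VoteRule,
    strict_fc_min: float | None = 1.5,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Genes sharing one direction across (almost) all datasets of the study.

    Returns two sorted (gene, direction) lists: the full signature under
    ``rule`` with no fold-change gate, and the strict sublist whose
    supporting datasets additionally all reach ``strict_fc_min``.
    """
    if len(table.dataset_ids) < 2:
        raise ValueError("common signature needs at least two datasets")
    base = _vote_frame(table.calls, table.fc, VoteRule(rule.min_same, rule.forbid_opposite, None))
    full = sorted((g, d) for g, d in base.items() if d != NONE)
    if strict_fc_min is None:
        return full, list(full)
    strict_rule = VoteRule(rule.min_same, rule.forbid_opposite, strict_fc_min)
    strict_calls = _vote_frame(table.calls, table.fc, strict_rule)
    strict = sorted((g, d) for g, d in strict_calls.items() if d != NONE and base[g] == d)
    return full, strict


def cross_species_concordance(
    tf: str,
    calls_a: ConversionDegs,
    calls_b: ConversionDegs,
    db,
) -> float:
    """Direction agreement of a TF's targets between two studies (e.g. the
    human and mouse fibroblast→cardiomyocyte panels).

    Over the TF's targets called DE (non-none) in both DEG lists, the
    fraction with identical direction. NaN when no target is called in both
    (flagged by the caller).
    """
    if tf not in db.regulons:
        raise KeyError(f"unknown TF {tf!r}")
    shared = []
    for g in db.regulons[tf]:
        da = calls_a.direction.get(g, NONE)
        db_ = calls_b.direction.get(g, NONE)
        if da != NONE and db_ != NONE:
            shared.append(da == db_)
    if not shared:
        log.warning("TF %s: no target called DE in both studies", tf)
        return float("nan")
    return float(np.mean(shared))
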