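"""Cell-specific signature discovery.

A gene is specific to one conversion when it is differentially expressed
there and shows the *opposite* pattern in (almost) all datasets of the other
conversions. To limit false negatives, a fine-tuning rule tolerates the
identical pattern in at most ``max_identical`` (default two) other datasets.
Datasets where the gene is not called at all count toward neither bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from convmine.consensus import ConversionDegs, DirectionTable, _OPPOSITE


@dataclass(frozen=True)
class SpecificityRule:
    """``min_opposite`` other datasets must show the opposite direction;
    at most ``max_identical`` may show the identical one; ``fc_min`` is the
    fold-change magnitude required of the target conversion's supporting
    datasets. ``min_opposite=None`` resolves to n_other − max_identical at
    evaluation time (e.g. 7 of 9 other datasets with 2 exceptions allowed)."""

    min_opposite: int | None = None
    max_identical: int = 2
    fc_min: float | None = 1.5

    def resolve(self, n_other: int) -> int:
        mo = self.min_opposite if self.min_opposite is not None else n_other - self.max_identical
        # the identical-pattern allowance is a tolerance, not a reservation:
        # requiring 7 opposite of 8 others while tolerating up to 2 identical
        # is satisfiable (7 opposite + 1 identical)
        if mo < 0 or mo > n_other:
            raise ValueError(
                f"rule infeasible for {n_other} other datasets (min_opposite={mo})"
            )
        return mo


@dataclass
class SpecificCall:
    gene: str
    direction: str
    opposite_count: int
    identical_count: int


def specific_signature(
    target_degs: ConversionDegs,
    table: DirectionTable,
    rule: SpecificityRule = SpecificityRule(),
) -> list[SpecificCall]:
    """Genes whose differential expression is exclusive to one conversion.

    A gene qualifies iff (a) it is called up/down in ``target_degs``;
    (b) among the datasets of *other* conversions, at least ``min_opposite``
    show the opposite direction; (c) at most ``max_identical`` show the
    identical direction; and (d) when ``rule.fc_min`` is set, every dataset
    of the target conversion supporting the call reaches that fold-change
    magnitude. Output sorted by gene symbol.
    """
    target_ids = set(table.datasets_of(target_degs.conversion))
    other_ids = [d for d in table.dataset_ids if d not in target_ids]
    min_opposite = rule.resolve(len(other_ids))

    others = table.calls[other_ids]
    out: list[SpecificCall] = []
    for gene, d in target_degs.degs.items():
        if gene not in others.index:
            continue
        row = others.loc[gene]
        n_opp = int((row == _OPPOSITE[d]).sum())
        n_same = int((row == d).sum())
        if n_opp < min_opposite or n_same > rule.max_identical:
            continue
        if rule.fc_min is not None and table.fc is not None:
            tcalls = table.calls.loc[gene, list(target_ids)]
            tfc = table.fc.loc[gene, list(target_ids)]
            support = tcalls[tcalls == d].index
            mag = pd.concat([tfc[support], 1.0 / tfc[support]], axis=1).max(axis=1)
            if len(support) and (mag < rule.fc_min).any():
                continue
        out.append(SpecificCall(gene, d, n_opp, n_same))
    out.sort(key=lambda c: c.gene)
    return out


def partition_counts(calls: list[SpecificCall]) -> dict[str, int]:
    """Up/down tally of a specific signature, for stage logging."""
    return {
        "up": sum(1 for c in calls if c.direction == "up"),
        "down": sum(1 for c in calls if c.direction == "down"),
    }
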