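"""Conversion-specific signatures with the exception-tolerance rule.

A gene is specific to a conversion when it is a consensus DEG there and
shows the opposite direction in almost all datasets of the other
conversions, tolerating the identical pattern in at most two of them.
Writes one TSV per conversion to results/specific/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, load_study

from convmine.consensus import VoteRule, merge_conversion
from convmine.specificity import SpecificityRule, partition_counts, specific_signature

OUT = RESULTS / "specific"
OUT.mkdir(parents=True, exist_ok=True)

table, _, _ = load_study()
rule = SpecificityRule()  # min_opposite = n_other - 2, max_identical = 2, fc >= 1.5

for conv in dict.fromkeys(table.conversions.values()):
    n_ds = len(table.datasets_of(conv))
    merged = merge_conversion(table, conv, VoteRule(max(1, n_ds - 1), forbid_opposite=True))
    calls = specific_signature(merged, table, rule)
    pd.DataFrame(
        [(c.gene, c.direction, c.opposite_count, c.identical_count) for c in calls],
        columns=["gene", "direction", "opposite_count", "identical_count"],
    ).to_csv(OUT / f"{conv}.tsv", sep="\t", index=False)
    counts = partition_counts(calls)
    print(f"{conv}: {len(calls)} specific genes ({counts['up']} up, {counts['down']} down)")
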