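"""Cross-dataset consensus: the common signature and per-conversion DEGs.

The common signature is the set of genes with the same direction of
differential expression in at least 8 of the 9 datasets (no opposite call
allowed), with a strict tier whose supporting datasets all show linear fold
change >= 1.5. Per-conversion DEG lists merge each conversion's datasets by
an all-but-one vote that forbids opposite calls (the 2-of-3 / 3-of-4
pattern). Writes results/consensus/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, load_study

from convmine.consensus import VoteRule, common_signature, merge_conversion

OUT = RESULTS / "consensus"
OUT.mkdir(parents=True, exist_ok=True)

table, _, _ = load_study()
n = len(table.dataset_ids)

full, strict = common_signature(table, VoteRule(min_same=n - 1, forbid_opposite=True),
                                strict_fc_min=1.5)
strict_set = {g for g, _ in strict}
df = pd.DataFrame(full, columns=["gene", "direction"])
df["strict"] = df["gene"].isin(strict_set)
df.to_csv(OUT / "common_signature.tsv", sep="\t", index=False)
n_up = (df["direction"] == "up").sum()
n_down = (df["direction"] == "down").sum()
print(f"common signature: {len(full)} genes ({n_up} up, {n_down} down), "
      f"{len(strict)} pass the fc>=1.5 strict tier in every supporting dataset")

for conv in dict.fromkeys(table.conversions.values()):
    n_ds = len(table.datasets_of(conv))
    merged = merge_conversion(table, conv, VoteRule(max(1, n_ds - 1), forbid_opposite=True))
    degs = merged.degs
    out = pd.DataFrame({"gene": degs.index, "direction": degs.to_numpy(),
                        "fc_linear": merged.fc.loc[degs.index].to_numpy()})
    out.to_csv(OUT / f"degs.{conv}.tsv", sep="\t", index=False)
    print(f"{conv}: {len(degs)} DEGs from {n_ds} dataset(s)")
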