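"""Hierarchical clustering of the common signature (genes and arrays).

Clusters the common-signature log2 fold-change matrix with average linkage
on 1 - uncentered correlation, on both axes, and writes TreeView-compatible
CDT/GTR files plus the leaf orders to results/clustering/.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, load_study

from convmine.cluster import cluster
from convmine.consensus import VoteRule, common_signature
from convmine.io import write_cdt_gtr

OUT = RESULTS / "clustering"
OUT.mkdir(parents=True, exist_ok=True)

table, _, _ = load_study()
n = len(table.dataset_ids)
full, _ = common_signature(table, VoteRule(n - 1, forbid_opposite=True))
genes = [g for g, _ in full]
log2fc = np.log2(table.fc.loc[genes])

gene_tree = cluster(log2fc, axis="genes")
write_cdt_gtr(gene_tree, log2fc, OUT / "common_signature")
array_tree = cluster(log2fc.T, axis="arrays")

(OUT / "gene_leaf_order.tsv").write_text(
    "\n".join(gene_tree.ordered_labels) + "\n")
(OUT / "array_leaf_order.tsv").write_text(
    "\n".join(array_tree.ordered_labels) + "\n")

print(f"clustered {len(genes)} common-signature genes across {n} arrays")
print("array leaf order:", " ".join(array_tree.ordered_labels))
up = {g for g, d in full if d == "up"}
ordered_dirs = ["up" if g in up else "down" for g in gene_tree.ordered_labels]
blocks = 1 + sum(a != b for a, b in zip(ordered_dirs, ordered_dirs[1:]))
print(f"gene dendrogram separates directions into {blocks} contiguous blocks")
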