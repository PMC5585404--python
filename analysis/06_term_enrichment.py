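"""Ontology-style term enrichment of the recovered signatures.

Tests every term of the term database against the common signature and
against each conversion's DEG list with the two-sided hypergeometric test
(twice the smaller tail) and Holm correction across the term family; terms
with adjusted p < 0.05 are flagged. Writes results/terms/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, load_study

from convmine.consensus import VoteRule, common_signature, merge_conversion
from convmine.enrichment import term_enrichment

OUT = RESULTS / "terms"
OUT.mkdir(parents=True, exist_ok=True)

table, _, term_db = load_study()
n = len(table.dataset_ids)

queries = {}
full, _ = common_signature(table, VoteRule(n - 1, forbid_opposite=True))
queries["common"] = [g for g, _ in full]
for conv in dict.fromkeys(table.conversions.values()):
    n_ds = len(table.datasets_of(conv))
    merged = merge_conversion(table, conv, VoteRule(max(1, n_ds - 1), forbid_opposite=True))
    queries[conv] = sorted(merged.gene_set())

for name, genes in queries.items():
    results = term_enrichment(genes, term_db)
    pd.DataFrame(
        [(t.term, t.name, t.overlap, t.term_size, t.p_two_sided, t.p_adjusted,
          t.direction, t.significant) for t in results],
        columns=["term", "name", "overlap", "term_size", "p_two_sided", "p_adjusted",
                 "direction", "significant"],
    ).to_csv(OUT / f"{name}.tsv", sep="\t", index=False)
    hits = [t.term for t in results if t.significant]
    print(f"{name} ({len(genes)} genes): {len(hits)} significant terms "
          f"{hits[:4]}{'...' if len(hits) > 4 else ''}")
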