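"""Gene regulatory networks and out-degree hub ranking per conversion.

For each conversion: TFs whose binding targets are over-represented among
the DEGs (one-sided hypergeometric, p < 0.05) and which are themselves
differential with fold change >= 1.5 become DE-TFs; the GRN wires each
DE-TF to its DEG targets, the core network keeps only DE-TF -> DE-TF edges,
and hubs are ranked by out-degree. Writes enrichment/ranking TSVs and SIF
edge lists to results/grn/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, load_study

from convmine.consensus import VoteRule, merge_conversion
from convmine.grn import (build_core_network, build_grn, enrichment_table,
                          filter_de_tfs, out_degree_ranking, ranking_table,
                          tf_enrichment)
from convmine.io import write_sif

OUT = RESULTS / "grn"
OUT.mkdir(parents=True, exist_ok=True)

table, regulon_db, _ = load_study()
universe = regulon_db.universe & frozenset(table.genes)

for conv in dict.fromkeys(table.conversions.values()):
    n_ds = len(table.datasets_of(conv))
    merged = merge_conversion(table, conv, VoteRule(max(1, n_ds - 1), forbid_opposite=True))
    degs = merged.gene_set()
    enr = tf_enrichment(degs, regulon_db, universe)
    de_tfs = filter_de_tfs(enr, merged, fc_min=1.5)
    grn = build_grn(de_tfs, degs, regulon_db)
    core = build_core_network(de_tfs, regulon_db)
    ranking = out_degree_ranking(grn)

    enrichment_table(enr).to_csv(OUT / f"tf_enrichment.{conv}.tsv", sep="\t", index=False)
    ranking_table(ranking).to_csv(OUT / f"ranking.{conv}.tsv", sep="\t", index=False)
    write_sif(grn, OUT / f"grn.{conv}.sif")
    write_sif(core, OUT / f"core.{conv}.sif")

    top = ", ".join(f"{tf}({deg})" for tf, deg, _ in ranking.entries[:5])
    print(f"{conv}: {len(de_tfs)} DE-TFs, {len(grn.edges)} GRN edges, "
          f"{len(core.edges)} core edges; top hubs: {top}")
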