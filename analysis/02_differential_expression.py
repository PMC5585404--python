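"""Per-dataset differential expression between origin and target cells.

Reads the simulated study from results/study/, computes per-gene fold change
(linear target/origin mean ratio), a two-sample t-test p-value on log2
intensities, and the three-way direction call (p < 0.05), and writes one
TSV per dataset to results/de/.
"""

from pathlib import Path

from convmine.diffexpr import differential_expression
from convmine.io import read_expression_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "de"
OUT.mkdir(parents=True, exist_ok=True)

conversions = dict(
    line.split("\t") for line in (ROOT / "study" / "conversions.tsv").read_text().splitlines()
)
for ds_id in conversions:
    ds = read_expression_matrix(ROOT / "study" / f"{ds_id}.matrix.tsv",
                                ROOT / "study" / f"{ds_id}.groups.tsv",
                                dataset_id=ds_id)
    de = differential_expression(ds)
    de.table.reset_index(names="gene").to_csv(OUT / f"{ds_id}.tsv", sep="\t", index=False)
    n_up = (de.directions == "up").sum()
    n_down = (de.directions == "down").sum()
    print(f"{ds_id} ({conversions[ds_id]}): {n_up} up, {n_down} down of {len(ds.genes)} genes")
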