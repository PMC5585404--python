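"""Shared loader for the analysis drivers: reads the study written by
01_simulate_study.py and rebuilds the per-dataset DE results and the
direction table (cheap, fully deterministic)."""

from pathlib import Path

from convmine.consensus import DirectionTable
from convmine.diffexpr import differential_expression
from convmine.io import RegulonDB, TermDB, read_expression_matrix, read_gmt

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY = RESULTS / "study"


def load_study():
    if not STUDY.exists():
        raise SystemExit("run 01_simulate_study.py first")
    conversions = dict(
        line.split("\t") for line in (STUDY / "conversions.tsv").read_text().splitlines()
    )
    datasets = [
        read_expression_matrix(STUDY / f"{ds_id}.matrix.tsv",
                               STUDY / f"{ds_id}.groups.tsv", dataset_id=ds_id)
        for ds_id in conversions
    ]
    results = [differential_expression(ds) for ds in datasets]
    table = DirectionTable.from_results(results, conversions)
    regulon_db = read_gmt(STUDY / "regulons.gmt", cls=RegulonDB)
    term_db = read_gmt(STUDY / "terms.gmt", cls=TermDB)
    return table, regulon_db, term_db


def load_truth():
    truth: dict[str, set] = {}
    for line in (STUDY / "truth.tsv").read_text().splitlines():
        what, direction, gene = line.split("\t")
        truth.setdefault(f"{what}:{direction}", set()).add(gene)
    return truth
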