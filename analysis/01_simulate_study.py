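"""Generate the study: five fibroblast-style conversions, nine datasets.

Simulates a multi-conversion expression study shaped like the human
fibroblast panel — five conversions carried by nine independent datasets
(1, 1, 3, 1, 3), three replicates per group — with planted common up/down
signatures, per-conversion specific signatures, and TF regulons whose
targets are enriched among each conversion's differential genes. Writes the
matrices, group maps, regulon/term GMT databases, a conversions manifest
and the planted truth to results/study/.
"""

from pathlib import Path

from convmine.simulate import StudyConfig, conversion_map, generate_study, write_study

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 1

cfg = StudyConfig(seed=SEED)
datasets, regulon_db, term_db, truth = generate_study(cfg)
write_study(datasets, regulon_db, term_db, truth, conversion_map(cfg), OUT)

n_specific = sum(len(u) + len(d) for u, d in truth.specific.values())
print(f"wrote {len(datasets)} datasets ({cfg.n_genes} genes) to {OUT}")
print(f"planted: {len(truth.common_up)} common-up, {len(truth.common_down)} common-down, "
      f"{n_specific} conversion-specific genes, "
      f"{sum(len(t) for t in truth.de_tfs.values())} master TFs "
      f"among {len(regulon_db)} regulons")
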