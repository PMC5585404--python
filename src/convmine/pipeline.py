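"""End-to-end study orchestration.

``run_analysis`` is the in-memory pipeline over already-loaded datasets:
per-dataset differential expression → direction table → common signature →
per-conversion consensus merging → specific signatures → per-conversion GRN
(TF enrichment, DE-TF filtering, network, out-degree ranking, core network)
→ term enrichment → clustering. ``run_study`` wraps it with file I/O: it
simulates or ingests the datasets named by a config, writes every stage's
artifacts (TSV/SIF/CDT/GTR) and a manifest with content checksums; identical
config and seed give identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from convmine import io as _io
from convmine.cluster import ClusterResult, cluster as _cluster_rows
from convmine.consensus import (ConversionDegs, DirectionTable, VoteRule,
                                common_signature, merge_conversion)
from convmine.diffexpr import DEResult, DEThresholds, differential_expression
from convmine.enrichment import TermResult, term_enrichment
from convmine.grn import (CentralityRanking, Grn, TfEnrichment, build_core_network,
                          build_grn, enrichment_table, filter_de_tfs,
                          out_degree_ranking, ranking_table, tf_enrichment)
from convmine.io import ExpressionDataset, RegulonDB, TermDB
from convmine.simulate import StudyConfig, conversion_map, generate_study
from convmine.specificity import SpecificCall, SpecificityRule, partition_counts, specific_signature

log = logging.getLogger(__name__)

ALL_STAGES = ("diffexpr", "consensus", "specificity", "grn", "enrichment", "clustering")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and stage toggles of one study run.

    ``within_min_same``/``common_min_same`` of None resolve to n − 1 for the
    datasets in scope (the 2-of-3 / 3-of-4 within-conversion rules and the
    8-of-9 cross-conversion rule of a nine-dataset study). Both the
    within-conversion merge and the cross-conversion common vote forbid
    opposite calls by default; either can be relaxed in config.
    """

    de: DEThresholds = DEThresholds()
    within_min_same: int | None = None
    within_forbid_opposite: bool = True
    common_min_same: int | None = None
    common_forbid_opposite: bool = True
    strict_fc_min: float = 1.5
    specificity: SpecificityRule = SpecificityRule()
    detf_fc_min: float = 1.5
    enrichment_alpha: float = 0.05
    grn_alpha: float = 0.05
    top_k: int = 5
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0

    def within_rule(self, n_datasets: int) -> VoteRule:
        ms = self.within_min_same if self.within_min_same is not None else max(1, n_datasets - 1)
        return VoteRule(min_same=ms, forbid_opposite=self.within_forbid_opposite)

    def common_rule(self, n_datasets: int) -> VoteRule:
        ms = self.common_min_same if self.common_min_same is not None else max(1, n_datasets - 1)
        return VoteRule(min_same=ms, forbid_opposite=self.common_forbid_opposite)


@dataclass
class ConversionGrn:
    """The regulatory layer of one conversion."""

    conversion: str
    enrichments: list[TfEnrichment]
    de_tfs: dict[str, str]
    grn: Grn
    ranking: CentralityRanking
    core: Grn
    core_ranking: CentralityRanking


@dataclass
class StudyResult:
    """Everything the pipeline computed for one study."""

    de_results: list[DEResult]
    table: DirectionTable
    common_full: list[tuple[str, str]] = field(default_factory=list)
    common_strict: list[tuple[str, str]] = field(default_factory=list)
    merged: dict[str, ConversionDegs] = field(default_factory=dict)
    specific: dict[str, list[SpecificCall]] = field(default_factory=dict)
    grns: dict[str, ConversionGrn] = field(default_factory=dict)
    terms: dict[str, list[TermResult]] = field(default_factory=dict)
    clustering: dict[str, ClusterResult] = field(default_factory=dict)


def _conversion_order(table: DirectionTable) -> list[str]:
    seen: list[str] = []
    for d in table.dataset_ids:
        c = table.conversions[d]
        if c not in seen:
            seen.append(c)
    return seen


def run_analysis(
    datasets: Sequence[ExpressionDataset],
    conversions: dict[str, str],
    regulon_db: RegulonDB | None,
    term_db: TermDB | None,
    cfg: PipelineConfig = PipelineConfig(),
) -> StudyResult:
    """Run the analysis stages in memory and return all stage results."""
    de_results = [differential_expression(ds, cfg.de) for ds in datasets]
    table = DirectionTable.from_results(de_results, conversions)
    result = StudyResult(de_results=de_results, table=table)
    convs = _conversion_order(table)

    if "consensus" in cfg.stages:
        rule = cfg.common_rule(len(table.dataset_ids))
        result.common_full, result.common_strict = common_signature(
            table, rule, strict_fc_min=cfg.strict_fc_min
        )
        log.info("common signature: %d genes (%d strict)",
                 len(result.common_full), len(result.common_strict))
        for conv in convs:
            n_ds = len(table.datasets_of(conv))
            result.merged[conv] = merge_conversion(table, conv, cfg.within_rule(n_ds))

    if "specificity" in cfg.stages:
        for conv in convs:
            calls = specific_signature(result.merged[conv], table, cfg.specificity)
            result.specific[conv] = calls
            log.info("%s-specific: %d genes %s", conv, len(calls), partition_counts(calls))

    if "grn" in cfg.stages and regulon_db is not None:
        measured = frozenset(table.genes)
        universe = regulon_db.universe & measured
        for conv in convs:
            degs = result.merged[conv].gene_set()
            enr = tf_enrichment(degs, regulon_db, universe, alpha=cfg.grn_alpha)
            de_tfs = filter_de_tfs(enr, result.merged[conv],
                                   fc_min=cfg.detf_fc_min, alpha=cfg.grn_alpha)
            grn = build_grn(de_tfs, degs, regulon_db)
            core = build_core_network(de_tfs, regulon_db)
            result.grns[conv] = ConversionGrn(
                conversion=conv,
                enrichments=enr,
                de_tfs=de_tfs,
                grn=grn,
                ranking=out_degree_ranking(grn),
                core=core,
                core_ranking=out_degree_ranking(core),
            )
            log.info("%s: %d DE-TFs, %d GRN edges", conv, len(de_tfs), len(grn.edges))

    if "enrichment" in cfg.stages and term_db is not None:
        common_genes = [g for g, _ in result.common_full]
        if common_genes:
            result.terms["common"] = term_enrichment(
                common_genes, term_db, alpha=cfg.enrichment_alpha
            )
        for conv in convs:
            degs = sorted(result.merged[conv].gene_set())
            if degs:
                result.terms[conv] = term_enrichment(degs, term_db, alpha=cfg.enrichment_alpha)

    if "clustering" in cfg.stages and table.fc is not None and len(result.common_full) >= 2:
        genes = [g for g, _ in result.common_full]
        log2fc = np.log2(table.fc.loc[genes])
        result.clustering["genes"] = _cluster_rows(log2fc, axis="genes")
        if len(table.dataset_ids) >= 2:
            result.clustering["arrays"] = _cluster_rows(log2fc.T, axis="arrays")

    return result


# ---------------------------------------------------------------------------
# file-level orchestration


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.8g")


def run_study(
    cfg: PipelineConfig,
    outdir: str | Path,
    datasets: Sequence[ExpressionDataset] | None = None,
    conversions: dict[str, str] | None = None,
    regulon_db: RegulonDB | None = None,
    term_db: TermDB | None = None,
    study_cfg: StudyConfig | None = None,
) -> dict:
    """Execute the study and write every artifact plus a checksum manifest.

    Either pass loaded inputs, or a :class:`StudyConfig` to simulate them
    (seeded from ``cfg.seed`` unless the study config carries its own).
    Returns the manifest (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if datasets is None:
        study_cfg = study_cfg or StudyConfig(seed=cfg.seed)
        datasets, regulon_db, term_db, _truth = generate_study(study_cfg)
        conversions = conversion_map(study_cfg)
    if conversions is None:
        raise ValueError("conversions map required with explicit datasets")

    result = run_analysis(datasets, conversions, regulon_db, term_db, cfg)
    artifacts: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        artifacts[name] = path.name

    for de in result.de_results:
        p = outdir / f"de.{de.dataset_id}.tsv"
        _write_tsv(de.table.reset_index(names="gene"), p)
        emit(f"de:{de.dataset_id}", p)

    if "consensus" in cfg.stages:
        p = outdir / "common_signature.tsv"
        strict = {g for g, _ in result.common_strict}
        df = pd.DataFrame(result.common_full, columns=["gene", "direction"])
        df["strict"] = df["gene"].isin(strict)
        _write_tsv(df, p)
        emit("common_signature", p)
        for conv, merged in result.merged.items():
            p = outdir / f"degs.{conv}.tsv"
            degs = merged.degs
            _write_tsv(
                pd.DataFrame({"gene": degs.index, "direction": degs.to_numpy(),
                              "fc_linear": merged.fc.loc[degs.index].to_numpy()}), p)
            emit(f"degs:{conv}", p)

    if "specificity" in cfg.stages:
        for conv, calls in result.specific.items():
            p = outdir / f"specific.{conv}.tsv"
            _write_tsv(pd.DataFrame(
                [(c.gene, c.direction, c.opposite_count, c.identical_count) for c in calls],
                columns=["gene", "direction", "opposite_count", "identical_count"]), p)
            emit(f"specific:{conv}", p)

    if "grn" in cfg.stages:
        for conv, cg in result.grns.items():
            p = outdir / f"tf_enrichment.{conv}.tsv"
            _write_tsv(enrichment_table(cg.enrichments), p)
            emit(f"tf_enrichment:{conv}", p)
            p = outdir / f"grn.{conv}.sif"
            _io.write_sif(cg.grn, p)
            emit(f"grn:{conv}", p)
            p = outdir / f"core.{conv}.sif"
            _io.write_sif(cg.core, p)
            emit(f"core:{conv}", p)
            p = outdir / f"ranking.{conv}.tsv"
            _write_tsv(ranking_table(cg.ranking), p)
            emit(f"ranking:{conv}", p)

    if "enrichment" in cfg.stages:
        for query, terms in result.terms.items():
            p = outdir / f"terms.{query}.tsv"
            _write_tsv(pd.DataFrame(
                [(t.term, t.name, t.overlap, t.term_size, t.p_two_sided,
                  t.p_adjusted, t.direction, t.significant) for t in terms],
                columns=["term", "name", "overlap", "term_size", "p_two_sided",
                         "p_adjusted", "direction", "significant"]), p)
            emit(f"terms:{query}", p)

    if "clustering" in cfg.stages and "genes" in result.clustering:
        genes = [g for g, _ in result.common_full]
        log2fc = np.log2(result.table.fc.loc[genes])
        _io.write_cdt_gtr(result.clustering["genes"], log2fc, outdir / "common_signature")
        emit("clustering:cdt", outdir / "common_signature.cdt")
        emit("clustering:gtr", outdir / "common_signature.gtr")

    manifest = {
        "artifacts": {
            name: {"path": fname, "sha256": _sha256(outdir / fname)}
            for name, fname in sorted(artifacts.items())
        },
        "seed": cfg.seed,
    }
    with open(outdir / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_pipeline_config(path: str | Path) -> tuple[PipelineConfig, StudyConfig | None]:
    """Read a structured YAML config into pipeline (and optional simulate)
    configs. The resolved config is logged verbatim for reproducibility."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    log.info("resolved config: %s", json.dumps(raw, sort_keys=True))
    de = DEThresholds(**raw.get("de", {}))
    spec = SpecificityRule(**raw.get("specificity", {}))
    pc_kwargs = {k: v for k, v in raw.items()
                 if k not in ("de", "specificity", "simulate", "stages")}
    stages = tuple(raw.get("stages", ALL_STAGES))
    cfg = PipelineConfig(de=de, specificity=spec, stages=stages, **pc_kwargs)
    sim = raw.get("simulate")
    study = None
    if sim is not None:
        if "conversions" in sim:
            sim["conversions"] = tuple(tuple(c) for c in sim["conversions"])
        study = StudyConfig(**sim)
    return cfg, study
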