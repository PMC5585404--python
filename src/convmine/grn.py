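"""TF-target enrichment, gene-regulatory-network construction and hub ranking.

The regulatory layer of a conversion is reconstructed from protein–DNA
binding data: TFs whose binding targets are over-represented among the
conversion's DEGs (one-sided hypergeometric p < 0.05) and which are
themselves differentially expressed with linear fold change >= 1.5 are the
DE-TFs; the GRN has a directed edge from each DE-TF to each of its targets
in the DEG list. Hubs are ranked by out-degree — the DE-TFs with the most
targets are the most central regulators of the conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from convmine.consensus import ConversionDegs
from convmine.diffexpr import NONE
from convmine.enrichment import holm_adjust
from convmine.io import RegulonDB

log = logging.getLogger(__name__)


@dataclass
class TfEnrichment:
    tf: str
    overlap: int
    regulon_size: int
    p_value: float
    enriched: bool  # raw p < 0.05


@dataclass
class Grn:
    """Directed TF→gene network. Edge sources are DE-TFs; edge targets are
    DEGs. ``annotations`` carries the direction of each DE-TF node."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())

    def out_degree(self, tf: str) -> int:
        return self.graph.out_degree(tf) if tf in self.graph else 0


def hypergeom_upper_tail(overlap: int, regulon_size: int, n_selected: int, n_universe: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(N, K, n) — the one-sided
    over-representation probability."""
    return float(stats.hypergeom.sf(overlap - 1, n_universe, regulon_size, n_selected))


def tf_enrichment(
    degs: Iterable[str],
    db: RegulonDB,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[TfEnrichment]:
    """Over-representation of each TF's binding targets among the DEGs.

    Per TF: p = P(X >= overlap) with population N = |universe|, successes
    K = |regulon ∩ universe|, draws n = |degs ∩ universe|. DEGs outside the
    universe are dropped with a warning. A Holm-adjusted column is attached
    by the result writer; the DE-TF gate itself uses the raw p (< 0.05),
    matching how binding-site databases are conventionally queried.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    deg_set = frozenset(degs)
    dropped = deg_set - uni
    if dropped:
        log.warning("%d DEGs outside the universe dropped", len(dropped))
    deg_set &= uni
    results = []
    for tf in sorted(db.regulons):
        regulon = db.regulons[tf] & uni
        if not regulon:
            continue
        overlap = len(regulon & deg_set)
        p = hypergeom_upper_tail(overlap, len(regulon), len(deg_set), len(uni))
        results.append(TfEnrichment(tf, overlap, len(regulon), p, p < alpha))
    return results


def enrichment_table(enr: list[TfEnrichment]) -> pd.DataFrame:
    """Tabular view with a Holm-adjusted column alongside the raw p."""
    df = pd.DataFrame(
        {
            "tf": [e.tf for e in enr],
            "overlap": [e.overlap for e in enr],
            "regulon_size": [e.regulon_size for e in enr],
            "p_value": [e.p_value for e in enr],
            "enriched": [e.enriched for e in enr],
        }
    )
    df["p_holm"] = holm_adjust(df["p_value"].tolist()) if len(df) else []
    return df.sort_values(["p_value", "tf"]).reset_index(drop=True)


def filter_de_tfs(
    enr: list[TfEnrichment],
    de: ConversionDegs,
    fc_min: float = 1.5,
    alpha: float = 0.05,
) -> dict[str, str]:
    """DE-TFs: enriched TFs that are themselves differentially expressed.

    A TF qualifies iff its target enrichment p < alpha AND the TF's own
    conversion-level call is up/down with linear fold-change magnitude
    >= fc_min. Returns TF → direction (the up/down annotation used for node
    coloring in network views).
    """
    out: dict[str, str] = {}
    for e in enr:
        if e.p_value >= alpha:
            continue
        d = de.direction.get(e.tf, NONE)
        if d == NONE:
            continue
        fc = de.fc.get(e.tf, np.nan)
        if not np.isfinite(fc) or max(fc, 1.0 / fc) < fc_min:
            continue
        out[e.tf] = d
    return out


def build_grn(de_tfs: dict[str, str] | Iterable[str], degs: Iterable[str], db: RegulonDB) -> Grn:
    """Directed network with an edge (t, g) for every DE-TF t and every
    DEG g in t's regulon. A self-loop (t, t) is kept only if t is itself a
    DEG."""
    annotations = dict(de_tfs) if isinstance(de_tfs, dict) else {t: "na" for t in de_tfs}
    deg_set = frozenset(degs)
    g = nx.DiGraph()
    for tf in sorted(annotations):
        if tf not in db.regulons:
            raise KeyError(f"DE-TF {tf!r} not in regulon database")
        for target in sorted(db.regulons[tf] & deg_set):
            g.add_edge(tf, target)
    return Grn(graph=g, annotations=annotations)


def build_core_network(de_tfs: dict[str, str] | Iterable[str], db: RegulonDB) -> Grn:
    """The regulatory core: edges restricted to DE-TF → DE-TF pairs,
    capturing how the identified regulators govern each other."""
    annotations = dict(de_tfs) if isinstance(de_tfs, dict) else {t: "na" for t in de_tfs}
    return build_grn(annotations, annotations.keys(), db)


@dataclass
class CentralityRanking:
    """TFs ordered by out-degree (descending, ties alphabetical and sharing
    the min rank)."""

    entries: list[tuple[str, int, int]]  # (tf, out_degree, rank)

    def top(self, k: int) -> list[str]:
        return [tf for tf, _, _ in self.entries[:k]]


def out_degree_ranking(g: Grn, top_k: int | None = None) -> CentralityRanking:
    """Hub ranking by out-degree over the network's TF nodes (nodes with at
    least one outgoing edge, plus annotated DE-TFs with none)."""
    tfs = set(g.annotations) | {u for u, _ in g.edges}
    scored = sorted(((tf, g.out_degree(tf)) for tf in tfs), key=lambda t: (-t[1], t[0]))
    entries: list[tuple[str, int, int]] = []
    for i, (tf, deg) in enumerate(scored):
        rank = entries[i - 1][2] if i > 0 and scored[i - 1][1] == deg else i + 1
        entries.append((tf, deg, rank))
    if top_k is not None:
        entries = entries[:top_k]
    return CentralityRanking(entries=entries)


def ranking_table(r: CentralityRanking) -> pd.DataFrame:
    return pd.DataFrame(r.entries, columns=["tf", "out_degree", "rank"])
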