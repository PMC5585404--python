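"""External representations: expression matrices, GMT gene sets, SIF edge
lists and CDT/GTR cluster files.

All text output is UTF-8 with LF line endings, and writers sort their records
so that write → read → write round-trips are byte-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ORIGIN = "origin"
TARGET = "target"


@dataclass
class ExpressionDataset:
    """One conversion dataset: a genes × samples intensity matrix plus the
    origin/target group of every sample.

    ``values`` holds non-negative linear-scale intensities (the matrices are
    assumed pre-normalized; no background correction is applied here), with
    gene symbols as the index and sample ids as columns. Gene symbols are
    case-normalized to uppercase so that mouse and human symbols unify.
    """

    dataset_id: str
    values: pd.DataFrame
    groups: dict[str, str]
    organism: str = "unknown"

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str).str.upper()
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"{self.dataset_id}: duplicate gene symbols {dup}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"{self.dataset_id}: samples missing from groups file: {missing}")
        bad = {s: g for s, g in self.groups.items() if g not in (ORIGIN, TARGET)}
        if bad:
            raise ValueError(f"{self.dataset_id}: invalid group labels {bad}")
        if not self.origin_samples or not self.target_samples:
            raise ValueError(f"{self.dataset_id}: need at least one origin and one target sample")
        if (self.values.to_numpy() < 0).any():
            raise ValueError(f"{self.dataset_id}: negative intensities (matrix must be linear scale)")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def origin_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == ORIGIN]

    @property
    def target_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == TARGET]


@dataclass
class GeneSetDB:
    """Named gene sets over a symbol universe (GMT carrier)."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            extra = members - self.universe
            if extra:
                raise ValueError(f"gene set {name!r} has members outside the universe: {sorted(extra)[:5]}")

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)


class RegulonDB(GeneSetDB):
    """TF → target-gene sets derived from protein–DNA binding data
    (ChIP-chip/ChIP-seq-style evidence, as in ChEA)."""

    @property
    def regulons(self) -> dict[str, frozenset[str]]:
        return self.sets


class TermDB(GeneSetDB):
    """Ontology term → gene sets (ClueGO-style term databases)."""

    @property
    def terms(self) -> dict[str, frozenset[str]]:
        return self.sets


def read_expression_matrix(
    path: str | Path,
    groups_path: str | Path,
    dataset_id: str | None = None,
    organism: str = "unknown",
) -> ExpressionDataset:
    """Read a tab-delimited genes × samples matrix and its sample→group map.

    The matrix has gene symbols in the first column and a header row of sample
    ids; the groups file is two-column TSV ``sample<TAB>origin|target``.
    Duplicate gene symbols (multi-probe genes) are collapsed by row mean, with
    a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        values = df.astype(float)
    except ValueError:
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(numeric.isna().to_numpy() & df.notna().to_numpy())
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        ) from None
    values.index = values.index.astype(str).str.upper()
    if values.index.has_duplicates:
        dup = sorted(values.index[values.index.duplicated()].unique())
        log.warning("%s: collapsing duplicated gene symbols by row mean: %s", path, dup)
        values = values.groupby(level=0, sort=False).mean()

    groups: dict[str, str] = {}
    for lineno, line in enumerate(Path(groups_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{groups_path}:{lineno}: expected 'sample<TAB>group'")
        groups[parts[0]] = parts[1]
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem, values=values, groups=groups, organism=organism
    )


def read_gmt(path: str | Path, cls: type[GeneSetDB] = GeneSetDB, universe: Iterable[str] | None = None):
    """Read gene sets in GMT dialect: ``name<TAB>description<TAB>member...``.

    The universe defaults to the union of all members; pass ``universe`` to
    supply an explicit one. Symbols are uppercased on ingest.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
        name = parts[0].upper()
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = frozenset(g.upper() for g in parts[2:] if g)
        descriptions[name] = parts[1]
    if not sets:
        log.warning("%s: empty GMT file, database has no sets", path)
    if universe is None:
        uni = frozenset().union(*sets.values()) if sets else frozenset()
    else:
        uni = frozenset(g.upper() for g in universe)
    return cls(sets=sets, universe=uni, descriptions=descriptions)


def write_gmt(db: GeneSetDB, path: str | Path) -> None:
    """Write gene sets in GMT dialect, sets and members sorted."""
    with open(path, "w", newline="\n") as fh:
        for name in sorted(db.sets):
            desc = db.descriptions.get(name, "na") or "na"
            fh.write("\t".join([name, desc, *sorted(db.sets[name])]) + "\n")


def write_sif(grn, path: str | Path) -> None:
    """Write a network as a SIF edge list: ``TF<TAB>regulates<TAB>TARGET``,
    sorted by (TF, target) for bit-stable output."""
    with open(path, "w", newline="\n") as fh:
        for tf, target in sorted(grn.edges):
            fh.write(f"{tf}\tregulates\t{target}\n")


def read_sif(path: str | Path) -> set[tuple[str, str]]:
    """Read a SIF edge list back into a set of (source, target) pairs."""
    edges: set[tuple[str, str]] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'source<TAB>relation<TAB>target'")
        edges.add((parts[0], parts[2]))
    return edges


def write_cdt_gtr(tree, matrix: pd.DataFrame, path_stem: str | Path) -> None:
    """Emit TreeView-compatible files for a gene-axis clustering: the
    clustered data table (``.cdt``, rows in leaf order) and the gene tree
    (``.gtr``, one join per line with the similarity at the join).

    ``tree`` is a :class:`convmine.cluster.ClusterResult` over the rows of
    ``matrix``.
    """
    path_stem = Path(path_stem)
    n = len(tree.leaf_order)
    if n != len(matrix.index):
        raise ValueError("clustering result does not match matrix rows")

    def node_name(node_id: int) -> str:
        return f"GENE{node_id}X" if node_id < n else f"NODE{node_id - n + 1}X"

    with open(path_stem.with_suffix(".gtr"), "w", newline="\n") as fh:
        for i, (a, b, sim) in enumerate(tree.merges):
            fh.write(f"NODE{i + 1}X\t{node_name(a)}\t{node_name(b)}\t{sim:.6f}\n")

    with open(path_stem.with_suffix(".cdt"), "w", newline="\n") as fh:
        fh.write("GID\tNAME\tGWEIGHT\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
        for leaf in tree.leaf_order:
            row = matrix.iloc[leaf]
            vals = "\t".join(f"{v:.6f}" for v in row.to_numpy())
            fh.write(f"{node_name(leaf)}\t{matrix.index[leaf]}\t1.000000\t{vals}\n")


def write_expression_matrix(ds: ExpressionDataset, path: str | Path, groups_path: str | Path) -> None:
    """Write a dataset back to matrix + groups TSVs (inverse of
    :func:`read_expression_matrix`)."""
    with open(path, "w", newline="\n") as fh:
        ds.values.to_csv(fh, sep="\t", index_label="gene", lineterminator="\n", float_format="%.6f")
    with open(groups_path, "w", newline="\n") as fh:
        for sample in ds.samples:
            fh.write(f"{sample}\t{ds.groups[sample]}\n")
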