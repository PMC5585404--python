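"""Synthetic multi-conversion expression studies with planted ground truth.

The generator emulates the statistical structure a cross-dataset conversion
study assumes: several conversions (origin → target cell type), each with
one to a few independently produced datasets; log-normal intensities
(i.i.d. Gaussian noise on the log2 scale); a planted *common* signature
shared by every conversion (same direction everywhere); planted
*conversion-specific* signatures (their direction in the home conversion
and the opposite direction in all others, so the specificity criterion's
opposite-pattern branch is exercised); and planted TF regulons whose targets
are enriched among the home conversion's differential genes, with the TF
itself planted differential so it passes the DE-TF fold-change gate.

Identical seed → bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from convmine.io import ExpressionDataset, RegulonDB, TermDB, write_expression_matrix, write_gmt


@dataclass(frozen=True)
class TfSpec:
    """One planted regulon: the TF's symbol, its regulon size, the fraction
    of the regulon drawn from the home conversion's planted differential
    genes, and the TF's own log2 effect in its home conversion (0 for decoy
    TFs that are never differential)."""

    name: str
    regulon_size: int = 80
    de_fraction: float = 0.6
    effect_log2: float = 2.0


@dataclass(frozen=True)
class StudyConfig:
    """Study design and generative parameters.

    The defaults mirror a desk-scale analogue of a nine-dataset,
    five-conversion fibroblast panel: tens-of-genes signatures, |log2 FC|
    of 2 for planted genes, log2-scale noise s.d. 0.5, three replicates per
    group, and one planted master TF per conversion plus decoy regulons.
    """

    n_genes: int = 5000
    conversions: tuple[tuple[str, int, int], ...] = (
        ("osteoblast", 1, 3),
        ("mbp", 1, 3),
        ("endothelial", 3, 3),
        ("phagocyte", 1, 3),
        ("cardiomyocyte", 3, 3),
    )
    common_up: int = 20
    common_down: int = 25
    specific_per_conversion: int = 15
    tf_regulons: tuple[TfSpec, ...] = tuple(
        [TfSpec(name=f"MASTER{i + 1}") for i in range(5)]
        + [TfSpec(name=f"DECOY{i + 1}", de_fraction=0.0, effect_log2=0.0) for i in range(10)]
    )
    effect_log2: float = 2.0
    noise_sd_log2: float = 0.5
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.common_up <= 0 or self.common_down <= 0:
            raise ValueError("all counts must be positive")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be > 0")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        n_planted = (
            self.common_up
            + self.common_down
            + self.specific_per_conversion * len(self.conversions)
        )
        if n_planted + len(self.tf_regulons) > self.n_genes:
            raise ValueError("planted signatures and TFs exceed n_genes")
        for tf in self.tf_regulons:
            if tf.regulon_size > self.n_genes:
                raise ValueError(f"regulon of {tf.name} larger than the gene universe")
            if not 0 <= tf.de_fraction <= 1:
                raise ValueError("de_fraction must be in [0, 1]")

    @property
    def conversion_names(self) -> list[str]:
        return [c[0] for c in self.conversions]

    @property
    def n_datasets(self) -> int:
        return sum(c[1] for c in self.conversions)


@dataclass
class GroundTruth:
    """Planted truth of one synthetic study."""

    common_up: frozenset[str]
    common_down: frozenset[str]
    specific: dict[str, tuple[frozenset[str], frozenset[str]]]  # conv -> (up, down)
    de_tfs: dict[str, frozenset[str]]
    universe: frozenset[str] = frozenset()

    def planted_de(self, conversion: str) -> dict[str, str]:
        """Gene → direction planted in one conversion: the common signature,
        the conversion's own specific genes, the opposite-signed specific
        genes of every other conversion, and the conversion's planted TFs."""
        out = {g: "up" for g in self.common_up}
        out.update({g: "down" for g in self.common_down})
        for conv, (up, down) in self.specific.items():
            if conv == conversion:
                out.update({g: "up" for g in up})
                out.update({g: "down" for g in down})
            else:
                out.update({g: "down" for g in up})
                out.update({g: "up" for g in down})
        for tf, d in self.tf_directions(conversion).items():
            out[tf] = d
        return out

    def tf_directions(self, conversion: str) -> dict[str, str]:
        return {tf: d for tf, d in self._tf_dirs.get(conversion, {}).items()}

    _tf_dirs: dict[str, dict[str, str]] = field(default_factory=dict)

    def grn_edges(self, conversion: str, db: RegulonDB) -> set[tuple[str, str]]:
        """The planted GRN of a conversion: every planted DE-TF wired to its
        regulon members that are planted differential there."""
        de = set(self.planted_de(conversion))
        return {
            (tf, g)
            for tf in self.de_tfs.get(conversion, frozenset())
            for g in db.regulons[tf] & de
        }


def generate_study(
    cfg: StudyConfig,
) -> tuple[list[ExpressionDataset], RegulonDB, TermDB, GroundTruth]:
    """Generate the datasets, regulon database, term database and truth.

    Per dataset: baseline log2 means are drawn per gene; target-group means
    get ±effect_log2 for genes planted differential in that conversion;
    i.i.d. Gaussian noise (noise_sd_log2) is added per sample; matrices are
    exponentiated to the linear scale.
    """
    rng = np.random.default_rng(cfg.seed)
    names = cfg.conversion_names

    tf_names = [t.name.upper() for t in cfg.tf_regulons]
    n_plain = cfg.n_genes - len(tf_names)
    genes = tf_names + [f"G{i + 1:05d}" for i in range(n_plain)]

    # -- plant signatures on the non-TF genes
    pool = rng.permutation(np.array(genes[len(tf_names):]))
    cursor = 0

    def take(k: int) -> frozenset[str]:
        nonlocal cursor
        out = frozenset(pool[cursor : cursor + k])
        cursor += k
        return out

    common_up = take(cfg.common_up)
    common_down = take(cfg.common_down)
    specific: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    for conv in names:
        n_up = math.ceil(cfg.specific_per_conversion / 2)
        specific[conv] = (take(n_up), take(cfg.specific_per_conversion - n_up))
    never_planted = list(pool[cursor:])

    # -- assign TFs to home conversions cyclically; effect sign alternates
    de_tfs: dict[str, set[str]] = {c: set() for c in names}
    tf_dirs: dict[str, dict[str, str]] = {c: {} for c in names}
    tf_home: dict[str, str] = {}
    tf_delta: dict[str, float] = {}
    for i, spec_tf in enumerate(cfg.tf_regulons):
        home = names[i % len(names)]
        tf_home[spec_tf.name.upper()] = home
        if spec_tf.effect_log2 != 0:
            sign = 1.0 if i % 2 == 0 else -1.0
            tf_delta[spec_tf.name.upper()] = sign * spec_tf.effect_log2
            de_tfs[home].add(spec_tf.name.upper())
            tf_dirs[home][spec_tf.name.upper()] = "up" if sign > 0 else "down"

    truth = GroundTruth(
        common_up=common_up,
        common_down=common_down,
        specific=specific,
        de_tfs={c: frozenset(s) for c, s in de_tfs.items()},
        universe=frozenset(genes),
        _tf_dirs=tf_dirs,
    )

    # -- per-conversion planted log2 deltas
    delta: dict[str, pd.Series] = {}
    for conv in names:
        d = pd.Series(0.0, index=genes)
        planted = truth.planted_de(conv)
        for g, direction in planted.items():
            if g in tf_delta and tf_home[g] == conv:
                d[g] = tf_delta[g]
            else:
                d[g] = cfg.effect_log2 if direction == "up" else -cfg.effect_log2
        delta[conv] = d

    # -- regulons: a fraction from the home conversion's planted DE genes,
    #    the rest from never-planted genes
    regulons: dict[str, frozenset[str]] = {}
    for spec_tf in cfg.tf_regulons:
        tf = spec_tf.name.upper()
        home = tf_home[tf]
        planted_pool = sorted(set(truth.planted_de(home)) - {tf})
        n_de = round(spec_tf.de_fraction * spec_tf.regulon_size)
        n_de = min(n_de, len(planted_pool))
        chosen = set(rng.choice(planted_pool, size=n_de, replace=False)) if n_de else set()
        n_bg = spec_tf.regulon_size - len(chosen)
        chosen |= set(rng.choice(never_planted, size=n_bg, replace=False))
        regulons[tf] = frozenset(chosen)
    regulon_db = RegulonDB(sets=regulons, universe=frozenset(genes),
                           descriptions={t: "planted regulon" for t in regulons})

    # -- expression matrices
    datasets: list[ExpressionDataset] = []
    for conv, n_ds, reps in cfg.conversions:
        for k in range(n_ds):
            ds_id = f"{conv}_d{k + 1}"
            base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=cfg.n_genes)
            d = delta[conv].to_numpy()
            log2 = np.empty((cfg.n_genes, 2 * reps))
            samples, groups = [], {}
            for j in range(reps):
                log2[:, j] = base + rng.normal(0.0, cfg.noise_sd_log2, size=cfg.n_genes)
                s = f"{ds_id}_origin{j + 1}"
                samples.append(s)
                groups[s] = "origin"
            for j in range(reps):
                log2[:, reps + j] = base + d + rng.normal(0.0, cfg.noise_sd_log2, size=cfg.n_genes)
                s = f"{ds_id}_target{j + 1}"
                samples.append(s)
                groups[s] = "target"
            values = pd.DataFrame(np.exp2(log2), index=genes, columns=samples)
            datasets.append(
                ExpressionDataset(dataset_id=ds_id, values=values, groups=groups,
                                  organism="synthetic")
            )

    term_db = generate_term_db(truth, n_decoy_terms=20, seed=int(rng.integers(2**31)))
    return datasets, regulon_db, term_db, truth


def generate_term_db(truth: GroundTruth, n_decoy_terms: int, seed: int) -> TermDB:
    """Term database with one term per planted signature (its genes plus a
    little random padding) and uniformly drawn decoy terms."""
    rng = np.random.default_rng(seed)
    universe = sorted(truth.universe)
    terms: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}

    def add(name: str, members: frozenset[str], what: str) -> None:
        pad = set(rng.choice(universe, size=5, replace=False))
        terms[name] = frozenset(members | pad)
        desc[name] = what

    add("TERM_COMMON_UP", truth.common_up, "planted common up signature")
    add("TERM_COMMON_DOWN", truth.common_down, "planted common down signature")
    for conv, (up, down) in truth.specific.items():
        add(f"TERM_SPECIFIC_{conv.upper()}", up | down, f"planted {conv}-specific signature")
    for i in range(n_decoy_terms):
        size = int(rng.integers(15, 50))
        terms[f"TERM_DECOY{i + 1:03d}"] = frozenset(rng.choice(universe, size=size, replace=False))
        desc[f"TERM_DECOY{i + 1:03d}"] = "decoy term"
    return TermDB(sets=terms, universe=frozenset(universe), descriptions=desc)


def write_study(
    datasets: list[ExpressionDataset],
    regulon_db: RegulonDB,
    term_db: TermDB,
    truth: GroundTruth,
    conversions: dict[str, str],
    outdir: str | Path,
) -> None:
    """Write a generated study as TSV matrices + groups files, GMT databases,
    a conversions manifest, and a planted-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        write_expression_matrix(ds, outdir / f"{ds.dataset_id}.matrix.tsv",
                                outdir / f"{ds.dataset_id}.groups.tsv")
    write_gmt(regulon_db, outdir / "regulons.gmt")
    write_gmt(term_db, outdir / "terms.gmt")
    with open(outdir / "conversions.tsv", "w", newline="\n") as fh:
        for ds in datasets:
            fh.write(f"{ds.dataset_id}\t{conversions[ds.dataset_id]}\n")
    with open(outdir / "truth.tsv", "w", newline="\n") as fh:
        for g in sorted(truth.common_up):
            fh.write(f"common\tup\t{g}\n")
        for g in sorted(truth.common_down):
            fh.write(f"common\tdown\t{g}\n")
        for conv in sorted(truth.specific):
            up, down = truth.specific[conv]
            for g in sorted(up):
                fh.write(f"specific:{conv}\tup\t{g}\n")
            for g in sorted(down):
                fh.write(f"specific:{conv}\tdown\t{g}\n")
        for conv in sorted(truth.de_tfs):
            for tf in sorted(truth.de_tfs[conv]):
                fh.write(f"de_tf:{conv}\t{truth.tf_directions(conv)[tf]}\t{tf}\n")


def conversion_map(cfg: StudyConfig) -> dict[str, str]:
    """Dataset id → conversion name for a config's study layout."""
    return {
        f"{conv}_d{k + 1}": conv
        for conv, n_ds, _ in cfg.conversions
        for k in range(n_ds)
    }
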