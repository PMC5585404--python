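"""Hierarchical clustering with uncentered correlation.

Similarity between two expression vectors is the uncentered correlation
Σxy/(‖x‖·‖y‖) — the cosine of the angle between them, with no
mean-centering — so that vectors differing only by a positive scale factor
are maximally similar. Agglomeration uses average linkage on the distance
d = 1 − similarity, with ties in the minimum-distance pair broken by the
smallest (i, j) index pair so that results are bit-reproducible.

Typical inputs are genes × datasets log2 fold-change matrices (the red/green
up–down clustergrams of conversion studies) or genes × samples intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def uncentered_correlation(x, y) -> float:
    """Cosine-form similarity Σxy/(‖x‖‖y‖) in [-1, 1], without centering."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm vector has undefined uncentered correlation")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def distance_matrix(m: np.ndarray) -> np.ndarray:
    """Pairwise 1 − uncentered correlation over the rows of ``m``."""
    m = np.asarray(m, dtype=float)
    norms = np.linalg.norm(m, axis=1)
    if (norms == 0).any():
        bad = list(np.where(norms == 0)[0])
        raise ValueError(f"zero-norm rows {bad}: drop them before clustering")
    sim = (m @ m.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ClusterResult:
    """Agglomeration result over n items.

    Nodes are numbered like the leaves-then-internals convention: leaves
    0..n−1, internal nodes n..2n−2 in merge order. ``merges`` holds one
    (node_a, node_b, similarity_at_join) triple per agglomeration step;
    ``leaf_order`` is the dendrogram's left-to-right leaf permutation.
    ``labels`` are the input row labels, in input order.
    """

    leaf_order: list[int]
    merges: list[tuple[int, int, float]]
    labels: list[str]
    axis: str = "genes"

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


_LINKAGES = ("average", "single", "complete")


def cluster(
    matrix: pd.DataFrame | np.ndarray,
    linkage: str = "average",
    axis: str = "genes",
) -> ClusterResult:
    """Agglomerative clustering of the rows of ``matrix``.

    Lance–Williams agglomeration on d = 1 − uncentered correlation. At each
    step the minimum-distance active pair is merged; exact ties go to the
    smallest (i, j) node-index pair. Average linkage weights by cluster
    sizes, so inter-cluster distance equals the mean of all original
    cross-pair distances.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if isinstance(matrix, pd.DataFrame):
        labels = [str(i) for i in matrix.index]
        m = matrix.to_numpy(dtype=float)
    else:
        m = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(m.shape[0])]
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least two items to cluster")

    d = distance_matrix(m)
    # distances between active nodes, keyed by node id (leaves 0..n-1)
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        (a, b), dmin = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = n + step
        merges.append((a, b, 1.0 - dmin))
        members[new] = members.pop(a) + members.pop(b)
        active -= {a, b}
        for c in sorted(active):
            dac = dist.pop((min(a, c), max(a, c)))
            dbc = dist.pop((min(b, c), max(b, c)))
            if linkage == "average":
                dnew = (size[a] * dac + size[b] * dbc) / (size[a] + size[b])
            elif linkage == "single":
                dnew = min(dac, dbc)
            else:
                dnew = max(dac, dbc)
            dist[(c, new)] = dnew
        del dist[(a, b)]
        size[new] = size[a] + size[b]
        active.add(new)

    leaf_order = members[2 * n - 2]
    return ClusterResult(leaf_order=leaf_order, merges=merges, labels=labels, axis=axis)
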