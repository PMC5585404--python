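"""Gene-set (ontology term) over/under-representation.

Terms are scored with a two-sided hypergeometric test — by convention
twice the smaller tail probability, capped at 1 (the doubling convention
used by ClueGO-style tools; a minimum-likelihood alternative is available
for sensitivity checks) — and corrected across the term family with the
Holm (Bonferroni step-down) procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from convmine.io import TermDB

log = logging.getLogger(__name__)


@dataclass
class TermResult:
    term: str
    name: str
    overlap: int
    term_size: int
    p_two_sided: float
    p_adjusted: float
    direction: str  # 'enriched' | 'depleted'
    significant: bool


def hypergeom_two_sided(
    overlap: int,
    term_size: int,
    n_selected: int,
    n_universe: int,
    method: str = "doubling",
) -> tuple[float, str]:
    """Two-sided hypergeometric probability and the over/under flag.

    ``doubling`` (default): p = min(1, 2·min(P(X >= k), P(X <= k))).
    ``minlike``: sum of P(X = j) over all j with P(X = j) <= P(X = k)
    (the minimum-likelihood two-sided convention).
    The flag is 'enriched' when the overlap exceeds its expectation
    n·K/N, else 'depleted'.
    """
    if not (0 <= overlap <= min(term_size, n_selected)):
        raise ValueError("overlap must be within [0, min(term_size, n_selected)]")
    if term_size > n_universe or n_selected > n_universe:
        raise ValueError("term_size and n_selected must not exceed the universe")
    dist = stats.hypergeom(n_universe, term_size, n_selected)
    upper = float(dist.sf(overlap - 1))
    lower = float(dist.cdf(overlap))
    if method == "doubling":
        p = min(1.0, 2.0 * min(upper, lower))
    elif method == "minlike":
        kmin = max(0, n_selected - (n_universe - term_size))
        kmax = min(term_size, n_selected)
        ks = np.arange(kmin, kmax + 1)
        pmf = dist.pmf(ks)
        p = float(min(1.0, pmf[pmf <= dist.pmf(overlap) * (1 + 1e-9)].sum()))
    else:
        raise ValueError(f"unknown method {method!r}")
    flag = "enriched" if overlap > n_selected * term_size / n_universe else "depleted"
    return p, flag


def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Holm (Bonferroni step-down) adjusted p-values, in input order.

    Equivalent to sorting ascending, taking the running maximum of
    (m − i + 1)·p_(i), capping at 1, and mapping back.
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def term_enrichment(
    genes: Iterable[str],
    db: TermDB,
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    method: str = "doubling",
) -> list[TermResult]:
    """Two-sided term over/under-representation for one query gene list.

    The family for Holm correction is all terms of the database tested for
    this query; terms with adjusted p < alpha are flagged significant.
    Query genes outside the universe are dropped with a log message.
    Results sorted by (adjusted p, raw p, term id).
    """
    if not db.terms:
        raise ValueError("empty term database")
    uni = frozenset(universe) if universe is not None else db.universe
    query = frozenset(genes)
    dropped = query - uni
    if dropped:
        log.info("%d query genes outside the universe dropped", len(dropped))
    query &= uni

    raw: list[tuple[str, int, int, float, str]] = []
    for term in sorted(db.terms):
        members = db.terms[term] & uni
        if not members:
            continue
        k = len(members & query)
        p, flag = hypergeom_two_sided(k, len(members), len(query), len(uni), method=method)
        raw.append((term, k, len(members), p, flag))
    adj = holm_adjust([r[3] for r in raw])
    results = [
        TermResult(
            term=t,
            name=db.descriptions.get(t, t),
            overlap=k,
            term_size=sz,
            p_two_sided=p,
            p_adjusted=pa,
            direction=flag,
            significant=pa < alpha,
        )
        for (t, k, sz, p, flag), pa in zip(raw, adj)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_two_sided, r.term))
    return results
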