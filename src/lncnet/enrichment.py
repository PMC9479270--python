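"""Hypergeometric gene-set over-representation analysis.

For a query of n ids drawn from a universe of N annotated ids, a gene set
with K members in the universe, and an observed overlap of k ids, the
enrichment p-value is the upper tail of the hypergeometric distribution,
P(X >= k) — one-sided, over-representation only. Benjamini-Hochberg
q-values are computed across all tested sets. The universe should normally
be the detection universe (all annotated transcripts on the array), not the
genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from lncnet.exceptions import ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int          # k
    query_size: int       # n
    set_size: int         # K (within the universe)
    universe_size: int    # N
    p_value: float
    q_value: float
    overlap_ids: frozenset[str]


def hypergeom_pvalue(k: int, n_query: int, k_set: int, n_universe: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k)."""
    if min(k, n_query, k_set, n_universe) < 0 or n_universe == 0:
        raise ParameterError("hypergeometric arguments must be non-negative, N > 0")
    return float(stats.hypergeom.sf(k - 1, n_universe, k_set, n_query))


def hypergeom_enrich(query, sets: dict[str, set[str]],
                     universe) -> list[EnrichmentResult]:
    """Over-representation test of ``query`` against every set in ``sets``.

    Query ids outside the universe are dropped with a warning; an empty
    query after restriction is a :class:`ParameterError`. Sets with no
    member in the universe are skipped and absent from the output. Results
    are sorted by p ascending, ties by set name.
    """
    universe = set(universe)
    if not universe:
        raise ParameterError("universe must be non-empty")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning("dropping %d query id(s) outside the universe (first: %s)",
                       len(outside), sorted(outside)[0])
    query &= universe
    if not query:
        raise ParameterError("query is empty after restriction to the universe")

    n, big_n = len(query), len(universe)
    tested = []
    for name in sorted(sets):
        members = sets[name] & universe
        if not members:
            continue
        overlap = query & members
        p = hypergeom_pvalue(len(overlap), n, len(members), big_n)
        tested.append((name, overlap, members, p))
    if not tested:
        return []
    q = multipletests([p for *_, p in tested], method="fdr_bh")[1]
    results = [
        EnrichmentResult(set_name=name, overlap=len(overlap), query_size=n,
                         set_size=len(members), universe_size=big_n,
                         p_value=p, q_value=float(qv),
                         overlap_ids=frozenset(overlap))
        for (name, overlap, members, p), qv in zip(tested, q)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
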