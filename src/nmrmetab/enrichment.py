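"""Metabolite-set over-representation analysis and co-membership networks.

Over-representation uses the hypergeometric upper tail: with a universe of
N background compounds, a pathway of n members and a matched query of K
compounds, the p-value of observing k or more query compounds in the
pathway is P(X >= k) for X ~ Hypergeometric(N, n, K).  The tail sum is
accumulated in log space for numerical stability.  The co-membership
network links compounds sharing at least one pathway, weighted by the
number of shared pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .library import PathwayDB
from .stocsy import adjust_pvalues

__all__ = [
    "EnrichmentRow",
    "hypergeom_upper_tail",
    "enrich",
    "enrichment_table",
    "cooccurrence_network",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    pathway_name: str
    p_value: float
    adjusted_p: float
    in_background: int
    in_set: int


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, n successes, K draws)."""
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k <= 0:
        return 1.0
    js = np.arange(k, min(K, n) + 1)
    logp = (
        _log_comb(n, js) + _log_comb(N - n, K - js) - _log_comb(N, K)
    )
    return float(min(1.0, np.exp(logsumexp(logp))))


def enrich(
    query: set[str], db: PathwayDB, method: str = "bh"
) -> list[EnrichmentRow]:
    """One row per pathway overlapping the query, sorted by ascending p.

    Compounds outside the universe are dropped (logged); pathways with no
    overlap are not tested, and the adjustment multiplicity is the number
    of tested pathways.  Ties in p break by pathway id.
    """
    query = set(query)
    effective = query & db.universe
    dropped = len(query) - len(effective)
    if dropped:
        log.info("%d query compounds outside the universe dropped", dropped)
    if not effective:
        raise ValueError("no query compounds in the background universe")
    K = len(effective)
    N = len(db.universe)
    tested = []
    for pid, rec in db.pathways.items():
        hit = effective & rec["compounds"]
        if hit:
            n = len(rec["compounds"])
            p = hypergeom_upper_tail(len(hit), K, n, N)
            tested.append((p, pid, rec["name"], n, len(hit)))
    if not tested:
        return []
    p_adj = adjust_pvalues(np.array([t[0] for t in tested]), method=method)
    rows = [
        EnrichmentRow(pid, name, p, float(pa), n, k)
        for (p, pid, name, n, k), pa in zip(tested, p_adj)
    ]
    rows.sort(key=lambda r: (r.p_value, r.pathway_id))
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """DataFrame in the standard report layout (ID, Pathway, p-value,
    Adjusted p-value, In background, In set)."""
    return pd.DataFrame(
        [
            {
                "ID": r.pathway_id,
                "Pathway": r.pathway_name,
                "p-value": r.p_value,
                "Adjusted p-value": r.adjusted_p,
                "In background": r.in_background,
                "In set": r.in_set,
            }
            for r in rows
        ]
    )


def cooccurrence_network(
    query: set[str], db: PathwayDB, log2_fc: dict[str, float] | None = None
) -> nx.Graph:
    """Undirected compound network: edge (a, b) iff a and b share >= 1
    pathway, weight = number of shared pathways; nodes annotated with the
    direction of change when a log2 fold-change map is supplied."""
    query = set(query) & db.universe
    membership: dict[str, set[str]] = {c: set() for c in query}
    for pid, rec in db.pathways.items():
        for c in rec["compounds"] & query:
            membership[c].add(pid)
    g = nx.Graph()
    for c in sorted(query):
        attrs = {}
        if log2_fc is not None and c in log2_fc:
            val = log2_fc[c]
            attrs["log2_fc"] = float(val)
            attrs["direction"] = "increased" if val > 0 else "decreased"
        g.add_node(c, **attrs)
    for a, b in combinations(sorted(query), 2):
        shared = membership[a] & membership[b]
        if shared:
            g.add_edge(a, b, weight=len(shared))
    return g
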