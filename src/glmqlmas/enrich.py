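"""Over-representation analysis (ORA) of significant gene lists.

For a significant list of size n drawn from a universe of size N, a gene
set with K universe members and k overlap genes is scored by the
hypergeometric upper tail P(X >= k); q-values are BH-adjusted p within the
tested collection. This is an overlap test (the enrichment style that
reports "overlap genes" per set), not the ranked running-sum statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSetCollection, IntegrityError
from .glm import adjust_pvalues

log = logging.getLogger("glmqlmas")


@dataclass
class EnrichmentResult:
    """One tested set: name, collection tag, overlap members and the
    hypergeometric test inputs (k, K, n, N) with p and BH q."""

    term: str
    collection: str
    overlap: list[str]
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float = float("nan")


def ora(
    sig_genes: set[str] | list[str],
    universe: set[str] | list[str],
    sets: GeneSetCollection,
    collection_name: str = "sets",
    min_size: int = 5,
    max_size: int = 2000,
    restrict_universe: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric ORA of ``sig_genes`` against each set.

    The working universe is the supplied universe intersected with the
    union of collection members (the conservative ORA convention) unless
    ``restrict_universe`` is False. Significant genes outside the universe
    are dropped with a warning. Sets whose universe membership K falls
    outside [min_size, max_size] are skipped. Results are sorted by q,
    then p, then term name.
    """
    universe = set(universe)
    if not universe:
        raise IntegrityError("empty universe")
    if restrict_universe:
        member_union = set()
        for _, members in sets:
            member_union.update(members)
        universe = universe & member_union
        if not universe:
            log.warning("universe does not overlap any collection member")
            return []
    sig = set(sig_genes)
    outside = sig - universe
    if outside:
        log.warning("%d significant gene(s) outside the universe dropped", len(outside))
        sig &= universe

    N, n = len(universe), len(sig)
    results = []
    for name, members in sets:
        in_universe = universe.intersection(members)
        K = len(in_universe)
        if not min_size <= K <= max_size:
            continue
        overlap = sorted(sig & in_universe)
        k = len(overlap)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(name, collection_name, overlap, k, K, n, N, min(p, 1.0))
        )
    if results:
        qs = adjust_pvalues([r.p for r in results], "BH")
        for r, q in zip(results, qs):
            r.q = float(q)
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


def top_terms(results: list[EnrichmentResult], n: int = 10, by: str = "q") -> list[EnrichmentResult]:
    """First ``n`` results after sorting by ``by`` (q or p), ties broken
    lexicographically by term name."""
    if by not in ("q", "p"):
        raise ValueError("by must be 'q' or 'p'")
    ordered = sorted(results, key=lambda r: (getattr(r, by), r.p, r.term))
    return ordered[:n]


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "collection": [r.collection for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "overlap_genes": [",".join(r.overlap) for r in results],
        }
    )
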