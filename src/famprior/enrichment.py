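"""Gene-set over-representation with the hypergeometric test and BH FDR.

For a background universe of M genes, a pathway with K members and a query
set of n genes sharing k hits, the enrichment p-value is the upper tail
P(X >= k) of the hypergeometric(M, K, n) distribution.  P-values are
adjusted across all tested pathways with the Benjamini-Hochberg step-up
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import GeneSetCollection

__all__ = ["EnrichmentRow", "hypergeom_upper", "bh_fdr", "enrich"]


def hypergeom_upper(k: int, n: int, K: int, M: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts pathway members among ``n`` genes drawn without replacement
    from a background of ``M`` genes of which ``K`` are in the pathway.
    Computed via the survival function in log-stable form.
    """
    if not (0 <= K <= M):
        raise ValueError(f"need 0 <= K <= M, got K={K}, M={M}")
    if not (0 <= n <= M):
        raise ValueError(f"need 0 <= n <= M, got n={n}, M={M}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, M, K, n)))


def bh_fdr(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass(slots=True)
class EnrichmentRow:
    """One pathway's over-representation result."""

    pathway: str
    K: int  # pathway size within the background
    M: int  # background size
    n: int  # query size within the background
    k: int  # hits
    ratio: float  # K / M
    p: float
    fdr: float
    hit_genes: List[str]

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError("hit count inconsistent with pathway/query sizes")


def enrich(
    query_genes: Set[str] | Sequence[str],
    collection: GeneSetCollection,
    background: Optional[Set[str] | Sequence[str]] = None,
) -> List[EnrichmentRow]:
    """Over-representation of ``query_genes`` in every pathway of the
    collection.

    The background defaults to the collection's declared universe (or the
    union of all its sets).  The query is restricted to the background
    before testing; pathway sizes K are likewise counted within the
    background.  Every pathway with K >= 1 is tested (so the BH adjustment
    spans all m tested pathways); only rows with k >= 1 hits are returned,
    sorted by ascending p.
    """
    bg = frozenset(
        g.upper() for g in (background if background is not None else collection.universe())
    )
    if not bg:
        raise ValueError("empty background universe")
    query = frozenset(g.upper() for g in query_genes) & bg
    M, n = len(bg), len(query)

    tested: List[tuple] = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & bg
        K = len(members)
        if K == 0:
            continue
        hits = sorted(query & members)
        tested.append((name, K, hits))
    if not tested:
        return []
    pvals = [hypergeom_upper(len(hits), n, K, M) for _, K, hits in tested]
    fdrs = bh_fdr(pvals)

    rows = [
        EnrichmentRow(
            pathway=name,
            K=K,
            M=M,
            n=n,
            k=len(hits),
            ratio=K / M,
            p=p,
            fdr=fdr,
            hit_genes=hits,
        )
        for (name, K, hits), p, fdr in zip(tested, pvals, fdrs)
        if hits
    ]
    rows.sort(key=lambda r: (r.p, r.pathway))
    return rows


def enrichment_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tabular view of enrichment rows (ratio reported to 4 decimals)."""
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in rows],
            "ratio": [round(r.ratio, 4) for r in rows],
            "pathway_size": [r.K for r in rows],
            "hits": [r.k for r in rows],
            "query_size": [r.n for r in rows],
            "background_size": [r.M for r in rows],
            "p_value": [r.p for r in rows],
            "fdr": [r.fdr for r in rows],
            "hit_genes": [",".join(r.hit_genes) for r in rows],
        }
    )
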