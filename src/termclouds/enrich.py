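"""Local over-representation testing of a gene list.

For a universe of ``N`` genes, a term annotating ``K`` of them, and a query
of ``n`` genes with ``k`` members of the term, the over-representation
p-value is the hypergeometric upper tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

i.e. a one-sided Fisher test. All terms overlapping the query (k >= 1) are
tested and the p-values adjusted with the Benjamini–Hochberg step-up
procedure across the tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .ontology import SIZE_UNKNOWN, AnnotationSet, GeneList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichedTerm:
    """One term's enrichment record.

    ``N``/``K``/``n``/``k`` are the universe size, term size, query size and
    overlap.  Records imported from a pre-computed table carry ``N = n = k = 0``
    and may carry ``K = SIZE_UNKNOWN`` (exempt from size filtering).
    """

    term_id: str
    term_name: str
    source: str
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_raw <= 1.0):
            raise ValueError(f"p_raw must be in (0, 1], got {self.p_raw}")
        if not (0.0 < self.p_adj <= 1.0):
            raise ValueError(f"p_adj must be in (0, 1], got {self.p_adj}")

    @property
    def size_exempt(self) -> bool:
        return self.K == SIZE_UNKNOWN


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Return ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

    Computed via the scipy survival function, which accumulates the tail in
    log space; ``k = 0`` returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"invalid hypergeometric bounds: N={N}, K={K}, n={n}, k={k} "
            f"(need 0 <= k <= min(K, n) and K, n <= N)"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    if p == 0.0:
        # extreme tail: recover through the log-space survival function, and
        # keep the result strictly positive even below double precision
        p = float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))
        if p == 0.0:
            p = float(np.nextafter(0, 1))
    return min(p, 1.0)


def bh_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _sort_key(t: EnrichedTerm):
    # significance first; ties broken by term size (larger = more generic
    # context retained), then id for full determinism
    return (t.p_adj, t.p_raw, -t.K, t.term_id)


def sort_terms(terms: Sequence[EnrichedTerm]) -> list[EnrichedTerm]:
    return sorted(terms, key=_sort_key)


def enrich(
    query: GeneList | Sequence[str],
    ann: AnnotationSet,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> list[EnrichedTerm]:
    """Test *query* against every term of *ann* and keep significant hits.

    Parameters
    ----------
    query:
        A :class:`~termclouds.ontology.GeneList` or a plain sequence of gene
        identifiers.  Genes outside the universe are ignored; an empty
        intersection with the universe is an error.
    alpha:
        Keep terms with ``p_adj <= alpha``.  ``alpha = 1`` keeps everything
        tested.
    correction:
        ``"fdr_bh"`` (default) or ``"bonferroni"``.

    Returns
    -------
    list of :class:`EnrichedTerm`, sorted ascending by ``p_adj`` then
    ``p_raw`` (ties: larger term, then lexicographic id).
    """
    genes = tuple(query.genes) if isinstance(query, GeneList) else tuple(query)
    qset = set(genes) & ann.universe
    if not qset:
        raise ValueError(
            "query has no genes in the annotation universe — check gene "
            "identifiers or supply a matching universe"
        )
    dropped = len(set(genes)) - len(qset)
    if dropped:
        logger.info("%d query gene(s) outside the universe ignored", dropped)

    N = len(ann.universe)
    n = len(qset)
    tested: list[EnrichedTerm] = []
    for tid in ann.term_ids:
        tgenes = ann.term_genes[tid]
        k = len(qset & tgenes)
        if k == 0:
            continue
        K = len(tgenes)
        p = hypergeom_upper_tail(N, K, n, k)
        tested.append(
            EnrichedTerm(
                term_id=tid,
                term_name=ann.term_names[tid],
                source=ann.source[tid],
                N=N, K=K, n=n, k=k,
                p_raw=p, p_adj=p,
            )
        )
    if not tested:
        return []
    if correction == "fdr_bh":
        adj = bh_adjust([t.p_raw for t in tested])
    elif correction == "bonferroni":
        adj = np.minimum(np.asarray([t.p_raw for t in tested]) * len(tested), 1.0)
    elif correction == "none":
        adj = np.asarray([t.p_raw for t in tested])
    else:
        raise ValueError(f"unknown correction {correction!r}")
    tested = [replace(t, p_adj=float(a)) for t, a in zip(tested, adj)]
    kept = [t for t in tested if t.p_adj <= alpha]
    return sort_terms(kept)
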