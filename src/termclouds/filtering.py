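"""Reduce an enrichment result to a displayable term set.

A typical characterisation of a gene list yields hundreds of significant
terms; a word cloud can show a few dozen.  Four filters are applied, in a
fixed order:

1. **sources** — keep only allowed annotation sources (default BP, KEGG,
   REAC);
2. **size** — drop terms that are too generic or too specific: retained iff
   ``min_size < term_size < max_size`` (strict; defaults 50 and 1000);
3. **hierarchy** — group significant terms that share direct parents (or
   where one is the other's direct parent) and keep only the most
   significant member of each group;
4. **cap** — keep at most ``max_terms`` (default 30) most significant terms.

The cap comes last so redundancy removal cannot be defeated by many related
terms filling the quota.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .enrich import EnrichedTerm, sort_terms

DEFAULT_SOURCES = frozenset({"BP", "KEGG", "REAC"})


@dataclass
class FilterConfig:
    """Parameters of the term-filtering pipeline.

    ``min_size``/``max_size`` are *exclusive* bounds on the number of genes
    annotated to a term; ``max_terms`` caps the final list; ``sources`` is
    the set of allowed annotation source labels.
    """

    min_size: int = 50
    max_size: int = 1000
    max_terms: int = 30
    sources: frozenset[str] = field(default_factory=lambda: DEFAULT_SOURCES)

    def __post_init__(self) -> None:
        if not (0 <= self.min_size < self.max_size):
            raise ValueError(f"need 0 <= min_size < max_size, got {self.min_size}, {self.max_size}")
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        self.sources = frozenset(self.sources)


def filter_sources(
    terms: Sequence[EnrichedTerm], cfg: FilterConfig | None = None
) -> list[EnrichedTerm]:
    """Keep only terms whose source label is allowed."""
    cfg = cfg or FilterConfig()
    return [t for t in terms if t.source in cfg.sources]


def filter_size(
    terms: Sequence[EnrichedTerm], cfg: FilterConfig | None = None
) -> list[EnrichedTerm]:
    """Keep terms with ``min_size < K < max_size``; size-exempt terms pass."""
    cfg = cfg or FilterConfig()
    return [
        t for t in terms
        if t.size_exempt or cfg.min_size < t.K < cfg.max_size
    ]


def _group_key(t: EnrichedTerm):
    # smallest adjusted p wins; ties: raw p, then the larger term, then id
    return (t.p_adj, t.p_raw, -t.K, t.term_id)


def filter_hierarchy(
    terms: Sequence[EnrichedTerm],
    parents: Mapping[str, set[str]],
    ancestors: bool = False,
) -> list[EnrichedTerm]:
    """Collapse groups of related terms to their most significant member.

    Two significant terms are related when they share at least one parent or
    one is the parent of the other.  With ``ancestors=False`` (default) only
    *direct* parents count; with ``ancestors=True`` the full is_a closure is
    used.  Groups are the connected components of the resulting relatedness
    graph; exactly one term per component survives.  Input order is
    preserved among survivors.
    """
    if not terms:
        return []
    up = _ancestor_closure(parents) if ancestors else {
        c: frozenset(p) for c, p in parents.items()
    }
    ids = [t.term_id for t in terms]
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        pa = up.get(a, frozenset())
        for b in ids[i + 1:]:
            pb = up.get(b, frozenset())
            if (pa & pb) or (b in pa) or (a in pb):
                g.add_edge(a, b)
    by_id = {t.term_id: t for t in terms}
    survivors: set[str] = set()
    for comp in nx.connected_components(g):
        best = min((by_id[i] for i in comp), key=_group_key)
        survivors.add(best.term_id)
    return [t for t in terms if t.term_id in survivors]


def _ancestor_closure(parents: Mapping[str, set[str]]) -> dict[str, frozenset[str]]:
    memo: dict[str, frozenset[str]] = {}

    def closure(t: str, trail: tuple[str, ...] = ()) -> frozenset[str]:
        if t in memo:
            return memo[t]
        if t in trail:
            raise ValueError(f"cycle through term {t!r}")
        acc: set[str] = set()
        for p in parents.get(t, ()):  # DAG: union of parents and their closures
            acc.add(p)
            acc |= closure(p, trail + (t,))
        memo[t] = frozenset(acc)
        return memo[t]

    for t in parents:
        closure(t)
    return memo


def cap_top_n(
    terms: Sequence[EnrichedTerm], cfg: FilterConfig | None = None
) -> list[EnrichedTerm]:
    """Keep the ``max_terms`` most significant terms (defensively re-sorted)."""
    cfg = cfg or FilterConfig()
    return sort_terms(terms)[: cfg.max_terms]


def filter_terms(
    terms: Sequence[EnrichedTerm],
    parents: Mapping[str, set[str]] | None = None,
    cfg: FilterConfig | None = None,
    ancestors: bool = False,
) -> list[EnrichedTerm]:
    """Run the full pipeline: sources → size → hierarchy → cap."""
    cfg = cfg or FilterConfig()
    out = filter_sources(terms, cfg)
    out = filter_size(out, cfg)
    out = filter_hierarchy(out, parents or {}, ancestors=ancestors)
    return cap_top_n(out, cfg)
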