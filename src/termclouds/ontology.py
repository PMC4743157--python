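"""Gene-set annotations and ontology structure.

The enrichment engine needs three things: a mapping from functional terms to
the genes annotated to them, the parent structure of the term hierarchy (for
redundancy filtering), and a gene *universe* that defines the background of
the over-representation test.  This module parses the standard plain-text
carriers of that information — GMT gene-set files, OBO ontologies (``is_a``
relations only) and two-column child/parent edge lists — and bundles them
into an :class:`AnnotationSet`.

Gene identifiers are opaque, case-sensitive strings; no identifier
conversion is performed (a two-column mapping TSV can be applied with
:func:`apply_id_map` as a preprocessing step).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Term-size sentinel for records that carry no size information (rows of a
#: user-supplied term table without a size column).  Terms with this size are
#: exempt from size filtering.
SIZE_UNKNOWN = -1


class ParseError(ValueError):
    """A structural problem in an input file (malformed line, cycle, ...)."""


@dataclass
class AnnotationSet:
    """Term → gene annotations plus term parent edges and source labels.

    Parameters
    ----------
    term_genes:
        Mapping from term id to the set of annotated gene identifiers.
    term_names:
        Mapping from term id to a human-readable phrase.
    parents:
        Mapping from term id to the set of *direct* parent term ids.
        Parents referencing unknown terms are dropped with a warning.
    source:
        Mapping from term id to a source label such as ``"BP"``, ``"KEGG"``
        or ``"REAC"``.  Terms without an entry get ``DEFAULT_SOURCE``.
    universe:
        The background gene set of the enrichment test.  Defaults to the
        union of all annotated genes.
    """

    DEFAULT_SOURCE = "BP"

    term_genes: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set[str]] = field(default_factory=dict)
    source: dict[str, str] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for tid, genes in list(self.term_genes.items()):
            if not genes:
                raise ValueError(f"term {tid!r} has no annotated genes")
        if not self.universe:
            self.universe = set().union(*self.term_genes.values()) if self.term_genes else set()
        else:
            missing = {
                g for genes in self.term_genes.values() for g in genes if g not in self.universe
            }
            if missing:
                raise ValueError(
                    f"{len(missing)} annotated gene(s) missing from the supplied universe, "
                    f"e.g. {sorted(missing)[:3]}"
                )
        known = set(self.term_genes)
        cleaned: dict[str, set[str]] = {}
        for child, pars in self.parents.items():
            unknown = pars - known
            if unknown:
                logger.warning(
                    "dropping %d unknown parent(s) of term %s: %s",
                    len(unknown), child, sorted(unknown)[:5],
                )
            kept = pars & known
            if kept:
                cleaned[child] = kept
        self.parents = cleaned
        self.term_names = {t: self.term_names.get(t, t) for t in known}
        self.source = {t: self.source.get(t, self.DEFAULT_SOURCE) for t in known}

    @property
    def term_ids(self) -> list[str]:
        return list(self.term_genes)

    def term_size(self, term_id: str) -> int:
        return len(self.term_genes[term_id])


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free list of genes with a display label.

    ``side`` records how the list relates to its block: a lone list
    (``"single"``), one half of a loading split (``"positive"`` /
    ``"negative"``) or one half of a differential-expression split
    (``"up"`` / ``"down"``).
    """

    label: str
    genes: tuple[str, ...]
    side: str = "single"

    _SIDES = ("single", "positive", "negative", "up", "down")

    def __post_init__(self) -> None:
        if self.side not in self._SIDES:
            raise ValueError(f"side must be one of {self._SIDES}, got {self.side!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene list {self.label!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)


def parse_gmt(path: str | Path) -> AnnotationSet:
    """Parse a GMT gene-set file into an :class:`AnnotationSet`.

    Each non-empty line is ``term_id<TAB>description<TAB>gene1<TAB>gene2...``.
    Duplicate genes within a line are deduplicated; duplicate term ids across
    lines are an error.
    """
    term_genes: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 2 fields")
            tid, name, *genes = fields
            if tid in term_genes:
                raise ParseError(f"{path}:{lineno}: duplicate term id {tid!r}")
            gene_set = {g for g in genes if g}
            if not gene_set:
                logger.warning("%s:%d: term %s has no genes; skipped", path, lineno, tid)
                continue
            term_genes[tid] = gene_set
            term_names[tid] = name
    if not term_genes:
        logger.warning("%s: no gene sets parsed (empty file?)", path)
    return AnnotationSet(term_genes=term_genes, term_names=term_names)


def write_gmt(ann: AnnotationSet, path: str | Path) -> None:
    """Write the term → gene mapping of *ann* as a GMT file (sorted genes)."""
    with open(path, "w") as fh:
        for tid in ann.term_ids:
            genes = "\t".join(sorted(ann.term_genes[tid]))
            fh.write(f"{tid}\t{ann.term_names[tid]}\t{genes}\n")


def _check_dag(parents: Mapping[str, set[str]]) -> None:
    import networkx as nx

    g = nx.DiGraph()
    for child, pars in parents.items():
        for p in pars:
            if p == child:
                raise ParseError(f"self-loop on term {child!r}")
            g.add_edge(child, p)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return
    pretty = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
    raise ParseError(f"cycle in parent structure: {pretty}")


def parse_dag(path: str | Path) -> dict[str, set[str]]:
    """Parse parent edges from an OBO file or a two-column child/parent TSV.

    The format is sniffed: a file whose first non-blank line starts with
    ``format-version:`` or ``[Term]`` is read as OBO (``is_a`` relations
    only), anything else as TSV.  Self-loops and cycles are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        head = ""
        for line in fh:
            if line.strip():
                head = line.strip()
                break
    if head.startswith("format-version:") or head.startswith("[Term]"):
        parents = _parse_obo_edges(path)
    else:
        parents = _parse_tsv_edges(path)
    _check_dag(parents)
    return parents


def _parse_tsv_edges(path: Path) -> dict[str, set[str]]:
    parents: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            child, parent = fields
            if child == parent:
                raise ParseError(f"{path}:{lineno}: self-loop on term {child!r}")
            parents.setdefault(child, set()).add(parent)
    return parents


def _parse_obo_edges(path: Path) -> dict[str, set[str]]:
    import obonet

    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    parents: dict[str, set[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        if child == parent:
            raise ParseError(f"self-loop on term {child!r} in {path}")
        parents.setdefault(child, set()).add(parent)
    return parents


def parse_obo_names(path: str | Path) -> dict[str, str]:
    """Extract id → name from an OBO file (ignores everything else)."""
    import obonet

    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    return {tid: data.get("name", tid) for tid, data in graph.nodes(data=True)}


def parse_term_table(path: str | Path):
    """Read a pre-computed enrichment table (g:Profiler/DAVID-style TSV).

    Columns: term id, term name, p-value, term size (optional), source
    (optional).  The p-value is taken as already multiplicity-corrected
    upstream, so ``p_adj = p_raw = p``.  Rows without a size get the
    size-exempt sentinel and pass size filtering unchanged.
    """
    from .enrich import EnrichedTerm

    terms: list[EnrichedTerm] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected ≥3 columns (id, name, p)")
            tid, name, p_str = fields[:3]
            if lineno == 1 and _looks_like_header(p_str):
                continue
            try:
                p = float(p_str)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: p-value {p_str!r} is not a number") from exc
            if not (0.0 <= p <= 1.0) or math.isnan(p):
                raise ParseError(f"{path}:{lineno}: p-value {p} outside [0, 1]")
            size = SIZE_UNKNOWN
            if len(fields) >= 4 and fields[3].strip():
                size = int(fields[3])
                if size < 1:
                    raise ParseError(f"{path}:{lineno}: term size {size} < 1")
            source = fields[4].strip() if len(fields) >= 5 and fields[4].strip() else AnnotationSet.DEFAULT_SOURCE
            terms.append(
                EnrichedTerm(
                    term_id=tid, term_name=name, source=source,
                    N=0, K=size, n=0, k=0, p_raw=p, p_adj=p,
                )
            )
    return terms


def _looks_like_header(p_field: str) -> bool:
    try:
        float(p_field)
        return False
    except ValueError:
        return True


def write_term_table(terms: Sequence, path: str | Path) -> None:
    """Write enriched terms in the TSV dialect :func:`parse_term_table` reads."""
    with open(path, "w") as fh:
        fh.write("term_id\tterm_name\tp_adj\tterm_size\tsource\n")
        for t in terms:
            size = "" if t.K == SIZE_UNKNOWN else str(t.K)
            fh.write(f"{t.term_id}\t{t.term_name}\t{t.p_adj:.6g}\t{size}\t{t.source}\n")


def parse_universe(path: str | Path) -> set[str]:
    """Read a one-gene-per-line background file."""
    with open(path) as fh:
        genes = {line.strip() for line in fh if line.strip()}
    if not genes:
        raise ParseError(f"{path}: empty universe file")
    return genes


def apply_id_map(genes: Iterable[str], mapping_path: str | Path) -> list[str]:
    """Translate gene identifiers through a two-column TSV (old → new).

    Unmapped identifiers are kept unchanged; order is preserved and the
    result deduplicated (first occurrence wins).
    """
    table: dict[str, str] = {}
    with open(mapping_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{mapping_path}:{lineno}: expected 2 columns")
            table[fields[0]] = fields[1]
    seen: set[str] = set()
    out: list[str] = []
    for g in genes:
        h = table.get(g, g)
        if h not in seen:
            seen.add(h)
            out.append(h)
    return out
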