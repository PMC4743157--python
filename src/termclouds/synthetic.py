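"""Seeded synthetic-data generators.

Every pipeline stage is testable offline: these generators emulate the
shapes of the real inputs — a tree-structured annotation with log-uniform
term sizes and multi-word term names (to exercise long-phrase packing),
spiked enrichment queries, clustered time-series expression (stem-cell
differentiation style: profiles switching on in waves across time points),
class-separated expression for planted-signal recovery, and grouped
taxon-abundance counts (body-site style, Dirichlet-multinomial).

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ontology import AnnotationSet, GeneList
from .producers import ExpressionMatrix

_VOCAB = [
    "regulation", "positive", "negative", "cell", "cycle", "signal",
    "transduction", "membrane", "transport", "immune", "response",
    "development", "differentiation", "metabolic", "process", "organ",
    "morphogenesis", "adhesion", "apoptotic", "replication", "repair",
    "biosynthetic", "catabolic", "chromatin", "organization", "muscle",
    "cardiovascular", "system", "embryonic", "mesoderm", "proliferation",
    "protein", "phosphorylation", "kinase", "activity", "receptor",
    "pathway", "stress", "oxidative", "mitotic",
]

_SYLLABLES = [
    "lacto", "strepto", "actino", "bacter", "coccus", "bacillus", "myces",
    "prevo", "tella", "fuso", "clostri", "dium", "rickett", "spiro",
    "chaeta", "pseudo", "monas", "entero", "vibrio", "neisse", "ria",
    "coryne", "staphylo", "micro", "flavo",
]


def _term_name(rng: np.random.Generator) -> str:
    n_words = int(rng.integers(2, 6))
    return " ".join(rng.choice(_VOCAB, size=n_words, replace=False))


def _taxon_name(rng: np.random.Generator, i: int) -> str:
    parts = rng.choice(_SYLLABLES, size=2, replace=False)
    return ("".join(parts)).capitalize() + f" {i:02d}"


def make_annotation(
    n_terms: int = 200,
    n_genes: int = 5000,
    depth: int = 3,
    seed: int = 0,
) -> AnnotationSet:
    """A random tree-shaped annotation with log-uniform term sizes.

    Terms are organised in *depth* layers; layer-0 terms are parentless and
    each deeper term's gene set is a subset of its parent's.  Term sizes are
    log-uniform in [5, 2000] (clipped to the universe and to the parent),
    so sizes fall on both sides of the default (50, 1000) display window.
    Source labels are mostly "BP" with a sprinkling of "KEGG", "REAC" and
    "MF" to exercise source filtering.  The universe is all *n_genes*
    genes, including unannotated ones.
    """
    if min(n_terms, n_genes, depth) < 1:
        raise ValueError("n_terms, n_genes and depth must all be >= 1")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    per_layer = [n_terms // depth + (1 if i < n_terms % depth else 0) for i in range(depth)]

    term_genes: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    source: dict[str, str] = {}
    src_choices = np.array(["BP", "KEGG", "REAC", "MF"])
    src_p = np.array([0.7, 0.1, 0.1, 0.1])

    max_size = min(2000, n_genes)
    prev_layer: list[str] = []
    tid_counter = 0
    for layer, count in enumerate(per_layer):
        layer_ids = []
        for _ in range(count):
            tid = f"T{tid_counter:04d}"
            tid_counter += 1
            if layer == 0 or not prev_layer:
                size = int(np.exp(rng.uniform(np.log(5), np.log(max_size))))
                members = rng.choice(genes, size=size, replace=False)
            else:
                parent = prev_layer[int(rng.integers(len(prev_layer)))]
                pool = np.array(sorted(term_genes[parent]))
                hi = len(pool)
                lo = min(5, hi)
                size = int(np.exp(rng.uniform(np.log(lo), np.log(hi)))) if hi > lo else hi
                size = max(size, 1)
                members = rng.choice(pool, size=size, replace=False)
                parents[tid] = {parent}
            term_genes[tid] = set(members.tolist())
            term_names[tid] = _term_name(rng)
            source[tid] = str(rng.choice(src_choices, p=src_p))
            layer_ids.append(tid)
        prev_layer = layer_ids

    return AnnotationSet(
        term_genes=term_genes,
        term_names=term_names,
        parents=parents,
        source=source,
        universe=set(genes.tolist()),
    )


def make_spiked_query(
    ann: AnnotationSet,
    target_term: str,
    signal_frac: float,
    seed: int = 0,
    n_background: int = 0,
) -> GeneList:
    """A query spiking a fraction of one term's genes into random background.

    ``signal_frac`` of the target term's genes (rounded) are combined with
    *n_background* genes drawn uniformly from the rest of the universe.
    ``signal_frac = 0`` gives a pure-noise query (type-I error checks);
    ``signal_frac = 1`` with no background reproduces the term exactly.
    """
    if not (0.0 <= signal_frac <= 1.0):
        raise ValueError("signal_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tgenes = np.array(sorted(ann.term_genes[target_term]))
    k = int(round(signal_frac * len(tgenes)))
    signal = rng.choice(tgenes, size=k, replace=False) if k else np.array([], dtype=tgenes.dtype)
    rest = np.array(sorted(ann.universe - set(signal.tolist())))
    n_bg = min(n_background, len(rest))
    background = rng.choice(rest, size=n_bg, replace=False) if n_bg else np.array([], dtype=rest.dtype)
    combined = list(dict.fromkeys([*signal.tolist(), *background.tolist()]))
    if not combined:
        raise ValueError("query would be empty: raise signal_frac or n_background")
    return GeneList(label=f"spiked {target_term}", genes=tuple(combined))


def make_expression(
    n_genes: int = 2000,
    n_samples: int = 18,
    n_clusters: int = 5,
    n_timepoints: int = 9,
    seed: int = 0,
    noise: float = 0.5,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Clustered time-series expression plus the true gene → cluster map.

    Cluster mean profiles are smooth sigmoidal switches with onsets spread
    across the time course (alternating on/off direction), mimicking genes
    switching on in waves during a differentiation time series.  Gaussian
    noise of s.d. *noise* is added per entry; ``noise = 0`` makes every
    gene's profile exactly its cluster mean.
    """
    if n_samples < n_timepoints:
        raise ValueError("need at least one sample per time point")
    rng = np.random.default_rng(seed)
    times = np.sort(np.resize(np.arange(n_timepoints), n_samples))
    sample_ids = [f"s{i:02d}" for i in range(n_samples)]
    classes = {sid: f"day{t}" for sid, t in zip(sample_ids, times)}

    t = times.astype(float)
    profiles = np.empty((n_clusters, n_samples))
    for c in range(n_clusters):
        onset = (c + 0.5) * (n_timepoints - 1) / n_clusters
        direction = 1.0 if c % 2 else -1.0
        profiles[c] = 3.0 / (1.0 + np.exp(-direction * 1.5 * (t - onset)))

    assignment_arr = np.resize(np.arange(n_clusters), n_genes)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    values = profiles[assignment_arr] + rng.normal(0.0, noise, size=(n_genes, n_samples))
    exprs = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        sample_classes=classes,
    )
    assignment = {g: int(c) + 1 for g, c in zip(gene_ids, assignment_arr)}
    return exprs, assignment


def make_separated_expression(
    n_genes: int = 2000,
    n_signal: int = 300,
    n_samples: int = 20,
    seed: int = 0,
    effect: float = 2.0,
    noise: float = 1.0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Two sample classes separated along one planted gene direction.

    The first *n_signal* genes are shifted by ±*effect* in class "B" (half
    up, half down); the rest are pure noise.  The planted direction should
    dominate the first principal component, whose top-loading gene lists
    are expected to recover the planted genes.
    """
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    classes_arr = np.array(["A"] * half + ["B"] * (n_samples - half))
    sample_ids = [f"s{i:02d}" for i in range(n_samples)]
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    values = rng.normal(0.0, noise, size=(n_genes, n_samples))
    is_b = classes_arr == "B"
    signs = np.where(np.arange(n_signal) % 2 == 0, 1.0, -1.0)
    values[:n_signal][:, is_b] += effect * signs[:, None]
    exprs = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        sample_classes=dict(zip(sample_ids, classes_arr)),
    )
    return exprs, gene_ids[:n_signal]


def make_abundance(
    n_features: int = 60,
    n_samples: int = 36,
    n_groups: int = 3,
    seed: int = 0,
    n_planted: int = 4,
    fold: float = 8.0,
    depth: int = 2000,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, list[str]]]:
    """Grouped taxon-abundance counts with planted discriminating features.

    Samples fall into *n_groups* body-site-style groups sharing a lognormal
    baseline composition; each group has *n_planted* features whose
    Dirichlet concentration is multiplied by *fold*.  Counts are
    Dirichlet-multinomial at *depth* reads per sample.  Returns the
    samples × features count table, sample → group labels, and the planted
    feature names per group.
    """
    rng = np.random.default_rng(seed)
    features = [_taxon_name(rng, i) for i in range(n_features)]
    base_alpha = np.exp(rng.normal(0.0, 1.0, size=n_features))
    planted: dict[str, list[str]] = {}
    group_alpha = {}
    order = rng.permutation(n_features)
    for gi in range(n_groups):
        gname = f"site{gi + 1}"
        idx = order[gi * n_planted: (gi + 1) * n_planted]
        alpha = base_alpha.copy()
        alpha[idx] *= fold
        group_alpha[gname] = alpha
        planted[gname] = [features[j] for j in idx]

    per_group = [n_samples // n_groups + (1 if i < n_samples % n_groups else 0) for i in range(n_groups)]
    rows, sample_ids, classes = [], [], {}
    si = 0
    for gi, count in enumerate(per_group):
        gname = f"site{gi + 1}"
        for _ in range(count):
            p = rng.dirichlet(group_alpha[gname])
            rows.append(rng.multinomial(depth, p))
            sid = f"sample{si:03d}"
            sample_ids.append(sid)
            classes[sid] = gname
            si += 1
    table = pd.DataFrame(np.asarray(rows), index=sample_ids, columns=features)
    return table, classes, planted
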