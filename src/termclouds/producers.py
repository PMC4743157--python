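"""Turn upstream analysis results into summary-figure blocks.

A *block* is the figure unit: one or two gene (or feature) lists, their word
clouds, and a panel showing the underlying experimental data — per-sample
expression boxplots for clustering and differential expression, stacked
score histograms for PCA and PCoA, or just the gene counts when no data
matrix is available.  Blocks stack vertically into a
:class:`SummaryModel`, the object the renderer consumes.

Producers exist for four common analyses:

* ``blocks_from_clusters`` — one block per cluster of a gene partition;
* ``blocks_from_de`` — one block per contrast, split into up/down lists;
* ``blocks_from_pca`` — one block per principal component, split into the
  genes with the largest positive and negative loadings (500 a side by
  default);
* ``blocks_from_pcoa`` — one block per principal coordinate of a
  Bray–Curtis ordination, with the clouds showing the features most
  correlated with the axis (Spearman test) instead of enrichment results.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .cloud import WordItem, feature_items
from .enrich import EnrichedTerm, bh_adjust
from .ontology import GeneList

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes × samples expression table with optional sample classes."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    sample_classes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("gene and sample identifiers must be unique")
        if self.values.index.isna().any() or self.values.columns.isna().any():
            raise ValueError("gene and sample identifiers must not be missing")
        if self.sample_classes is not None:
            missing = set(self.values.columns) - set(self.sample_classes)
            if missing:
                raise ValueError(f"samples without class label: {sorted(missing)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PCAResult:
    """Loadings (genes × components), scores (samples × components) and the
    percentage of variance captured by each component."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    var_pct: np.ndarray


@dataclass
class PCoAResult:
    """Principal-coordinate embedding of a distance matrix.

    ``coords`` holds samples × axes (eigenvector · sqrt(eigenvalue));
    ``eigenvalues`` the retained positive eigenvalues, non-increasing;
    ``feature_assoc`` is filled by :func:`associate_features` with one
    table per axis (rho, p, p_adj per feature).
    """

    coords: pd.DataFrame
    eigenvalues: np.ndarray
    feature_assoc: dict[int, pd.DataFrame] = field(default_factory=dict)


@dataclass(frozen=True)
class BoxStats:
    """Tukey five-number summary of one sample: quartiles by linear
    interpolation, whiskers at the most extreme data within 1.5·IQR."""

    med: float
    q1: float
    q3: float
    whislo: float
    whishi: float


@dataclass(frozen=True)
class BoxplotPanel:
    sample_ids: tuple[str, ...]
    stats: tuple[BoxStats, ...]
    kind: str = "boxplot"


@dataclass(frozen=True)
class HistogramPanel:
    """Stacked histogram: shared bin edges, one count row per class (classes
    stacked in first-appearance order)."""

    bin_edges: tuple[float, ...]
    classes: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]
    kind: str = "histogram"


@dataclass(frozen=True)
class CountPanel:
    kind: str = "none"


Panel = BoxplotPanel | HistogramPanel | CountPanel


@dataclass
class Block:
    """One or two related gene lists plus their clouds and a data panel."""

    title: str
    gene_lists: tuple[GeneList, ...]
    panel: Panel
    annotation: str = ""
    clouds: tuple[tuple[WordItem, ...], ...] = ()
    terms: tuple[tuple[EnrichedTerm, ...], ...] = ()

    def __post_init__(self) -> None:
        if len(self.gene_lists) not in (1, 2):
            raise ValueError("a block carries one or two gene lists")
        if not self.clouds:
            self.clouds = tuple(() for _ in self.gene_lists)
        if not self.terms:
            self.terms = tuple(() for _ in self.gene_lists)
        if len(self.clouds) != len(self.gene_lists):
            raise ValueError("one cloud per gene list required")


@dataclass
class DisplayParams:
    """Global display knobs: per-cloud canvas (points; sized so 5–6 blocks
    fit a portrait page), font limits and grayscale range."""

    cloud_width: float = 250.0
    cloud_height: float = 110.0
    max_font: float = 20.0
    min_font: float = 4.0
    weight_cap: float = 16.0
    gray_range: tuple[float, float] = (0.65, 0.0)


@dataclass
class SummaryModel:
    """Ordered blocks plus display parameters; the renderer's input."""

    blocks: list[Block]
    panel_kind: str = "boxplot"  # boxplot | histogram | none
    display: DisplayParams = field(default_factory=DisplayParams)

    def __post_init__(self) -> None:
        if self.panel_kind not in ("boxplot", "histogram", "none"):
            raise ValueError(f"unknown panel kind {self.panel_kind!r}")


# ---------------------------------------------------------------------------
# panel statistics
# ---------------------------------------------------------------------------

def boxplot_stats(values: np.ndarray) -> BoxStats:
    v = np.asarray(values, dtype=float).ravel()
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo) & (v <= hi)]
    return BoxStats(
        med=float(med), q1=float(q1), q3=float(q3),
        whislo=float(inside.min()), whishi=float(inside.max()),
    )


def _boxplot_panel(sub: pd.DataFrame) -> BoxplotPanel:
    return BoxplotPanel(
        sample_ids=tuple(sub.columns),
        stats=tuple(boxplot_stats(sub[c].to_numpy()) for c in sub.columns),
    )


def _histogram_panel(
    values: np.ndarray, classes: Sequence[str]
) -> HistogramPanel:
    values = np.asarray(values, dtype=float)
    nbins = max(1, int(math.ceil(math.log2(len(values))) + 1))  # Sturges
    edges = np.histogram_bin_edges(values, bins=nbins)
    class_order = list(dict.fromkeys(classes))
    counts = []
    cls_arr = np.asarray(classes)
    for c in class_order:
        cnt, _ = np.histogram(values[cls_arr == c], bins=edges)
        counts.append(tuple(int(x) for x in cnt))
    return HistogramPanel(
        bin_edges=tuple(float(e) for e in edges),
        classes=tuple(class_order),
        counts=tuple(counts),
    )


# ---------------------------------------------------------------------------
# clustering and differential expression
# ---------------------------------------------------------------------------

def blocks_from_clusters(
    exprs: ExpressionMatrix, assignment: Mapping[str, object]
) -> SummaryModel:
    """One block per cluster: members, per-sample boxplots, member count.

    *assignment* maps gene id → cluster id; blocks are ordered by cluster
    id.  A gene assigned but absent from the matrix is an error; a cluster
    id with no genes is skipped with a warning.
    """
    absent = [g for g in assignment if g not in exprs.values.index]
    if absent:
        raise KeyError(f"assigned gene(s) not in the expression matrix: {absent[:5]}")
    clusters: dict[object, list[str]] = {}
    for g, cid in assignment.items():
        clusters.setdefault(cid, []).append(g)
    blocks = []
    for cid in sorted(clusters, key=str):
        members = clusters[cid]
        if not members:
            logger.warning("cluster %s has no genes; skipped", cid)
            continue
        sub = exprs.values.loc[members]
        blocks.append(
            Block(
                title=f"Cluster {cid}",
                gene_lists=(GeneList(label=f"Cluster {cid}", genes=tuple(members)),),
                panel=_boxplot_panel(sub),
                annotation=f"{len(members)} genes",
            )
        )
    return SummaryModel(blocks=blocks, panel_kind="boxplot")


def blocks_from_de(
    de_table: pd.DataFrame,
    threshold: float = 0.05,
    exprs: ExpressionMatrix | None = None,
) -> SummaryModel:
    """Per contrast, a block with up- and down-regulated gene lists.

    *de_table* needs columns ``gene``, ``effect`` and ``p_adj``; an optional
    ``contrast`` column splits the table into one block per contrast.  A
    gene is *up* when ``effect > 0`` and ``p_adj <= threshold``, *down* when
    ``effect < 0`` and significant; zero effects belong to neither side.
    An empty side still yields a (empty) list so the block shows "0 genes".
    """
    required = {"gene", "effect", "p_adj"}
    if not required <= set(de_table.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    if "contrast" in de_table.columns:
        groups = list(de_table.groupby("contrast", sort=True))
    else:
        groups = [("contrast", de_table)]
    blocks = []
    for name, sub in groups:
        sig = sub[sub["p_adj"] <= threshold]
        up = sig[sig["effect"] > 0].sort_values("effect", ascending=False)
        down = sig[sig["effect"] < 0].sort_values("effect", ascending=True)
        up_genes = tuple(dict.fromkeys(up["gene"]))
        down_genes = tuple(dict.fromkeys(down["gene"]))
        if exprs is not None:
            members = [g for g in (*down_genes, *up_genes) if g in exprs.values.index]
            panel: Panel = (
                _boxplot_panel(exprs.values.loc[members]) if members else CountPanel()
            )
        else:
            panel = CountPanel()
        blocks.append(
            Block(
                title=str(name),
                gene_lists=(
                    GeneList(label="down", genes=down_genes, side="down"),
                    GeneList(label="up", genes=up_genes, side="up"),
                ),
                panel=panel,
                annotation=f"{len(up_genes)} up / {len(down_genes)} down",
            )
        )
    kind = "boxplot" if exprs is not None else "none"
    return SummaryModel(blocks=blocks, panel_kind=kind)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(exprs: ExpressionMatrix, n_comp: int | None = None) -> PCAResult:
    """PCA by SVD of the gene-centered matrix; no variance scaling.

    Each gene's row is centered across samples before decomposition.  Every
    component is oriented so its largest-magnitude loading is positive (the
    sign of a principal component is arbitrary; a fixed convention keeps
    outputs reproducible).  ``n_comp`` beyond the rank bound of the centered
    matrix, ``min(genes, samples - 1)``, is clamped with a warning.
    """
    X = exprs.values.to_numpy(dtype=float)
    G, S = X.shape
    if S < 2:
        raise ValueError("PCA needs at least 2 samples")
    r_max = min(G, S - 1)
    if n_comp is None:
        n_comp = r_max
    elif n_comp > r_max:
        logger.warning("n_comp=%d clamped to %d (= min(genes, samples - 1))", n_comp, r_max)
        n_comp = r_max
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    var_pct = (s[:n_comp] ** 2) / total * 100.0 if total > 0 else np.zeros(n_comp)
    U = U[:, :n_comp]
    sv = s[:n_comp]
    scores = Vt[:n_comp].T * sv  # = Xcᵀ · U
    # orient: largest-|loading| positive per component
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(n_comp)])
    flip[flip == 0] = 1.0
    U = U * flip
    scores = scores * flip
    comp_ids = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        loadings=pd.DataFrame(U, index=exprs.values.index, columns=comp_ids),
        scores=pd.DataFrame(scores, index=exprs.values.columns, columns=comp_ids),
        var_pct=np.asarray(var_pct, dtype=float),
    )


def loading_gene_lists(
    loadings: pd.Series, n_genes: int = 500
) -> tuple[GeneList, GeneList]:
    """Split one component's loadings into (negative, positive) gene lists.

    The positive list holds genes with loading > 0 sorted descending, the
    negative list genes with loading < 0 sorted ascending; each truncated to
    *n_genes*.  Zero loadings belong to neither side.
    """
    pos = loadings[loadings > 0].sort_values(ascending=False).index[:n_genes]
    neg = loadings[loadings < 0].sort_values(ascending=True).index[:n_genes]
    return (
        GeneList(label="negative", genes=tuple(neg), side="negative"),
        GeneList(label="positive", genes=tuple(pos), side="positive"),
    )


def blocks_from_pca(
    exprs: ExpressionMatrix, n_comp: int = 4, n_genes: int = 500
) -> SummaryModel:
    """One block per principal component.

    Left/negative and right/positive clouds later summarise the *n_genes*
    (default 500) genes with the largest negative and positive loadings;
    the panel is a stacked histogram of the sample scores coloured by class,
    annotated with the percentage of variance explained.
    """
    res = pca(exprs, n_comp=n_comp)
    classes = (
        [exprs.sample_classes[s] for s in exprs.sample_ids]
        if exprs.sample_classes
        else ["all"] * len(exprs.sample_ids)
    )
    blocks = []
    for i, comp in enumerate(res.loadings.columns):
        neg, pos = loading_gene_lists(res.loadings[comp], n_genes=n_genes)
        blocks.append(
            Block(
                title=comp,
                gene_lists=(neg, pos),
                panel=_histogram_panel(res.scores[comp].to_numpy(), classes),
                annotation=f"{res.var_pct[i]:.1f}%",
            )
        )
    return SummaryModel(blocks=blocks, panel_kind="histogram")


# ---------------------------------------------------------------------------
# Bray–Curtis + PCoA
# ---------------------------------------------------------------------------

def bray_curtis(abundance: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Pairwise Bray–Curtis dissimilarity, samples as rows.

    ``d(i, j) = Σ_f |x_if − x_jf| / Σ_f (x_if + x_jf)``, in [0, 1].  A pair
    of all-zero samples has an undefined ratio; it is defined as 0 here
    (identical emptiness) with a warning.
    """
    from scipy.spatial.distance import pdist, squareform

    X = abundance.to_numpy(dtype=float) if isinstance(abundance, pd.DataFrame) else np.asarray(abundance, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray–Curtis needs nonnegative abundances")
    with np.errstate(invalid="ignore"):
        D = squareform(pdist(X, metric="braycurtis"))
    if np.isnan(D).any():
        logger.warning("all-zero sample pair(s): Bray–Curtis defined as 0")
        D = np.nan_to_num(D, nan=0.0)
    np.fill_diagonal(D, 0.0)
    if isinstance(abundance, pd.DataFrame):
        return pd.DataFrame(D, index=abundance.index, columns=abundance.index)
    return D


def pcoa(distance: pd.DataFrame | np.ndarray, n_axes: int = 3) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower double-centering of ``−½·d²`` followed by an eigendecomposition;
    coordinates are the eigenvectors of the top ``n_axes`` positive
    eigenvalues scaled by the square root of the eigenvalue.  Negative
    eigenvalues (non-Euclidean distances) are dropped with a logged
    magnitude summary; no positive eigenvalue is an error.
    """
    if isinstance(distance, pd.DataFrame):
        ids = list(distance.index)
        D = distance.to_numpy(dtype=float)
    else:
        D = np.asarray(distance, dtype=float)
        ids = [f"s{i}" for i in range(D.shape[0])]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-12 if vals.size else 0.0
    pos = vals > tol
    if not pos.any():
        raise ValueError("no positive eigenvalue: distances carry no metric structure")
    neg = vals[vals < -tol]
    if neg.size:
        logger.info(
            "dropping %d negative eigenvalue(s), total magnitude %.3g "
            "(%.1f%% of positive mass)",
            neg.size, -neg.sum(), -neg.sum() / vals[pos].sum() * 100,
        )
    m = min(n_axes, int(pos.sum()))
    keep_vals = vals[pos][:m]
    coords = vecs[:, pos][:, :m] * np.sqrt(keep_vals)
    return PCoAResult(
        coords=pd.DataFrame(
            coords, index=ids, columns=[f"Axis{i + 1}" for i in range(m)]
        ),
        eigenvalues=keep_vals,
    )


# ---------------------------------------------------------------------------
# Spearman association of features with ordination axes
# ---------------------------------------------------------------------------

def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p; exact permutation p for n ≤ 8.

    For small n the t approximation is unreliable, but enumerating all n!
    rank orders is cheap, so the exact permutation null is used there; the
    usual t approximation applies for larger n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 4:
        raise ValueError("Spearman test needs two vectors of equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman test undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 8:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, min(p, 1.0)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    target = abs(rho_obs) - 1e-12
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = float(np.dot(rx, ry[list(perm)])) / n
        hits += abs(r) >= target
        total += 1
    return hits / total


def associate_features(
    res: PCoAResult, abundance: pd.DataFrame, alpha: float = 0.05
) -> PCoAResult:
    """Spearman-correlate every feature with every axis; BH within axis.

    Constant features are excluded with a warning.  Fills
    ``res.feature_assoc[axis]`` with a table (rho, p, p_adj) indexed by
    feature name.
    """
    X = abundance.to_numpy(dtype=float)
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = X.shape[1] - len(keep)
    if dropped:
        logger.warning("%d constant feature(s) excluded from association testing", dropped)
    names = [abundance.columns[j] for j in keep]
    for ax in range(res.coords.shape[1]):
        coord = res.coords.iloc[:, ax].to_numpy()
        rhos, ps = [], []
        for j in keep:
            rho, p = spearman_test(X[:, j], coord)
            rhos.append(rho)
            ps.append(p)
        res.feature_assoc[ax] = pd.DataFrame(
            {"rho": rhos, "p": ps, "p_adj": bh_adjust(ps) if ps else []},
            index=pd.Index(names, name="feature"),
        )
    return res


def blocks_from_pcoa(
    abundance: pd.DataFrame,
    sample_classes: Mapping[str, str] | None = None,
    n_axes: int = 3,
    alpha: float = 0.05,
) -> SummaryModel:
    """One block per principal coordinate of a Bray–Curtis ordination.

    Word clouds hold the features significantly correlated (right cloud)
    and anti-correlated (left cloud) with the axis, weighted by
    ``−log10(p_adj)`` of the Spearman test — no enrichment step; the panel
    is a stacked histogram of the axis coordinates coloured by class.
    Needs at least 4 samples (the correlation test is degenerate below).
    """
    if abundance.shape[0] < 4:
        raise ValueError("PCoA association needs at least 4 samples")
    D = bray_curtis(abundance)
    res = pcoa(D, n_axes=n_axes)
    associate_features(res, abundance, alpha=alpha)
    classes = (
        [sample_classes[s] for s in abundance.index]
        if sample_classes
        else ["all"] * abundance.shape[0]
    )
    total = res.eigenvalues.sum()
    blocks = []
    for ax in range(res.coords.shape[1]):
        tab = res.feature_assoc[ax]
        sig = tab[tab["p_adj"] <= alpha]
        pos = sig[sig["rho"] > 0].sort_values("p_adj")
        neg = sig[sig["rho"] < 0].sort_values("p_adj")
        pct = res.eigenvalues[ax] / total * 100 if total > 0 else 0.0
        blocks.append(
            Block(
                title=res.coords.columns[ax],
                gene_lists=(
                    GeneList(label="anti-correlated", genes=tuple(neg.index), side="negative"),
                    GeneList(label="correlated", genes=tuple(pos.index), side="positive"),
                ),
                panel=_histogram_panel(res.coords.iloc[:, ax].to_numpy(), classes),
                annotation=f"{pct:.1f}%",
                clouds=(
                    tuple(feature_items(list(neg.index), list(neg["p_adj"]))),
                    tuple(feature_items(list(pos.index), list(pos["p_adj"]))),
                ),
            )
        )
    return SummaryModel(blocks=blocks, panel_kind="histogram")


# ---------------------------------------------------------------------------
# attach enrichment clouds to a model
# ---------------------------------------------------------------------------

def annotate_model(
    model: SummaryModel,
    ann,
    cfg=None,
    alpha: float = 0.05,
    ancestors: bool = False,
) -> SummaryModel:
    """Run enrichment + filtering for every gene list and attach clouds.

    Empty gene lists and lists with no universe overlap yield empty clouds
    rather than errors (a block with nothing significant still renders).
    """
    from .cloud import compute_weights
    from .filtering import FilterConfig, filter_terms

    cfg = cfg or FilterConfig()
    for block in model.blocks:
        clouds, term_sets = [], []
        for gl in block.gene_lists:
            terms: list[EnrichedTerm] = []
            if gl.genes and set(gl.genes) & ann.universe:
                from .enrich import enrich

                terms = filter_terms(
                    enrich(gl, ann, alpha=alpha),
                    parents=ann.parents, cfg=cfg, ancestors=ancestors,
                )
            term_sets.append(tuple(terms))
            clouds.append(tuple(compute_weights(terms)))
        block.clouds = tuple(clouds)
        block.terms = tuple(term_sets)
    return model
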