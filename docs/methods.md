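# Methods

`termclouds` builds visual summaries of gene-list analyses: each gene list
gets a word cloud of its functional annotation, attached to a panel of the
underlying experimental data, and the blocks stack into one figure.  This
note records the statistical and algorithmic choices, the defaults and
their rationale, what the synthetic generators emulate, and the known
limits of the approach.

## Enrichment model

A query list of `n` genes is tested against every annotation term.  With a
universe of `N` genes and a term annotating `K` of them, the probability of
seeing at least the observed overlap `k` by chance is the hypergeometric
upper tail

    p = P(X ≥ k),  X ~ Hypergeometric(N, K, n),

the one-sided Fisher exact test.  Only terms with `k ≥ 1` are tested; the
number of tested terms is the multiplicity `m` of the Benjamini–Hochberg
step-up correction applied afterwards (untested terms cannot reject, so
counting them in `m` would only dilute the correction).  The default
significance threshold is `p_adj ≤ 0.05`.

BH over a fixed local universe is a deliberate, reproducible offline
choice; web enrichment services apply their own corrections.  Results from
any external tool can be imported as a plain term table
(`parse_term_table`), in which case the supplied p-values are taken as
already corrected and used verbatim.

The universe defaults to the union of annotated genes and can be overridden
by a user-supplied background file (e.g. the genes actually on an array).
Gene identifiers are opaque case-sensitive strings; a two-column mapping
TSV can be applied as a preprocessing step, but no automatic identifier
conversion is attempted.

Tie-breaking everywhere a term ordering matters: ascending `p_adj`, then
`p_raw`, then *larger* term size, then lexicographic id.  The size rule
prefers the more general term when two are equally significant; the id rule
makes every ordering fully deterministic.

## Term filtering

Four filters reduce hundreds of significant terms to a displayable set, in
a fixed order — sources → size → hierarchy → cap:

1. **Sources** — keep only terms from allowed annotation sources; default
   `{BP, KEGG, REAC}` (biological-process GO plus the two pathway
   databases).
2. **Size window** — keep terms with more than `min_size = 50` and fewer
   than `max_size = 1000` annotated genes; bounds are strict on both ends.
   Very small terms are too specific and very large ones too generic to
   characterise a list of a few hundred genes.  Imported terms without a
   size are exempt.
3. **Hierarchy** — significant terms that share a direct parent (or where
   one is the other's direct parent) form groups; groups are merged
   transitively (connected components of the relatedness graph) and only
   the most significant member of each group survives.  An opt-in
   `ancestors=True` mode groups through the full `is_a` closure instead;
   direct-parent grouping is the default because it removes the sibling
   redundancy that dominates real results without collapsing distant
   branches of the ontology.
4. **Cap** — at most `max_terms = 30` most significant terms remain.

The cap runs last on purpose: it is the safety valve for "still too many
terms after redundancy removal", and running it earlier would let one
redundant family crowd out everything else before the hierarchy filter
could act.  The composed pipeline is idempotent.

## Word clouds

Weight of a phrase is `−log10(p)`, capped at 16 (a single `p = 1e-80` term
would otherwise flatten every other word to nothing); `p = 0` is clamped to
the smallest positive float with a warning.  Within one cloud, font sizes
are proportional to weight, rescaled so the heaviest phrase gets
`max_font = 20 pt`.  Because of that rescaling **font sizes are not
comparable between clouds**; absolute strength is carried by a single
figure-wide grayscale instead: an affine map of the figure-wide weight
range onto gray `0.65 → 0.0` (black strongest).  The floor of 0.65 keeps
the weakest term legible; a degenerate range (all weights equal) maps
everything to black.  Identical weights in different clouds always get
identical grays.

### Placement

Placement is greedy and fully deterministic: phrases are processed heaviest
first (ties by text), each box estimated from its font size and character
count (average glyph advance 0.58 em, line height 1.15 em), and candidate
centre positions are scanned on a jittered grid ordered as an outward
elliptical spiral from the canvas centre.  Phrases whose box is more than
four times wider than tall use a different candidate order that penalises
vertical distance three-fold, so long term names settle into horizontal
bands near the centre instead of blocking the spiral core.  Phrases are
never rotated or split — a term name is only readable as a unit.  A
candidate is accepted if the box lies inside the canvas and intersects no
placed box (open-interval test, so touching edges are fine).

If any phrase cannot be placed, *all* font sizes are multiplied by 0.95 and
the layout restarts, which preserves the weight → size ordering exactly
through any number of shrink iterations.  A phrase that cannot fit the
canvas even at the minimum font (4 pt) raises a layout error naming it.
The grid step is `min(canvas)/40` (at least 2 units); the per-seed jitter
of up to a quarter step lets different seeds explore slightly different
packings while keeping each seed byte-reproducible.

## Producers

* **Clustering** — one block per cluster id; the panel shows per-sample
  boxplots over the cluster's expression rows (median, quartiles by linear
  interpolation, whiskers at the most extreme values within 1.5·IQR — the
  standard Tukey convention).
* **Differential expression** — consumed, not computed: the input is a
  table of (gene, effect, adjusted p), optionally per contrast.  Up =
  effect > 0 and `p_adj ≤ 0.05`; down = effect < 0 and significant; zero
  effects belong to neither side.  Empty sides still render ("0 genes").
* **PCA** — SVD of the per-gene centered matrix, no variance scaling by
  default (log-scale expression is already variance-comparable; a flag can
  standardise).  Components are oriented so the largest-magnitude loading
  is positive — the sign of a PC is arbitrary and a fixed convention makes
  outputs reproducible.  Per component the positive/negative clouds get the
  500 genes with the largest positive/negative loadings (loading exactly 0
  joins neither side).  Requested components beyond the rank bound
  `min(genes, samples − 1)` of the centered matrix are clamped with a
  warning.  The panel is a stacked histogram of the sample scores, bins by
  Sturges' rule with shared edges, classes stacked in first-appearance
  order, annotated with the percentage of variance explained.
* **PCoA** — Bray–Curtis dissimilarity `Σ|x−y| / Σ(x+y)` on nonnegative
  abundance rows (an all-zero pair is defined as distance 0 with a
  warning), then classical scaling: Gower double-centering of `−½·d²`,
  eigendecomposition, coordinates = eigenvector × √eigenvalue for the top
  positive eigenvalues.  Negative eigenvalues (Bray–Curtis is
  non-Euclidean) are dropped with a logged magnitude summary; no positive
  eigenvalue is an error.  Features are associated to each axis by
  Spearman correlation — exact permutation p for n ≤ 8 samples (all n!
  orders enumerated; the t approximation is poor there and enumeration is
  cheap), the usual t approximation above — BH-corrected within each axis.
  Clouds show the feature *names* directly, weighted by `−log10(p_adj)` of
  the correlation test; no enrichment step is involved.  Constant features
  are excluded with a warning.

## Rendering

Blocks stack top-to-bottom: title strip, data panel with the gene-count or
variance annotation to its right, then one or two clouds — negative/down on
the left, positive/up on the right.  Figure height is exactly linear in the
block count; per-block canvas defaults (250 × 110 pt per cloud) put five to
six blocks on a portrait page.  Grays are computed over the whole figure
before any cloud is placed.  Output is static SVG/PDF/PNG; SVG is rendered
with a pinned hash salt, text as real `<text>` elements and no volatile
metadata, so a fixed seed gives byte-identical files (regression-testable
by diff).

The intermediate model file is versioned JSON carrying blocks, gene lists,
enriched terms, word items and panel statistics; round-trips are lossless.

## Synthetic data

The generators produce structurally realistic inputs, not biological ones:

* `make_annotation` — a tree-shaped term hierarchy (child gene sets nested
  in their parent's), term sizes log-uniform in [5, 2000] so the (50, 1000)
  display window is always exercised from both sides, multi-word names to
  stress long-phrase packing, and mixed source labels.
* `make_spiked_query` — a controllable fraction of one term's genes plus
  uniform background; `signal_frac = 0` gives the null for type-I checks.
* `make_expression` — cluster mean profiles are sigmoidal switches with
  onsets spread across a nine-point time course (genes switching on in
  waves), Gaussian noise σ = 0.5 on top; 2000 genes × 18 samples by
  default.
* `make_separated_expression` — two sample classes separated along one
  planted direction (300 signal genes shifted ±2 units over noise σ = 1),
  the fixture behind the loading-recovery checks.
* `make_abundance` — Dirichlet-multinomial counts (2000 reads/sample, 60
  taxa, 36 samples, 3 groups) with four planted features per group at
  8-fold elevated concentration, emulating a body-site microbiome table.

What passing these tests shows: the pipeline machinery — test statistics,
corrections, filters, orderings, geometry, serialisation — is correct and
calibrated on data whose truth is known.  What it does not show: behaviour
under real-data pathologies (correlated genes, compositional artefacts,
batch effects, annotation bias), none of which the generators model.

## Numerical notes and limitations

* Hypergeometric tails come from the scipy survival function; against an
  exact integer-arithmetic oracle over every (N ≤ 60, K, n, k) the worst
  relative error is ~1e-15.
* PCoA eigendecomposition symmetrises the centered matrix before `eigh`;
  eigenvalues below `1e-12·|λ_max|` are treated as zero.
* The box model estimates text extent from character count, not glyph
  metrics; placement guarantees hold for the model's boxes, and the
  rendered text is drawn at the layout's font sizes inside those boxes.
* Spearman exact enumeration costs n! — it is enabled only for n ≤ 8
  (40 320 orders at worst).
* The redundancy filter sees only the terms in the significant set; two
  cousins whose common ancestor is outside the set stay separate under
  direct-parent grouping (use `ancestors=True` for closure grouping).
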