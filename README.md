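# termclouds

Visual functional summaries for gene-list analyses.  Many analyses —
clustering, differential expression, principal component analysis — end in
*lists of genes*, and each list is typically characterised by Gene Ontology
enrichment, producing hundreds of significant terms per list.  `termclouds`
compresses each list's annotation into a word cloud (font size ∝
−log₁₀ p), filters the terms down to a readable set, and stacks the clouds
together with plots of the underlying experimental data into one compact
figure.  It is aimed at computational biologists who want a one-page
functional overview of a clustering, a set of contrasts, or tens of
principal components — and at microbiome analysts, where the same layout
shows the taxa driving each principal coordinate of a Bray–Curtis
ordination.

## The statistics at the core

**Enrichment.**  For a query of *n* genes from a universe of *N*, a term
annotating *K* genes with overlap *k*, the enrichment p-value is the
hypergeometric upper tail (one-sided Fisher test)

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ k),&nbsp;&nbsp; X ~ Hypergeom(N, K, n),

Benjamini–Hochberg corrected over all terms with k ≥ 1.

**Filtering.**  Significant terms pass four filters in order: allowed
sources (default BP/KEGG/REAC) → size window (strictly more than 50 and
fewer than 1000 annotated genes) → redundancy reduction (terms sharing a
direct parent are grouped transitively and only each group's most
significant member survives) → a cap of the 30 most significant terms.

**Clouds.**  Word weight is −log₁₀(p_adj), capped at 16.  Fonts are
rescaled per cloud (so sizes are not comparable across clouds); absolute
enrichment strength is encoded in a figure-wide grayscale, black =
strongest.  Placement is a deterministic greedy packing on an outward
elliptical spiral, with long phrases preferring horizontal bands — no
rotation, no phrase splitting, no box overlaps.

**Producers.**  Besides plain gene lists, block models can be built from a
cluster assignment (per-sample expression boxplots), a differential
expression table (up/down lists), PCA of an expression matrix (per
component, the 500 genes with the largest positive and negative loadings;
stacked score histograms with % variance), and Bray–Curtis PCoA of an
abundance table (per axis, features significantly Spearman-correlated with
the coordinates — shown by name, no enrichment step).

See `docs/methods.md` for the full model description and defaults.

## Worked example

```python
from termclouds import enrich, filter_terms, compute_weights
from termclouds.synthetic import make_annotation, make_spiked_query

ann = make_annotation(n_terms=200, n_genes=5000, depth=3, seed=42)
query = make_spiked_query(ann, "T0007", signal_frac=0.6, seed=42, n_background=80)
terms = filter_terms(enrich(query, ann), parents=ann.parents)
for t in terms:
    print(f"{t.term_id}  {t.term_name:42s}  K={t.K:4d}  k={t.k:3d}  p_adj={t.p_adj:.3g}")
print("weights:", [round(i.weight, 2) for i in compute_weights(terms)])
```

prints

```
T0007  muscle membrane development                 K= 251  k=152  p_adj=1.84e-158
T0050  cell transduction proliferation adhesion    K=  52  k=  8  p_adj=0.0483
weights: [16.0, 1.32]
```

The query spikes 60% of term `T0007`'s 251 genes into 80 random background
genes, so `T0007` is recovered with overwhelming significance (`k=152` of
the 231-gene query); its weight hits the display cap of 16.  A second,
weakly overlapping term squeaks under α = 0.05 with weight 1.3, so it will
be drawn small and light-gray.  Everything else is filtered out.

The same flow from the shell, ending in a figure:

```bash
termclouds summarize-pca --exprs exprs.tsv --classes classes.tsv \
    --n-comp 3 --gmt annotations.gmt --dag parents.tsv -o model.json
termclouds plot model.json --format svg -o summary.svg
```

`model.json` is a versioned, round-trippable description of the blocks;
`summary.svg` stacks one block per principal component — score histogram
coloured by class, % variance, and the negative/positive loading clouds
left/right.

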