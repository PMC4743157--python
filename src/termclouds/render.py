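"""Assemble summary blocks into a stacked figure (SVG / PDF / PNG).

Each block renders, top to bottom: a title strip, an optional data panel
(per-sample expression boxplots, or a stacked score histogram annotated
with the percentage of variance explained, or just the gene counts), and
one or two word clouds.  Two-cloud blocks put the negative/down cloud on
the left and the positive/up cloud on the right.  Figure height grows
linearly with the number of blocks; the per-block canvas defaults are sized
so five to six blocks fit a portrait page.

Gray levels are computed figure-wide *before* any cloud is placed, so the
grayscale is the channel on which enrichment strength can be compared
across clouds (font sizes cannot — each cloud rescales them to fill its
canvas).

Output is deterministic for a fixed seed: the SVG hash salt is pinned and
volatile metadata (creation dates) suppressed, so identical inputs give
byte-identical SVG files.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
from matplotlib.figure import Figure

from .cloud import CloudLayout, compute_grays, place_words
from .producers import BoxplotPanel, CountPanel, HistogramPanel, SummaryModel

_PT = 1.0 / 72.0  # inches per point
_CLASS_COLORS = matplotlib.colormaps["tab10"].colors


def render(
    model: SummaryModel,
    path: str | Path,
    format: str | None = None,
    seed: int = 0,
) -> Path:
    """Render *model* to *path*; format from the suffix unless given."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("svg", "pdf", "png"):
        raise ValueError(f"unsupported format {fmt!r} (use svg, pdf or png)")
    if not model.blocks:
        raise ValueError("model has no blocks to render")

    fig = _build_figure(model, seed=seed)
    save_kw: dict = {"format": fmt}
    if fmt == "svg":
        save_kw["metadata"] = {"Date": None}
    elif fmt == "pdf":
        save_kw["metadata"] = {"CreationDate": None}
    # real <text> elements (not glyph paths): smaller, diffable output
    with matplotlib.rc_context({"svg.hashsalt": "termclouds", "svg.fonttype": "none"}):
        try:
            fig.savefig(path, **save_kw)
        except OSError as exc:
            raise OSError(f"cannot write figure to {path}: {exc}") from exc
    return path


def _block_geometry(model: SummaryModel) -> dict:
    d = model.display
    cloud_w_in = d.cloud_width * _PT
    cloud_h_in = d.cloud_height * _PT
    n_cols = max(len(b.gene_lists) for b in model.blocks)
    panel_h = {"boxplot": 1.0, "histogram": 1.0, "none": 0.25}[model.panel_kind]
    title_h, pad = 0.25, 0.15
    block_h = title_h + panel_h + cloud_h_in + pad
    margin = 0.4
    fig_w = margin * 2 + cloud_w_in * n_cols + 0.2 * (n_cols - 1) + 0.8  # room for counts
    fig_h = block_h * len(model.blocks)
    return {
        "cloud_w": cloud_w_in, "cloud_h": cloud_h_in, "n_cols": n_cols,
        "panel_h": panel_h, "title_h": title_h, "pad": pad,
        "block_h": block_h, "margin": margin, "fig_w": fig_w, "fig_h": fig_h,
    }


def _build_figure(model: SummaryModel, seed: int = 0) -> Figure:
    g = _block_geometry(model)
    fig = Figure(figsize=(g["fig_w"], g["fig_h"]))

    # figure-wide grayscale before any placement
    flat = [list(cloud) for b in model.blocks for cloud in b.clouds]
    grayed = compute_grays(flat, gray_range=model.display.gray_range)
    it = iter(grayed)
    shaded = [[tuple(next(it)) for _ in b.clouds] for b in model.blocks]

    for bi, block in enumerate(model.blocks):
        y_top = 1.0 - bi * g["block_h"] / g["fig_h"]
        _draw_title(fig, block.title, y_top, g)
        _draw_panel(fig, block, bi, y_top, g)
        _draw_clouds(fig, block, shaded[bi], y_top, g, model.display, seed=seed)
    return fig


def _draw_title(fig: Figure, title: str, y_top: float, g: dict) -> None:
    y = y_top - 0.5 * g["title_h"] / g["fig_h"]
    fig.text(0.5, y, title, ha="center", va="center", fontsize=11, weight="bold")


def _draw_panel(fig: Figure, block, bi: int, y_top: float, g: dict) -> None:
    x0 = g["margin"] / g["fig_w"]
    w = (g["fig_w"] - 2 * g["margin"] - 0.8) / g["fig_w"]
    y0 = y_top - (g["title_h"] + g["panel_h"]) / g["fig_h"]
    h = (g["panel_h"] - 0.12) / g["fig_h"]
    panel = block.panel
    if isinstance(panel, CountPanel):
        fig.text(
            x0, y0 + h / 2, block.annotation, ha="left", va="center", fontsize=9
        )
        return
    ax = fig.add_axes((x0, y0, w, h))
    ax.tick_params(labelsize=6)
    if isinstance(panel, BoxplotPanel):
        stats = [
            {"med": s.med, "q1": s.q1, "q3": s.q3,
             "whislo": s.whislo, "whishi": s.whishi, "fliers": []}
            for s in panel.stats
        ]
        ax.bxp(stats, showfliers=False)
        ax.set_xticks(range(1, len(panel.sample_ids) + 1))
        ax.set_xticklabels(panel.sample_ids, rotation=90, fontsize=5)
    elif isinstance(panel, HistogramPanel):
        import numpy as np

        edges = np.asarray(panel.bin_edges)
        widths = np.diff(edges)
        bottom = np.zeros(len(widths))
        for ci, cls in enumerate(panel.classes):
            counts = np.asarray(panel.counts[ci], dtype=float)
            ax.bar(
                edges[:-1], counts, width=widths, bottom=bottom, align="edge",
                color=_CLASS_COLORS[ci % len(_CLASS_COLORS)], label=str(cls),
                linewidth=0,
            )
            bottom += counts
        if len(panel.classes) > 1:
            ax.legend(fontsize=5, frameon=False, loc="upper right")
    # gene counts / variance percentage sit right of the panel
    fig.text(
        x0 + w + 0.01, y0 + h / 2, block.annotation,
        ha="left", va="center", fontsize=8,
    )


def _draw_clouds(
    fig: Figure, block, clouds, y_top: float, g: dict, display, seed: int
) -> None:
    y0 = y_top - (g["title_h"] + g["panel_h"] + g["cloud_h"]) / g["fig_h"]
    for ci in range(len(block.gene_lists)):
        x0 = (g["margin"] + ci * (g["cloud_w"] + 0.2)) / g["fig_w"]
        ax = fig.add_axes(
            (x0, y0, g["cloud_w"] / g["fig_w"], g["cloud_h"] / g["fig_h"])
        )
        ax.set_xlim(0, g["cloud_w"] / _PT)
        ax.set_ylim(0, g["cloud_h"] / _PT)
        ax.set_axis_off()
        items = clouds[ci]
        if not items:
            ax.text(
                g["cloud_w"] / _PT / 2, g["cloud_h"] / _PT / 2, "0 terms",
                ha="center", va="center", fontsize=7, color="0.5", style="italic",
            )
            continue
        layout = place_words(
            items,
            canvas=(g["cloud_w"] / _PT, g["cloud_h"] / _PT),
            seed=seed,
            max_font=display.max_font,
            min_font=display.min_font,
        )
        _draw_layout(ax, layout)


def _draw_layout(ax, layout: CloudLayout) -> None:
    for p in layout.placements:
        ax.text(
            p.x, p.y, p.text,
            fontsize=p.font_size,
            color=str(p.gray),
            ha="left", va="bottom",
            clip_on=False,
        )
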