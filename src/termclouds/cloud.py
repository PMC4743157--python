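"""Word-cloud construction: weights, grayscale and rectangle packing.

Each displayed phrase gets a weight ``-log10(p)`` so font size encodes the
strength of association.  Because every cloud rescales its fonts to use the
available space, font sizes are **not** comparable across clouds; absolute
strength is instead carried by a figure-wide grayscale (black = strongest).

Placement is a greedy, deterministic packing: phrases are placed heaviest
first on an outward elliptical spiral of candidate positions around the
canvas centre.  Long phrases search positions in an order that prefers
horizontal bands near the vertical centre, which packs multi-word term
names much tighter than square-ish spirals.  Phrases are never split or
rotated — a term name only carries meaning as a unit.  If some phrase
cannot be placed, all font sizes are shrunk by a common factor and the
layout restarts, so relative sizes are preserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .enrich import EnrichedTerm

#: weights are capped here so a single extreme p-value cannot dominate a cloud
DEFAULT_WEIGHT_CAP = 16.0
#: grayscale range: weakest term at 0.65 (still legible), strongest at 0.0
GRAY_RANGE = (0.65, 0.0)

# box-size model: average glyph advance and line height as fractions of the
# font size, for a typical sans-serif face
_CHAR_ASPECT = 0.58
_LINE_HEIGHT = 1.15
_SMALLEST_POSITIVE = float(np.nextafter(0, 1))


class LayoutError(RuntimeError):
    """A word cannot be placed even at the minimum font size."""


@dataclass(frozen=True)
class WordItem:
    """A phrase with its display weight and (optional) gray level."""

    text: str
    weight: float
    gray: float = 0.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"displayed items need weight > 0, got {self.weight}")
        if not (0.0 <= self.gray <= 1.0):
            raise ValueError(f"gray must be in [0, 1], got {self.gray}")


@dataclass(frozen=True)
class Placement:
    """One placed phrase: lower-left anchor, box extent and font size."""

    text: str
    x: float
    y: float
    width: float
    height: float
    font_size: float
    gray: float


@dataclass(frozen=True)
class CloudLayout:
    """A packed cloud: canvas extent plus non-overlapping placements."""

    canvas_width: float
    canvas_height: float
    placements: tuple[Placement, ...]
    scale: float = 1.0  # global shrink factor that was needed to fit


def compute_weights(
    terms: Sequence[EnrichedTerm], cap: float = DEFAULT_WEIGHT_CAP
) -> list[WordItem]:
    """Map terms to :class:`WordItem` with ``weight = -log10(p_adj)``.

    ``p_adj`` of exactly 0 is clamped to the smallest positive float (with a
    warning); weights are capped (default 16) so one term cannot dwarf the
    rest of the cloud.
    """
    import logging

    items: list[WordItem] = []
    for t in terms:
        p = t.p_adj
        if p == 0:
            logging.getLogger(__name__).warning(
                "term %s has p_adj = 0; clamping for the log scale", t.term_id
            )
            p = _SMALLEST_POSITIVE
        w = min(-math.log10(p), cap)
        if w <= 0:
            continue  # p == 1 carries no display weight
        items.append(WordItem(text=t.term_name, weight=w))
    return items


def feature_items(
    names: Sequence[str], p_values: Sequence[float], cap: float = DEFAULT_WEIGHT_CAP
) -> list[WordItem]:
    """Build WordItems directly from feature names and p-values.

    Used when the cloud shows correlated features (taxa, metabolites, gene
    names) rather than enrichment results.
    """
    items = []
    for name, p in zip(names, p_values):
        if p == 0:
            p = _SMALLEST_POSITIVE
        w = min(-math.log10(p), cap)
        if w > 0:
            items.append(WordItem(text=name, weight=w))
    return items


def compute_grays(
    clouds: Sequence[Sequence[WordItem]], gray_range: tuple[float, float] = GRAY_RANGE
) -> list[list[WordItem]]:
    """Assign grays by a single affine map over the figure-wide weight range.

    The weakest item anywhere in the figure gets ``gray_range[0]`` and the
    strongest ``gray_range[1]``; identical weights in different clouds get
    identical grays.  A degenerate range (all weights equal) maps everything
    to the strong end (black).
    """
    weights = [it.weight for cloud in clouds for it in cloud]
    if not weights:
        return [list(c) for c in clouds]
    w_min, w_max = min(weights), max(weights)
    g_lo, g_hi = gray_range

    def gray(w: float) -> float:
        if w_max == w_min:
            return g_hi
        return g_lo + (w - w_min) * (g_hi - g_lo) / (w_max - w_min)

    return [[replace(it, gray=gray(it.weight)) for it in cloud] for cloud in clouds]


def _box_size(text: str, font: float) -> tuple[float, float]:
    return _CHAR_ASPECT * font * max(len(text), 1), _LINE_HEIGHT * font


def _candidate_grid(width: float, height: float, step: float, rng: np.random.Generator):
    xs = np.arange(step / 2, width, step)
    ys = np.arange(step / 2, height, step)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    # deterministic sub-grid jitter so repeated layouts with different seeds
    # explore slightly different packings
    pts = pts + rng.uniform(-step / 4, step / 4, size=pts.shape)
    return pts


def place_words(
    items: Sequence[WordItem],
    canvas: tuple[float, float] = (250.0, 110.0),
    seed: int = 0,
    max_font: float = 20.0,
    min_font: float = 4.0,
    shrink: float = 0.95,
    max_restarts: int = 200,
) -> CloudLayout:
    """Pack *items* into *canvas*; greedy, heaviest first, deterministic.

    Font sizes are proportional to weight, rescaled so the heaviest item
    gets ``max_font`` points.  If any phrase cannot be placed, every font is
    multiplied by ``shrink`` and the whole layout restarts; the final common
    factor is reported as ``CloudLayout.scale``.

    Raises
    ------
    LayoutError
        If a single phrase cannot fit the canvas even at ``min_font``, or
        the restart budget is exhausted.
    """
    if not items:
        raise ValueError("cannot lay out an empty cloud")
    W, H = float(canvas[0]), float(canvas[1])
    if W <= 0 or H <= 0:
        raise ValueError("canvas must have positive area")

    order = sorted(items, key=lambda it: (-it.weight, it.text))
    w_max = order[0].weight
    base_fonts = np.array([max_font * it.weight / w_max for it in order])

    # a phrase that overflows the canvas at the minimum font can never be placed
    for it in order:
        bw, bh = _box_size(it.text, min_font)
        if bw > W or bh > H:
            raise LayoutError(
                f"phrase {it.text!r} cannot fit a {W:g}x{H:g} canvas even at "
                f"{min_font:g} pt"
            )

    rng = np.random.default_rng(seed)
    step = max(2.0, min(W, H) / 40.0)
    cand = _candidate_grid(W, H, step, rng)
    dx = (cand[:, 0] - W / 2) / (W / 2)
    dy = (cand[:, 1] - H / 2) / (H / 2)
    # normal order: elliptical spiral outward from centre;
    # long-phrase order: vertical deviation penalised, forming horizontal bands
    order_normal = np.argsort(dx**2 + dy**2, kind="stable")
    order_band = np.argsort(dx**2 + (3.0 * dy) ** 2, kind="stable")

    scale = 1.0
    for _ in range(max_restarts):
        fonts = base_fonts * scale
        result = _try_layout(order, fonts, cand, order_normal, order_band, W, H)
        if result is not None:
            return CloudLayout(
                canvas_width=W, canvas_height=H,
                placements=tuple(result), scale=scale,
            )
        if fonts[0] * shrink < min_font:
            # even the heaviest word would drop below the minimum font
            raise LayoutError(
                f"cloud of {len(order)} phrases cannot be packed into a "
                f"{W:g}x{H:g} canvas at >= {min_font:g} pt"
            )
        scale *= shrink
    raise LayoutError(
        f"layout did not converge after {max_restarts} shrink restarts"
    )


def _try_layout(order, fonts, cand, order_normal, order_band, W, H):
    placed: list[Placement] = []
    px = np.empty(len(order)); py = np.empty(len(order))
    pw = np.empty(len(order)); ph = np.empty(len(order))
    for i, (it, font) in enumerate(zip(order, fonts)):
        bw, bh = _box_size(it.text, font)
        long_phrase = bw > 4.0 * bh
        idx = order_band if long_phrase else order_normal
        cx, cy = cand[idx, 0], cand[idx, 1]
        ok = (
            (cx - bw / 2 >= 0) & (cx + bw / 2 <= W)
            & (cy - bh / 2 >= 0) & (cy + bh / 2 <= H)
        )
        if placed:
            # open-interval overlap against every placed box, vectorised
            sep_x = np.abs(cx[:, None] - px[None, :i]) >= (bw + pw[None, :i]) / 2
            sep_y = np.abs(cy[:, None] - py[None, :i]) >= (bh + ph[None, :i]) / 2
            ok &= (sep_x | sep_y).all(axis=1)
        hit = np.flatnonzero(ok)
        if hit.size == 0:
            return None
        j = hit[0]
        x, y = float(cx[j]), float(cy[j])
        px[i], py[i], pw[i], ph[i] = x, y, bw, bh
        placed.append(
            Placement(
                text=it.text, x=x - bw / 2, y=y - bh / 2,
                width=bw, height=bh, font_size=float(font), gray=it.gray,
            )
        )
    return placed
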