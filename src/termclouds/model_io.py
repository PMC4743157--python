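"""Versioned JSON serialization of a :class:`SummaryModel`.

The two-step workflow (analyse, then plot) hands an intermediate model file
between the steps.  The schema is flat JSON: blocks with their gene lists,
enriched terms, word items and panel statistics, plus the display
parameters.  Round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

from .cloud import WordItem
from .enrich import EnrichedTerm
from .ontology import GeneList
from .producers import (
    Block,
    BoxplotPanel,
    BoxStats,
    CountPanel,
    DisplayParams,
    HistogramPanel,
    SummaryModel,
)

SCHEMA_VERSION = 1


def _panel_to_dict(panel) -> dict:
    if isinstance(panel, BoxplotPanel):
        return {
            "kind": "boxplot",
            "sample_ids": list(panel.sample_ids),
            "stats": [vars(s) for s in panel.stats],
        }
    if isinstance(panel, HistogramPanel):
        return {
            "kind": "histogram",
            "bin_edges": list(panel.bin_edges),
            "classes": list(panel.classes),
            "counts": [list(c) for c in panel.counts],
        }
    return {"kind": "none"}


def _panel_from_dict(d: dict):
    if d["kind"] == "boxplot":
        return BoxplotPanel(
            sample_ids=tuple(d["sample_ids"]),
            stats=tuple(BoxStats(**s) for s in d["stats"]),
        )
    if d["kind"] == "histogram":
        return HistogramPanel(
            bin_edges=tuple(d["bin_edges"]),
            classes=tuple(d["classes"]),
            counts=tuple(tuple(c) for c in d["counts"]),
        )
    return CountPanel()


def model_to_dict(model: SummaryModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "panel_kind": model.panel_kind,
        "display": {
            **vars(model.display),
            "gray_range": list(model.display.gray_range),
        },
        "blocks": [
            {
                "title": b.title,
                "annotation": b.annotation,
                "gene_lists": [
                    {"label": g.label, "genes": list(g.genes), "side": g.side}
                    for g in b.gene_lists
                ],
                "clouds": [[vars(w) for w in cloud] for cloud in b.clouds],
                "terms": [[vars(t) for t in ts] for ts in b.terms],
                "panel": _panel_to_dict(b.panel),
            }
            for b in model.blocks
        ],
    }


def model_from_dict(d: dict) -> SummaryModel:
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r}")
    disp = dict(d["display"])
    disp["gray_range"] = tuple(disp["gray_range"])
    blocks = []
    for bd in d["blocks"]:
        blocks.append(
            Block(
                title=bd["title"],
                annotation=bd["annotation"],
                gene_lists=tuple(
                    GeneList(label=g["label"], genes=tuple(g["genes"]), side=g["side"])
                    for g in bd["gene_lists"]
                ),
                clouds=tuple(
                    tuple(WordItem(**w) for w in cloud) for cloud in bd["clouds"]
                ),
                terms=tuple(
                    tuple(EnrichedTerm(**t) for t in ts) for ts in bd["terms"]
                ),
                panel=_panel_from_dict(bd["panel"]),
            )
        )
    return SummaryModel(
        blocks=blocks, panel_kind=d["panel_kind"], display=DisplayParams(**disp)
    )


def save_model(model: SummaryModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path) -> SummaryModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
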