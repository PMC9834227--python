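"""Developmental-origin classification for a mosaic somatic variant.

Cell types descend from the embryonic germ layers; a post-zygotic variant
observed in cell types from two or more distinct layers must have arisen
before gastrulation separated them. The classifier consumes the per-cluster
call composition, maps clusters to germ layers, and applies a configurable
minimum-evidence threshold per layer — a guard against the single-nucleus
false positives the genotyper's null-set analysis shows are possible. The
threshold is this package's parameter, not a field convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

GERM_LAYERS = ("ectoderm", "mesoderm", "endoderm", "unknown")

#: germ-layer assignment for the major cell types of a brain resection
DEFAULT_GERM_LAYER_MAP: dict[str, str] = {
    "Microglia": "mesoderm",
    "Lymphocytes": "mesoderm",
    "ExcitatoryNeurons": "ectoderm",
    "Interneurons": "ectoderm",
    "MGE-DerivedInterneurons": "ectoderm",
    "CGE-DerivedInterneurons": "ectoderm",
    "Astrocytes": "ectoderm",
    "Oligodendrocytes": "ectoderm",
    "OPC": "ectoderm",
    "Mitochondrial": "unknown",
}

PRE_GASTRULATION = "pre_gastrulation"
LINEAGE_RESTRICTED = "lineage_restricted"
INSUFFICIENT_EVIDENCE = "insufficient_evidence"


@dataclass(frozen=True)
class LineageCall:
    variant: str
    layers_with_alt: frozenset[str]
    n_alt_per_layer: Mapping[str, int]
    classification: str
    excluded_clusters: tuple[str, ...]  # clusters with no known germ layer

    def __post_init__(self) -> None:
        if self.classification == PRE_GASTRULATION and len(self.layers_with_alt) < 2:
            raise ValueError("pre_gastrulation requires alt evidence in >= 2 layers")


def classify_origin(
    vaf_table: pd.DataFrame,
    germ_map: Mapping[str, str],
    min_alt_cells_per_layer: int = 2,
    variant: str = "",
) -> LineageCall:
    """Classify a variant's developmental origin from per-cluster alt counts.

    A germ layer "has alt" when the alt-cell total over its cell types
    reaches ``min_alt_cells_per_layer``. Two or more such layers imply the
    variant predates gastrulation; exactly one implies a lineage-restricted
    origin; none is insufficient evidence. Clusters mapping to 'unknown'
    or missing from the map are excluded and reported.
    """
    if vaf_table.empty:
        raise ValueError("empty per-cluster table")
    df = vaf_table[vaf_table["cluster"] != "ALL"]
    n_alt_per_layer: dict[str, int] = {}
    excluded = []
    for _, row in df.iterrows():
        layer = germ_map.get(row["cluster"], "unknown")
        if layer == "unknown":
            excluded.append(row["cluster"])
            continue
        n_alt_per_layer[layer] = n_alt_per_layer.get(layer, 0) + int(row["n_alt"])
    layers_with_alt = frozenset(
        layer for layer, n in n_alt_per_layer.items() if n >= min_alt_cells_per_layer
    )
    if len(layers_with_alt) >= 2:
        classification = PRE_GASTRULATION
    elif len(layers_with_alt) == 1:
        classification = LINEAGE_RESTRICTED
    else:
        classification = INSUFFICIENT_EVIDENCE
    return LineageCall(
        variant=variant,
        layers_with_alt=layers_with_alt,
        n_alt_per_layer=n_alt_per_layer,
        classification=classification,
        excluded_clusters=tuple(excluded),
    )


def load_germ_layer_map(path: str) -> dict[str, str]:
    """Read a cell_type -> germ layer map from TSV (two columns) or YAML."""
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            mapping = yaml.safe_load(fh)
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["cell_type", "germ_layer"])
        mapping = dict(zip(df["cell_type"], df["germ_layer"]))
    bad = {k: v for k, v in mapping.items() if v not in GERM_LAYERS}
    if bad:
        raise ValueError(f"unknown germ layers: {bad}")
    return mapping
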