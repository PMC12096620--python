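"""Marker panels and phenotype vocabularies.

Two multiplexed-immunofluorescence panels are supported:

* ``IHC4`` — the clinical breast-cancer biomarkers ER, PR, HER2, Ki67 plus
  CK8/18 as the epithelial mask marker, with DAPI for nuclear QC.
* ``Immune`` — T-cell and macrophage lineage markers plus checkpoint
  proteins (CD3, CD8, CD68, CD163, FoxP3, PD1, PDL1), Ki67, CK8/18, DAPI.

Column names use ``_`` instead of ``/`` so they are safe CSV headers.
"""

from __future__ import annotations

IHC4 = "IHC4"
IMMUNE = "Immune"

DAPI = "DAPI"
CK = "CK8_18"

IHC4_MARKERS = ["ER", "PR", "HER2", "Ki67", CK]
IMMUNE_MARKERS = ["CD3", "CD8", "CD68", "CD163", "FoxP3", "PD1", "PDL1", "Ki67", CK]

#: markers actually constrained by the default immune gates
GATED_IMMUNE_MARKERS = ["CD3", "CD8", "CD68", "CD163", "PD1", "PDL1", CK]

PANEL_MARKERS = {IHC4: IHC4_MARKERS, IMMUNE: IMMUNE_MARKERS}

#: identifier / geometry columns every cell table must carry
ID_COLUMNS = ["cell_id", "case_id", "core_id", "x", "y", "area"]

#: the ten cell-type features used for patch composition vectors:
#: cancer epithelium plus nine immune lineage phenotypes
CELL_CLASSES = [
    "CK+",
    "CD3+/CD8-",
    "CD3+/CD8+",
    "CD68+",
    "CD163+",
    "CD68+/CD163+",
    "CD68+/PDL1+",
    "CD163+/PDL1+",
    "CD3+/CD8+/PD1+",
    "CD3+/CD8-/PD1+",
]

OTHER = "other"

SUBTYPES = ["LumA", "LumB", "HER2E", "Basal"]

NORM_SUFFIX = "_norm"


def norm_col(marker: str) -> str:
    """Column name holding the normalized intensity of ``marker``."""
    return marker + NORM_SUFFIX


def required_columns(panel: str) -> list[str]:
    """Required columns of a raw cell table for ``panel`` (ids + DAPI + markers)."""
    if panel not in PANEL_MARKERS:
        raise KeyError(f"unknown panel {panel!r}; expected one of {sorted(PANEL_MARKERS)}")
    return ID_COLUMNS + [DAPI] + PANEL_MARKERS[panel]
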