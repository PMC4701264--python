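"""Feature taxonomy for river hydromorphology mapping.

Twelve feature classes cover the substrate, water and vegetation units used
in UK river habitat assessment (side bars, erosion, riffle, deep water,
shallow water, tree, vegetated bar, vegetated bank, submerged and emergent
free-floating vegetation, grass) plus shadow. Classified maps store one small
integer code per pixel, with 0 reserved for unclassified/nodata.

For grid validation the map side of the comparison uses nine merged
categories: the non-tree vegetation classes collapse to a single VG category
(trees stay separate as TE), and GE flags points displaced by tile
misregistration when that fault-injection mode is active.
"""

from __future__ import annotations

import enum


class FeatureClass(enum.IntEnum):
    """Hydromorphological feature classes; integer values are the raster codes."""

    SIDE_BAR = 1
    EROSION = 2
    RIFFLE = 3
    DEEP_WATER = 4
    SHALLOW_WATER = 5
    TREE = 6
    VEGETATED_BAR = 7
    VEGETATED_BANK = 8
    SUBMERGED_VEG = 9
    EMERGENT_VEG = 10
    GRASS = 11
    SHADOW = 12


UNCLASSIFIED = 0

#: Canonical truth-row order for confusion matrices.
TRUTH_ORDER: tuple[FeatureClass, ...] = (
    FeatureClass.SIDE_BAR,
    FeatureClass.EROSION,
    FeatureClass.RIFFLE,
    FeatureClass.DEEP_WATER,
    FeatureClass.SHALLOW_WATER,
    FeatureClass.TREE,
    FeatureClass.VEGETATED_BAR,
    FeatureClass.VEGETATED_BANK,
    FeatureClass.SUBMERGED_VEG,
    FeatureClass.EMERGENT_VEG,
    FeatureClass.GRASS,
    FeatureClass.SHADOW,
)

#: Merged map-side categories, in canonical column order. "NC" (not
#: classified) is appended by :func:`hydromorph.validation.confusion` only
#: when unclassified predictions occur.
PRED_CATEGORIES: tuple[str, ...] = (
    "SB", "ER", "RI", "DW", "SW", "TE", "SH", "VG", "GE",
)

#: Merged category each feature class maps to on the prediction side.
CATEGORY_OF: dict[FeatureClass, str] = {
    FeatureClass.SIDE_BAR: "SB",
    FeatureClass.EROSION: "ER",
    FeatureClass.RIFFLE: "RI",
    FeatureClass.DEEP_WATER: "DW",
    FeatureClass.SHALLOW_WATER: "SW",
    FeatureClass.TREE: "TE",
    FeatureClass.VEGETATED_BAR: "VG",
    FeatureClass.VEGETATED_BANK: "VG",
    FeatureClass.SUBMERGED_VEG: "VG",
    FeatureClass.EMERGENT_VEG: "VG",
    FeatureClass.GRASS: "VG",
    FeatureClass.SHADOW: "SH",
}

_NAME_ALIASES = {
    "side_bar": FeatureClass.SIDE_BAR,
    "side bars": FeatureClass.SIDE_BAR,
    "bars": FeatureClass.SIDE_BAR,
    "sb": FeatureClass.SIDE_BAR,
    "erosion": FeatureClass.EROSION,
    "er": FeatureClass.EROSION,
    "riffle": FeatureClass.RIFFLE,
    "ri": FeatureClass.RIFFLE,
    "deep_water": FeatureClass.DEEP_WATER,
    "deep water": FeatureClass.DEEP_WATER,
    "dw": FeatureClass.DEEP_WATER,
    "shallow_water": FeatureClass.SHALLOW_WATER,
    "shallow water": FeatureClass.SHALLOW_WATER,
    "sw": FeatureClass.SHALLOW_WATER,
    "tree": FeatureClass.TREE,
    "trees": FeatureClass.TREE,
    "tr": FeatureClass.TREE,
    "te": FeatureClass.TREE,
    "vegetated_bar": FeatureClass.VEGETATED_BAR,
    "vegetated bar": FeatureClass.VEGETATED_BAR,
    "vb": FeatureClass.VEGETATED_BAR,
    "vegetated_bank": FeatureClass.VEGETATED_BANK,
    "vegetated bank": FeatureClass.VEGETATED_BANK,
    "vk": FeatureClass.VEGETATED_BANK,
    "submerged_veg": FeatureClass.SUBMERGED_VEG,
    "submerged vegetation": FeatureClass.SUBMERGED_VEG,
    "sv": FeatureClass.SUBMERGED_VEG,
    "emergent_veg": FeatureClass.EMERGENT_VEG,
    "emergent vegetation": FeatureClass.EMERGENT_VEG,
    "ev": FeatureClass.EMERGENT_VEG,
    "grass": FeatureClass.GRASS,
    "gr": FeatureClass.GRASS,
    "shadow": FeatureClass.SHADOW,
    "shadows": FeatureClass.SHADOW,
    "sh": FeatureClass.SHADOW,
}


def parse_class(name: str) -> FeatureClass:
    """Resolve a class name or common abbreviation to a :class:`FeatureClass`."""
    key = name.strip().lower().replace("-", "_")
    try:
        return _NAME_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown feature class {name!r}") from None
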