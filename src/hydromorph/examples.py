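"""Bundled worked example: a field-survey confusion matrix.

The matrix tallies 13,085 validation grid points (2 m spacing) from a UAV
survey of a 1.4 km upland river reach: rows are the visually classified truth
classes, columns the merged map categories produced by the one-vs-rest ANN
classification, including a GE column for points displaced by tile
misregistration in the mapping workflow. It exercises the full metric
arithmetic on realistic, imbalanced class counts.
"""

from __future__ import annotations

import numpy as np

from .classes import PRED_CATEGORIES, TRUTH_ORDER
from .validation import ConfusionMatrix

# columns: SB, ER, RI, DW, SW, TE, SH, VG, GE
_SURVEY_COUNTS = {
    "SIDE_BAR":       [1097, 0,    8,    0,    2,    0,   10,  214, 3],
    "EROSION":        [0,    22,   13,   1,    3,    0,   10,  238, 0],
    "RIFFLE":         [0,    1,    2717, 0,    318,  0,   219, 76,  8],
    "DEEP_WATER":     [0,    0,    60,   1927, 54,   0,   8,   29,  4],
    "SHALLOW_WATER":  [0,    0,    262,  80,   1514, 0,   493, 217, 7],
    "TREE":           [0,    0,    76,   1,    29,   496, 135, 1013, 5],
    "VEGETATED_BAR":  [0,    0,    0,    0,    0,    0,   0,   299, 0],
    "VEGETATED_BANK": [0,    10,   0,    6,    0,    0,   15,  281, 1],
    "SUBMERGED_VEG":  [0,    0,    160,  0,    125,  0,   46,  135, 2],
    "EMERGENT_VEG":   [0,    1,    9,    0,    2,    0,   1,   58,  0],
    "GRASS":          [0,    0,    0,    0,    0,    0,   0,   343, 1],
    "SHADOW":         [0,    4,    0,    0,    5,    0,   180, 31,  0],
}


def example_survey_confusion() -> ConfusionMatrix:
    """The bundled 12-class x 9-category survey confusion matrix (13,085 points)."""
    counts = np.array([_SURVEY_COUNTS[c.name] for c in TRUTH_ORDER], dtype=np.int64)
    return ConfusionMatrix(truth_classes=TRUTH_ORDER,
                           pred_categories=PRED_CATEGORIES, counts=counts)
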