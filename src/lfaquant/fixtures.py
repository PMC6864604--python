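"""Packaged reference data: the published T/C reading tables and confusion matrix.

Three LFA sets of five quantity classes (10 fg, 100 fg, 1 pg, 10 pg, 100 pg),
five readings each — 75 readings total, stored verbatim at the 3-decimal
precision the tables print. Sets #1 and #2 are the study's training sets,
set #3 its test set.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import List

import numpy as np

from .calibration import Reading
from .classify import ConfusionMatrix

__all__ = [
    "load_fixture_readings",
    "load_test_confusion_matrix",
    "QUANTITY_CLASSES_FG",
    "TRAINING_SET_IDS",
    "TEST_SET_ID",
]

QUANTITY_CLASSES_FG = (10.0, 100.0, 1000.0, 10000.0, 100000.0)
TRAINING_SET_IDS = (1, 2)
TEST_SET_ID = 3


def load_fixture_readings() -> List[Reading]:
    """All 75 packaged T/C readings (3 sets x 5 classes x 5 readings)."""
    path = resources.files("lfaquant.data").joinpath("tc_readings.csv")
    readings: List[Reading] = []
    lines = path.read_text().strip().splitlines()
    for line in lines[1:]:
        set_id, quantity, index, tc = line.split(",")
        readings.append(
            Reading(
                set_id=int(set_id),
                quantity_fg=float(quantity),
                tc_ratio=float(tc),
                reading_index=int(index),
            )
        )
    return readings


def load_test_confusion_matrix() -> ConfusionMatrix:
    """The published test-set confusion matrix (10 replicate readings per strip)."""
    path = resources.files("lfaquant.data").joinpath("test_confusion_matrix.json")
    d = json.loads(path.read_text())
    return ConfusionMatrix(
        labels=tuple(float(q) for q in d["labels_fg"]),
        counts=np.array(d["counts"], dtype=int),
    )
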