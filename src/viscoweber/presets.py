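"""Bundled stimulus inventory, group layouts and task presets.

The package ships the silicone-oil stimulus set used by the discrimination
studies it was written for: 21 samples, each prepared in a transparent and an
opaque (pigmented) variant whose measured viscosities differ slightly.  Five
constant-stimuli groups (A-E) are defined over the same sample ids for both
variants; each group pairs a central reference with three thinner and three
thicker tests.  Adjacent groups share a physical test/reference pair, which is
what makes pair de-duplication within an appearance possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

GROUP_LABELS = ("A", "B", "C", "D", "E")

APPEARANCES = ("transparent", "opaque")

# sample_id -> (transparent viscosity cP, opaque viscosity cP)
VISCOSITY_TABLE: Mapping[int, tuple[float, float]] = {
    1: (153.0, 152.0),
    2: (179.0, 202.0),
    3: (272.0, 306.0),
    4: (547.0, 544.0),
    5: (620.0, 687.0),
    6: (756.0, 827.0),
    7: (1040.0, 1110.0),
    8: (1130.0, 1230.0),
    9: (1290.0, 1420.0),
    10: (1560.0, 1710.0),
    11: (1930.0, 2140.0),
    12: (2580.0, 2980.0),
    13: (3520.0, 4050.0),
    14: (5520.0, 5870.0),
    15: (7060.0, 7420.0),
    16: (9480.0, 10630.0),
    17: (12950.0, 14140.0),
    18: (15530.0, 16850.0),
    19: (18930.0, 20440.0),
    20: (22780.0, 25650.0),
    21: (31160.0, 33810.0),
}

# group label -> (reference sample id, ordered test sample ids)
GROUPINGS: Mapping[str, tuple[int, tuple[int, ...]]] = {
    "A": (4, (1, 2, 3, 5, 6, 7)),
    "B": (7, (4, 5, 6, 8, 9, 10)),
    "C": (10, (7, 8, 9, 11, 12, 13)),
    "D": (13, (10, 11, 12, 14, 15, 16)),
    "E": (18, (15, 16, 17, 19, 20, 21)),
}


@dataclass(frozen=True)
class TaskPreset:
    """Layout and cohort size of one 2AFC task, plus a plausible observer."""

    task_id: str
    modality: str  # visual | haptic | mixed
    reference_appearance: str
    test_appearance: str
    n_subjects: int
    n_pairs: int
    measured: str  # "weber" (fixed-p fits) | "bias" (free-p fits)
    w_by_group: Mapping[str, float]
    appearance_gain: Mapping[str, float]


# Weber fractions in the presets sit in the ~0.5-1.5 range reported for this
# kind of task; the opaque group-E value is deliberately near-flat so that the
# CI-width exclusion rule fires on simulated data, as it did on the real data.
TASK_PRESETS: Mapping[str, TaskPreset] = {
    "task1a": TaskPreset(
        "task1a", "visual", "transparent", "transparent", 57, 32, "weber",
        {"A": 1.00, "B": 0.78, "C": 0.57, "D": 1.05, "E": 1.43},
        {"transparent": 1.0, "opaque": 1.0},
    ),
    "task1b": TaskPreset(
        "task1b", "visual", "opaque", "opaque", 57, 32, "weber",
        {"A": 0.87, "B": 0.61, "C": 0.77, "D": 1.06, "E": 2.50},
        {"transparent": 1.0, "opaque": 1.0},
    ),
    "task1c": TaskPreset(
        "task1c", "visual", "opaque", "transparent", 110, 35, "bias",
        {"A": 1.00, "B": 0.78, "C": 0.57, "D": 1.05, "E": 1.43},
        # transparent liquids look thinner: a transparent test must be ~2.6x
        # as viscous as an opaque reference to match it at low viscosity
        {"transparent": 0.38, "opaque": 1.0},
    ),
    "task2": TaskPreset(
        "task2", "haptic", "transparent", "transparent", 64, 32, "weber",
        {"A": 1.05, "B": 1.08, "C": 0.66, "D": 0.82, "E": 0.74},
        {"transparent": 1.0, "opaque": 1.0},
    ),
    "task3a": TaskPreset(
        "task3a", "mixed", "transparent", "transparent", 50, 32, "weber",
        {"A": 1.29, "B": 0.86, "C": 0.63, "D": 0.54, "E": 0.62},
        {"transparent": 1.0, "opaque": 1.0},
    ),
    "task3b": TaskPreset(
        "task3b", "mixed", "opaque", "transparent", 50, 35, "bias",
        {"A": 1.29, "B": 0.86, "C": 0.63, "D": 0.54, "E": 0.62},
        # haptic access strongly reduces, but does not abolish, the bias
        {"transparent": 0.81, "opaque": 1.0},
    ),
}


def stimulus_rows() -> list[tuple[int, str, float]]:
    """Flatten the bundled inventory to (sample_id, appearance, viscosity_cp)."""
    rows: list[tuple[int, str, float]] = []
    for sid, (v_t, v_o) in VISCOSITY_TABLE.items():
        rows.append((sid, "transparent", v_t))
        rows.append((sid, "opaque", v_o))
    return rows
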