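"""Bundled reference figures for the worked economic example.

Average annual grain-maize gross margins and direct economic impacts for
13 EU member states (FADN-derived panel means 2010-2020, EUROSTAT areas),
under three expert-elicited yield-loss scenarios (best / moderate / worst
= 2.25th / 50th / 97.5th percentile of the member-state yield-loss
distribution). Per-hectare values are € / ha rounded to integers; national
values are million € rounded to one decimal — the published presentation
precision. These tables serve as inputs to the worked example and the
consistency checks of the partial-budgeting operations; they are not
recomputed by the package.
"""

from __future__ import annotations

import pandas as pd

_STATES = [
    "Austria", "Bulgaria", "Croatia", "France", "Germany", "Greece",
    "Hungary", "Italy", "Poland", "Portugal", "Slovakia", "Slovenia",
    "Spain",
]

# state: (baseline, best, moderate, worst) gross margin €/ha,
#        then (best, moderate, worst) direct economic impact €/ha
_PER_HA = {
    "Austria":  (373, 372, 354, 300, 1, 19, 73),
    "Bulgaria": (446, 444, 420, 346, 2, 26, 100),
    "Croatia":  (196, 194, 166, 80, 2, 30, 116),
    "France":   (375, 373, 346, 264, 2, 29, 111),
    "Germany":  (343, 342, 330, 293, 1, 13, 51),
    "Greece":   (766, 755, 623, 220, 11, 143, 546),
    "Hungary":  (417, 415, 396, 337, 2, 21, 80),
    "Italy":    (756, 748, 652, 357, 8, 104, 398),
    "Poland":   (408, 408, 400, 377, 1, 8, 31),
    "Portugal": (760, 752, 645, 321, 9, 115, 440),
    "Slovakia": (189, 188, 175, 137, 1, 14, 52),
    "Slovenia": (81, 78, 50, -37, 2, 31, 118),
    "Spain":    (985, 979, 905, 679, 6, 80, 306),
}

# state: (baseline, best, moderate, worst) gross margin million €,
#        then (best, moderate, worst) direct economic impact million €
_NATIONAL = {
    "Austria":  (78, 78, 74, 63, 0.3, 4.0, 15.2),
    "Bulgaria": (217, 216, 204, 168, 1.0, 12.8, 48.7),
    "Croatia":  (52, 51, 44, 21, 0.6, 8.0, 30.7),
    "France":   (585, 582, 540, 412, 3.5, 45.3, 172.9),
    "Germany":  (152, 152, 146, 130, 0.5, 5.9, 22.6),
    "Greece":   (102, 101, 83, 29, 1.5, 19.1, 72.8),
    "Hungary":  (423, 421, 402, 342, 1.6, 21.2, 81.1),
    "Italy":    (496, 490, 427, 234, 5.3, 68.4, 261.3),
    "Poland":   (328, 327, 321, 303, 0.5, 6.6, 25.0),
    "Portugal": (65, 65, 55, 28, 0.8, 9.9, 37.8),
    "Slovakia": (7, 7, 7, 5, 0.0, 0.5, 2.1),
    "Slovenia": (15, 15, 9, -7, 0.4, 5.8, 22.2),
    "Spain":    (349, 347, 321, 241, 2.2, 28.4, 108.6),
}

_COLUMNS = ["gm_baseline", "gm_best", "gm_moderate", "gm_worst",
            "dei_best", "dei_moderate", "dei_worst"]


def eu_maize_gross_margins_per_ha() -> pd.DataFrame:
    """Per-hectare reference table (€/ha), one row per member state."""
    df = pd.DataFrame.from_dict(_PER_HA, orient="index", columns=_COLUMNS)
    df.index.name = "state"
    return df.loc[_STATES].reset_index()


def eu_maize_gross_margins_national() -> pd.DataFrame:
    """National reference table (million €), one row per member state."""
    df = pd.DataFrame.from_dict(_NATIONAL, orient="index", columns=_COLUMNS)
    df.index.name = "state"
    return df.loc[_STATES].reset_index()
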