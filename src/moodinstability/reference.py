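"""Published reference values from the bipolar longitudinal cohort (PLS-BD).

The cohort itself is available only under a Data Use Agreement, but the
published participant-level threshold-membership counts serve as worked-
example fixtures: the percentages can be recomputed from the counts and the
counts can seed contingency-table examples.  Only the raw counts are stored;
no published test statistic is treated as a ground truth (their exact
contingency construction is not documented).
"""

from __future__ import annotations

#: Participants with at least one usable one-year rolling-variance window,
#: per scale and diagnostic group (BD bipolar, HC healthy control, PC
#: psychiatric comparison).
REFERENCE_N = {
    "ASRM": {"BD": 325, "HC": 140, "PC": 64},
    "GAD7": {"BD": 286, "HC": 132, "PC": 55},
    "PHQ9": {"BD": 322, "HC": 140, "PC": 66},
}

#: Participant counts in each instability category (published Table-1-style
#: membership).  Percentages are NOT stored; they are recomputed from these
#: counts, which is exactly what the worked examples verify.
REFERENCE_THRESHOLD_COUNTS = {
    "ASRM": {
        "low": {"BD": 133, "HC": 114, "PC": 44},
        "moderate": {"BD": 157, "HC": 24, "PC": 17},
        "high": {"BD": 35, "HC": 2, "PC": 3},
    },
    "GAD7": {
        "low": {"BD": 113, "HC": 126, "PC": 39},
        "moderate": {"BD": 147, "HC": 5, "PC": 14},
        "high": {"BD": 26, "HC": 1, "PC": 2},
    },
    "PHQ9": {
        "low": {"BD": 115, "HC": 136, "PC": 49},
        "moderate": {"BD": 170, "HC": 4, "PC": 17},
        "high": {"BD": 37, "HC": 0, "PC": 0},
    },
}

#: Published cohort group sizes (enrolled, before per-scale missingness).
REFERENCE_GROUP_SIZES = {"BD": 385, "PC": 71, "HC": 147}


def membership_percentage(scale: str, category: str, group: str) -> float:
    """Category membership as a percentage of the group's per-scale N."""
    count = REFERENCE_THRESHOLD_COUNTS[scale][category][group]
    n = REFERENCE_N[scale][group]
    return 100.0 * count / n
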