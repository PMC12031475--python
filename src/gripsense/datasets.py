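"""Summary data of the 21-participant wearable grip-detection
feasibility study, as inputs for re-analysis.

The study enrolled 12 relatively healthy (RH) adults and 9 adults
self-reporting a neurodegenerative disorder (ND).  Raw per-participant
recordings were not deposited; what is available are the participant
ages, the pooled grip-detection confusion counts per group, and the
per-question means of the six-item user-satisfaction questionnaire.
"""

from __future__ import annotations

__all__ = [
    "RH_AGES",
    "ND_AGES",
    "YOUNGER_RH_AGES",
    "OLDER_RH_AGES",
    "DETECTION_COUNTS",
    "USEQ_QUESTION_MEANS",
]

#: Ages of the 12 relatively healthy participants.
RH_AGES = (19, 19, 23, 26, 49, 56, 63, 69, 72, 75, 82, 89)

#: Ages of the 9 participants with a self-reported neurodegenerative disorder.
ND_AGES = (61, 78, 79, 81, 61, 66, 57, 71, 84)

#: The RH group split used in the age analyses: youngest six vs the rest.
YOUNGER_RH_AGES = tuple(sorted(RH_AGES)[:6])
OLDER_RH_AGES = tuple(sorted(RH_AGES)[6:])

#: Pooled grip-detection confusion counts per group: (TP, FP, FN),
#: aggregated over all participants of the group.
DETECTION_COUNTS = {
    "RH": (3450, 1323, 47),
    "ND": (2184, 777, 46),
}

#: Mean response per user-satisfaction question (1-5 Likert), Q1..Q6:
#: enjoyment, engagement, responsiveness, comfort, perceived performance,
#: ease of use.
USEQ_QUESTION_MEANS = {
    "Q1": 4.76,
    "Q2": 4.81,
    "Q3": 4.05,
    "Q4": 4.95,
    "Q5": 4.38,
    "Q6": 4.95,
}
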