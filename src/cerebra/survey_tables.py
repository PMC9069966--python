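"""Published summary counts from the CEREBRA behavioral survey.

Four rater streams (three participants who answered the full 24
questionnaires, plus a fourth stream pooled from 24 single-questionnaire
raters) each produced 3,600 ratings in {-1, 0, +1} of whether a target
word's attribute increased in a sentence. These summary counts support the
exact-arithmetic analyses: response distributions, pairwise agreement, the
consensus subsets, and the majority-class chance baselines.
"""

from __future__ import annotations

TOTAL_QUESTIONS = 3600

# Per-participant counts of ratings -1 / 0 / +1.
RESPONSE_DISTRIBUTION = {
    "P1": {-1: 2065, 0: 149, 1: 1386},
    "P2": {-1: 995, 0: 1120, 1: 1485},
    "P3": {-1: 645, 0: 1895, 1: 1060},
    "P4": {-1: 1185, 0: 1270, 1: 1145},
}

# Number of questions on which each pair of rater streams gave the same
# rating (out of TOTAL_QUESTIONS).
PAIRWISE_MATCHES = {
    ("P1", "P2"): 1726,
    ("P1", "P3"): 1308,
    ("P1", "P4"): 1650,
    ("P2", "P3"): 1944,
    ("P2", "P4"): 1758,
    ("P3", "P4"): 1741,
}

# Consensus subsets: questions where all four streams agreed, and where at
# least three of the four agreed.
UNANIMOUS_COUNT = 631
MAJORITY3_COUNT = 1966

# Consensus-label distributions (-1 / 0 / +1) within each subset.
UNANIMOUS_LABEL_COUNTS = {-1: 190, 0: 15, 1: 426}
MAJORITY3_LABEL_COUNTS = {-1: 618, 0: 456, 1: 892}
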