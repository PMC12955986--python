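"""Published summary tables of the reference study the generators emulate.

These are printed inputs, not computed outputs: the demographic table gives
group means, sample SDs and group sizes (plus male/female counts) for the
two clinical cohorts, and the decoder table gives the reported mean +/- SD
leave-one-subject-out accuracy (percent) of each state-combination emotion
decoder.  The statistics kernel recomputes the demographic test statistics
from these summaries, and the optimal-model rule is exercised against the
decoder table.
"""

from __future__ import annotations

from .stats import GroupSummary

#: (variable, cohort) -> (control summary, patient summary); reported t in
#: ``REPORTED_T`` follows the control-minus-patient sign convention.
DEMOGRAPHIC_SUMMARIES = {
    ("age", "MDD"): (GroupSummary(49.14, 12.29, 100), GroupSummary(43.38, 10.68, 58)),
    ("BDI", "MDD"): (GroupSummary(8.10, 6.34, 100), GroupSummary(25.71, 8.62, 58)),
    ("age", "BD"): (GroupSummary(29.84, 7.13, 50), GroupSummary(31.71, 7.95, 59)),
    ("education", "BD"): (GroupSummary(14.58, 2.30, 50), GroupSummary(13.66, 2.67, 59)),
    ("YMRS", "BD"): (GroupSummary(0.16, 0.50, 19), GroupSummary(0.64, 0.93, 36)),
    ("BDI", "BD"): (GroupSummary(4.53, 4.33, 19), GroupSummary(9.50, 7.63, 22)),
    ("BAI", "BD"): (GroupSummary(22.7, 2.18, 19), GroupSummary(28.0, 6.03, 22)),
}

REPORTED_T = {
    ("age", "MDD"): 2.9756,
    ("BDI", "MDD"): -14.7003,
    ("age", "BD"): -1.2838,
    ("education", "BD"): 1.9086,
    ("YMRS", "BD"): -2.0924,
    ("BDI", "BD"): -2.5108,
    ("BAI", "BD"): -3.5655,
}

#: Sex contingency tables, rows = (control, patient), cols = (male, female).
SEX_TABLES = {
    "MDD": [[37, 63], [29, 29]],
    "BD": [[24, 26], [30, 29]],
}

REPORTED_CHI2 = {"MDD": 2.5506, "BD": 0.0878}

#: State-combination decoder accuracies, percent mean and SD, as published.
EMOTION_DECODER_ACCURACY = {
    (1,): (58.93, 31.84),
    (2,): (73.82, 19.48),
    (3,): (81.93, 19.78),
    (4,): (82.25, 20.82),
    (1, 2): (70.16, 24.59),
    (1, 3): (72.54, 30.03),
    (1, 4): (72.34, 24.27),
    (2, 3): (81.93, 18.20),
    (2, 4): (80.20, 22.53),
    (3, 4): (83.99, 18.56),
    (1, 2, 3): (73.21, 24.22),
    (1, 2, 4): (76.03, 20.75),
    (1, 3, 4): (71.67, 25.91),
    (2, 3, 4): (84.25, 19.06),
    (1, 2, 3, 4): (75.60, 21.56),
}
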