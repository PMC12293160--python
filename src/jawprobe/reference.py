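"""Published summary statistics of the 41 TD / 13 SSD validation cohort.

These printed tables are inputs to the package's metric computations: the
raw videos and consensus score sheets behind them are not deposited, but
the confusion matrices and group summaries they report are sufficient to
recompute every derived statistic (balanced accuracy/precision, per-class
recall/precision, Cohen's d with CI, pooled t).
"""

from __future__ import annotations

from .evaluate import ConfusionSummary
from .groupstats import GroupSummary

#: Confusion matrices of the published classification analyses.  Keys name
#: the scheme; positive class is SSD for "diagnosis" and "inappropriate"
#: for the word-level schemes.
REFERENCE_CONFUSIONS: dict[str, ConfusionSummary] = {
    # TD/SSD diagnosis from consensus perceptual scores
    "diagnosis": ConfusionSummary(tp=11, fn=2, fp=11, tn=30),
    # word-level appropriateness from kinematic features
    "jaw_range_mouth_opening": ConfusionSummary(tp=71, fn=45, fp=117, tn=307),
    "jaw_control_velocity": ConfusionSummary(tp=85, fn=100, fp=84, tn=271),
    "jaw_control_lateral": ConfusionSummary(tp=109, fn=76, fp=127, tn=228),
    "jaw_control_combined": ConfusionSummary(tp=88, fn=97, fp=71, tn=284),
}

#: Group summaries (TD as group 1, SSD as group 2) of the mandibular
#: criterion totals, percent total, and phoneme-accuracy percentages.
REFERENCE_GROUP_SUMMARIES: dict[str, GroupSummary] = {
    "jaw_range": GroupSummary(41, 13, 8.29, 6.46, 1.79, 2.22),
    "jaw_control": GroupSummary(41, 13, 6.95, 5.38, 2.96, 2.84),
    "phase": GroupSummary(41, 13, 6.54, 5.23, 3.29, 2.74),
    "voicing_transitions": GroupSummary(41, 13, 9.07, 7.92, 1.17, 1.38),
    "syllable_structure": GroupSummary(41, 13, 9.76, 9.54, 0.54, 0.52),
    "percent_total": GroupSummary(41, 13, 81.22, 69.08, 15.33, 14.37),
    "pvc": GroupSummary(41, 13, 91.23, 79.50, 8.30, 16.17),
    "pcc": GroupSummary(41, 13, 89.93, 80.18, 10.22, 13.84),
    "ppc": GroupSummary(41, 13, 89.93, 79.75, 7.31, 9.93),
}

#: Cohort composition of the validation study.
N_TD = 41
N_SSD = 13
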