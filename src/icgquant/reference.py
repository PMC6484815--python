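"""Published summary data from the 86-patient laparoscopic colorectal cohort.

The default cut-offs, the synthetic-cohort calibration and the desk-checkable
diagnostic tables in this package all derive from a single-center study of
ICG fluorescence angiography during laparoscopic colorectal cancer surgery
(n = 86; 6 anastomotic complications, 7% incidence).  Only the published
summary statistics are reproduced here -- per-group means with standard
errors for the perfusion parameters, ROC-derived cut-offs, per-zone
complication counts and 2x2 diagnostic counts.  No patient-level data exist
in this package.

Group summary values are mean +/- standard error; the cohort simulator
converts SE to SD via SD = SE * sqrt(n).
"""

from __future__ import annotations

from .stats import ContingencyTable2x2

#: Cohort size and complication count (incidence 6/86 ~ 7%).
N_TOTAL = 86
N_COMPLICATION = 6
N_NO_COMPLICATION = 80

#: Per-group perfusion parameter summaries, mean and standard error.
#: Keys: group -> parameter -> (mean, se).  f_max is the published peak-minus-
#: baseline difference (delta F); slope = delta F / T_MAX in AU/s.
GROUP_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    "no_complication": {
        "f_min": (10.6, 1.0),
        "f_max": (58.0, 3.4),
        "slope": (2.5, 0.2),
        "t_max": (30.3, 2.3),
        "t_half_max": (11.7, 0.8),
        "tr": (0.4, 0.0),
    },
    "complication": {
        "f_min": (11.5, 2.5),
        "f_max": (34.9, 7.4),
        "slope": (0.7, 0.2),
        "t_max": (64.0, 11.7),
        "t_half_max": (40.37, 7.8),
        "tr": (0.6, 0.0),
    },
}

#: ROC-derived cut-offs and AUCs per perfusion factor.
#: slope AUC is printed in the raw "larger value => complication" orientation
#: (hence below 0.5: a *smaller* slope indicates complication).
ROC_TABLE: dict[str, dict[str, float | tuple[float, float]]] = {
    "slope": {"cutoff": 0.7, "auc": 0.123, "ci": (0.001, 0.245)},
    "t_half_max": {"cutoff": 18.0, "auc": 0.963, "ci": (0.910, 1.0)},
    "tr": {"cutoff": 0.6, "auc": 0.929, "ci": (0.845, 1.000)},
}

#: Fast/slow classification cut-offs per factor (values between the bounds,
#: inclusive, are "moderate").  Slope is reversed: fast flow means a steep rise.
CUTOFFS = {
    "slope": {"fast_gt": 1.0, "slow_lt": 0.7},
    "t_half_max": {"fast_lt": 10.0, "slow_gt": 18.0},
    "tr": {"fast_lt": 0.4, "slow_gt": 0.6},
}

#: Per-zone complication counts (complications, total) per factor:
#: safe = fast, intermediate = moderate, dangerous = slow.
ZONE_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "slope": {"safe": (1, 60), "intermediate": (1, 16), "dangerous": (4, 10)},
    "t_half_max": {"safe": (0, 44), "intermediate": (0, 23), "dangerous": (6, 19)},
    "tr": {"safe": (0, 47), "intermediate": (1, 31), "dangerous": (5, 8)},
}

#: 2x2 contingency counts for the binary slow / not-slow split per factor
#: (positive test = slow perfusion, positive outcome = complication).
CONTINGENCY: dict[str, ContingencyTable2x2] = {
    "slope": ContingencyTable2x2(tp=4, fp=6, fn=2, tn=74),
    "t_half_max": ContingencyTable2x2(tp=6, fp=13, fn=0, tn=67),
    "tr": ContingencyTable2x2(tp=5, fp=3, fn=1, tn=77),
}

#: Published diagnostic percentages (one decimal as printed) per factor.
PUBLISHED_DIAGNOSTICS: dict[str, dict[str, float]] = {
    "slope": {
        "sensitivity": 66.7, "specificity": 92.5, "ppv": 40.0,
        "npv": 97.4, "accuracy": 90.7,
    },
    "t_half_max": {
        "sensitivity": 100.0, "specificity": 83.7, "ppv": 31.6,
        "npv": 100.0, "accuracy": 84.9,
    },
    "tr": {
        "sensitivity": 83.3, "specificity": 96.3, "ppv": 62.5,
        "npv": 98.7, "accuracy": 95.3,
    },
}

#: Published per-zone complication percentages (one decimal as printed).
PUBLISHED_ZONE_RATES: dict[str, dict[str, float]] = {
    "slope": {"safe": 1.7, "intermediate": 6.3, "dangerous": 40.0},
    "t_half_max": {"safe": 0.0, "intermediate": 0.0, "dangerous": 31.6},
    "tr": {"safe": 0.0, "intermediate": 3.2, "dangerous": 62.5},
}
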