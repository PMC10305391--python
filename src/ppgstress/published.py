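"""Published reference grids used as worked-example inputs.

The study protocol this pipeline re-implements reported two summary grids
computed on a 17-participant human cohort that is not publicly available:
the feature-agreement R-squared between short-window and 5-minute PRV
features (nine features x seven window lengths), and the 10-fold CV
R-squared of four regressors predicting the 1-minute sqrt stress index
(four models x seven window lengths, plus their per-length mean).  The
printed numbers are inputs here: the selection rule and the mean-row
summarization can be applied to them directly as desk-checkable worked
examples, independent of any simulation.
"""

from __future__ import annotations

__all__ = [
    "FEATURE_AGREEMENT_R2",
    "PREDICTION_R2_GRID",
    "PREDICTION_R2_MEAN_ROW",
    "REPORTED_SELECTED_COUNTS",
]

# Feature-agreement R-squared (short window vs 5-minute reference), by
# window length in seconds.  Column order is the reported one.
FEATURE_AGREEMENT_R2: dict[float, dict[str, float]] = {
    5.0:  {"mean_nni": 0.9096, "sdnn": -0.0089, "sdsd": 0.3678, "rmssd": 0.5448,
           "median_nni": 0.8963, "cvsd": -0.2537, "mean_hr": 0.9100,
           "min_hr": 0.6410, "max_nni": 0.6301},
    10.0: {"mean_nni": 0.9350, "sdnn": 0.2859, "sdsd": 0.5741, "rmssd": 0.5848,
           "median_nni": 0.9272, "cvsd": 0.5637, "mean_hr": 0.9363,
           "min_hr": 0.7518, "max_nni": 0.7576},
    20.0: {"mean_nni": 0.9516, "sdnn": 0.4887, "sdsd": 0.8060, "rmssd": 0.8074,
           "median_nni": 0.9476, "cvsd": 0.7174, "mean_hr": 0.9521,
           "min_hr": 0.8250, "max_nni": 0.8387},
    30.0: {"mean_nni": 0.9606, "sdnn": 0.5890, "sdsd": 0.8468, "rmssd": 0.8473,
           "median_nni": 0.9582, "cvsd": 0.7731, "mean_hr": 0.9610,
           "min_hr": 0.8587, "max_nni": 0.8731},
    40.0: {"mean_nni": 0.9674, "sdnn": 0.6472, "sdsd": 0.8616, "rmssd": 0.8619,
           "median_nni": 0.9649, "cvsd": 0.7823, "mean_hr": 0.9676,
           "min_hr": 0.8798, "max_nni": 0.8934},
    50.0: {"mean_nni": 0.9723, "sdnn": 0.6940, "sdsd": 0.8623, "rmssd": 0.8624,
           "median_nni": 0.9705, "cvsd": 0.7878, "mean_hr": 0.9722,
           "min_hr": 0.8956, "max_nni": 0.9080},
    60.0: {"mean_nni": 0.9759, "sdnn": 0.7330, "sdsd": 0.8830, "rmssd": 0.8831,
           "median_nni": 0.9745, "cvsd": 0.8081, "mean_hr": 0.9755,
           "min_hr": 0.9079, "max_nni": 0.9187},
}

# Number of features at agreement R2 >= 0.6 reported per window length.
REPORTED_SELECTED_COUNTS: dict[float, int] = {
    5.0: 5, 10.0: 5, 20.0: 8, 30.0: 8, 40.0: 9, 50.0: 9, 60.0: 9,
}

# Mean 10-fold CV R-squared of each regressor per window length (s).
PREDICTION_R2_GRID: dict[tuple[str, float], float] = {
    ("extra_trees", 5.0): 0.6390, ("extra_trees", 10.0): 0.7589,
    ("extra_trees", 20.0): 0.9036, ("extra_trees", 30.0): 0.9480,
    ("extra_trees", 40.0): 0.9723, ("extra_trees", 50.0): 0.9816,
    ("extra_trees", 60.0): 0.9962,
    ("gradient_boosting", 5.0): 0.6892, ("gradient_boosting", 10.0): 0.7606,
    ("gradient_boosting", 20.0): 0.8484, ("gradient_boosting", 30.0): 0.8905,
    ("gradient_boosting", 40.0): 0.9290, ("gradient_boosting", 50.0): 0.9600,
    ("gradient_boosting", 60.0): 0.9850,
    ("knn", 5.0): 0.6284, ("knn", 10.0): 0.7403, ("knn", 20.0): 0.8783,
    ("knn", 30.0): 0.9286, ("knn", 40.0): 0.9635, ("knn", 50.0): 0.9759,
    ("knn", 60.0): 0.9933,
    ("linear", 5.0): 0.6305, ("linear", 10.0): 0.7056, ("linear", 20.0): 0.7740,
    ("linear", 30.0): 0.8189, ("linear", 40.0): 0.8705, ("linear", 50.0): 0.9172,
    ("linear", 60.0): 0.9475,
}

# The printed per-length means of the four model scores.
PREDICTION_R2_MEAN_ROW: dict[float, float] = {
    5.0: 0.6467, 10.0: 0.7414, 20.0: 0.8511, 30.0: 0.8965,
    40.0: 0.9338, 50.0: 0.9586, 60.0: 0.9805,
}
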