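"""Published reference summaries for the smoking FLIO study design.

The clinical cohort behind this pipeline (26 non-smokers, 28 smokers,
both eyes, 108 FLIO samples) is not publicly deposited, but the study's
summary tables report, for every feature subset, the confusion-matrix
cells averaged over 20 iterations of grouped stratified 5-fold
cross-validation.  Those printed mean cells are reproduced here as
reference inputs: the derived rates (TPR, FPR, accuracy) are *not*
stored but recomputed from the cells by
:func:`fliopipe.svm.confusion_metrics`, which pins down the pipeline's
aggregation conventions against the published numbers.

Each row: subset name -> (n_features, mean_tp, mean_fn, mean_fp, mean_tn).
The printed rates and their per-repeat SDs are kept separately (as
printed, two decimals) so tests can check the recomputation.
"""

from __future__ import annotations

__all__ = [
    "SUBSET_ORDER",
    "REPORTED_CELLS_SMOKER",
    "REPORTED_RATES_SMOKER",
    "REPORTED_CELLS_HEAVY",
    "REPORTED_RATES_HEAVY",
    "REPORTED_ACCURACY_PROSE",
]

#: Table row order of the published experiments.
SUBSET_ORDER = (
    "all",
    "intensity",
    "tau_m",
    "tau_ssc",
    "tau_lsc",
    "tau_ir",
    "tau_or",
    "tau_ir_ssc_or_lsc",
    "tau_or_ssc_ir_lsc",
    "ttest_top3",
)

# Non-smoker vs smoker: 56 positive (smoker) and 52 negative eyes.
REPORTED_CELLS_SMOKER: dict[str, tuple[int, float, float, float, float]] = {
    "all":               (36, 32.70, 23.30, 21.35, 30.65),
    "intensity":         (18, 27.30, 28.70, 27.90, 24.10),
    "tau_m":             (18, 34.90, 21.10, 21.15, 30.85),
    "tau_ssc":           (9,  33.50, 22.50, 33.40, 18.60),
    "tau_lsc":           (9,  33.25, 22.75, 18.90, 33.10),
    "tau_ir":            (8,  38.80, 17.20, 18.05, 33.95),
    "tau_or":            (8,  27.25, 28.75, 19.05, 32.95),
    "tau_ir_ssc_or_lsc": (8,  35.00, 21.00, 17.05, 34.95),
    "tau_or_ssc_ir_lsc": (8,  26.80, 29.20, 27.45, 24.55),
    "ttest_top3":        (3,  40.65, 15.35, 16.40, 35.60),
}

#: Printed (TPR, FPR, accuracy) percentages, two decimals, same rows.
REPORTED_RATES_SMOKER: dict[str, tuple[float, float, float]] = {
    "all":               (58.39, 41.06, 58.66),
    "intensity":         (48.75, 53.65, 47.59),
    "tau_m":             (62.32, 40.67, 60.88),
    "tau_ssc":           (59.82, 64.23, 48.24),
    "tau_lsc":           (59.38, 36.35, 61.44),
    "tau_ir":            (69.29, 34.71, 67.36),
    "tau_or":            (48.66, 36.63, 55.74),
    "tau_ir_ssc_or_lsc": (62.50, 32.79, 64.77),
    "tau_or_ssc_ir_lsc": (47.86, 52.79, 47.55),
    "ttest_top3":        (72.59, 31.54, 70.60),
}

# Non-smoker vs heavy smoker: 28 positive and 52 negative eyes.
REPORTED_CELLS_HEAVY: dict[str, tuple[int, float, float, float, float]] = {
    "all":               (36, 11.85, 16.15, 9.50, 42.50),
    "intensity":         (18, 8.15, 19.85, 13.45, 38.55),
    "tau_m":             (18, 14.30, 13.70, 8.45, 43.55),
    "tau_ssc":           (9,  6.05, 21.95, 14.50, 37.50),
    "tau_lsc":           (9,  11.75, 16.25, 10.15, 41.85),
    "tau_ir":            (8,  15.30, 12.70, 10.70, 41.30),
    "tau_or":            (8,  11.95, 16.05, 10.95, 41.05),
    "tau_ir_ssc_or_lsc": (8,  18.05, 9.95, 6.40, 45.60),
    "tau_or_ssc_ir_lsc": (8,  9.15, 18.85, 11.90, 40.10),
    "ttest_top3":        (3,  19.10, 8.90, 7.10, 44.90),
}

REPORTED_RATES_HEAVY: dict[str, tuple[float, float, float]] = {
    "all":               (42.32, 18.27, 67.94),
    "intensity":         (29.11, 25.87, 58.38),
    "tau_m":             (51.07, 16.25, 72.31),
    "tau_ssc":           (21.61, 27.88, 54.44),
    "tau_lsc":           (41.96, 19.52, 67.00),
    "tau_ir":            (54.64, 20.58, 70.75),
    "tau_or":            (42.68, 21.06, 66.25),
    "tau_ir_ssc_or_lsc": (64.46, 12.31, 79.56),
    "tau_or_ssc_ir_lsc": (32.68, 22.88, 61.56),
    "ttest_top3":        (68.21, 13.65, 80.00),
}

#: Accuracies quoted in the study's prose, rounded to the nearest percent,
#: keyed by (experiment, subset).  The prose rounds the table values.
REPORTED_ACCURACY_PROSE: dict[tuple[str, str], int] = {
    ("smoker", "intensity"): 48,
    ("smoker", "tau_m"): 61,
    ("smoker", "tau_lsc"): 61,
    ("smoker", "tau_ir"): 67,
    ("smoker", "tau_or"): 56,
    ("smoker", "tau_ir_ssc_or_lsc"): 65,
    ("smoker", "tau_or_ssc_ir_lsc"): 48,
    ("smoker", "ttest_top3"): 71,
    ("heavy_smoker", "intensity"): 58,
    ("heavy_smoker", "tau_m"): 72,
    ("heavy_smoker", "tau_ssc"): 54,
    ("heavy_smoker", "tau_lsc"): 67,
    ("heavy_smoker", "tau_ir"): 71,
    ("heavy_smoker", "tau_or"): 66,
    ("heavy_smoker", "tau_ir_ssc_or_lsc"): 80,
    ("heavy_smoker", "tau_or_ssc_ir_lsc"): 62,
    ("heavy_smoker", "ttest_top3"): 80,
}
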