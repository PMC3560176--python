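"""Published case-control summary statistics used to calibrate the synthetic cohort.

These are the group means and 95% confidence intervals, effect sizes and
ROC areas reported for a 40-ADHD / 60-control adult cohort measured with
infrared motion capture during a high-target-density ("No-4's") cognitive
control task, plus a standard letter CPT.  They are the *inputs* of this
package: the subject-level data were never deposited, so the synthetic
cohort generator reconstructs per-group distributions from these printed
summaries (see :mod:`actipheno.cohort`).

Only summary statistics appear here; per-measure standard deviations are
reconstructed at run time from the CI half-widths
(:func:`actipheno.cohort.reconstruct_sd_from_ci`).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MeasureRef:
    """Printed per-measure row: group means with 95% CIs plus reported stats."""

    key: str
    label: str
    domain: str            # activity | no4s | cptii
    units: str
    family: str            # normal | gamma | reflected_gamma (| lognormal)
    control: tuple[float, float, float]   # mean, ci_low, ci_high
    adhd: tuple[float, float, float]
    f_group: float
    d_printed: float
    auc_printed: float
    reflect_at: float | None = None       # for reflected families


# --- Table 1: head and lower-extremity movement measures -------------------

TABLE1: tuple[MeasureRef, ...] = (
    MeasureRef("head_immobility", "Head immobility duration", "activity", "s",
               "gamma", (0.42, 0.33, 0.50), (0.18, 0.16, 0.21), 14.97, 0.85, 0.77),
    MeasureRef("head_microevents", "Head microevents", "activity", "count",
               "gamma", (1283, 1055, 1511), (2255, 1907, 2603), 19.36, 1.00, 0.79),
    MeasureRef("head_displacement", "Head displacement", "activity", "m",
               "gamma", (2.25, 1.62, 2.89), (3.94, 3.28, 4.59), 11.65, 0.73, 0.79),
    MeasureRef("head_area", "Head movement area", "activity", "cm2",
               "gamma", (65.02, 45.38, 84.66), (145.6, 116.6, 174.7), 24.09, 0.98, 0.82),
    MeasureRef("head_spatial", "Head spatial complexity", "activity", "exponent",
               "normal", (1.31, 1.25, 1.37), (1.11, 1.09, 1.13), 25.71, 1.08, 0.85),
    MeasureRef("head_temporal", "Head temporal scaling", "activity", "exponent",
               "normal", (0.41, 0.34, 0.49), (0.63, 0.56, 0.71), 12.58, 0.83, 0.72),
    MeasureRef("shin_immobility", "Shin immobility duration", "activity", "s",
               "gamma", (4.84, 3.60, 6.08), (0.74, 0.53, 0.94), 29.62, 1.10, 0.88),
    MeasureRef("shin_microevents", "Shin microevents", "activity", "count",
               "gamma", (250.7, 149.6, 351.8), (1048.4, 680.4, 1416.5), 23.69, 1.01, 0.88),
    MeasureRef("shin_displacement", "Shin displacement", "activity", "m",
               "gamma", (0.44, 0.21, 0.67), (1.93, 1.23, 2.64), 22.42, 0.96, 0.88),
    MeasureRef("shin_area", "Shin movement area", "activity", "cm2",
               "gamma", (12.65, 6.32, 18.99), (45.36, 32.79, 57.92), 27.09, 1.05, 0.88),
    MeasureRef("shin_spatial", "Shin spatial complexity", "activity", "exponent",
               "normal", (2.22, 2.02, 2.42), (1.33, 1.26, 1.40), 44.44, 1.45, 0.87),
    MeasureRef("shin_temporal", "Shin temporal scaling", "activity", "exponent",
               "normal", (0.07, -0.001, 0.14), (0.49, 0.42, 0.57), 57.25, 1.60, 0.88),
)

# --- Table 2: No-4's cognitive control task --------------------------------

TABLE2: tuple[MeasureRef, ...] = (
    MeasureRef("no4s_accuracy", "No-4's accuracy", "no4s", "%",
               "reflected_gamma", (97.46, 97.00, 97.93), (95.76, 94.87, 96.65),
               16.83, 0.76, 0.71, reflect_at=100.0),
    MeasureRef("no4s_eom", "No-4's errors of omission", "no4s", "count",
               "gamma", (0.54, 0.33, 0.76), (1.5, 0.86, 2.13), 9.22, 0.67, 0.71),
    MeasureRef("no4s_eoc", "No-4's errors of commission", "no4s", "count",
               "gamma", (20.48, 16.87, 24.09), (30.71, 24.84, 36.58), 11.23, 0.64, 0.67),
    MeasureRef("no4s_latency", "No-4's response latency", "no4s", "ms",
               "normal", (482.9, 467.1, 498.7), (481.6, 459.5, 503.7), 0.11, 0.02, 0.52),
    MeasureRef("no4s_latency_sd", "No-4's latency SD", "no4s", "ms",
               "normal", (97.93, 90.38, 105.5), (119.4, 108.6, 130.1), 8.75, 0.69, 0.70),
    MeasureRef("no4s_latency_cov", "No-4's latency COV", "no4s", "%",
               "normal", (20.37, 19.06, 21.67), (24.32, 22.58, 26.07), 13.43, 0.76, 0.73),
    MeasureRef("no4s_attention_shifts", "No-4's attention shifts", "no4s", "count",
               "normal", (13.95, 12.62, 15.28), (15.22, 13.93, 16.52), 2.27, 0.27, 0.58),
    MeasureRef("no4s_pct_attentive", "Attentive %-time", "no4s", "%",
               "normal", (60.0, 55.0, 65.0), (42.0, 35.0, 49.0), 19.28, 0.87, 0.73),
    MeasureRef("no4s_pct_distracted", "Distracted %-time", "no4s", "%",
               "gamma", (16.0, 13.0, 20.0), (25.0, 19.0, 31.0), 4.78, 0.54, 0.65),
    MeasureRef("no4s_pct_impulsive", "Impulsive %-time", "no4s", "%",
               "gamma", (23.0, 19.0, 27.0), (32.0, 26.0, 39.0), 7.41, 0.51, 0.62),
    MeasureRef("no4s_pct_random", "Random %-time", "no4s", "%",
               "gamma", (0.22, 0.0, 0.4), (0.76, 0.1, 1.4), 1.92, 0.36, 0.54),
    MeasureRef("no4s_pct_minimal", "Minimal %-time", "no4s", "%",
               "gamma", (0.19, 0.0, 0.5), (0.99, 0.2, 1.8), 4.09, 0.44, 0.56),
)

# --- Table 3: letter CPT ---------------------------------------------------

TABLE3: tuple[MeasureRef, ...] = (
    MeasureRef("cpt_eom", "CPT errors of omission", "cptii", "count",
               "gamma", (1.95, 0.91, 2.98), (1.79, 0.93, 2.65), 0.15, 0.05, 0.47),
    MeasureRef("cpt_eoc", "CPT errors of commission", "cptii", "count",
               "gamma", (8.70, 7.26, 10.15), (12.26, 10.11, 14.42), 8.30, 0.60, 0.67),
    MeasureRef("cpt_rt", "CPT correct reaction time", "cptii", "ms",
               "normal", (385.2, 370.5, 399.9), (389.3, 369.8, 408.9), 0.01, 0.07, 0.52),
    MeasureRef("cpt_rt_se", "CPT RT standard error", "cptii", "ms",
               "normal", (5.31, 4.86, 5.77), (6.35, 5.65, 7.05), 8.13, 0.55, 0.63),
    MeasureRef("cpt_rt_block_var", "CPT RT variability by blocks", "cptii", "ms",
               "normal", (6.76, 5.87, 7.65), (8.65, 7.14, 10.16), 7.55, 0.48, 0.63),
    MeasureRef("cpt_dprime", "CPT discriminability (d prime)", "cptii", "unitless",
               "normal", (0.96, 0.84, 1.07), (0.74, 0.61, 0.88), 3.95, 0.49, 0.66),
    MeasureRef("cpt_beta", "CPT response bias (beta)", "cptii", "unitless",
               "gamma", (0.91, 0.62, 1.20), (0.68, 0.45, 0.92), 1.45, 0.23, 0.57),
    MeasureRef("cpt_perseverations", "CPT perseverative errors", "cptii", "count",
               "gamma", (0.19, 0.03, 0.36), (0.71, 0.19, 1.23), 7.07, 0.46, 0.61),
    MeasureRef("cpt_rt_slope_blocks", "CPT change in RT by blocks", "cptii", "ms/block",
               "normal", (0.0, -0.007, 0.007), (0.0, -0.012, 0.017), 0.02, 0.08, 0.51),
    MeasureRef("cpt_rt_se_slope_blocks", "CPT change in RT SE by blocks", "cptii", "ms/block",
               "normal", (0.0, -0.021, 0.014), (0.0, -0.034, 0.023), 0.02, 0.02, 0.50),
    MeasureRef("cpt_rt_slope_isi", "CPT change in RT by ISI", "cptii", "ms/level",
               "normal", (0.05, 0.035, 0.063), (0.07, 0.056, 0.086), 4.5, 0.43, 0.61),
    MeasureRef("cpt_rt_se_slope_isi", "CPT change in RT SE by ISI", "cptii", "ms/level",
               "normal", (0.01, -0.011, 0.039), (0.06, 0.015, 0.095), 4.41, 0.39, 0.60),
)

# Natural resolution of discrete measures: counts are integers and the
# state percentages move in steps of 2.5 (one of forty 30-s epochs).  The
# generator rounds stochastically to these grids, which preserves group
# means exactly while reproducing the heavy ties at zero that keep the
# printed ROC areas of the rare-event measures near chance.
MEASURE_QUANTUM: dict[str, float] = {
    "head_microevents": 1.0, "shin_microevents": 1.0,
    "no4s_eom": 1.0, "no4s_eoc": 1.0,
    "cpt_eom": 1.0, "cpt_eoc": 1.0, "cpt_perseverations": 1.0,
    "no4s_pct_distracted": 2.5, "no4s_pct_impulsive": 2.5,
    "no4s_pct_random": 2.5, "no4s_pct_minimal": 2.5,
}

ALL_MEASURES: tuple[MeasureRef, ...] = TABLE1 + TABLE2 + TABLE3
MEASURE_BY_KEY = {m.key: m for m in ALL_MEASURES}

ACTIVITY_KEYS = tuple(m.key for m in TABLE1)
NO4S_KEYS = tuple(m.key for m in TABLE2)
CPTII_KEYS = tuple(m.key for m in TABLE3)

# --- Demographics ----------------------------------------------------------

N_ADHD = 40
N_CONTROL = 60
ADHD_MALES, ADHD_FEMALES = 23, 17
CONTROL_MALES, CONTROL_FEMALES = 28, 32
ADHD_AGE_MEAN, ADHD_AGE_SD = 35.0, 10.0
CONTROL_AGE_MEAN, CONTROL_AGE_SD = 29.0, 9.0
AGE_RANGE = (18.0, 57.0)
N_INATTENTIVE = 17        # of the 40 ADHD subjects

# --- Table 4: executive-function rating correlations ----------------------
# rows: Brown ADD rating domains; columns: composite indices.

RATING_DOMAINS = ("Activation", "Attention", "Effort",
                  "Affective Control", "Memory", "Total")

TABLE4_R: dict[str, dict[str, float]] = {
    "confidence_index":   {"Activation": 0.25, "Attention": 0.23, "Effort": 0.33,
                           "Affective Control": 0.23, "Memory": 0.28, "Total": 0.28},
    "distraction_composite": {"Activation": 0.23, "Attention": 0.28, "Effort": 0.28,
                              "Affective Control": 0.23, "Memory": 0.26, "Total": 0.28},
    "activity_composite": {"Activation": 0.51, "Attention": 0.54, "Effort": 0.51,
                           "Affective Control": 0.40, "Memory": 0.49, "Total": 0.54},
    "discriminative_index": {"Activation": 0.66, "Attention": 0.72, "Effort": 0.60,
                             "Affective Control": 0.52, "Memory": 0.62, "Total": 0.68},
}

# --- Published composite ROC areas (report surface, Figure-2 analog) -------

COMPOSITE_AUC_PRINTED = {
    "activity_composite": 0.83,
    "distraction_composite": 0.65,
    "confidence_index": 0.63,
    "discriminative_index": 0.96,
}

# --- Task geometry ---------------------------------------------------------

NO4S_STIM_MS = 240.0
NO4S_MEAN_ISI_MS = 2500.0
NO4S_TARGET_FRACTION = 0.90
NO4S_SESSION_S = 1200.0            # 20-minute cognitive control task

CPT_STIM_MS = 250.0
CPT_ISI_LEVELS_MS = (1000.0, 2000.0, 4000.0)
CPT_N_BLOCKS = 6
CPT_TRIALS_PER_SUBBLOCK = 20       # conventional geometry, configurable
CPT_NONTARGET_RATE = 0.10

SAMPLING_RATE_HZ = 50.0
RESOLUTION_MM = 0.04
MEAN_FRAME_LOSS = 0.18
EPOCH_LENGTH_S = 30.0
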