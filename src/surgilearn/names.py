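"""Canonical feature names, cortex labels, skill levels, and task rubrics.

Every table that flows between stages uses these exact column names, so the
synthetic generator, the feature extractors and the model fitters agree on
the 36-predictor design (12 gaze + 20 EEG + 4 experience).
"""

from __future__ import annotations

CORTICES = ("frontal", "parietal", "occipital", "temporal")

#: Skill levels in increasing-experience order.
LEVELS = ("pre-medical student", "resident", "fellow", "faculty")

GAZE_FEATURES = (
    "avg_pupil_nondom",
    "avg_pupil_dom",
    "entropy_pupil_nondom",
    "entropy_pupil_dom",
    "rate_fixation",
    "rate_saccade",
    "rate_dirchange_nondom_h",
    "rate_dirchange_nondom_v",
    "rate_dirchange_dom_h",
    "rate_dirchange_dom_v",
    "traj_len_nondom",
    "traj_len_dom",
)

EEG_METRICS = ("flexibility", "integration", "recruitment", "search_information", "strength")

EEG_FEATURES = tuple(f"{metric}_{cortex}" for cortex in CORTICES for metric in EEG_METRICS)

EXPERIENCE_FEATURES = (
    "hours_ras_experience",
    "laparoscopic_cases_primary",
    "years_clinical_practice",
    "years_formal_training",
)

ALL_FEATURES = GAZE_FEATURES + EEG_FEATURES + EXPERIENCE_FEATURES

#: Canonical task labels and the rating rubric attached to each.
#: GOALS: 5 domains on 1-5 Likert (total 5-25); OSAT: 8 domains (8-40);
#: GEARS: 6 domains (6-30).
TASK_RUBRICS = {
    "fls_peg": ("GOALS", 5.0, 25.0),
    "fls_cut": ("GOALS", 5.0, 25.0),
    "fls_suture": ("OSAT", 8.0, 40.0),
    "ras_cut": ("GEARS", 6.0, 30.0),
    "ras_dissect": ("GEARS", 6.0, 30.0),
}

TASKS = tuple(TASK_RUBRICS)

KEY_COLUMNS = ("participant_id", "task", "attempt")
SCORE_COLUMN = "score"


def rubric_range(task: str) -> tuple[float, float]:
    """Return ``(lo, hi)`` of the rating rubric for a canonical task label."""
    try:
        _, lo, hi = TASK_RUBRICS[task]
    except KeyError:
        raise ValueError(
            f"unknown task label {task!r}; expected one of {sorted(TASK_RUBRICS)}"
        ) from None
    return lo, hi
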