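"""Synthetic study generator with known ground truth.

Emulates the study design the downstream stages expect: a cohort of
participants at four skill levels with experience covariates, binocular
gaze/pupil streams at 50 Hz with planted fixation/saccade segments, EEG at
500 Hz whose channels carry planted time-varying community structure, and
attempt-wise performance scores built as a sparse linear function of the
extracted features plus a participant random intercept, a per-participant
linear learning trend, and Gaussian noise, clipped to the task's rating
rubric.  Every generated quantity is reproducible from a single seed and
the generative parameters are returned as ground truth, so recovery of the
planted structure can be quantified end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .eegnet import CortexMap, EEGRecording, default_cortex_map, extract_eeg_features, synthetic_channel_names
from .gaze import GazeRecording, extract_gaze_features
from .names import ALL_FEATURES, EXPERIENCE_FEATURES, LEVELS, rubric_range

# Experience-covariate sampling ranges per skill level, loosely matched to
# the study cohort (pre-medical students have no surgical experience at
# all; faculty span the widest ranges).  (lo, hi) per covariate in the
# order hours RAS / laparoscopic cases / years practice / years training.
EXPERIENCE_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    "pre-medical student": ((0, 0), (0, 0), (0, 0), (0, 0)),
    "resident": ((10, 40), (25, 25), (0, 0), (0, 2)),
    "fellow": ((0, 500), (0, 75), (0, 0), (0, 5)),
    "faculty": ((5, 1000), (0, 250), (2, 10), (0, 5)),
}

# Planted effects sit on attempt-varying features: a participant-constant
# covariate (e.g. experience) is confounded with the random intercept and
# its effect is barely identifiable at cohort scale, which would make the
# generator a poor recovery benchmark.
DEFAULT_TRUE_COEFFICIENTS = {
    "avg_pupil_dom": 2.0,
    "recruitment_parietal": 1.5,
    "entropy_pupil_nondom": 1.0,
}

# Per-attempt learning trends depend on the first-attempt state (score
# units per attempt per feature-sd), so the learning-rate models have a
# planted signal to recover, mirroring the premise that the initial
# brain/gaze state shapes the learning trajectory.
# Effect sizes are set for comfortable power at cohort scale: the slope
# estimate carries sampling noise ~noise_sd/sqrt(10) on top of slope_sd,
# so |gamma| ~ 2x that combined sd keeps the planted predictors clearly
# detectable at n = 25 participants.
DEFAULT_SLOPE_COEFFICIENTS = {
    "avg_pupil_dom": -0.4,
    "flexibility_frontal": 0.3,
}


@dataclass
class SimulationConfig:
    """Study-design constants and generative parameters.

    Defaults mirror the emulated study: EEG at 500 Hz from a 124-channel
    headset, eye tracking at 50 Hz, five attempts per task, a 25-person
    cohort spanning four skill levels.  ``true_coefficients`` act on
    standardized feature columns, so their magnitudes are in residual-sd
    units per feature-sd.
    """

    n_participants: int = 25
    levels: Sequence[str] | None = None     # per-participant labels; None = default mix
    n_attempts: int = 5
    eeg_channels: int = 124
    eeg_rate: float = 500.0
    gaze_rate: float = 50.0
    duration: float = 20.0
    task: str = "ras_dissect"
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    random_intercept_sd: float = 1.0
    noise_sd: float = 1.0
    slope_mean: float = 0.8
    slope_sd: float = 0.2
    slope_map: dict[str, float] | None = None
    slope_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SLOPE_COEFFICIENTS)
    )
    # EEG generative / extraction knobs
    n_module_layers: int | None = None      # None = one per 2 s window
    n_communities: int = 3
    switch_fraction: float = 0.15
    eeg_noise_sd: float = 0.5
    window_length: float = 2.0
    louvain_runs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0 or self.n_attempts < 1:
            raise ValueError("counts must be positive")
        if min(self.eeg_rate, self.gaze_rate, self.duration) <= 0:
            raise ValueError("rates and duration must be positive")
        if self.levels is None:
            self.levels = _default_cohort_levels(self.n_participants)
        self.levels = [canonical_level(lv) for lv in self.levels]
        if len(self.levels) != self.n_participants:
            raise ValueError("levels must list one skill level per participant")
        unknown = set(self.true_coefficients) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"unknown feature names in true_coefficients: {sorted(unknown)}")
        unknown = set(self.slope_coefficients) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"unknown feature names in slope_coefficients: {sorted(unknown)}")
        rubric_range(self.task)  # validates the task label

    @property
    def n_layers(self) -> int:
        if self.n_module_layers is not None:
            return self.n_module_layers
        return max(2, int(self.duration // self.window_length))


def canonical_level(label: str) -> str:
    lv = label.strip().lower().replace("_", " ").replace("-", " ")
    lv = {"pre medical student": "pre-medical student", "premedical student": "pre-medical student"}.get(lv, lv)
    if lv not in LEVELS:
        raise ValueError(f"invalid skill level {label!r}; expected one of {LEVELS}")
    return lv


def _default_cohort_levels(n: int) -> list[str]:
    """Cohort composition echoing the study: 11/2/6/6 of 25 pre-med/
    resident/fellow/faculty, scaled to ``n``."""
    weights = {"pre-medical student": 11, "resident": 2, "fellow": 6, "faculty": 6}
    out: list[str] = []
    for level, w in weights.items():
        out.extend([level] * max(1, round(n * w / 25)) if n >= 4 else [level])
    out = out[:n]
    while len(out) < n:
        out.append("pre-medical student")
    return out


@dataclass
class GroundTruth:
    """Generative parameters behind a synthetic study."""

    active_features: set[str]
    coefficients: dict[str, float]
    intercepts: dict[str, float]            # participant -> random intercept
    slopes: dict[str, float]                # participant -> score units / attempt
    base_score: float
    slope_coefficients: dict[str, float] = field(default_factory=dict)
    gaze_labels: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    module_schedule: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Participant table with skill level and four experience covariates.

    Pre-medical students get zeros for all covariates; other levels sample
    uniformly from per-level ranges.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for i, level in enumerate(config.levels):
        ranges = EXPERIENCE_RANGES[level]
        values = [float(np.round(rng.uniform(lo, hi), 1)) for lo, hi in ranges]
        rows.append(
            {
                "participant_id": f"P{i + 1:03d}",
                "level": level,
                **dict(zip(EXPERIENCE_FEATURES, values)),
            }
        )
    cols = ["participant_id", "level", *EXPERIENCE_FEATURES]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# gaze streams


def make_gaze_schedule(
    duration: float,
    rng: np.random.Generator,
    fixation_range: tuple[float, float] = (0.2, 0.5),
    saccade_range: tuple[float, float] = (0.04, 0.1),
) -> list[tuple[str, float]]:
    """Alternating fixation/saccade segments summing to ``duration``."""
    schedule: list[tuple[str, float]] = []
    t, fixating = 0.0, True
    while t < duration:
        rng_range = fixation_range if fixating else saccade_range
        d = min(float(rng.uniform(*rng_range)), duration - t)
        schedule.append(("fixation" if fixating else "saccade", d))
        t += d
        fixating = not fixating
    return schedule


def generate_gaze_recording(
    schedule: Sequence[tuple[str, float]],
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    *,
    pupil_mean: float = 3.5,
    pupil_ar: float = 0.95,
    pupil_sd: float = 0.05,
    pupil_asymmetry_sd: float = 0.3,
    constant_pupil: bool = False,
    fixation_speed: tuple[float, float] = (2.0, 10.0),
    saccade_speed: tuple[float, float] = (90.0, 300.0),
    dominant_eye: str = "right",
) -> tuple[GazeRecording, np.ndarray]:
    """Binocular gaze/pupil stream with planted fixation/saccade labels.

    Within fixation segments the angular speed stays well below the
    30 deg/s I-VT threshold, within saccade segments well above it; the
    pupil follows a bounded AR(1) process around ``pupil_mean`` mm.
    Returns the recording and the per-sample ground-truth labels.
    """
    rng = np.random.default_rng(rng)
    rate = config.gaze_rate
    for label, d in schedule:
        if d < 0:
            raise ValueError("segment durations must be nonnegative")
        if label not in ("fixation", "saccade"):
            raise ValueError(f"unknown segment label {label!r}")
    counts = [int(round(d * rate)) for _, d in schedule]
    n = sum(counts)
    if n < 2:
        raise ValueError("schedule too short for the sampling rate")
    labels = np.concatenate(
        [np.full(c, lab, dtype=object) for (lab, _), c in zip(schedule, counts)]
    )

    # dominant-eye trajectory: per-sample step with segment-dependent speed
    speeds = np.where(
        labels == "fixation",
        rng.uniform(*fixation_speed, size=n),
        rng.uniform(*saccade_speed, size=n),
    )
    theta = np.empty(n)
    start = 0
    for (lab, _), c in zip(schedule, counts):
        if c == 0:
            continue
        if lab == "saccade":
            # a saccade keeps one direction with small wobble
            theta[start : start + c] = rng.uniform(0, 2 * np.pi) + rng.normal(0, 0.1, c)
        else:
            theta[start : start + c] = rng.uniform(0, 2 * np.pi, c)
        start += c
    steps = speeds / rate
    dx, dy = steps * np.cos(theta), steps * np.sin(theta)
    x = np.concatenate(([0.0], np.cumsum(dx[1:])))
    y = np.concatenate(([0.0], np.cumsum(dy[1:])))
    # keep gaze inside a +-25 degree field via reflection
    x = 25.0 - np.abs(np.mod(x + 25.0, 100.0) - 50.0)
    y = 25.0 - np.abs(np.mod(y + 25.0, 100.0) - 50.0)

    def pupil_series() -> np.ndarray:
        if constant_pupil:
            return np.full(n, pupil_mean)
        # anisocoria: each eye gets its own baseline around pupil_mean
        mu = pupil_mean + rng.normal(0, pupil_asymmetry_sd)
        p = np.empty(n)
        p[0] = mu
        eps = rng.normal(0, pupil_sd, n)
        for t in range(1, n):
            p[t] = mu + pupil_ar * (p[t - 1] - mu) + eps[t]
        return np.clip(p, 1.5, 7.0)

    jitter = 0.02
    other_x = x + rng.normal(0, jitter, n)
    other_y = y + rng.normal(0, jitter, n)
    nondom = "left" if dominant_eye == "right" else "right"
    recording = GazeRecording(
        timestamps=np.arange(n) / rate,
        gaze_x={dominant_eye: x, nondom: other_x},
        gaze_y={dominant_eye: y, nondom: other_y},
        pupil={dominant_eye: pupil_series(), nondom: pupil_series()},
        valid=np.ones(n, dtype=bool),
        dominant_eye=dominant_eye,
        sampling_rate=rate,
    )
    return recording, labels


# ---------------------------------------------------------------------------
# EEG with planted community structure


def make_module_schedule(
    n_channels: int,
    n_layers: int,
    n_communities: int,
    switch_fraction: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Planted node -> community assignment per layer.

    Starts from contiguous equal blocks; per layer transition, a random
    ``switch_fraction`` of channels are reassigned to a random community,
    which sets the planted temporal flexibility.
    """
    rng = np.random.default_rng(rng)
    base = (np.arange(n_channels) * n_communities // n_channels).astype(int)
    schedule = np.empty((n_layers, n_channels), dtype=int)
    schedule[0] = base
    for l in range(1, n_layers):
        g = schedule[l - 1].copy()
        n_switch = int(round(switch_fraction * n_channels))
        if n_switch:
            who = rng.choice(n_channels, size=n_switch, replace=False)
            g[who] = rng.integers(0, n_communities, size=n_switch)
        schedule[l] = g
    return schedule


def generate_eeg_recording(
    module_schedule: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    *,
    amplitude: float = 1.0,
    noise_sd: float | None = None,
    channel_names: list[str] | None = None,
) -> tuple[EEGRecording, np.ndarray]:
    """Multichannel EEG whose windows carry planted community structure.

    Channels sharing a community within a layer window share a latent
    sinusoid (random 4-30 Hz frequency per community, frequencies spaced
    apart across communities) plus independent white noise, so
    within-community correlation is high and between-community correlation
    is near zero.  The ratio ``amplitude / noise_sd`` is the
    clustering-strength knob.
    """
    rng = np.random.default_rng(rng)
    module_schedule = np.asarray(module_schedule, dtype=int)
    n_layers, n_channels = module_schedule.shape
    if n_channels != config.eeg_channels:
        raise ValueError("schedule channel count differs from config.eeg_channels")
    fs = config.eeg_rate
    n_samples = int(round(config.duration * fs))
    win = n_samples // n_layers
    if win < 2:
        raise ValueError("layer count inconsistent with duration: windows too short")
    noise = config.eeg_noise_sd if noise_sd is None else noise_sd
    signal = rng.normal(0, noise, size=(n_channels, n_samples)) if noise > 0 else np.zeros((n_channels, n_samples))
    t = np.arange(n_samples) / fs
    for l in range(n_layers):
        sl = slice(l * win, n_samples if l == n_layers - 1 else (l + 1) * win)
        comms = np.unique(module_schedule[l])
        freqs = np.linspace(5.0, 28.0, comms.size) + rng.uniform(-0.4, 0.4, comms.size)
        for c, f in zip(comms, freqs):
            latent = amplitude * np.sin(2 * np.pi * f * t[sl] + rng.uniform(0, 2 * np.pi))
            signal[module_schedule[l] == c, sl] += latent
    names = channel_names or synthetic_channel_names(n_channels)
    return EEGRecording(signal * 10.0, fs, names), module_schedule


# ---------------------------------------------------------------------------
# scores


def generate_attempts(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    *,
    clip: bool = True,
) -> pd.DataFrame:
    """Attach rubric-range performance scores to a feature table.

    ``score = base + sum_f beta_f * z(feature_f) + b_participant
    + slope_participant * (attempt - 1) + noise``, clipped to the task's
    rubric range.  ``features`` must hold one row per participant x attempt
    with the feature columns named in ``truth.coefficients`` (experience
    covariates are merged in from the cohort if absent).  A warning is
    raised when more than 5% of scores clip, since clipping biases slope
    recovery downstream.
    """
    rng = np.random.default_rng(rng)
    lo, hi = rubric_range(config.task)
    table = features.copy()
    missing_exp = [c for c in EXPERIENCE_FEATURES if c in truth.coefficients and c not in table]
    if missing_exp:
        table = table.merge(
            cohort[["participant_id", *missing_exp]], on="participant_id", how="left"
        )
    score = np.full(len(table), truth.base_score, dtype=float)
    for name, beta in truth.coefficients.items():
        if name not in table:
            raise ValueError(f"feature {name!r} needed by true coefficients is missing")
        col = table[name].to_numpy(dtype=float)
        sd = col.std(ddof=1) if len(col) > 1 else 0.0
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        score += beta * z
    pid = table["participant_id"].astype(str)
    score += pid.map(truth.intercepts).to_numpy(dtype=float)
    score += pid.map(truth.slopes).to_numpy(dtype=float) * (
        table["attempt"].to_numpy(dtype=float) - 1.0
    )
    if config.noise_sd > 0:
        score += rng.normal(0, config.noise_sd, size=len(table))
    if clip:
        clipped = np.clip(score, lo, hi)
        frac = float(np.mean(clipped != score))
        if frac > 0.05:
            warnings.warn(
                f"{frac:.0%} of scores clipped to the [{lo}, {hi}] rubric range; "
                "planted slopes will be attenuated",
                stacklevel=2,
            )
        score = clipped
    out = table.copy()
    out["task"] = config.task
    out["score"] = score
    return out


# ---------------------------------------------------------------------------
# end-to-end study


def simulate_study(
    config: SimulationConfig,
    *,
    keep_ground_truth_streams: bool = False,
) -> tuple[pd.DataFrame, GroundTruth, pd.DataFrame]:
    """Generate a full synthetic study and extract its feature table.

    For every participant x attempt a gaze stream and an EEG recording are
    generated, the 12 gaze and 20 EEG features extracted, experience
    covariates merged in, and scores planted on the extracted features.
    Returns ``(feature_table, ground_truth, cohort)``.
    """
    rng = np.random.default_rng(config.seed)
    cohort = generate_cohort(config)
    names = synthetic_channel_names(config.eeg_channels)
    cortex_map = default_cortex_map(names)

    intercepts = {
        pid: float(rng.normal(0, config.random_intercept_sd))
        for pid in cohort["participant_id"]
    }
    slope_noise = {
        pid: float(rng.normal(0.0, config.slope_sd)) for pid in cohort["participant_id"]
    }
    lo, hi = rubric_range(config.task)
    truth = GroundTruth(
        active_features=set(config.true_coefficients),
        coefficients=dict(config.true_coefficients),
        intercepts=intercepts,
        slopes={},  # filled once first-attempt features exist
        base_score=(lo + hi) / 2.0,
        slope_coefficients=dict(config.slope_coefficients),
    )

    rows = []
    for pid in cohort["participant_id"]:
        for attempt in range(1, config.n_attempts + 1):
            schedule = make_gaze_schedule(config.duration, rng)
            gaze_rec, gaze_labels = generate_gaze_recording(
                schedule, config, rng, pupil_mean=float(rng.uniform(3.0, 4.5))
            )
            module = make_module_schedule(
                config.eeg_channels,
                config.n_layers,
                config.n_communities,
                switch_fraction=float(np.clip(rng.normal(config.switch_fraction, 0.05), 0.0, 0.6)),
                rng=rng,
            )
            eeg_rec, _ = generate_eeg_recording(
                module, config, rng, amplitude=float(rng.uniform(0.7, 1.3))
            )
            feats = extract_gaze_features(gaze_rec)
            feats.update(
                extract_eeg_features(
                    eeg_rec,
                    cortex_map,
                    window_length=config.window_length,
                    window_step=config.window_length,
                    n_runs=config.louvain_runs,
                    seed=rng,
                )
            )
            rows.append({"participant_id": pid, "attempt": attempt, **feats})
            if keep_ground_truth_streams:
                truth.gaze_labels[(pid, attempt)] = gaze_labels
                truth.module_schedule[(pid, attempt)] = module
    features = pd.DataFrame(rows).merge(
        cohort[["participant_id", *EXPERIENCE_FEATURES]], on="participant_id", how="left"
    )

    # learning trend: slope_mean + planted dependence on the standardized
    # first-attempt state + participant-level noise
    if config.slope_map is not None:
        truth.slopes = {
            pid: float(config.slope_map[pid]) for pid in cohort["participant_id"]
        }
    else:
        first = features[features["attempt"] == 1].set_index("participant_id")
        trend = pd.Series(config.slope_mean, index=first.index, dtype=float)
        for name, gamma in config.slope_coefficients.items():
            col = first[name].astype(float)
            sd = col.std(ddof=1) if len(col) > 1 else 0.0
            if sd > 0:
                trend = trend + gamma * (col - col.mean()) / sd
        truth.slopes = {
            pid: float(trend[pid] + slope_noise[pid]) for pid in cohort["participant_id"]
        }

    table = generate_attempts(cohort, features, truth, config, rng)
    key_cols = ["participant_id", "task", "attempt"]
    ordered = key_cols + [c for c in ALL_FEATURES if c in table] + ["score"]
    return table[ordered], truth, cohort
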