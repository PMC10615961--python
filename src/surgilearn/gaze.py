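"""Eye-gaze feature extraction.

Computes twelve features from a binocular gaze/pupil stream sampled at a
nominal 50 Hz: average and entropy of pupil diameter per eye, the fraction
of fixation and saccade samples under an I-VT velocity-threshold filter
(30 deg/s), horizontal/vertical gaze direction-change rates per eye, and the
gaze trajectory length per eye.  Gaze directions are horizontal/vertical
visual angles in degrees; angular velocity between consecutive samples is
the Euclidean angular displacement divided by the time step, so the
threshold applies in deg/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .names import GAZE_FEATURES

IVT_THRESHOLD_DEG_S = 30.0


@dataclass
class GazeRecording:
    """Timestamped binocular gaze directions and pupil diameters.

    Angles are in degrees of visual angle, pupil diameters in millimetres.
    ``dominant_eye`` names which of the two streams ("left"/"right") is the
    participant's sighting-dominant eye; features are reported per
    dominant/nondominant eye, not per left/right.
    """

    timestamps: np.ndarray          # seconds, strictly increasing
    gaze_x: dict[str, np.ndarray]   # eye -> degrees
    gaze_y: dict[str, np.ndarray]
    pupil: dict[str, np.ndarray]    # eye -> mm
    valid: np.ndarray               # per-sample bool
    dominant_eye: str = "right"
    sampling_rate: float = 50.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.timestamps.size
        if n == 0:
            raise ValueError("empty recording")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.dominant_eye not in ("left", "right"):
            raise ValueError("dominant_eye must be 'left' or 'right'")
        for d in (self.gaze_x, self.gaze_y, self.pupil):
            for eye in ("left", "right"):
                d[eye] = np.asarray(d[eye], dtype=float)
                if d[eye].size != n:
                    raise ValueError("field lengths differ from timestamps")
        if self.valid.size != n:
            raise ValueError("validity length differs from timestamps")

    @property
    def nondominant_eye(self) -> str:
        return "left" if self.dominant_eye == "right" else "right"


def smooth_series(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    Output has the same length as the input; ``window`` must be odd so the
    window is symmetric about each sample.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot smooth an empty series")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return series.copy()
    half = window // 2
    csum = np.cumsum(np.concatenate(([0.0], series)))
    n = series.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def angular_velocity(
    gaze_x: np.ndarray, gaze_y: np.ndarray, timestamps: np.ndarray
) -> np.ndarray:
    """Per-sample angular velocity in deg/s.

    ``velocity[i]`` is the Euclidean angular displacement between samples
    ``i-1`` and ``i`` divided by the time step; ``velocity[0]`` is NaN.
    """
    dx = np.diff(gaze_x)
    dy = np.diff(gaze_y)
    dt = np.diff(timestamps)
    v = np.hypot(dx, dy) / dt
    return np.concatenate(([np.nan], v))


def classify_ivt(
    recording: GazeRecording, threshold: float = IVT_THRESHOLD_DEG_S, *, smooth: bool = False
) -> np.ndarray:
    """I-VT velocity-threshold classification of each sample.

    Returns an array of labels ``{"fixation", "saccade", "invalid"}``.  The
    dominant-eye gaze stream is classified; velocity below ``threshold``
    deg/s marks fixation, at or above marks saccade.  Velocities are taken
    between consecutive *valid* samples; the first valid sample inherits its
    successor's label.  ``smooth=True`` applies the window-3 moving average
    before computing velocities, as the full extraction pipeline does.
    """
    eye = recording.dominant_eye
    valid_idx = np.flatnonzero(recording.valid)
    if valid_idx.size < 2:
        raise ValueError("fewer than 2 valid samples; gaze stream unusable")
    x = recording.gaze_x[eye][valid_idx]
    y = recording.gaze_y[eye][valid_idx]
    if smooth:
        x = smooth_series(x)
        y = smooth_series(y)
    t = recording.timestamps[valid_idx]
    v = angular_velocity(x, y, t)

    labels = np.full(recording.timestamps.size, "invalid", dtype=object)
    # relative tolerance keeps a velocity exactly at threshold on the
    # saccade side despite float rounding of time steps
    sub = np.where(v[1:] >= threshold * (1.0 - 1e-9), "saccade", "fixation")
    labels[valid_idx[1:]] = sub
    labels[valid_idx[0]] = sub[0]  # first valid sample inherits successor
    return labels


def binned_entropy(series: np.ndarray, bins: int = 16) -> float:
    """Shannon entropy (bits) of an equal-width histogram over [min, max].

    A constant series occupies a single bin and has zero entropy.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot compute entropy of an empty series")
    if np.any(np.isnan(series)):
        raise ValueError("series contains NaN; filter invalid samples first")
    lo, hi = series.min(), series.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(series, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / series.size
    return float(-(p * np.log2(p)).sum())


def direction_change_rate(gaze_axis: np.ndarray, timestamps: np.ndarray) -> float:
    """Sign reversals of consecutive nonzero displacements per second.

    Zero displacements are skipped, so a pause does not reset the running
    direction.  The elapsed time is last-minus-first timestamp.
    """
    gaze_axis = np.asarray(gaze_axis, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if gaze_axis.size < 3:
        raise ValueError("direction change rate needs at least 3 samples")
    if gaze_axis.size != timestamps.size:
        raise ValueError("axis and timestamps differ in length")
    d = np.diff(gaze_axis)
    d = d[d != 0.0]
    if d.size < 2:
        return 0.0
    reversals = int(np.sum(np.sign(d[1:]) != np.sign(d[:-1])))
    elapsed = timestamps[-1] - timestamps[0]
    if elapsed <= 0:
        raise ValueError("non-positive elapsed time")
    return reversals / elapsed


def trajectory_length(gaze_x: np.ndarray, gaze_y: np.ndarray) -> float:
    """Total Euclidean path length (degrees) of the gaze trace."""
    gaze_x = np.asarray(gaze_x, dtype=float)
    gaze_y = np.asarray(gaze_y, dtype=float)
    if gaze_x.size != gaze_y.size:
        raise ValueError("gaze_x and gaze_y differ in length")
    if gaze_x.size < 2:
        raise ValueError("trajectory length needs at least 2 samples")
    return float(np.hypot(np.diff(gaze_x), np.diff(gaze_y)).sum())


def extract_gaze_features(
    recording: GazeRecording,
    *,
    threshold: float = IVT_THRESHOLD_DEG_S,
    entropy_bins: int = 16,
    smoothing_window: int = 3,
) -> dict[str, float]:
    """Compute the 12 gaze features of a recording.

    Smoothing (moving average, window 3) is applied to the gaze and pupil
    series before everything else; the I-VT filter then labels samples on
    the dominant eye, and per-eye statistics are reported for the dominant
    and nondominant eye.  Invalid samples are excluded throughout.
    """
    valid_idx = np.flatnonzero(recording.valid)
    if valid_idx.size < 3:
        raise ValueError("too few valid samples to extract gaze features")
    if valid_idx.size < 0.5 * recording.valid.size:
        warnings.warn(
            "less than 50% of gaze samples are valid; features may be unreliable",
            stacklevel=2,
        )
    t = recording.timestamps[valid_idx]
    dom, nondom = recording.dominant_eye, recording.nondominant_eye

    sm: dict[tuple[str, str], np.ndarray] = {}
    for eye in (dom, nondom):
        sm["x", eye] = smooth_series(recording.gaze_x[eye][valid_idx], smoothing_window)
        sm["y", eye] = smooth_series(recording.gaze_y[eye][valid_idx], smoothing_window)
        sm["p", eye] = smooth_series(recording.pupil[eye][valid_idx], smoothing_window)

    labels = classify_ivt(recording, threshold, smooth=True)
    classified = labels[labels != "invalid"]
    n_class = classified.size
    rate_fix = float(np.mean(classified == "fixation")) if n_class else np.nan

    feats = {
        "avg_pupil_nondom": float(sm["p", nondom].mean()),
        "avg_pupil_dom": float(sm["p", dom].mean()),
        "entropy_pupil_nondom": binned_entropy(sm["p", nondom], entropy_bins),
        "entropy_pupil_dom": binned_entropy(sm["p", dom], entropy_bins),
        "rate_fixation": rate_fix,
        "rate_saccade": 1.0 - rate_fix if n_class else np.nan,
        "rate_dirchange_nondom_h": direction_change_rate(sm["x", nondom], t),
        "rate_dirchange_nondom_v": direction_change_rate(sm["y", nondom], t),
        "rate_dirchange_dom_h": direction_change_rate(sm["x", dom], t),
        "rate_dirchange_dom_v": direction_change_rate(sm["y", dom], t),
        "traj_len_nondom": trajectory_length(sm["x", nondom], sm["y", nondom]),
        "traj_len_dom": trajectory_length(sm["x", dom], sm["y", dom]),
    }
    assert tuple(feats) == GAZE_FEATURES
    return feats
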