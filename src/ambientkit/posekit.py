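"""Occupancy counting and activity phenotyping from pose keypoints.

A keypoint frame holds one (17, 2) x-y array per tracked person; an
all-zero array means the person was not detected.  Occupancy is the count
of non-zero arrays.  Standing is separated from (hand-)exercising by the
interquartile range of frame-to-frame Euclidean displacement of the four
hand keypoints (left/right elbow, left/right wrist): standing keypoints
barely move (IQR under ~5 px), exercise oscillations move them far more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthgen import HAND_KEYPOINTS, N_KEYPOINTS

ACTIVITY_THRESHOLD_PX = 5.0


def count_occupancy(frame) -> int:
    """Number of people present in one keypoint frame.

    A person counts as present when any coordinate of their 17-point array
    is non-zero (partial detections count as present).
    """
    n = 0
    for person in frame:
        arr = np.asarray(person, dtype=float)
        if arr.shape != (N_KEYPOINTS, 2):
            raise ValueError(
                f"person array has shape {arr.shape}, expected ({N_KEYPOINTS}, 2)"
            )
        if np.any(arr != 0):
            n += 1
    return n


def occupancy_series(frames) -> np.ndarray:
    return np.array([count_occupancy(f) for f in frames], dtype=int)


def occupancy_accuracy(counts, truth) -> float:
    """Per-frame exact-match accuracy of estimated occupancy counts."""
    counts = np.asarray(counts)
    truth = np.asarray(truth)
    if counts.shape != truth.shape:
        raise ValueError(f"length mismatch: {counts.shape} vs {truth.shape}")
    return float(np.mean(counts == truth))


def hand_track(frames, subject: int) -> np.ndarray:
    """Extract one subject's 4 hand keypoints over time, shape (T, 4, 2)."""
    idx = list(HAND_KEYPOINTS.values())
    return np.stack(
        [np.asarray(frame[subject], dtype=float)[idx] for frame in frames]
    )


def hand_displacements(track: np.ndarray) -> np.ndarray:
    """Euclidean frame-to-frame distance per hand keypoint, shape (T-1, 4)."""
    track = np.asarray(track, dtype=float)
    if track.shape[0] < 2:
        raise ValueError("need at least two frames")
    return np.linalg.norm(np.diff(track, axis=0), axis=2)


def iqr(x) -> float:
    """Interquartile range with linear quantile interpolation."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty distance vector")
    q1, q3 = np.percentile(x, [25, 75], method="linear")
    return float(q3 - q1)


@dataclass(frozen=True)
class ActivityCall:
    keypoint_iqrs: tuple[float, ...]  # per hand keypoint, px
    mean_iqr: float
    threshold: float
    label: str  # "standing" | "exercising"


def classify_activity(
    distances: np.ndarray, threshold: float = ACTIVITY_THRESHOLD_PX
) -> ActivityCall:
    """Label a subject standing vs exercising from hand-keypoint displacement.

    ``distances`` is (T-1, 4): the frame-to-frame distances of the four
    hand keypoints.  The mean IQR across the four keypoints at or above
    ``threshold`` px labels the subject exercising.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[1] != 4:
        raise ValueError("expected (T-1, 4) distances for the four hand keypoints")
    iqrs = tuple(iqr(distances[:, k]) for k in range(4))
    mean_iqr = float(np.mean(iqrs))
    label = "exercising" if mean_iqr >= threshold else "standing"
    return ActivityCall(iqrs, mean_iqr, threshold, label)


def classify_subjects(
    frames, n_subjects: int, threshold: float = ACTIVITY_THRESHOLD_PX
) -> list[ActivityCall]:
    """Activity call per subject for a keypoint stream."""
    return [
        classify_activity(hand_displacements(hand_track(frames, k)), threshold)
        for k in range(n_subjects)
    ]
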