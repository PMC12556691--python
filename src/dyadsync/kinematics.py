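"""Objective movement-synchrony and movement-complexity metrics.

The synchrony score compares two movers frame by frame through "pose
vectors": the 21 pairwise Euclidean distances among the 7 upper-body
joints, L1-normalised so that absolute position and body size cancel.
Two normalised pose vectors are compared with total-variation similarity
(1 = identical pose shape, 0 = no overlap), and the per-frame values are
averaged over the video.

Movement complexity is the sample entropy of the hand trajectories
(2 hands x 2 axes x 2 movers = 8 series), averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .pose import JOINT_PAIRS, PoseSequence

__all__ = [
    "smooth_pose",
    "pose_distance_vector",
    "pose_distance_matrix",
    "frame_similarity",
    "synchrony_score",
    "sample_entropy",
    "movement_complexity",
    "PoseDistanceVector",
    "ComplexityScore",
]


def smooth_pose(seq: PoseSequence, window: int = 13, polyorder: int = 2) -> PoseSequence:
    """Savitzky-Golay smooth every joint coordinate series.

    Defaults (window 13 frames, order 2) match the stimulus-preparation
    settings used for keypoint trajectories at 25 fps.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if seq.n_frames < window:
        raise ValueError(
            f"sequence has {seq.n_frames} frames; at least {window} required for smoothing"
        )
    smoothed = savgol_filter(seq.coords, window_length=window, polyorder=polyorder, axis=0)
    return PoseSequence(coords=smoothed, fps=seq.fps)


@dataclass(frozen=True)
class PoseDistanceVector:
    """Normalised pairwise joint distances for one frame (the "pose vector").

    values sum to 1 and are non-negative; ``degenerate`` is set when all
    joints coincide (tracking dropout), in which case the uniform vector
    is substituted.
    """

    values: np.ndarray
    frame_index: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(JOINT_PAIRS),):
            raise ValueError(f"expected {len(JOINT_PAIRS)} distances, got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        if not self.degenerate and abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("normalised distance vector must sum to 1")
        object.__setattr__(self, "values", v)


def _raw_distances(coords_frame: np.ndarray) -> np.ndarray:
    i, j = np.transpose(JOINT_PAIRS)
    return np.linalg.norm(coords_frame[i] - coords_frame[j], axis=-1)


def pose_distance_vector(seq: PoseSequence, frame: int) -> PoseDistanceVector:
    """L1-normalised 21-distance pose vector of one frame.

    Distances are invariant to translation; dividing by their sum removes
    overall scale, so differences in height or camera distance cancel.
    """
    if not 0 <= frame < seq.n_frames:
        raise IndexError(f"frame {frame} out of range [0, {seq.n_frames})")
    d = _raw_distances(seq.coords[frame])
    total = d.sum()
    if total == 0.0:
        uniform = np.full(len(JOINT_PAIRS), 1.0 / len(JOINT_PAIRS))
        return PoseDistanceVector(values=uniform, frame_index=frame, degenerate=True)
    return PoseDistanceVector(values=d / total, frame_index=frame)


def pose_distance_matrix(seq: PoseSequence) -> np.ndarray:
    """All frames' normalised pose vectors, shape (n_frames, 21).

    Degenerate (all-coincident) frames get the uniform vector.
    """
    i, j = np.transpose(JOINT_PAIRS)
    d = np.linalg.norm(seq.coords[:, i, :] - seq.coords[:, j, :], axis=-1)
    totals = d.sum(axis=1, keepdims=True)
    out = np.where(totals > 0, d / np.where(totals > 0, totals, 1.0), 1.0 / d.shape[1])
    return out


def frame_similarity(a: PoseDistanceVector | np.ndarray, b: PoseDistanceVector | np.ndarray) -> float:
    """Total-variation similarity 1 - 0.5*sum|a - b| between two pose vectors.

    On L1-normalised non-negative vectors this is 1 iff the poses are
    identical in shape and 0 iff their supports are disjoint.
    """
    av = a.values if isinstance(a, PoseDistanceVector) else np.asarray(a, float)
    bv = b.values if isinstance(b, PoseDistanceVector) else np.asarray(b, float)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape} vs {bv.shape}")
    return float(1.0 - 0.5 * np.abs(av - bv).sum())


def synchrony_score(a: PoseSequence, b: PoseSequence) -> float:
    """Frame-averaged pose similarity of a dyad; the objective synchrony S in [0, 1]."""
    if a.n_frames != b.n_frames:
        raise ValueError(f"frame count mismatch: {a.n_frames} vs {b.n_frames}")
    if a.fps != b.fps:
        raise ValueError(f"fps mismatch: {a.fps} vs {b.fps}")
    pa = pose_distance_matrix(a)
    pb = pose_distance_matrix(b)
    sims = 1.0 - 0.5 * np.abs(pa - pb).sum(axis=1)
    return float(sims.mean())


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy SampEn(m, r) with r = r_factor * SD(x).

    -ln(A/B) where B counts pairs of length-m templates within Chebyshev
    distance r and A the same at length m+1; self-matches are excluded
    and both counts run over the first n-m templates (Richman-Moorman
    convention, as in the pracma implementation). Returns 0 for a
    constant series and +inf when no (m+1)-template pair matches.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < m + 2:
        raise ValueError(f"series of length {n} too short for m={m}; need at least {m + 2}")
    sd = x.std(ddof=1)
    if sd == 0.0:
        return 0.0
    r = r_factor * sd
    # Chebyshev distances between all pairs of the first n-m length-(m+1)
    # windows; the length-m distance is the max over the first m coords.
    nt = n - m
    idx = np.arange(nt)[:, None] + np.arange(m + 1)[None, :]
    templates = x[idx]  # (nt, m+1)
    diff = np.abs(templates[:, None, :] - templates[None, :, :])
    dm = diff[:, :, :m].max(axis=2)
    dm1 = diff.max(axis=2)
    iu = np.triu_indices(nt, k=1)
    b = int(np.count_nonzero(dm[iu] <= r))
    a = int(np.count_nonzero(dm1[iu] <= r))
    if b == 0:
        return float("nan")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


@dataclass(frozen=True)
class ComplexityScore:
    """Movement complexity H: mean of 8 per-hand/axis/mover sample entropies."""

    value: float
    components: np.ndarray = field(default_factory=lambda: np.empty(0))


def movement_complexity(a: PoseSequence, b: PoseSequence, m: int = 2, r_factor: float = 0.2) -> ComplexityScore:
    """Mean sample entropy of the x/y series of both hands of both movers."""
    hands = ("l_hand", "r_hand")
    comps = []
    for person_idx, seq in enumerate((a, b)):
        for hand in hands:
            traj = seq.joint(hand)
            for axis_idx, axis in enumerate("xy"):
                try:
                    comps.append(sample_entropy(traj[:, axis_idx], m=m, r_factor=r_factor))
                except ValueError as exc:
                    raise ValueError(
                        f"sample entropy failed for mover {person_idx}, {hand}, axis {axis}: {exc}"
                    ) from exc
    components = np.asarray(comps)
    return ComplexityScore(value=float(components.mean()), components=components)
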