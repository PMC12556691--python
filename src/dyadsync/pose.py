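"""Pose time-series container for one mover.

A pose is seven named upper-body joints (neck, shoulders, elbows, hands)
with 2-D pixel-like coordinates per frame, as produced by markerless
keypoint trackers on mirror-game video.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical joint order; every PoseSequence uses exactly these, in this order.
JOINTS: tuple[str, ...] = (
    "neck",
    "l_shoulder",
    "r_shoulder",
    "l_elbow",
    "r_elbow",
    "l_hand",
    "r_hand",
)

#: The 21 joint pairs, lexicographic in the joint enumeration above.
JOINT_PAIRS: tuple[tuple[int, int], ...] = tuple(combinations(range(len(JOINTS)), 2))


@dataclass(frozen=True)
class PoseSequence:
    """2-D coordinates of the 7 upper-body joints over time.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, 7, 2)
        (x, y) per frame and joint, in pixel-like units.
    fps : float
        Sampling rate in frames per second.
    """

    coords: np.ndarray
    fps: float = 25.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1] != len(JOINTS) or coords.shape[2] != 2:
            raise ValueError(
                f"coords must have shape (n_frames, {len(JOINTS)}, 2); got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "coords", coords)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration(self) -> float:
        """Length of the sequence in seconds."""
        return self.n_frames / self.fps

    def joint(self, name: str) -> np.ndarray:
        """Return the (n_frames, 2) trajectory of a named joint."""
        if name not in JOINTS:
            raise KeyError(f"unknown joint {name!r}; expected one of {JOINTS}")
        return self.coords[:, JOINTS.index(name), :]

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation with columns (frame, joint, x, y)."""
        n, j = self.coords.shape[:2]
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n), j),
                "joint": np.tile(np.asarray(JOINTS), n),
                "x": self.coords[:, :, 0].ravel(),
                "y": self.coords[:, :, 1].ravel(),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, fps: float = 25.0) -> "PoseSequence":
        df = pd.read_csv(path, sep="\t")
        missing = set(JOINTS) - set(df["joint"])
        if missing:
            raise ValueError(f"pose table is missing joints: {sorted(missing)}")
        n = int(df["frame"].max()) + 1
        coords = np.empty((n, len(JOINTS), 2))
        for j, name in enumerate(JOINTS):
            sub = df[df["joint"] == name].sort_values("frame")
            if len(sub) != n:
                raise ValueError(f"joint {name!r} has {len(sub)} frames, expected {n}")
            coords[:, j, 0] = sub["x"].to_numpy()
            coords[:, j, 1] = sub["y"].to_numpy()
        return cls(coords=coords, fps=fps)
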