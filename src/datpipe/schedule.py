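"""Dynamic PET frame schedules.

A dynamic acquisition is described by the start and duration of every frame,
in seconds from injection.  The default schedule is the 75-min protocol used
for dynamic [18F]FE-PE2I imaging: 9 x 20 s, 3 x 60 s, 5 x 180 s, 9 x 360 s
(26 frames, 4500 s total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FrameSchedule", "make_default_schedule"]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping dynamic frames.

    Parameters
    ----------
    starts_s : array of frame start times, seconds from injection.
    durations_s : array of frame durations, seconds.
    """

    starts_s: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        durs = np.asarray(self.durations_s, dtype=float)
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "durations_s", durs)
        if starts.ndim != 1 or starts.shape != durs.shape or starts.size == 0:
            raise ValueError("starts and durations must be equal-length 1-D arrays")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        ends = starts + durs
        if not np.allclose(starts[1:], ends[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")
        if np.any(np.diff(self.mid_s) <= 0):
            raise ValueError("frame mid-times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.starts_s.size

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s

    @property
    def total_s(self) -> float:
        return float(self.ends_s[-1] - self.starts_s[0])

    @property
    def mid_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s / 2.0

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations_s / 60.0

    def frames_in_window(self, t0_min: float, t1_min: float) -> np.ndarray:
        """Indices of frames lying fully inside the window [t0, t1] (minutes).

        The window endpoints must align with frame boundaries: a frame cut by
        either endpoint is an error, as is an empty window.
        """
        t0_s, t1_s = t0_min * 60.0, t1_min * 60.0
        starts, ends = self.starts_s, self.ends_s
        cut = (starts < t0_s) & (ends > t0_s) | (starts < t1_s) & (ends > t1_s)
        if np.any(cut):
            bad = int(np.flatnonzero(cut)[0])
            raise ValueError(
                f"window [{t0_min}, {t1_min}] min cuts frame {bad} "
                f"({starts[bad]}-{ends[bad]} s); endpoints must align with frame boundaries"
            )
        inside = np.flatnonzero((starts >= t0_s) & (ends <= t1_s))
        if inside.size == 0:
            raise ValueError(f"window [{t0_min}, {t1_min}] min contains no frames")
        return inside

    def to_frame(self) -> pd.DataFrame:
        """Sidecar timing table (frame, start_s, duration_s)."""
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "start_s": self.starts_s,
                "duration_s": self.durations_s,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrameSchedule":
        df = df.sort_values("frame")
        return cls(df["start_s"].to_numpy(float), df["duration_s"].to_numpy(float))


def make_default_schedule() -> FrameSchedule:
    """The default 75-min dynamic schedule: 9x20 s, 3x60 s, 5x180 s, 9x360 s."""
    durations = np.concatenate(
        [np.full(9, 20.0), np.full(3, 60.0), np.full(5, 180.0), np.full(9, 360.0)]
    )
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)
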