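"""In-memory container for a calibrated grayscale image sequence."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComflowError

__all__ = ["ImageSequence"]


@dataclass
class ImageSequence:
    """Ordered grayscale frames with spatial and temporal calibration.

    frames : (n, H, W) float array in [0, 1].
    mm_per_px : spatial calibration (mm per pixel), or None if unknown.
    frame_interval_s : time between consecutive frames (s), or None.
    """

    frames: np.ndarray
    mm_per_px: float | None = None
    frame_interval_s: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise ComflowError("frames must be a nonempty (n, H, W) stack")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, k) -> np.ndarray:
        return self.frames[k]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]
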