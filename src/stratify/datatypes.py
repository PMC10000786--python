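"""Core containers shared across the pipeline.

A dynamic epifluorescence acquisition is a video of whole-body NIR
fluorescence after an intravenous indocyanine-green (ICG) bolus; the two
objects every stage exchanges are the video itself (:class:`FrameStack`)
and per-ROI mean-brightness time courses (:class:`IntensitySeries`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class StratifyError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(StratifyError, ValueError):
    """An argument violates a documented precondition."""


class LandmarkError(StratifyError):
    """Latency/peak detection failed (e.g. peak at frame 0, monotone decay)."""


class DetectionError(StratifyError):
    """Tumor ROI detection found no acceptable blob."""


class RegistrationError(StratifyError):
    """Rigid registration cannot be estimated (degenerate reference)."""


class SelectionError(StratifyError):
    """Congenic pair selection left no surviving pair."""

    def __init__(self, message: str, audit=None):
        super().__init__(message)
        self.audit = audit


@dataclass
class FrameStack:
    """A dynamic image sequence.

    Parameters
    ----------
    data : ndarray, shape (frames, rows, cols)
        Nonnegative fluorescence intensities.
    fps : float
        Acquisition frame rate in frames per second.
    n_background_frames : int
        Number of leading pre-injection frames available for background
        correction. Zero after :func:`~stratify.preprocessing.subtract_background`.
    """

    data: np.ndarray
    fps: float
    n_background_frames: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError(
                f"stack data must be (frames, rows, cols); got ndim={self.data.ndim}"
            )
        if not self.fps > 0:
            raise InvalidArgumentError(f"fps must be positive; got {self.fps}")
        if self.n_background_frames < 0:
            raise InvalidArgumentError("n_background_frames must be >= 0")
        if self.n_background_frames > self.n_frames:
            raise InvalidArgumentError(
                "n_background_frames exceeds the number of frames"
            )
        if not np.isfinite(self.data).all():
            raise InvalidArgumentError("stack data must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds from acquisition start."""
        return np.arange(self.n_frames) / self.fps


@dataclass
class IntensitySeries:
    """Mean-brightness time course of one ROI, I(t)."""

    values: np.ndarray
    fps: float
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not self.fps > 0:
            raise InvalidArgumentError(f"fps must be positive; got {self.fps}")
        if self.values.size == 0:
            raise InvalidArgumentError("empty intensity series")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fps

    def normalized(self) -> "IntensitySeries":
        """Min–max normalize to [0, 1].

        A constant (degenerate-range) series maps to all zeros by convention.
        """
        lo = float(self.values.min())
        hi = float(self.values.max())
        if hi - lo <= 0:
            vals = np.zeros_like(self.values)
        else:
            vals = (self.values - lo) / (hi - lo)
        return IntensitySeries(vals, self.fps, name=self.name, meta=dict(self.meta))


def minmax_image(img: np.ndarray) -> np.ndarray:
    """Min–max normalize an image to [0, 1]; constant images map to zeros."""
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)
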