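"""Background subtraction, respiratory denoising and rigid alignment.

The acquisition protocol records ~50 pre-injection frames; their per-pixel
mean (CCD offset + excitation-light leakage) is the background estimate.
Respiratory motion shows up as high-frequency intensity jitter in every
pixel's kinetic sequence; it is removed by a zero-phase temporal low-pass
filter combined with 1-D wavelet shrinkage, both applied independently per
pixel along time. Rigid (rotation + translation) registration aligns a
stack to a reference image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage, signal
from skimage.registration import phase_cross_correlation

from .datatypes import (
    FrameStack,
    IntensitySeries,
    InvalidArgumentError,
    RegistrationError,
    StratifyError,
)


@dataclass(frozen=True)
class DenoiseConfig:
    """Respiratory denoising parameters.

    ``lowpass_cutoff`` (Hz) sits below rodent respiratory rates but above
    the ICG kinetics bandwidth; the wavelet step uses soft universal-
    threshold shrinkage of the detail coefficients.
    """

    lowpass_cutoff: float = 0.8
    wavelet_name: str = "db4"
    wavelet_level: int | None = None  # None: maximum usable level
    threshold_rule: str = "universal"

    def __post_init__(self):
        if not self.lowpass_cutoff > 0:
            raise InvalidArgumentError("lowpass_cutoff must be positive")
        if self.threshold_rule != "universal":
            raise InvalidArgumentError("only the 'universal' threshold rule is implemented")


def subtract_background(stack: FrameStack) -> FrameStack:
    """Subtract the pre-injection background and drop those frames.

    The per-pixel mean of the first ``n_background_frames`` frames is
    subtracted from every remaining frame; negative results are clipped to
    zero (intensities are photon counts). The returned stack has
    ``n_background_frames = 0``, which makes a second application an
    invalid-state error.
    """
    if stack.n_background_frames < 1:
        raise StratifyError(
            "no background frames available (already background-corrected?)"
        )
    nb = stack.n_background_frames
    background = stack.data[:nb].mean(axis=0)
    corrected = stack.data[nb:] - background[None]
    np.maximum(corrected, 0.0, out=corrected)
    return FrameStack(corrected, fps=stack.fps, n_background_frames=0)


def _denoise_array(arr: np.ndarray, fps: float, cfg: DenoiseConfig) -> np.ndarray:
    """Low-pass + wavelet-shrink along axis 0 of ``arr``."""
    nyquist = fps / 2.0
    if cfg.lowpass_cutoff >= nyquist:
        raise InvalidArgumentError(
            f"lowpass_cutoff {cfg.lowpass_cutoff} >= Nyquist {nyquist}"
        )
    n = arr.shape[0]
    sos = signal.butter(4, cfg.lowpass_cutoff, fs=fps, output="sos")
    out = signal.sosfiltfilt(sos, arr, axis=0)

    wavelet = pywt.Wavelet(cfg.wavelet_name)
    max_level = pywt.dwt_max_level(n, wavelet.dec_len)
    level = min(cfg.wavelet_level or max_level, max_level)
    if level < 1:
        raise InvalidArgumentError(
            f"series of length {n} too short for wavelet '{cfg.wavelet_name}'"
        )
    coeffs = pywt.wavedec(out, wavelet, level=level, axis=0)
    # universal threshold, noise scale from the finest detail level (MAD)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest), axis=0) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(n))
    coeffs = [coeffs[0]] + [
        pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]
    ]
    rec = pywt.waverec(coeffs, wavelet, axis=0)
    return rec[:n]


def denoise_respiratory(obj, cfg: DenoiseConfig | None = None):
    """Remove respiratory jitter from a series or a whole stack.

    Applied independently per pixel along time; output shape equals input
    shape. A pure sinusoid above the cutoff is attenuated by >= 90% in
    amplitude while slow kinetic trends pass essentially unchanged.
    """
    cfg = cfg or DenoiseConfig()
    if isinstance(obj, IntensitySeries):
        vals = _denoise_array(obj.values[:, None], obj.fps, cfg)[:, 0]
        return IntensitySeries(vals, obj.fps, name=obj.name, meta=dict(obj.meta))
    if isinstance(obj, FrameStack):
        flat = obj.data.reshape(obj.n_frames, -1)
        out = _denoise_array(flat, obj.fps, cfg).reshape(obj.data.shape)
        np.maximum(out, 0.0, out=out)
        return FrameStack(out, fps=obj.fps, n_background_frames=obj.n_background_frames)
    raise InvalidArgumentError("expected IntensitySeries or FrameStack")


@dataclass(frozen=True)
class RigidTransform:
    """Estimated rigid-body transform: rotation (deg, CCW) then shift (px)."""

    rotation_deg: float
    shift: tuple[float, float]  # (row, col)


def _apply_rigid(image: np.ndarray, rotation_deg: float, shift) -> np.ndarray:
    out = image
    if rotation_deg != 0.0:
        out = ndimage.rotate(out, rotation_deg, reshape=False, order=1, mode="constant")
    if shift[0] != 0.0 or shift[1] != 0.0:
        out = ndimage.shift(out, shift, order=1, mode="constant")
    return out


def _shift_and_score(moving: np.ndarray, reference: np.ndarray):
    shift, error, _ = phase_cross_correlation(
        reference, moving, upsample_factor=20, normalization=None
    )
    return tuple(float(s) for s in shift), 1.0 - float(error)


def register_rigid(
    stack: FrameStack,
    reference: np.ndarray,
    rotation_range_deg: float = 10.0,
    coarse_step_deg: float = 1.0,
) -> tuple[FrameStack, RigidTransform]:
    """Rigidly align a stack to a reference image.

    The transform (rotation about the frame center + translation) is
    estimated between the stack's temporal-mean image and the reference by
    maximizing the phase-correlation score over a rotation grid (then a
    local parabolic refinement), and applied to all frames.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != stack.frame_shape:
        raise InvalidArgumentError("reference shape must match the frame shape")
    if np.ptp(reference) == 0:
        raise RegistrationError("constant reference image")
    moving = stack.data.mean(axis=0)
    if np.ptp(moving) == 0:
        raise RegistrationError("constant stack")

    def score_at(angle: float) -> float:
        rotated = _apply_rigid(moving, angle, (0.0, 0.0))
        _, score = _shift_and_score(rotated, reference)
        return score

    angles = np.arange(-rotation_range_deg, rotation_range_deg + 1e-9, coarse_step_deg)
    scores = np.array([score_at(a) for a in angles])
    best = int(np.argmax(scores))
    best_angle = float(angles[best])
    # parabolic refinement on the coarse grid
    if 0 < best < len(angles) - 1:
        y0, y1, y2 = scores[best - 1 : best + 2]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-12:
            best_angle += 0.5 * coarse_step_deg * (y0 - y2) / denom

    rotated = _apply_rigid(moving, best_angle, (0.0, 0.0))
    shift, _ = _shift_and_score(rotated, reference)
    transform = RigidTransform(rotation_deg=best_angle, shift=shift)
    aligned = np.stack(
        [_apply_rigid(frame, best_angle, shift) for frame in stack.data]
    )
    np.maximum(aligned, 0.0, out=aligned)
    return (
        FrameStack(aligned, fps=stack.fps, n_background_frames=stack.n_background_frames),
        transform,
    )
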