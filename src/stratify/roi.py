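"""PCA decomposition, component ranking and tumor ROI segmentation.

A dynamic stack is unfolded to a pixels-by-time matrix, mean-centered per
pixel and decomposed by PCA along the time dimension; the per-pixel scores
of each component form a spatial loading image in which organs with
similar kinetics (tumor, liver, fat pads) appear as coherent patterns.
Components are ranked by the maximum absolute normalized 2-D
cross-correlation (2DCC) of their display-normalized images against a
reference image containing a tumor; the best component is segmented
(2DCC-derived bounding box, morphological dilation, thresholding, largest
connected blob) into the tumor ROI. ROI mean-brightness series are then
extracted from the stack.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk

from .datatypes import (
    DetectionError,
    FrameStack,
    IntensitySeries,
    InvalidArgumentError,
    minmax_image,
)

logger = logging.getLogger(__name__)


@dataclass
class PCDecomposition:
    """PCA of a stack along time.

    ``component_images``: (k, rows, cols) unit-norm spatial loadings,
    sign-fixed so each image's 99th percentile is positive.
    ``temporal_weights``: (k, frames) matched temporal profiles carrying
    the magnitude. ``explained_variance``: fractions, non-increasing.
    """

    component_images: np.ndarray
    temporal_weights: np.ndarray
    explained_variance: np.ndarray
    mean_pixel: np.ndarray  # per-pixel temporal mean, (rows, cols)

    @property
    def k(self) -> int:
        return self.component_images.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.component_images.shape[1:]

    def display_image(self, i: int) -> np.ndarray:
        """Component image min-max normalized to [0, 1] for display/ranking."""
        return minmax_image(self.component_images[i])

    def reconstruct(self) -> np.ndarray:
        """Rebuild the (frames, rows, cols) data from all k components."""
        rows, cols = self.frame_shape
        imgs = self.component_images.reshape(self.k, -1)  # (k, pixels)
        data = imgs.T @ self.temporal_weights  # (pixels, frames)
        data = data + self.mean_pixel.reshape(-1, 1)
        return data.T.reshape(-1, rows, cols)


def pca_decompose(stack: FrameStack, k: int) -> PCDecomposition:
    """Decompose a stack by PCA along the time dimension.

    Observations are pixels, variables are time frames; each pixel's time
    course is mean-centered before the SVD. If ``k`` exceeds the matrix
    rank it is reduced with a warning.
    """
    n_frames = stack.n_frames
    rows, cols = stack.frame_shape
    n_pixels = rows * cols
    max_k = min(n_pixels, n_frames)
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if k > max_k:
        warnings.warn(
            f"k={k} exceeds min(n_pixels, n_frames)={max_k}; reduced", stacklevel=2
        )
        k = max_k

    X = stack.data.reshape(n_frames, n_pixels).T.astype(float)  # (pixels, frames)
    mean_pixel = X.mean(axis=1)
    Xc = X - mean_pixel[:, None]
    # economy SVD: Xc = U S Vt; scores (pixel loadings) = U S, temporal basis = Vt
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((S**2).sum())
    rank = int((S > S[0] * 1e-12).sum()) if S.size and S[0] > 0 else 0
    if k > rank and rank > 0:
        warnings.warn(f"k={k} exceeds rank {rank}; reduced", stacklevel=2)
        k = rank
    scores = U[:, :k] * S[:k]  # (pixels, k)
    temporal = Vt[:k]  # (k, frames)

    images = np.empty((k, rows, cols))
    weights = np.empty((k, n_frames))
    for i in range(k):
        img = scores[:, i]
        norm = np.linalg.norm(img)
        if norm == 0:
            norm = 1.0
        img_u = img / norm
        w = temporal[i] * norm
        # sign convention: the image's 99th percentile is positive
        if np.percentile(img_u, 99) < 0:
            img_u = -img_u
            w = -w
        images[i] = img_u.reshape(rows, cols)
        weights[i] = w
    ev = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PCDecomposition(
        component_images=images,
        temporal_weights=weights,
        explained_variance=ev,
        mean_pixel=mean_pixel.reshape(rows, cols),
    )


def _ncc_score(image: np.ndarray, reference: np.ndarray) -> float:
    """Max |normalized 2-D cross-correlation| of an image against a reference."""
    ref = np.asarray(reference, dtype=float)
    if np.ptp(ref) == 0:
        raise InvalidArgumentError("reference image is constant/all-zero")
    resp = match_template(image, ref, pad_input=True)
    return float(np.abs(resp).max())


def rank_components(
    pcd: PCDecomposition, reference: np.ndarray, top_k: int = 10
) -> list[tuple[int, float]]:
    """Rank the first ``top_k`` components against a tumor reference image.

    Each display-normalized component image is scored by the maximum
    absolute value of its normalized 2-D cross-correlation with the
    reference; indices are returned sorted by descending score. Absolute-
    value scoring makes the ranking invariant to PCA sign flips, and the
    normalized correlation makes it invariant to affine rescaling of the
    reference.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != pcd.frame_shape:
        raise InvalidArgumentError("reference shape must match component images")
    if np.ptp(reference) == 0:
        raise InvalidArgumentError("all-zero/constant reference image")
    if top_k < 1 or top_k > pcd.k:
        top_k = min(max(top_k, 1), pcd.k)
    scored = [
        (i, _ncc_score(pcd.display_image(i), reference)) for i in range(top_k)
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


@dataclass
class ROISet:
    """Detected/assigned ROIs of one acquisition (masks pairwise disjoint)."""

    tumor_mask: np.ndarray
    fatpad_masks: list = field(default_factory=list)
    tumor_centroid: tuple[float, float] | None = None
    bounding_box: tuple[int, int, int, int] | None = None  # row, col, height, width

    def validate(self) -> None:
        if self.tumor_mask is not None and not self.tumor_mask.any():
            raise InvalidArgumentError("empty tumor mask")
        total = np.zeros_like(self.tumor_mask, dtype=int)
        for m in [self.tumor_mask, *self.fatpad_masks]:
            total += m.astype(int)
        if (total > 1).any():
            raise InvalidArgumentError("ROI masks must be pairwise disjoint")


def segment_tumor(
    component_image: np.ndarray,
    reference_stack,
    dilation_radius: int = 2,
    threshold_method: str = "otsu",
    min_area: int = 5,
) -> ROISet:
    """Segment the tumor from a selected component image.

    For each reference image the tumor template (the reference's Otsu
    foreground bounding box) is located in the component image by
    normalized 2DCC; the per-reference boxes are averaged into one
    bounding box. Inside the box, morphological dilation emphasizes the
    tumor boundary, a threshold separates it from background, and the
    largest connected blob becomes the tumor mask/centroid.
    """
    if threshold_method != "otsu":
        raise InvalidArgumentError("only the 'otsu' threshold method is implemented")
    refs = list(reference_stack)
    if not refs:
        raise InvalidArgumentError("need at least one reference image")
    img = minmax_image(np.asarray(component_image, dtype=float))
    rows, cols = img.shape

    boxes = []
    signed_peaks = []
    for ref in refs:
        ref = np.asarray(ref, dtype=float)
        if np.ptp(ref) == 0:
            raise InvalidArgumentError("constant reference image")
        fg = ref > threshold_otsu(ref)
        if not fg.any():
            continue
        rr, cc = np.nonzero(fg)
        template = ref[rr.min() : rr.max() + 1, cc.min() : cc.max() + 1]
        th, tw = template.shape
        resp = match_template(img, template, pad_input=True)
        peak = np.unravel_index(np.argmax(np.abs(resp)), resp.shape)
        signed_peaks.append(float(resp[peak]))
        # pad_input peaks at the template center position
        boxes.append((peak[0] - th / 2.0, peak[1] - tw / 2.0, th, tw))
    if not boxes:
        raise DetectionError("no usable reference image")
    if np.mean(signed_peaks) < 0:
        # the tumor appears with negative polarity in this component
        # (PCA signs are arbitrary); invert so it is the bright structure
        img = 1.0 - img
    boxes = np.array(boxes)
    r0, c0, h, w = boxes.mean(axis=0)
    margin = dilation_radius + 1
    top = int(np.clip(round(r0) - margin, 0, rows - 1))
    left = int(np.clip(round(c0) - margin, 0, cols - 1))
    bottom = int(np.clip(round(r0 + h) + margin, top + 1, rows))
    right = int(np.clip(round(c0 + w) + margin, left + 1, cols))
    bbox = (top, left, bottom - top, right - left)

    patch = img[top:bottom, left:right]
    if dilation_radius > 0:
        patch = dilation(patch, disk(dilation_radius))
    if np.ptp(patch) == 0:
        raise DetectionError("flat region inside the bounding box")
    binary = patch > threshold_otsu(patch)
    labels, n_blobs = ndimage.label(binary)
    if n_blobs == 0:
        raise DetectionError("no blob above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_blobs + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        raise DetectionError(
            f"largest blob ({int(sizes[best - 1])} px) below minimum area {min_area}"
        )
    mask = np.zeros_like(img, dtype=bool)
    mask[top:bottom, left:right] = labels == best
    centroid = ndimage.center_of_mass(mask)
    return ROISet(
        tumor_mask=mask,
        tumor_centroid=(float(centroid[0]), float(centroid[1])),
        bounding_box=bbox,
    )


def detect_tumor_roi(
    stack: FrameStack,
    reference_stack,
    k: int = 10,
    dilation_radius: int = 2,
) -> tuple[ROISet, list[tuple[int, float]]]:
    """PCA-decompose, rank against references, segment the best component."""
    pcd = pca_decompose(stack, k=min(k, min(stack.n_frames, int(np.prod(stack.frame_shape)))))
    refs = list(reference_stack)
    ranking = rank_components(pcd, refs[0], top_k=min(10, pcd.k))
    best_idx = ranking[0][0]
    rois = segment_tumor(
        pcd.display_image(best_idx), refs, dilation_radius=dilation_radius
    )
    return rois, ranking


def extract_series(stack: FrameStack, rois: ROISet) -> dict:
    """Per-ROI mean-brightness series, raw and min-max normalized.

    Returns ``{name: (raw, normalized)}`` with the tumor under ``"tumor"``
    and fat pads under ``"fatpad_0"`` ... Masks must be nonempty and lie
    within the frame bounds.
    """
    named = [("tumor", rois.tumor_mask)]
    named += [(f"fatpad_{i}", m) for i, m in enumerate(rois.fatpad_masks)]
    out = {}
    for name, mask in named:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.frame_shape:
            raise InvalidArgumentError(f"mask {name} does not match frame shape")
        if not mask.any():
            raise InvalidArgumentError(f"empty mask {name}")
        series = stack.data[:, mask].mean(axis=1)
        raw = IntensitySeries(series, stack.fps, name=name)
        out[name] = (raw, raw.normalized())
    return out
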