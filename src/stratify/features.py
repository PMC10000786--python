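"""Curve landmarks and the 86-dimensional kinetic feature vector.

Per ROI the smoothed, min-max-normalized curve I(t) yields landmarks
(latency L = dye arrival, peak, time-to-peak TTP = peak - L, first
half-maximum crossing) and base features:

* ``U``     = (1 - I(L)) / TTP                      (average upslope)
* ``D_S``   = (1 - I(L + TTP + S)) / S              (downslope, S s past peak)
* ``TR``    = TTP / (t_halfmax - t_L)               (uptake time ratio)
* ``HIF_S`` = (1 - I(L + T_1/2 + S)) / S            (half-intensity forward)

with S in a fixed 20-element grid (2..80 s). Each base quantity comes in a
plain variant (suffix ``_rel``) and a window-robustified variant
(``_avg``): D/HIF take the median of D(S+s)/HIF(S+s) over anchor offsets
s in {-1.5, -1.3, ..., 1.5} s, and TTP/U/TR take the median over the same
offsets applied to the latency anchor. That makes 43 base quantities x 2
variants = 86 features per ROI; the per-animal feature vector relates the
tumor ROI to healthy tissue via the fat-pad median,

    Fn = (F_tumor - median(F_fatpad)) / median(F_fatpad).

Seconds convert to frame offsets by round(seconds * fps). Indices past the
series end are clipped to the last frame (with a logged warning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .datatypes import IntensitySeries, InvalidArgumentError, LandmarkError

logger = logging.getLogger(__name__)

S_SET_DEFAULT = (
    2, 4, 5, 6, 8, 10, 12, 14, 16, 18, 20, 23, 25, 30, 35, 40, 50, 60, 70, 80,
)
WINDOW_OFFSETS_DEFAULT = tuple(np.round(np.arange(-1.5, 1.51, 0.2), 10))


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky-Golay smoothing: order-3 polynomial, 31-frame window."""

    polynomial_order: int = 3
    window_length: int = 31

    def __post_init__(self):
        if self.window_length % 2 != 1:
            raise InvalidArgumentError("window_length must be odd")
        if self.window_length <= self.polynomial_order:
            raise InvalidArgumentError("window_length must exceed polynomial_order")


@dataclass(frozen=True)
class FeatureConfig:
    s_set: tuple = S_SET_DEFAULT
    window_offsets: tuple = WINDOW_OFFSETS_DEFAULT
    fps: float = 10.6

    def __post_init__(self):
        if not self.fps > 0:
            raise InvalidArgumentError("fps must be positive")
        if any(s <= 0 for s in self.s_set):
            raise InvalidArgumentError("all S values must be positive")


@dataclass(frozen=True)
class CurveLandmarks:
    """Landmarks of one smoothed, normalized curve (frame indices)."""

    latency_frame: int
    peak_frame: int
    ttp_s: float
    half_max_frame: int
    peak_value: float

    def __post_init__(self):
        if not (
            self.latency_frame <= self.half_max_frame <= self.peak_frame
        ):
            raise InvalidArgumentError("landmarks must satisfy L <= T1/2 <= peak")
        if self.ttp_s < 0:
            raise InvalidArgumentError("ttp_s must be >= 0")


def smooth_series(series: IntensitySeries, cfg: SmoothingConfig | None = None) -> IntensitySeries:
    """Least-squares local-polynomial (Savitzky-Golay) smoothing.

    Output length equals input length; edges are handled by fitting the
    polynomial on the truncated window (scipy's ``interp`` mode).
    """
    cfg = cfg or SmoothingConfig()
    if series.n < cfg.window_length:
        raise InvalidArgumentError(
            f"series length {series.n} < window_length {cfg.window_length}"
        )
    vals = savgol_filter(
        series.values, cfg.window_length, cfg.polynomial_order, mode="interp"
    )
    return IntensitySeries(vals, series.fps, name=series.name, meta=dict(series.meta))


def detect_landmarks(
    series: IntensitySeries,
    cfg: SmoothingConfig | None = None,
    robust_len: int = 5,
    presmoothed: bool = False,
) -> CurveLandmarks:
    """Find latency, peak, TTP and half-maximum crossing of one series.

    The peak is the first global maximum of the smoothed curve. The latency
    is the last robust zero crossing of the smoothed first difference
    before the peak: the last frame at which the difference crosses from
    <= 0 to > 0 and then stays positive for at least ``robust_len``
    consecutive frames (the start of the final sustained rise). The
    half-max frame is the first frame at/after the latency whose
    normalized intensity reaches half the peak value.

    Raises :class:`LandmarkError` for curves without a usable wash-in
    (peak at frame 0 or a monotone-decreasing series).
    """
    smoothed = series if presmoothed else smooth_series(series, cfg)
    norm = smoothed.normalized().values
    peak = int(np.argmax(norm))  # first occurrence on ties
    if peak == 0:
        raise LandmarkError("peak at frame 0: no wash-in phase")
    diff = np.diff(norm)
    if (diff <= 0).all():
        raise LandmarkError("monotone-decreasing series")

    latency = None
    for i in range(peak - 1, -1, -1):
        if diff[i] <= 0 or (i > 0 and diff[i - 1] > 0):
            continue  # not a <=0 -> >0 crossing
        run = diff[i : i + robust_len]
        if run.size == robust_len and (run > 0).all():
            latency = i
            break
    if latency is None:
        # the rise extends back to the very first frame
        latency = int(np.argmin(norm[: peak + 1]))
    else:
        # refine: correlated noise can keep the difference positive through a
        # flat pre-arrival stretch; advance to the last frame still at the
        # crossing's intensity level (within 1% of the peak value)
        level = norm[latency] + 0.01 * norm[peak]
        below = np.nonzero(norm[latency : peak + 1] <= level)[0]
        if below.size:
            latency = latency + int(below[-1])

    peak_value = float(norm[peak])
    half_candidates = np.nonzero(norm[latency : peak + 1] >= 0.5 * peak_value)[0]
    half = latency + int(half_candidates[0])
    ttp = (peak - latency) / series.fps
    return CurveLandmarks(
        latency_frame=int(latency),
        peak_frame=peak,
        ttp_s=float(ttp),
        half_max_frame=half,
        peak_value=peak_value,
    )


def feature_names(cfg: FeatureConfig | None = None) -> list[str]:
    """The 86 feature names in canonical order (TTP, U, TR, D_S, HIF_S) x (_rel, _avg)."""
    cfg = cfg or FeatureConfig()
    bases = ["TTP", "U", "TR"]
    bases += [f"D{s:g}" for s in cfg.s_set]
    bases += [f"HIF{s:g}" for s in cfg.s_set]
    names = []
    for base in bases:
        names.append(f"{base}_rel")
        names.append(f"{base}_avg")
    return names


def _finite_median(values) -> float:
    """Median of the finite entries; NaN when none are finite."""
    finite = [v for v in values if np.isfinite(v)]
    return float(np.median(finite)) if finite else float("nan")


def _value_at(vals: np.ndarray, idx: int, clip_log: list) -> float:
    if idx >= vals.size:
        clip_log.append(idx)
        idx = vals.size - 1
    return float(vals[max(idx, 0)])


def _anchor_quantities(
    vals: np.ndarray, latency: int, peak: int, fps: float
) -> tuple[float, float, float, int]:
    """TTP, U, TR and the half-max frame for one latency anchor."""
    latency = int(np.clip(latency, 0, peak - 1)) if peak > 0 else 0
    ttp = (peak - latency) / fps
    peak_value = float(vals[peak])
    upslope = (1.0 - float(vals[latency])) / ttp if ttp > 0 else np.nan
    half_rel = np.nonzero(vals[latency : peak + 1] >= 0.5 * peak_value)[0]
    half = latency + int(half_rel[0]) if half_rel.size else peak
    t_half = (half - latency) / fps
    tr = ttp / t_half if t_half > 0 else np.nan
    return ttp, upslope, tr, half


def compute_base_features(
    series: IntensitySeries,
    lm: CurveLandmarks,
    cfg: FeatureConfig | None = None,
) -> dict:
    """Compute the 86 raw features of one normalized series.

    ``series`` must be the smoothed, min-max-normalized curve (peak value
    1). Values are raw per-ROI features; see :func:`normalize_features`
    for the fat-pad-referenced per-animal vector.
    """
    cfg = cfg or FeatureConfig(fps=series.fps)
    vals = series.values
    fps = cfg.fps
    clip_log: list = []

    def f2i(seconds: float) -> int:
        return int(round(seconds * fps))

    out: dict[str, float] = {}

    # plain variants, anchored at the detected latency
    L = lm.latency_frame
    peak = lm.peak_frame
    ttp, upslope, tr, half = _anchor_quantities(vals, L, peak, fps)
    if ttp == 0:
        logger.warning("TTP = 0: U and TR undefined for %s", series.name)
    out["TTP_rel"] = ttp
    out["U_rel"] = upslope
    out["TR_rel"] = tr
    for s in cfg.s_set:
        out[f"D{s:g}_rel"] = (1.0 - _value_at(vals, peak + f2i(s), clip_log)) / s
        out[f"HIF{s:g}_rel"] = (1.0 - _value_at(vals, half + f2i(s), clip_log)) / s

    # window-robustified variants
    offsets = cfg.window_offsets
    ttps, ups, trs = [], [], []
    for s_off in offsets:
        q = _anchor_quantities(vals, L + f2i(s_off), peak, fps)
        ttps.append(q[0])
        ups.append(q[1])
        trs.append(q[2])
    out["TTP_avg"] = _finite_median(ttps)
    out["U_avg"] = _finite_median(ups)
    out["TR_avg"] = _finite_median(trs)
    for s in cfg.s_set:
        d_vals = []
        h_vals = []
        for s_off in offsets:
            s_eff = s + s_off
            if s_eff <= 0:  # pragma: no cover - S_SET minimum is 2 s
                continue
            d_vals.append(
                (1.0 - _value_at(vals, peak + f2i(s_eff), clip_log)) / s_eff
            )
            h_vals.append(
                (1.0 - _value_at(vals, half + f2i(s_eff), clip_log)) / s_eff
            )
        out[f"D{s:g}_avg"] = float(np.median(d_vals))
        out[f"HIF{s:g}_avg"] = float(np.median(h_vals))

    if clip_log:
        logger.warning(
            "%d feature indices beyond the series end were clipped to the last "
            "frame (series %s)",
            len(clip_log),
            series.name,
        )
    return out


def normalize_features(tumor_features: dict, fatpad_feature_sets: list[dict]) -> dict:
    """Per-animal feature vector: percentage difference to the fat-pad median.

    ``Fn = (F_tumor - median(F_fatpad)) / median(F_fatpad)`` for each of the
    86 names. A zero fat-pad median flags the feature as missing (NaN).
    """
    if len(fatpad_feature_sets) < 3:
        raise InvalidArgumentError("need at least 3 fat-pad feature sets")
    out = {}
    for name, tumor_val in tumor_features.items():
        ref = _finite_median([fp[name] for fp in fatpad_feature_sets])
        if ref == 0 or not np.isfinite(ref):
            logger.warning("fat-pad median of %s is zero/non-finite; flagged", name)
            out[name] = np.nan
        else:
            out[name] = (tumor_val - ref) / ref
    return out


def extract_animal_features(
    tumor: IntensitySeries,
    fatpads: list[IntensitySeries],
    smoothing: SmoothingConfig | None = None,
    cfg: FeatureConfig | None = None,
    robust_len: int = 5,
) -> dict:
    """Smooth, normalize, detect landmarks and compute the 86-entry vector."""
    smoothing = smoothing or SmoothingConfig()
    cfg = cfg or FeatureConfig(fps=tumor.fps)

    def _roi_features(series: IntensitySeries) -> dict:
        smoothed = smooth_series(series, smoothing)
        norm = smoothed.normalized()
        lm = detect_landmarks(norm, robust_len=robust_len, presmoothed=True)
        return compute_base_features(norm, lm, cfg)

    tumor_feats = _roi_features(tumor)
    fatpad_feats = [_roi_features(fp) for fp in fatpads]
    return normalize_features(tumor_feats, fatpad_feats)


def cohort_feature_table(
    records,
    smoothing: SmoothingConfig | None = None,
    cfg: FeatureConfig | None = None,
    robust_len: int = 5,
) -> pd.DataFrame:
    """Feature table with one row per animal: id, group, dll4_label + 86 features.

    Animals whose landmark detection fails are excluded with a logged
    warning.
    """
    rows = []
    for rec in records:
        try:
            feats = extract_animal_features(
                rec.tumor, rec.fatpads, smoothing, cfg, robust_len
            )
        except LandmarkError as exc:
            logger.warning("excluding %s: %s", rec.animal_id, exc)
            continue
        row = {
            "animal_id": rec.animal_id,
            "group": rec.group,
            "dll4_label": rec.dll4_label,
        }
        row.update(feats)
        rows.append(row)
    table = pd.DataFrame(rows)
    order = ["animal_id", "group", "dll4_label"] + feature_names(cfg)
    return table.loc[:, order]
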