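"""Synthetic ICG kinetics, cohorts and phantom videos.

No imaging data were deposited for the consomic/congenic rat study this
package analyzes, so every downstream stage is exercised against synthetic
stand-ins generated here:

* per-ROI ICG wash-in/wash-out curves with class-dependent latency,
  time-to-peak and washout (Dll4-low hosts take up dye faster and retain it
  longer than Dll4-high hosts),
* cohorts with the published group structure (parental Dll4+ n=8 and
  Dll4- n=17 plus eight congenic groups CG1..CG8, 133 animals total),
* ellipse phantoms rendered into frame stacks (tumor, 3-4 mammary fat
  pads, liver on distinct kinetics), and
* the geometric augmentation used to stress classification models.

The kinetic curve is a smoothstep wash-in on [latency, latency+ttp]
followed by a bi-exponential wash-out

    I(t) = peak * (r * exp(-k_slow dt) + (1-r) * exp(-k_fast dt)),

with additive Gaussian noise and a sinusoidal respiratory intensity
modulation. The curve family is a minimal parameterization of the
wash-in/wash-out morphology of observed tumor ICG kinetics, not a
pharmacokinetic compartment model.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datatypes import FrameStack, IntensitySeries, InvalidArgumentError

DEFAULT_FPS = 10.6
#: series length used for cohort kinetics (~283 s, the full acquisition window)
DEFAULT_N_FRAMES = 3000
#: desk-scale phantom geometry
DESK_SHAPE = (64, 64)
DESK_STACK_FRAMES = 600
FULL_SHAPE = (256, 256)
FULL_STACK_FRAMES = 3000

_PARAM_FIELDS = (
    "latency_s",
    "ttp_s",
    "peak_amp",
    "fast_decay_rate",
    "slow_decay_rate",
    "retention_frac",
    "noise_sd",
    "resp_amp",
    "resp_freq",
)


@dataclass(frozen=True)
class KineticParams:
    """Parameters of one ROI's ICG time-intensity curve.

    Units: times in seconds, rates in 1/s, amplitudes in arbitrary
    intensity units, ``retention_frac`` the fraction of peak signal that
    decays at the slow rate.
    """

    latency_s: float
    ttp_s: float
    peak_amp: float = 1.0
    fast_decay_rate: float = 0.05
    slow_decay_rate: float = 0.01
    retention_frac: float = 0.4
    noise_sd: float = 0.0
    resp_amp: float = 0.0
    resp_freq: float = 1.0

    def __post_init__(self):
        if self.latency_s < 0:
            raise InvalidArgumentError("latency_s must be >= 0")
        if not self.ttp_s > 0:
            raise InvalidArgumentError("ttp_s must be > 0")
        if not self.peak_amp > 0:
            raise InvalidArgumentError("peak_amp must be > 0")
        if self.fast_decay_rate < 0 or self.slow_decay_rate < 0:
            raise InvalidArgumentError("decay rates must be >= 0")
        if self.slow_decay_rate > self.fast_decay_rate:
            raise InvalidArgumentError("slow_decay_rate must be <= fast_decay_rate")
        if not 0 <= self.retention_frac <= 1:
            raise InvalidArgumentError("retention_frac must be in [0, 1]")
        if self.noise_sd < 0 or self.resp_amp < 0:
            raise InvalidArgumentError("noise_sd and resp_amp must be >= 0")
        if not self.resp_freq > 0:
            raise InvalidArgumentError("resp_freq must be > 0")


def simulate_curve(
    params: KineticParams, n_frames: int, fps: float, seed: int | None = 0
) -> IntensitySeries:
    """Simulate one ROI time-intensity curve.

    The noiseless curve is zero before ``latency_s``, rises monotonically
    (smoothstep) to a unique maximum ``peak_amp`` at ``latency_s + ttp_s``
    and then decays bi-exponentially. Gaussian noise (sd ``noise_sd``) and a
    respiratory sinusoid (amplitude ``resp_amp``, frequency ``resp_freq``)
    are added on top. Identical ``seed`` gives identical output.
    """
    if not isinstance(n_frames, (int, np.integer)) or n_frames <= 0:
        raise InvalidArgumentError("n_frames must be a positive integer")
    if not fps > 0:
        raise InvalidArgumentError("fps must be positive")
    peak_time = params.latency_s + params.ttp_s
    if n_frames <= fps * peak_time:
        raise InvalidArgumentError(
            "series ends before the curve peaks: "
            f"n_frames={n_frames} <= fps*(latency+ttp)={fps * peak_time:.1f}"
        )
    t = np.arange(n_frames) / fps
    x = np.clip((t - params.latency_s) / params.ttp_s, 0.0, 1.0)
    rise = x * x * (3.0 - 2.0 * x)
    dt = np.maximum(t - peak_time, 0.0)
    decay = params.retention_frac * np.exp(-params.slow_decay_rate * dt) + (
        1.0 - params.retention_frac
    ) * np.exp(-params.fast_decay_rate * dt)
    clean = params.peak_amp * np.where(t <= peak_time, rise, decay)

    if params.noise_sd > 0 or params.resp_amp > 0:
        rng = np.random.default_rng(seed)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        clean = clean + params.resp_amp * np.sin(
            2.0 * np.pi * params.resp_freq * t + phase
        )
        clean = clean + rng.normal(0.0, params.noise_sd, n_frames)
    return IntensitySeries(clean, fps, meta={"params": params})


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One strain group: name, size, class label and parameter distribution.

    ``param_distribution`` maps each :class:`KineticParams` field to a
    ``(mean, sd)`` pair; per-animal parameters are drawn normally and
    clipped into the field's valid range.
    """

    name: str
    n: int
    dll4_label: str  # "high" or "low"
    param_distribution: dict

    def __post_init__(self):
        if self.n < 1:
            raise InvalidArgumentError("group size n must be >= 1")
        if self.dll4_label not in ("high", "low"):
            raise InvalidArgumentError("dll4_label must be 'high' or 'low'")
        missing = set(_PARAM_FIELDS) - set(self.param_distribution)
        if missing:
            raise InvalidArgumentError(f"param_distribution missing {sorted(missing)}")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple
    fatpad_distribution: dict
    n_fatpads_range: tuple[int, int] = (3, 4)
    n_frames: int = DEFAULT_N_FRAMES
    fps: float = DEFAULT_FPS
    seed: int = 0

    def __post_init__(self):
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("group names must be unique")
        lo, hi = self.n_fatpads_range
        if not (1 <= lo <= hi):
            raise InvalidArgumentError("invalid n_fatpads_range")

    @property
    def total_n(self) -> int:
        return sum(g.n for g in self.groups)


@dataclass
class AnimalRecord:
    """One synthetic animal: a tumor series plus 3-4 fat-pad series."""

    animal_id: str
    group: str
    dll4_label: str
    tumor: IntensitySeries
    fatpads: list
    params: KineticParams

    @property
    def n_fatpads(self) -> int:
        return len(self.fatpads)


def _draw_params(dist: dict, rng: np.random.Generator) -> KineticParams:
    raw = {}
    for name in _PARAM_FIELDS:
        mean, sd = dist[name]
        raw[name] = rng.normal(mean, sd) if sd > 0 else float(mean)
    raw["latency_s"] = max(raw["latency_s"], 0.0)
    raw["ttp_s"] = max(raw["ttp_s"], 0.1)
    raw["peak_amp"] = max(raw["peak_amp"], 1e-3)
    raw["fast_decay_rate"] = max(raw["fast_decay_rate"], 0.0)
    raw["slow_decay_rate"] = float(
        np.clip(raw["slow_decay_rate"], 0.0, raw["fast_decay_rate"])
    )
    raw["retention_frac"] = float(np.clip(raw["retention_frac"], 0.0, 1.0))
    raw["noise_sd"] = max(raw["noise_sd"], 0.0)
    raw["resp_amp"] = max(raw["resp_amp"], 0.0)
    raw["resp_freq"] = max(raw["resp_freq"], 1e-2)
    return KineticParams(**raw)


def _draw_group_params(
    dist: dict, n: int, rng: np.random.Generator
) -> list[KineticParams]:
    """Per-animal parameters of one strain group.

    Consomic/congenic strains are inbred: the strain's genetic effect on
    each kinetic parameter is a fixed constant, and per-animal spread is
    exchangeable environmental variation. Draws are therefore re-centered
    so each group's sample mean sits at the strain mean (then clipped into
    the parameter's valid range).
    """
    raw = {}
    for name in _PARAM_FIELDS:
        mean, sd = dist[name]
        if sd > 0 and n > 1:
            draws = rng.normal(mean, sd, n)
            raw[name] = draws - draws.mean() + mean
        elif sd > 0:
            raw[name] = np.array([rng.normal(mean, sd)])
        else:
            raw[name] = np.full(n, float(mean))
    out = []
    for i in range(n):
        p = {name: float(raw[name][i]) for name in _PARAM_FIELDS}
        p["latency_s"] = max(p["latency_s"], 0.0)
        p["ttp_s"] = max(p["ttp_s"], 0.1)
        p["peak_amp"] = max(p["peak_amp"], 1e-3)
        p["fast_decay_rate"] = max(p["fast_decay_rate"], 0.0)
        p["slow_decay_rate"] = float(
            np.clip(p["slow_decay_rate"], 0.0, p["fast_decay_rate"])
        )
        p["retention_frac"] = float(np.clip(p["retention_frac"], 0.0, 1.0))
        p["noise_sd"] = max(p["noise_sd"], 0.0)
        p["resp_amp"] = max(p["resp_amp"], 0.0)
        p["resp_freq"] = max(p["resp_freq"], 1e-2)
        out.append(KineticParams(**p))
    return out


def generate_cohort(spec: CohortSpec) -> list[AnimalRecord]:
    """Generate all animals of a cohort; pure function of the spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    records = []
    lo, hi = spec.n_fatpads_range
    for group in spec.groups:
        group_params = _draw_group_params(group.param_distribution, group.n, rng)
        for i in range(group.n):
            params = group_params[i]
            curve_seed = int(rng.integers(2**31))
            tumor = simulate_curve(params, spec.n_frames, spec.fps, curve_seed)
            n_fp = int(rng.integers(lo, hi + 1))
            fatpads = []
            for _ in range(n_fp):
                fp_params = _draw_params(spec.fatpad_distribution, rng)
                fp_seed = int(rng.integers(2**31))
                fatpads.append(
                    simulate_curve(fp_params, spec.n_frames, spec.fps, fp_seed)
                )
            records.append(
                AnimalRecord(
                    animal_id=f"{group.name}_{i:03d}",
                    group=group.name,
                    dll4_label=group.dll4_label,
                    tumor=tumor,
                    fatpads=fatpads,
                    params=params,
                )
            )
    return records


#: published group sizes (133 animals in total)
DEFAULT_GROUP_SIZES = {
    "Dll4+": 8,
    "Dll4-": 17,
    "CG1": 19,
    "CG2": 2,
    "CG3": 26,
    "CG4": 12,
    "CG5": 28,
    "CG6": 12,
    "CG7": 5,
    "CG8": 4,
}

#: Dll4 expression class of each group (host vasculature)
DEFAULT_GROUP_LABELS = {
    "Dll4+": "high",
    "Dll4-": "low",
    "CG1": "high",
    "CG2": "low",
    "CG3": "low",
    "CG4": "low",
    "CG5": "high",
    "CG6": "high",
    "CG7": "low",
    "CG8": "low",
}

#: strength of the high/low axis per group: the planted best congenic pair
#: CG5|CG4 carries roughly three times the class-effect strength of the
#: other congenic groups; the parental strains sit at +/-1
DEFAULT_GROUP_EFFECT = {
    "Dll4+": 1.0,
    "Dll4-": -1.0,
    "CG1": 0.45,
    "CG2": -0.45,
    "CG3": -0.45,
    "CG4": -1.4,
    "CG5": 1.4,
    "CG6": 0.45,
    "CG7": -0.45,
    "CG8": -0.45,
}


def group_param_distribution(alpha: float, effect_scale: float = 1.0) -> dict:
    """Tumor kinetic-parameter distribution at class strength ``alpha``.

    ``alpha`` in [-1, 1] interpolates between the Dll4-low pole (-1: faster
    uptake, longer retention) and the Dll4-high pole (+1: slower uptake,
    faster washout). ``effect_scale`` scales every between-class gap and is
    used by tests that probe monotonicity of class separation.
    """
    a = alpha * effect_scale
    return {
        "latency_s": (11.0 + 1.0 * a, 1.1),
        "ttp_s": (7.5 + 1.5 * a, 1.1),
        "peak_amp": (1.0, 0.05),
        "fast_decay_rate": (0.05, 0.005),
        "slow_decay_rate": (0.009 + 0.003 * a, 0.0027),
        "retention_frac": (0.475 - 0.125 * a, 0.09),
        "noise_sd": (0.02, 0.0),
        "resp_amp": (0.02, 0.0),
        "resp_freq": (1.0, 0.0),
    }


def fatpad_param_distribution() -> dict:
    """Healthy mammary-fat-pad kinetics, shared across classes."""
    return {
        "latency_s": (10.5, 0.5),
        "ttp_s": (5.0, 0.5),
        "peak_amp": (0.6, 0.05),
        "fast_decay_rate": (0.08, 0.005),
        "slow_decay_rate": (0.010, 0.001),
        "retention_frac": (0.25, 0.03),
        "noise_sd": (0.02, 0.0),
        "resp_amp": (0.02, 0.0),
        "resp_freq": (1.0, 0.0),
    }


def default_cohort_spec(
    seed: int = 0,
    effect_scale: float = 1.0,
    n_frames: int = DEFAULT_N_FRAMES,
    fps: float = DEFAULT_FPS,
) -> CohortSpec:
    """The default study conditions: published group structure, planted Dll4 effect."""
    groups = tuple(
        GroupSpec(
            name=name,
            n=n,
            dll4_label=DEFAULT_GROUP_LABELS[name],
            param_distribution=group_param_distribution(
                DEFAULT_GROUP_EFFECT[name], effect_scale
            ),
        )
        for name, n in DEFAULT_GROUP_SIZES.items()
    )
    return CohortSpec(
        groups=groups,
        fatpad_distribution=fatpad_param_distribution(),
        n_frames=n_frames,
        fps=fps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates (row-major, 0-based)."""

    center_row: float
    center_col: float
    semi_row: float
    semi_col: float

    def mask(self, rows: int, cols: int) -> np.ndarray:
        rr, cc = np.mgrid[0:rows, 0:cols]
        return (
            ((rr - self.center_row) / self.semi_row) ** 2
            + ((cc - self.center_col) / self.semi_col) ** 2
        ) <= 1.0

    def inside(self, rows: int, cols: int) -> bool:
        return (
            self.center_row - self.semi_row >= 0
            and self.center_row + self.semi_row < rows
            and self.center_col - self.semi_col >= 0
            and self.center_col + self.semi_col < cols
        )


@dataclass(frozen=True)
class PhantomLayout:
    """Anatomy of one phantom: tumor, 3-4 fat pads, liver, flat background."""

    tumor: Ellipse
    fatpads: tuple
    liver: Ellipse
    background_level: float = 0.05

    def validate(self, rows: int, cols: int) -> None:
        for ell in (self.tumor, *self.fatpads, self.liver):
            if not ell.inside(rows, cols):
                raise InvalidArgumentError("ellipse does not fit inside the frame")
        tmask = self.tumor.mask(rows, cols)
        for fp in self.fatpads:
            if (tmask & fp.mask(rows, cols)).any():
                raise InvalidArgumentError("tumor overlaps a fat pad")
        if not 3 <= len(self.fatpads) <= 4:
            raise InvalidArgumentError("layout must have 3 or 4 fat pads")
        if self.background_level < 0:
            raise InvalidArgumentError("background_level must be >= 0")


def default_phantom_layout(
    rows: int = DESK_SHAPE[0],
    cols: int = DESK_SHAPE[1],
    n_fatpads: int = 4,
    seed: int | None = 0,
) -> PhantomLayout:
    """Random non-overlapping phantom anatomy inside a rows x cols frame.

    The tumor sits in the lower half (where the mammary fat pad xenografts
    grow), fat pads are smaller ellipses nearby, the liver a large ellipse
    in the upper half.
    """
    rng = np.random.default_rng(seed)
    liver = Ellipse(
        center_row=rng.uniform(0.18, 0.25) * rows,
        center_col=rng.uniform(0.4, 0.6) * cols,
        semi_row=0.12 * rows,
        semi_col=0.2 * cols,
    )
    placed = []
    tumor = None
    for attempt in range(500):
        cand = Ellipse(
            center_row=rng.uniform(0.55, 0.8) * rows,
            center_col=rng.uniform(0.25, 0.75) * cols,
            semi_row=rng.uniform(0.08, 0.11) * rows,
            semi_col=rng.uniform(0.09, 0.13) * cols,
        )
        if cand.inside(rows, cols):
            tumor = cand
            break
    if tumor is None:  # pragma: no cover - geometry always fits defaults
        raise InvalidArgumentError("could not place tumor inside frame")
    tmask = tumor.mask(rows, cols)
    occupied = tmask | liver.mask(rows, cols)
    struct = np.ones((5, 5), dtype=bool)
    for _ in range(2000):
        if len(placed) == n_fatpads:
            break
        cand = Ellipse(
            center_row=rng.uniform(0.45, 0.9) * rows,
            center_col=rng.uniform(0.08, 0.92) * cols,
            semi_row=rng.uniform(0.035, 0.055) * rows,
            semi_col=rng.uniform(0.035, 0.055) * cols,
        )
        if not cand.inside(rows, cols):
            continue
        cmask = cand.mask(rows, cols)
        # keep a 2-px clearance to everything already placed
        if (ndimage.binary_dilation(cmask, struct) & occupied).any():
            continue
        placed.append(cand)
        occupied |= cmask
    if len(placed) < n_fatpads:  # pragma: no cover
        raise InvalidArgumentError("could not place all fat pads")
    layout = PhantomLayout(tumor=tumor, fatpads=tuple(placed), liver=liver)
    layout.validate(rows, cols)
    return layout


#: liver reference kinetics used when rendering phantoms (fast, bright)
LIVER_PARAMS = KineticParams(
    latency_s=4.0,
    ttp_s=3.0,
    peak_amp=1.4,
    fast_decay_rate=0.03,
    slow_decay_rate=0.004,
    retention_frac=0.5,
)


def render_stack(
    record: AnimalRecord,
    layout: PhantomLayout,
    rows: int = DESK_SHAPE[0],
    cols: int = DESK_SHAPE[1],
    n_background_frames: int = 50,
    pixel_noise_sd: float = 0.0,
    seed: int | None = 0,
) -> FrameStack:
    """Render an animal's kinetics into a phantom video.

    The first ``n_background_frames`` frames contain only the flat
    background (plus pixel noise); afterwards each ellipse's pixels carry
    its assigned curve on top of the background. All pixels of one ellipse
    share the same time course up to pixel noise.
    """
    layout.validate(rows, cols)
    if len(layout.fatpads) != record.n_fatpads:
        raise InvalidArgumentError(
            f"layout has {len(layout.fatpads)} fat pads but the record has "
            f"{record.n_fatpads} fat-pad series"
        )
    n_curve = record.tumor.n
    fps = record.tumor.fps
    n_frames = n_background_frames + n_curve
    data = np.full((n_frames, rows, cols), layout.background_level, dtype=float)

    rng = np.random.default_rng(seed)
    liver_seed = int(rng.integers(2**31))
    liver_curve = simulate_curve(
        dataclasses.replace(
            LIVER_PARAMS,
            noise_sd=record.params.noise_sd,
            resp_amp=record.params.resp_amp,
        ),
        n_curve,
        fps,
        liver_seed,
    )

    pairs = [(layout.tumor, record.tumor), (layout.liver, liver_curve)]
    pairs += list(zip(layout.fatpads, record.fatpads))
    for ell, series in pairs:
        mask = ell.mask(rows, cols)
        data[n_background_frames:, mask] += series.values[:, None]
    if pixel_noise_sd > 0:
        data += rng.normal(0.0, pixel_noise_sd, data.shape)
    np.maximum(data, 0.0, out=data)
    return FrameStack(data, fps=fps, n_background_frames=n_background_frames)


def make_reference_images(
    shape: tuple[int, int] = DESK_SHAPE, n: int = 4, seed: int | None = 0
) -> list[np.ndarray]:
    """Synthetic tumor reference images for component ranking/segmentation.

    The published analysis ranked components against reference images of
    real tumors; none were deposited, so these are synthetic stand-ins:
    tumor-sized ellipses (matching the default phantom tumor geometry) at
    random positions, lightly blurred. Users may supply their own
    references instead.
    """
    rows, cols = shape
    rng = np.random.default_rng(seed)
    refs = []
    for _ in range(n):
        ell = Ellipse(
            center_row=rng.uniform(0.35, 0.65) * rows,
            center_col=rng.uniform(0.35, 0.65) * cols,
            semi_row=rng.uniform(0.08, 0.11) * rows,
            semi_col=rng.uniform(0.09, 0.13) * cols,
        )
        img = ell.mask(rows, cols).astype(float)
        refs.append(ndimage.gaussian_filter(img, sigma=1.0))
    return refs


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def augment_stack(
    stack: FrameStack,
    seed: int | None = 0,
    max_rescale: float = 0.02,
    rotation_range_deg: float = 10.0,
    hflip: bool = False,
) -> FrameStack:
    """Geometric augmentation: random rotation, optional horizontal flip,
    up to ``max_rescale`` isotropic rescaling; constant-padded interpolation.

    Shape and frame count are preserved; identical ``seed`` gives identical
    output. Degenerate parameters (rotation range 0, max_rescale 0, no
    flip) return the input data unchanged.
    """
    if max_rescale < 0:
        raise InvalidArgumentError("max_rescale must be >= 0")
    if rotation_range_deg < 0:
        raise InvalidArgumentError("rotation_range_deg must be >= 0")
    if stack.n_frames == 0:
        raise InvalidArgumentError("empty stack")
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-rotation_range_deg, rotation_range_deg)
    scale = rng.uniform(1.0 - max_rescale, 1.0 + max_rescale)

    data = stack.data
    if hflip:
        data = data[:, :, ::-1]
    if angle != 0.0 or scale != 1.0:
        out = np.empty_like(data)
        rows, cols = stack.frame_shape
        center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
        theta = math.radians(angle)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        # inverse map: output -> input is rotation by -theta and division by scale
        matrix = rot.T / scale
        offset = center - matrix @ center
        for i in range(stack.n_frames):
            out[i] = ndimage.affine_transform(
                data[i], matrix, offset=offset, order=1, mode="constant", cval=0.0
            )
        data = out
    else:
        data = data.copy()
    np.maximum(data, 0.0, out=data)
    return FrameStack(data, fps=stack.fps, n_background_frames=stack.n_background_frames)


def augment_records(
    records: list[AnimalRecord],
    n_total: int,
    seed: int = 0,
    max_rescale: float = 0.02,
    extra_noise_sd: float = 0.01,
) -> list[AnimalRecord]:
    """Series-level augmentation of a cohort to ``n_total`` records.

    Each base record is kept and augmented ``k`` times (smallest ``k`` with
    ``N*(k+1) >= n_total``), then the list is truncated to ``n_total``.
    Each augmented copy applies the footprint that the stack-level geometric
    transforms leave on ROI-mean series: a global intensity rescale of up to
    ``max_rescale`` and small interpolation-like Gaussian noise.
    """
    if not records:
        raise InvalidArgumentError("no base records")
    if n_total < len(records):
        raise InvalidArgumentError("n_total must be >= number of base records")
    n_base = len(records)
    k = math.ceil(n_total / n_base) - 1
    rng = np.random.default_rng(seed)
    out = list(records)
    for copy_idx in range(k):
        for rec in records:
            factor = rng.uniform(1.0 - max_rescale, 1.0 + max_rescale)

            def _perturb(series: IntensitySeries) -> IntensitySeries:
                vals = series.values * factor
                if extra_noise_sd > 0:
                    vals = vals + rng.normal(0.0, extra_noise_sd, vals.size)
                return IntensitySeries(vals, series.fps)

            out.append(
                AnimalRecord(
                    animal_id=f"{rec.animal_id}_aug{copy_idx}",
                    group=rec.group,
                    dll4_label=rec.dll4_label,
                    tumor=_perturb(rec.tumor),
                    fatpads=[_perturb(fp) for fp in rec.fatpads],
                    params=rec.params,
                )
            )
    return out[:n_total]
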