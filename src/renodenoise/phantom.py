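"""Synthetic dynamic renogram phantom.

Emulates a pediatric 99mTc-MAG3 dynamic renal scintigraphy acquisition:
120 frames of 128 x 128 pixels captured every 10 s.  Two elliptical kidneys
whose size grows with patient age follow a gamma-variate time-activity
curve (uptake then washout); a bladder disk fills late in the study; every
pixel count is an independent Poisson draw whose mean scales linearly with
the simulated count level, mirroring the statistics of radioactive decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Literal, Tuple

import numpy as np

__all__ = [
    "PhantomSpec", "DynamicStudy", "ROISet", "CurveParams",
    "make_phantom_spec", "time_activity_curve", "render_mean_frame",
    "sample_study", "ground_truth_rois", "DegenerateROIError",
]

Side = Literal["left", "right"]

# Kidney semi-axis anchors in pixels on the 128-pixel grid: a newborn kidney
# (~4.5 cm) spans roughly 12 px at the drsbru pixel pitch, an adolescent one
# (~10 cm) roughly 26 px; stored as (semi-major, semi-minor).
_AXES_AGE0 = (6.0, 4.0)
_AXES_AGE17 = (13.0, 8.5)
_MAX_AGE = 17.0


class DegenerateROIError(ValueError):
    """Raised when a requested ROI mask would be empty."""


@dataclass(frozen=True)
class CurveParams:
    """Gamma-variate renogram curve: a(t) = (t/tp)^k * exp(k*(1 - t/tp)).

    ``uptake_shape`` (k, unitless) controls the steepness of uptake,
    ``peak_time_s`` (tp) is where the curve attains its maximum of 1, and
    the implied washout rate is k/tp per second.
    """
    uptake_shape: float
    peak_time_s: float

    @property
    def washout_rate(self) -> float:
        return self.uptake_shape / self.peak_time_s


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and kinetics of one synthetic patient."""
    image_size: int
    kidney_centers: Dict[str, Tuple[float, float]]       # (row, col) pixels
    kidney_axes: Tuple[float, float]                     # semi-axes, pixels
    bladder_center: Tuple[float, float]
    bladder_radius: float
    background_level: float                              # counts/px/frame, 100% dose
    kidney_peak_amplitude: Dict[str, float]              # counts/px/frame at peak
    bladder_amplitude: float
    curve_params: Dict[str, CurveParams]
    patient_age_years: float
    seed: int

    def __post_init__(self):
        if not (0.0 <= self.patient_age_years <= _MAX_AGE):
            raise ValueError("patient_age_years must lie in [0, 17]")
        if self.background_level <= 0:
            raise ValueError("background_level must be positive")
        for side in ("left", "right"):
            if self.kidney_peak_amplitude[side] <= 0:
                raise ValueError("kidney_peak_amplitude must be positive")
            cp = self.curve_params[side]
            if cp.uptake_shape <= 0 or cp.peak_time_s <= 0:
                raise ValueError("curve parameters must be strictly positive")
        n = self.image_size
        a, b = self.kidney_axes
        for r, c in self.kidney_centers.values():
            if not (a <= r <= n - 1 - a and b <= c <= n - 1 - b):
                raise ValueError("kidney ellipse extends outside the image")
        br, bc = self.bladder_center
        if not (self.bladder_radius <= br <= n - 1 - self.bladder_radius
                and self.bladder_radius <= bc <= n - 1 - self.bladder_radius):
            raise ValueError("bladder disk extends outside the image")


@dataclass(frozen=True)
class DynamicStudy:
    """One acquired (or simulated) dynamic study."""
    frames: np.ndarray                 # (n_frames, H, W) integer counts
    frame_duration_s: float
    patient_age_years: float
    study_id: str
    provenance: str = "synthetic"
    count_scale: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a 3-D (n_frames, H, W) array")
        if frames.min() < 0 or not np.issubdtype(frames.dtype, np.integer):
            raise ValueError("frames must hold non-negative integer counts")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def total_duration_s(self) -> float:
        return self.n_frames * self.frame_duration_s


@dataclass(frozen=True)
class ROISet:
    """Binary masks for the two kidneys and the surrounding background."""
    left_kidney: np.ndarray
    right_kidney: np.ndarray
    background: np.ndarray

    def __post_init__(self):
        for name in ("left_kidney", "right_kidney", "background"):
            mask = np.asarray(getattr(self, name), dtype=bool)
            if not mask.any():
                raise DegenerateROIError(f"{name} mask is empty")
            object.__setattr__(self, name, mask)
        if (self.left_kidney & self.right_kidney).any():
            raise ValueError("kidney masks overlap")
        if (self.background & (self.left_kidney | self.right_kidney)).any():
            raise ValueError("background mask overlaps a kidney mask")

    def kidney(self, side: Side) -> np.ndarray:
        return self.left_kidney if side == "left" else self.right_kidney


def _age_scaled_axes(age: float) -> Tuple[float, float]:
    f = age / _MAX_AGE
    return (_AXES_AGE0[0] + f * (_AXES_AGE17[0] - _AXES_AGE0[0]),
            _AXES_AGE0[1] + f * (_AXES_AGE17[1] - _AXES_AGE0[1]))


def make_phantom_spec(seed: int, patient_age_years: float,
                      image_size: int = 128,
                      background_level: float = 0.5,
                      kidney_peak_amplitude: float = 6.0) -> PhantomSpec:
    """Draw a randomized but reproducible phantom for one synthetic patient.

    The default count levels place roughly 0.5 background counts/pixel/frame
    and a 12:1 kidney-to-background peak contrast, giving summed 100% images
    with count densities typical of a MAG3 renogram; organ sizes interpolate
    linearly between newborn and adolescent anchors.
    """
    if not (0.0 <= patient_age_years <= _MAX_AGE):
        raise ValueError("patient_age_years must lie in [0, 17]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD05E]))
    n = image_size
    axes = tuple(a * n / 128.0 for a in _age_scaled_axes(patient_age_years))
    row = 0.42 * n + rng.uniform(-0.02, 0.02) * n
    offset = 0.20 * n + rng.uniform(-0.015, 0.015) * n
    centers = {
        "left": (row + rng.uniform(-2, 2) * n / 128, n / 2 + offset),
        "right": (row + rng.uniform(-2, 2) * n / 128, n / 2 - offset),
    }
    amplitudes = {
        side: kidney_peak_amplitude * rng.uniform(0.8, 1.2)
        for side in ("left", "right")
    }
    curves = {
        side: CurveParams(uptake_shape=rng.uniform(2.0, 3.5),
                          peak_time_s=rng.uniform(180.0, 300.0))
        for side in ("left", "right")
    }
    return PhantomSpec(
        image_size=n,
        kidney_centers=centers,
        kidney_axes=axes,
        bladder_center=(0.85 * n, 0.5 * n),
        bladder_radius=(0.05 + 0.02 * patient_age_years / _MAX_AGE) * n,
        background_level=background_level,
        kidney_peak_amplitude=amplitudes,
        bladder_amplitude=kidney_peak_amplitude * 0.6,
        curve_params=curves,
        patient_age_years=patient_age_years,
        seed=int(seed),
    )


def time_activity_curve(spec: PhantomSpec, t_seconds, side: Side = "left"):
    """Relative kidney activity at time ``t`` (unitless, 0 at t=0, peak 1)."""
    t = np.asarray(t_seconds, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    cp = spec.curve_params[side]
    x = t / cp.peak_time_s
    safe_x = np.maximum(x, 1e-12)
    value = np.where(x > 0,
                     safe_x ** cp.uptake_shape * np.exp(cp.uptake_shape * (1.0 - safe_x)),
                     0.0)
    return value if value.ndim else float(value)


def _bladder_curve(spec: PhantomSpec, t: float) -> float:
    # excreted tracer accumulates: smooth sigmoidal fill after the renal peak
    tp = max(cp.peak_time_s for cp in spec.curve_params.values())
    return float(1.0 / (1.0 + np.exp(-(t - 2.0 * tp) / (0.6 * tp))) -
                 1.0 / (1.0 + np.exp(2.0 * tp / (0.6 * tp)))) if t > 0 else 0.0


def _ellipse_mask(n: int, center: Tuple[float, float],
                  axes: Tuple[float, float], angle_deg: float = 0.0) -> np.ndarray:
    rr, cc = np.mgrid[0:n, 0:n]
    dr, dc = rr - center[0], cc - center[1]
    theta = np.deg2rad(angle_deg)
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def organ_masks(spec: PhantomSpec) -> Dict[str, np.ndarray]:
    """Exact phantom organ supports (left/right kidney ellipses, bladder disk)."""
    n = spec.image_size
    masks = {
        side: _ellipse_mask(n, spec.kidney_centers[side], spec.kidney_axes)
        for side in ("left", "right")
    }
    masks["bladder"] = _ellipse_mask(
        n, spec.bladder_center, (spec.bladder_radius, spec.bladder_radius))
    return masks


def render_mean_frame(spec: PhantomSpec, t_seconds: float) -> np.ndarray:
    """Expected counts per pixel for one frame at time ``t`` (100% dose)."""
    masks = organ_masks(spec)
    mean = np.full((spec.image_size,) * 2, spec.background_level, dtype=float)
    for side in ("left", "right"):
        mean[masks[side]] += (spec.kidney_peak_amplitude[side]
                              * time_activity_curve(spec, t_seconds, side))
    mean[masks["bladder"]] += spec.bladder_amplitude * _bladder_curve(spec, t_seconds)
    return mean


def sample_study(spec: PhantomSpec, count_scale: float = 1.0,
                 n_frames: int = 120, frame_duration_s: float = 10.0,
                 study_id: str | None = None) -> DynamicStudy:
    """Draw a Poisson realisation of the phantom at a given count level.

    ``count_scale`` in (0, 1] scales every pixel's expected count, which is
    how a proportionally lower administered activity manifests in the data.
    """
    if not (0.0 < count_scale <= 1.0):
        raise ValueError("count_scale must lie in (0, 1]")
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0DE]))
    # frame midpoint times
    times = (np.arange(n_frames) + 0.5) * frame_duration_s
    frames = np.empty((n_frames, spec.image_size, spec.image_size), dtype=np.int32)
    for k, t in enumerate(times):
        frames[k] = rng.poisson(count_scale * render_mean_frame(spec, t))
    return DynamicStudy(
        frames=frames,
        frame_duration_s=frame_duration_s,
        patient_age_years=spec.patient_age_years,
        study_id=study_id or f"synthetic-{spec.seed:06d}",
        provenance="synthetic",
        count_scale=count_scale,
        seed=spec.seed,
    )


def ground_truth_rois(spec: PhantomSpec, margin_pixels: int = 2,
                      band_width: int = 4) -> ROISet:
    """Kidney masks equal the phantom ellipses; background is a surrounding
    band that starts ``margin_pixels`` outside each kidney, is ``band_width``
    pixels wide, and excludes every organ."""
    if margin_pixels < 0:
        raise ValueError("margin_pixels must be non-negative")
    from scipy.ndimage import binary_dilation

    masks = organ_masks(spec)
    organs = masks["left"] | masks["right"] | masks["bladder"]
    background = np.zeros_like(organs)
    for side in ("left", "right"):
        inner = binary_dilation(masks[side], iterations=margin_pixels) \
            if margin_pixels else masks[side]
        outer = binary_dilation(inner, iterations=band_width)
        background |= outer & ~inner
    background &= ~organs
    if not background.any():
        raise DegenerateROIError("background annulus is empty at this margin")
    return ROISet(left_kidney=masks["left"], right_kidney=masks["right"],
                  background=background)
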