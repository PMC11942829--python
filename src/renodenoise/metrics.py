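"""Image-quality metrics: kidney-ROI SNR, MS-SSIM, and evaluation reports.

SNR follows the lesion/background definition ``(mu_L - mu_B) / sigma_B``
with means and the population standard deviation taken over the ROI masks.
MS-SSIM combines a luminance term at the coarsest scale with contrast and
structure terms at every dyadic scale, using the canonical five-scale
weights, an 11x11 Gaussian window (sigma 1.5) and stabilisers
``C1 = (0.01 L)^2``, ``C2 = (0.03 L)^2`` for data range L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .phantom import DegenerateROIError, ROISet
from .training import relative_error

__all__ = [
    "ROIStats", "MSSSIMParams", "UndefinedSNRError",
    "roi_stats", "snr", "snr_image", "ms_ssim",
    "evaluate_images", "evaluate_method",
]

_CANONICAL_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


class UndefinedSNRError(ValueError):
    """Raised when the background standard deviation is zero."""


@dataclass(frozen=True)
class ROIStats:
    """Masked means and background spread feeding the SNR."""
    mu_L: float
    mu_B: float
    sigma_B: float


def roi_stats(image: np.ndarray, lesion_mask: np.ndarray,
              background_mask: np.ndarray) -> ROIStats:
    """Lesion/background means and population background std over masks."""
    image = np.asarray(image, dtype=np.float64)
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if lesion_mask.shape != image.shape or background_mask.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    if not lesion_mask.any() or not background_mask.any():
        raise DegenerateROIError("ROI masks must be non-empty")
    background = image[background_mask]
    return ROIStats(mu_L=float(image[lesion_mask].mean()),
                    mu_B=float(background.mean()),
                    sigma_B=float(background.std()))   # ddof=0


def snr(stats: ROIStats) -> float:
    """(mu_L - mu_B) / sigma_B."""
    if stats.sigma_B <= 0:
        raise UndefinedSNRError("background standard deviation is zero")
    return (stats.mu_L - stats.mu_B) / stats.sigma_B


def snr_image(image: np.ndarray, rois: ROISet, side: str) -> float:
    return snr(roi_stats(image, rois.kidney(side), rois.background))


@dataclass(frozen=True)
class MSSSIMParams:
    """Scales, exponent weights and window of the MS-SSIM."""
    M: int = 5
    weights: Tuple[float, ...] = _CANONICAL_WEIGHTS   # alpha = beta = gamma
    window_size: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("need at least one scale")
        if self.window_size % 2 == 0:
            raise ValueError("window size must be odd")
        if len(self.weights) < self.M:
            raise ValueError("need one weight per scale")


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    half = size // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    w = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return w / w.sum()


def _filter_valid(img: np.ndarray, window: np.ndarray) -> np.ndarray:
    """Separable Gaussian filtering, cropped to the valid region."""
    half = window.size // 2
    out = convolve1d(img, window, axis=0, mode="nearest")
    out = convolve1d(out, window, axis=1, mode="nearest")
    return out[half:-half, half:-half]


def _ssim_maps(x: np.ndarray, y: np.ndarray, params: MSSSIMParams
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Pixel-wise luminance and contrast*structure maps at one scale."""
    window = _gaussian_window(params.window_size, params.sigma)
    c1 = (params.k1 * params.data_range) ** 2
    c2 = (params.k2 * params.data_range) ** 2
    mu_x = _filter_valid(x, window)
    mu_y = _filter_valid(y, window)
    var_x = _filter_valid(x * x, window) - mu_x ** 2
    var_y = _filter_valid(y * y, window) - mu_y ** 2
    cov = _filter_valid(x * y, window) - mu_x * mu_y
    luminance = (2.0 * mu_x * mu_y + c1) / (mu_x ** 2 + mu_y ** 2 + c1)
    cs = (2.0 * cov + c2) / (var_x + var_y + c2)
    return luminance, cs


def _downsample2(img: np.ndarray) -> np.ndarray:
    h, w = (img.shape[0] // 2) * 2, (img.shape[1] // 2) * 2
    img = img[:h, :w]
    return (img[0::2, 0::2] + img[1::2, 0::2] + img[0::2, 1::2] + img[1::2, 1::2]) / 4.0


def _signed_power(base: float, exponent: float) -> float:
    return float(np.sign(base) * np.abs(base) ** exponent)


def ms_ssim(x: np.ndarray, y: np.ndarray, params: Optional[MSSSIMParams] = None,
            strict: bool = False) -> float:
    """Multiscale structural similarity between two images.

    The luminance exponent applies at the coarsest scale only; contrast and
    structure apply at every scale.  Images too small for the requested
    number of scales reduce M with a warning (or raise when ``strict``).
    Contrast/structure terms are combined by sign-preserving powers, so the
    value is unclamped in general and lies in [0, 1] for the non-negative
    normalized images the pipeline produces (1 = identical).
    """
    params = params or MSSSIMParams()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    min_side = min(x.shape)
    m = params.M
    while m > 1 and min_side < params.window_size * 2 ** (m - 1):
        m -= 1
    if m < params.M:
        if strict:
            raise ValueError(
                f"image of side {min_side} supports only {m} of the requested "
                f"{params.M} scales")
        warnings.warn(f"image too small for {params.M} scales; using M={m}")
    weights = np.asarray(params.weights[:m], dtype=np.float64)
    weights = weights / weights.sum()

    value = 1.0
    for j in range(m):
        luminance, cs = _ssim_maps(x, y, params)
        if j == m - 1:
            # coarsest scale: the luminance exponent applies here, via the
            # mean of the full per-pixel similarity map
            value *= _signed_power(float((luminance * cs).mean()), weights[j])
        else:
            value *= _signed_power(float(cs.mean()), weights[j])
            x, y = _downsample2(x), _downsample2(y)
    return float(value)


def evaluate_images(images: np.ndarray, references: np.ndarray,
                    rois: Sequence[ROISet],
                    params: Optional[MSSSIMParams] = None,
                    study_ids: Optional[Sequence[str]] = None,
                    ages: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Per-image SNR (left/right kidney) and MS-SSIM against a reference."""
    rows = []
    for i, (img, ref, roi) in enumerate(zip(images, references, rois)):
        rows.append({
            "study_id": study_ids[i] if study_ids is not None else str(i),
            "age": float(ages[i]) if ages is not None else np.nan,
            "snr_left": snr_image(img, roi, "left"),
            "snr_right": snr_image(img, roi, "right"),
            "ms_ssim": ms_ssim(img, ref, params),
        })
    return pd.DataFrame(rows)


_METRIC_COLUMNS = ("snr_right", "snr_left", "ms_ssim")


def evaluate_method(denoised_by_method: Dict[str, np.ndarray],
                    baseline_images: np.ndarray,
                    reference_images: np.ndarray,
                    rois: Sequence[ROISet],
                    params: Optional[MSSSIMParams] = None,
                    study_ids: Optional[Sequence[str]] = None,
                    ages: Optional[Sequence[float]] = None,
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Score every method's images and summarise gains/losses vs baseline.

    ``baseline_images`` are the un-denoised reduced-count images (the
    comparison baseline), ``reference_images`` the full-count references
    MS-SSIM is computed against.  Returns (per-image report, summary).
    The summary holds the signed mean percent change of each metric
    relative to the baseline (positive = gain), one row per metric and one
    column per method.
    """
    reports = []
    baseline = evaluate_images(baseline_images, reference_images, rois,
                               params, study_ids, ages)
    baseline.insert(0, "method", "original")
    reports.append(baseline)
    for method, images in denoised_by_method.items():
        frame = evaluate_images(images, reference_images, rois,
                                params, study_ids, ages)
        frame.insert(0, "method", method)
        reports.append(frame)
    report = pd.concat(reports, ignore_index=True)

    summary = {}
    for method in denoised_by_method:
        method_frame = report[report.method == method]
        column = {}
        for metric in _METRIC_COLUMNS:
            base = baseline[metric].to_numpy(dtype=float)
            new = method_frame[metric].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                change = (new - base) / np.maximum(np.abs(new), np.abs(base))
            column[metric] = float(np.nanmean(change) * 100.0)
        summary[method] = column
    summary_frame = pd.DataFrame(summary).reindex(list(_METRIC_COLUMNS))
    summary_frame.index.name = "metric"
    return report, summary_frame
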