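"""ROI SNR and MS-SSIM against brute-force and reference oracles."""

import numpy as np
import pytest

from renodenoise import metrics as qm
from renodenoise import phantom
from renodenoise.phantom import DegenerateROIError


# ------------------------------------------------------------ roi_stats ----

def test_roi_stats_constants():
    image = np.full((6, 6), 5.0)
    mask = np.zeros((6, 6), bool)
    mask[1, 1] = True
    bg = np.zeros((6, 6), bool)
    bg[4, :] = True
    stats = qm.roi_stats(image, mask, bg)
    assert (stats.mu_L, stats.mu_B, stats.sigma_B) == (5.0, 5.0, 0.0)


def test_roi_stats_exact_arithmetic():
    image = np.zeros((3, 3))
    image[0, :2] = 8.0
    image[2, :] = 2.0
    image[2, 1] = 2.0
    lesion = np.zeros((3, 3), bool)
    lesion[0, :2] = True
    bg = np.zeros((3, 3), bool)
    bg[2, :] = True
    stats = qm.roi_stats(image, lesion, bg)
    assert (stats.mu_L, stats.mu_B, stats.sigma_B) == (8.0, 2.0, 0.0)


def test_roi_stats_matches_masked_loops(rng):
    image = rng.random((12, 12))
    lesion = rng.random((12, 12)) > 0.7
    bg = (rng.random((12, 12)) > 0.6) & ~lesion
    stats = qm.roi_stats(image, lesion, bg)
    lesion_vals = [image[i, j] for i in range(12) for j in range(12) if lesion[i, j]]
    bg_vals = [image[i, j] for i in range(12) for j in range(12) if bg[i, j]]
    mean_b = sum(bg_vals) / len(bg_vals)
    var_b = sum((v - mean_b) ** 2 for v in bg_vals) / len(bg_vals)
    assert abs(stats.mu_L - sum(lesion_vals) / len(lesion_vals)) < 1e-12
    assert abs(stats.mu_B - mean_b) < 1e-12
    assert abs(stats.sigma_B - np.sqrt(var_b)) < 1e-12


def test_roi_stats_rejects_empty_mask():
    with pytest.raises(DegenerateROIError):
        qm.roi_stats(np.ones((4, 4)), np.zeros((4, 4), bool),
                     np.ones((4, 4), bool))


# ------------------------------------------------------------------ snr ----

def test_snr_closed_forms():
    assert qm.snr(qm.ROIStats(8.0, 2.0, 2.0)) == 3.0
    assert qm.snr(qm.ROIStats(5.0, 5.0, 1.0)) == 0.0
    with pytest.raises(qm.UndefinedSNRError):
        qm.snr(qm.ROIStats(8.0, 2.0, 0.0))


def test_snr_invariant_under_positive_affine_transforms(rng):
    image = rng.random((32, 32)) + 0.1
    lesion = np.zeros((32, 32), bool)
    lesion[8:12, 8:12] = True
    bg = np.zeros((32, 32), bool)
    bg[20:28, 20:28] = True
    base = qm.snr(qm.roi_stats(image, lesion, bg))
    for a, b in [(2.0, 0.0), (0.5, 3.0), (7.3, -1.2)]:
        transformed = qm.snr(qm.roi_stats(a * image + b, lesion, bg))
        assert transformed == pytest.approx(base, rel=1e-10)


# -------------------------------------------------------------- ms_ssim ----

def test_ms_ssim_identity_and_symmetry(rng):
    x = rng.random((64, 64))
    y = np.clip(x + rng.normal(0, 0.1, (64, 64)), 0, 1)
    assert qm.ms_ssim(x, x) == pytest.approx(1.0, abs=1e-8)
    assert qm.ms_ssim(x, y) == pytest.approx(qm.ms_ssim(y, x), abs=1e-10)


def test_single_scale_matches_skimage_reference(rng):
    """With M=1 the metric reduces to SSIM (Gaussian window, population
    covariance), which an independent implementation reproduces."""
    from skimage.metrics import structural_similarity

    x = rng.random((96, 96))
    y = np.clip(x + rng.normal(0, 0.08, (96, 96)), 0, 1)
    params = qm.MSSSIMParams(M=1, weights=(1.0,))
    reference = structural_similarity(x, y, gaussian_weights=True, sigma=1.5,
                                      use_sample_covariance=False,
                                      data_range=1.0)
    assert qm.ms_ssim(x, y, params) == pytest.approx(reference, abs=1e-4)


def test_multiscale_matches_independent_computation(rng):
    """Independent oracle built from scipy.ndimage filtering (reflect-padded
    maps cropped to the valid interior) reproduces the multiscale value."""
    from scipy.ndimage import gaussian_filter

    def oracle(x, y, m, weights):
        c1, c2 = 0.01 ** 2, 0.03 ** 2
        # truncate the Gaussian to the same 11-tap support
        blur = lambda img: gaussian_filter(img, 1.5, truncate=10 / 3, mode="nearest")
        total = 1.0
        for j in range(m):
            mx, my = blur(x), blur(y)
            vx = blur(x * x) - mx ** 2
            vy = blur(y * y) - my ** 2
            cov = blur(x * y) - mx * my
            lum = (2 * mx * my + c1) / (mx ** 2 + my ** 2 + c1)
            cs = (2 * cov + c2) / (vx + vy + c2)
            crop = (slice(5, -5), slice(5, -5))
            if j == m - 1:
                total *= (lum * cs)[crop].mean() ** weights[j]
            else:
                total *= cs[crop].mean() ** weights[j]
                x = (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2]) / 4
                y = (y[0::2, 0::2] + y[1::2, 0::2] + y[0::2, 1::2] + y[1::2, 1::2]) / 4
        return total

    x = rng.random((128, 128))
    y = np.clip(x + rng.normal(0, 0.05, (128, 128)), 0, 1)
    m = 3
    weights = np.array(qm.MSSSIMParams().weights[:m])
    weights = weights / weights.sum()
    params = qm.MSSSIMParams(M=m, weights=tuple(weights))
    assert qm.ms_ssim(x, y, params) == pytest.approx(
        oracle(x, y, m, weights), abs=2e-4)


def test_ms_ssim_decreases_with_noise_level(rng):
    x = rng.random((128, 128))
    means = []
    for sigma in (0.02, 0.05, 0.1, 0.2):
        values = [qm.ms_ssim(x, np.clip(x + np.random.default_rng(s).normal(
            0, sigma, x.shape), 0, 1)) for s in range(20)]
        means.append(np.mean(values))
    assert all(a > b for a, b in zip(means, means[1:]))


def test_ms_ssim_scale_reduction_behaviour(rng):
    x = rng.random((32, 32))
    with pytest.warns(UserWarning, match="scales"):
        qm.ms_ssim(x, x)
    with pytest.raises(ValueError):
        qm.ms_ssim(x, x, strict=True)
    with pytest.raises(ValueError):
        qm.ms_ssim(x, rng.random((16, 16)))


# ------------------------------------------------------- evaluate_method ----

def _toy_set(rng, n=2):
    spec = phantom.make_phantom_spec(31, 9, image_size=32)
    rois = phantom.ground_truth_rois(spec)
    refs = np.stack([np.clip(
        phantom.render_mean_frame(spec, 200.0) / 8 + rng.normal(0, 0.01, (32, 32)),
        0, 1) for _ in range(n)])
    noisy = np.clip(refs + rng.normal(0, 0.05, refs.shape), 0, 1)
    return refs, noisy, [rois] * n


def test_evaluate_identity_scores_perfect_similarity(rng):
    refs, noisy, rois = _toy_set(rng)
    report, summary = qm.evaluate_method({"perfect": refs}, noisy, refs, rois)
    perfect = report[report.method == "perfect"]
    assert np.allclose(perfect.ms_ssim, 1.0, atol=1e-8)
    assert summary.shape == (3, 1)
    assert list(summary.index) == ["snr_right", "snr_left", "ms_ssim"]


def test_evaluate_summary_matches_hand_computation(rng):
    refs, noisy, rois = _toy_set(rng)
    denoised = np.clip(refs + rng.normal(0, 0.02, refs.shape), 0, 1)
    report, summary = qm.evaluate_method({"m": denoised}, noisy, refs, rois)
    base = report[report.method == "original"]
    mine = report[report.method == "m"]
    for metric in ("snr_right", "snr_left", "ms_ssim"):
        changes = []
        for new, old in zip(mine[metric], base[metric]):
            changes.append((new - old) / max(abs(new), abs(old)) * 100)
        assert summary.loc[metric, "m"] == pytest.approx(np.mean(changes))


def test_summed_100_beats_summed_50_in_kidney_snr():
    from renodenoise import dose

    deltas = []
    for seed in range(20):
        spec = phantom.make_phantom_spec(500 + seed, float(seed % 18),
                                         image_size=32)
        rois = phantom.ground_truth_rois(spec)
        study = phantom.sample_study(spec, 1.0, n_frames=40)
        full = dose.sum_frames(study, 1.0).pixels
        half = dose.sum_frames(study, 0.5).pixels
        deltas.append(qm.snr_image(full, rois, "right")
                      - qm.snr_image(half, rois, "right"))
    assert np.mean(deltas) > 0
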