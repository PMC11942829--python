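"""Canned study-scale experiments used by the acceptance checks.

The scaled-down denoising experiment reproduces the study design at desk
scale: a synthetic cohort with one patient per (scaled) age group, 100% and
50% summed images, a UDnCNN trained with the published optimal
hyperparameters (batch 16, learning rate 1e-3, Adam), and evaluation of
kidney SNR and MS-SSIM on the held-out test images.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from . import dose, phantom
from .metrics import evaluate_images
from .models import NetworkConfig, build_discriminator, build_model, denoise
from .study_io import StudyRecord
from .training import TrainingConfig, train, _stack

__all__ = ["make_cohort", "scaled_denoising_experiment"]


def make_cohort(n_studies: int, image_size: int, seed: int,
                n_frames: int = 120) -> list[StudyRecord]:
    """Synthetic cohort with ages spread evenly over 0-17 years."""
    records = []
    for i in range(n_studies):
        age = float((i * 17) // max(n_studies - 1, 1))
        spec = phantom.make_phantom_spec(seed=seed * 10_000 + i,
                                         patient_age_years=age,
                                         image_size=image_size)
        study = phantom.sample_study(spec, count_scale=1.0, n_frames=n_frames,
                                     study_id=f"study_{i:03d}")
        records.append(StudyRecord(study=study,
                                   rois=phantom.ground_truth_rois(spec)))
    return records


def scaled_denoising_experiment(seed: int = 1, n_studies: int = 32,
                                image_size: int = 64, family: str = "udncnn",
                                epochs: int = 200, batch_size: int = 16,
                                learning_rate: float = 1e-3,
                                ) -> Dict[str, float]:
    """Train one denoiser at desk scale and score it on the test split.

    Returns mean kidney SNR (left/right averaged) and MS-SSIM for both the
    un-denoised 50% images and the denoised ones, plus the implied percent
    gains relative to the noisy baseline.
    """
    records = make_cohort(n_studies, image_size, seed)
    pairs, _ = dose.build_dataset(records)
    assignment = dose.split_dataset(pairs, seed=seed,
                                    group_ids=[p.study_id for p in pairs])
    by_split = {name: [p for p, s in zip(pairs, assignment) if s == name]
                for name in ("train", "val", "test")}

    net_config = NetworkConfig(family=family, seed=seed)
    model = build_model(net_config)
    discriminator = build_discriminator(net_config) if family == "attngan" else None
    config = TrainingConfig(batch_size=batch_size, learning_rate=learning_rate,
                            optimizer="adam", epochs=epochs, seed=seed)
    model, history = train(model, by_split["train"], by_split["val"], config,
                           target_size=image_size, discriminator=discriminator)

    xs, ys = _stack(by_split["test"], image_size)
    rois = [p.rois for p in by_split["test"]]
    noisy = evaluate_images(xs, ys, rois)
    denoised = evaluate_images(denoise(model, xs), ys, rois)

    def kidney_snr(frame):
        return float((frame.snr_left.mean() + frame.snr_right.mean()) / 2.0)

    result = {
        "n_test_images": len(xs),
        "snr_noisy": kidney_snr(noisy),
        "snr_denoised": kidney_snr(denoised),
        "ms_ssim_noisy": float(noisy.ms_ssim.mean()),
        "ms_ssim_denoised": float(denoised.ms_ssim.mean()),
        "final_val_mse": history.validation[-1],
    }
    result["snr_gain_percent"] = 100.0 * (
        result["snr_denoised"] - result["snr_noisy"]) / result["snr_noisy"]
    result["ms_ssim_change"] = (result["ms_ssim_denoised"]
                                - result["ms_ssim_noisy"])
    return result
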