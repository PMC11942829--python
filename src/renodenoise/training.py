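"""Training and model selection.

Models minimise the mean-squared error between the denoised 50%-count image
and the 100%-count reference.  The AttnGAN additionally plays the usual
adversarial game: the generator loss is MSE plus a small adversarial term
(``lambda_adv`` defaults to 0.01 so the pixel loss stays dominant) while a
patch discriminator is updated in alternation.

Selection follows the published grid (batch size in {4, 16, 32}, learning
rate in {1e-3, 1e-4, 1e-5}, Adam or SGD) scored by the mean relative error
of the image-quality metrics on held-out images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .dose import PairedSample, preprocess
from .models import NetworkConfig, build_discriminator, build_model, denoise
from .nn import functional as F
from .nn.autograd import Tensor

__all__ = [
    "TrainingConfig", "LossHistory", "TrainingDivergedError",
    "mse_loss", "relative_error", "train", "hyperparameter_search",
    "TABLE_GRID",
]

_BATCH_GRID = (4, 16, 32)
_LR_GRID = (1e-3, 1e-4, 1e-5)

#: The published tuning grid: five Adam runs over the batch/learning-rate
#: crosses plus an SGD comparison at the favoured setting.
TABLE_GRID: Tuple["TrainingConfig", ...]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss turns non-finite during training."""


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    epochs: int = 1000
    seed: int = 0
    loss: str = "mse"
    lambda_adv: float = 0.01
    allow_off_grid: bool = False

    def __post_init__(self):
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if self.loss != "mse":
            raise ValueError("only the MSE loss is supported")
        if not self.allow_off_grid:
            if self.batch_size not in _BATCH_GRID:
                raise ValueError(f"batch_size restricted to {_BATCH_GRID} "
                                 "(set allow_off_grid=True to override)")
            if not any(np.isclose(self.learning_rate, lr) for lr in _LR_GRID):
                raise ValueError(f"learning_rate restricted to {_LR_GRID} "
                                 "(set allow_off_grid=True to override)")


TABLE_GRID = (
    TrainingConfig(batch_size=32, learning_rate=1e-4),
    TrainingConfig(batch_size=32, learning_rate=1e-3),
    TrainingConfig(batch_size=32, learning_rate=1e-5),
    TrainingConfig(batch_size=16, learning_rate=1e-3),
    TrainingConfig(batch_size=4, learning_rate=1e-3),
    TrainingConfig(batch_size=16, learning_rate=1e-3, optimizer="sgd"),
)


@dataclass
class LossHistory:
    """Per-epoch train/validation MSE; entry 0 is the pre-training loss."""
    train: List[float] = field(default_factory=list)
    validation: List[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train)


def mse_loss(prediction: np.ndarray, target: np.ndarray) -> float:
    """Mean squared pixel difference over a batch."""
    prediction = np.asarray(prediction, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prediction.shape != target.shape:
        raise ValueError(f"shape mismatch: {prediction.shape} vs {target.shape}")
    return float(np.mean((prediction - target) ** 2))


def relative_error(candidate: np.ndarray, reference: np.ndarray) -> float:
    """Mean pixel-wise |candidate - reference| / max(candidate, reference), in %.

    Pixels where both values are zero contribute zero.  A fully degenerate
    pair (both images identically zero) returns 0 with a warning.
    """
    candidate = np.asarray(candidate, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if candidate.shape != reference.shape:
        raise ValueError(f"shape mismatch: {candidate.shape} vs {reference.shape}")
    denom = np.maximum(candidate, reference)
    if not denom.any():
        warnings.warn("relative_error of two all-zero images is defined as 0")
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.abs(candidate - reference) / denom
    ratio[denom == 0] = 0.0
    return float(ratio.mean() * 100.0)


def _stack(pairs: Sequence[PairedSample], target_size: int) -> Tuple[np.ndarray, np.ndarray]:
    xs = np.stack([preprocess(p.input_image, target_size) for p in pairs])
    ys = np.stack([preprocess(p.reference_image, target_size) for p in pairs])
    return xs, ys


def _epoch_loss(model: nn.Module, xs: np.ndarray, ys: np.ndarray,
                batch_size: int) -> float:
    model.eval()
    total, n = 0.0, 0
    for start in range(0, len(xs), batch_size):
        xb = xs[start:start + batch_size]
        yb = ys[start:start + batch_size]
        pred = model(Tensor(xb[..., None])).numpy()
        total += np.sum((pred[..., 0].astype(np.float64) - yb) ** 2)
        n += yb.size
    return total / n


def _make_optimizer(params, config: TrainingConfig):
    if config.optimizer == "adam":
        return nn.Adam(params, lr=config.learning_rate)
    return nn.SGD(params, lr=config.learning_rate, momentum=0.9)


def train(model: nn.Module, train_pairs: Sequence[PairedSample],
          val_pairs: Sequence[PairedSample], config: TrainingConfig,
          target_size: int = 128, discriminator: Optional[nn.Module] = None,
          log=None) -> Tuple[nn.Module, LossHistory]:
    """Train a denoiser; returns the model and its loss history.

    For the adversarial family pass a ``discriminator``; generator and
    discriminator then update in alternation each batch.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("need non-empty train and validation splits")
    xs, ys = _stack(train_pairs, target_size)
    xv, yv = _stack(val_pairs, target_size)

    history = LossHistory()
    history.train.append(_epoch_loss(model, xs, ys, config.batch_size))
    history.validation.append(_epoch_loss(model, xv, yv, config.batch_size))

    opt = _make_optimizer(model.parameters(), config)
    d_opt = _make_optimizer(discriminator.parameters(), config) \
        if discriminator is not None else None
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7EA1]))

    for epoch in range(1, config.epochs + 1):
        model.train()
        order = rng.permutation(len(xs))
        epoch_total, epoch_n = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            xb = Tensor(xs[sel][..., None])
            yb = ys[sel][..., None]

            if discriminator is not None:
                # discriminator step on detached generator output
                discriminator.train()
                fake = model(xb).detach()
                d_opt.zero_grad()
                d_loss = (F.bce_with_logits(discriminator(Tensor(yb)),
                                            np.ones(1, dtype=np.float32))
                          + F.bce_with_logits(discriminator(fake),
                                              np.zeros(1, dtype=np.float32)))
                d_loss.backward()
                d_opt.step()

            opt.zero_grad()
            pred = model(xb)
            loss = F.mse(pred, yb)
            batch_mse = loss.item()
            if discriminator is not None:
                discriminator.eval()
                adv = F.bce_with_logits(discriminator(pred),
                                        np.ones(1, dtype=np.float32))
                loss = loss + config.lambda_adv * adv
            if not np.isfinite(loss.item()):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} "
                    f"(lr={config.learning_rate}, batch={config.batch_size})")
            loss.backward()
            opt.step()
            epoch_total += batch_mse * len(sel)
            epoch_n += len(sel)

        history.train.append(epoch_total / epoch_n)
        history.validation.append(_epoch_loss(model, xv, yv, config.batch_size))
        if log is not None:
            log(epoch, history.train[-1], history.validation[-1])
    return model, history


def _score_config(model: nn.Module, test_pairs: Sequence[PairedSample],
                  target_size: int) -> float:
    """Mean relative error (%) of the metric values (SNR left/right,
    MS-SSIM) of the denoised images against the 100% reference metrics."""
    from .metrics import evaluate_images

    xs, ys = _stack(test_pairs, target_size)
    preds = denoise(model, xs)
    rois = [p.rois for p in test_pairs]
    denoised_metrics = evaluate_images(preds, ys, rois)
    reference_metrics = evaluate_images(ys, ys, rois)
    errors = []
    for column in ("snr_left", "snr_right", "ms_ssim"):
        a = denoised_metrics[column].to_numpy()
        b = reference_metrics[column].to_numpy()
        errors.append(relative_error(a, b))
    return float(np.mean(errors))


def hyperparameter_search(family: str, train_pairs, val_pairs, test_pairs,
                          grid: Sequence[TrainingConfig] = TABLE_GRID,
                          network: Optional[NetworkConfig] = None,
                          target_size: int = 128,
                          ) -> List[Tuple[TrainingConfig, float]]:
    """Train every grid config and rank by metric relative error (ascending).

    Scoring uses the test split, mirroring the use of the held-out patients
    for the published relative-error selection; pass the validation pairs as
    ``test_pairs`` to select on validation instead.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    network = network or NetworkConfig(family=family)
    results = []
    for config in grid:
        model = build_model(network)
        discriminator = build_discriminator(network) if family == "attngan" else None
        try:
            model, _ = train(model, train_pairs, val_pairs, config,
                             target_size=target_size, discriminator=discriminator)
            score = _score_config(model, test_pairs, target_size)
        except (TrainingDivergedError, ValueError):
            # a run that diverges (or degenerates to an unscorable constant
            # image) ranks strictly behind every finished run
            score = float("inf")
        results.append((config, score))
    results.sort(key=lambda item: item[1])
    return results
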