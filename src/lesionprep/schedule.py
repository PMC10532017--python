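"""Training-configuration arithmetic and seeded augmentation.

Nothing here builds or runs a detector.  The module computes the bookkeeping
numbers a detector configuration needs — epoch count from step count and
batch size, the cosine learning-rate decay curve, the uniform
weight-initialization limit — and applies the stochastic augmentation set
(flips, 90-degree rotation, brightness/contrast jitter) to an image and its
boxes so the geometry can be verified without a training framework.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import Box2D

__all__ = [
    "ScheduleParams",
    "AugmentationSpec",
    "epochs",
    "cosine_lr",
    "init_limit",
    "apply_augmentation",
    "schedule_summary",
]


@dataclass(frozen=True)
class ScheduleParams:
    total_steps: int
    batch_size: int
    train_set_size: int
    base_lr: float = 0.05
    n_gpus: int = 0  # 0 = unspecified

    def __post_init__(self) -> None:
        if min(self.total_steps, self.batch_size, self.train_set_size) <= 0:
            raise ValueError("total_steps, batch_size and train_set_size must be > 0")
        if self.base_lr <= 0:
            raise ValueError(f"base_lr must be > 0, got {self.base_lr}")
        if self.n_gpus and self.batch_size % self.n_gpus:
            raise ValueError(
                f"batch_size {self.batch_size} not divisible by {self.n_gpus} GPUs"
            )


@dataclass(frozen=True)
class AugmentationSpec:
    """Stochastic augmentation set: each geometric op fires independently."""

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_rot90: float = 0.5
    max_brightness_delta: float = 0.05
    contrast_range: tuple[float, float] = (0.5, 0.95)

    def __post_init__(self) -> None:
        for p in (self.p_hflip, self.p_vflip, self.p_rot90):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        lo, hi = self.contrast_range
        if lo > hi:
            raise ValueError(f"contrast_range {self.contrast_range} not ordered")


def epochs(params: ScheduleParams) -> float:
    """Epochs of training implied by a step budget.

    One step consumes one batch, so ``total_steps * batch_size`` images are
    seen in total; dividing by the train-set size gives passes through the
    data.  E.g. 200,000 steps at batch 32 over 39,592 images is 161.65
    epochs, conventionally reported as 162.
    """
    return params.total_steps * params.batch_size / params.train_set_size


def cosine_lr(step: int, total_steps: int, base_lr: float = 0.05) -> float:
    """Cosine learning-rate decay without warmup.

    ``base_lr * (1 + cos(pi * step / total_steps)) / 2`` — starts at
    ``base_lr``, reaches exactly 0 at the final step.
    """
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * step / total_steps))


def init_limit(n: int) -> float:
    """Bound of the uniform weight initialization: ``sqrt(3 / fan_in)``.

    Weights are drawn uniformly in (-limit, +limit); this scaling keeps the
    variance of a unit's pre-activation at 1/fan_in.
    """
    if n < 1:
        raise ValueError(f"fan-in must be >= 1, got {n}")
    return math.sqrt(3.0 / n)


def apply_augmentation(
    image: np.ndarray,
    boxes: list[Box2D],
    spec: AugmentationSpec | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[Box2D]]:
    """Apply one random draw of the augmentation set to an image and boxes.

    Geometric operations (horizontal/vertical flip, one 90-degree CCW
    rotation) transform the boxes consistently; photometric jitter
    (brightness shift, contrast scaling about the mean) leaves them
    untouched.  Deterministic for a fixed seed.  The image must be square —
    rot90 would not preserve box validity otherwise.
    """
    spec = spec or AugmentationSpec()
    if image.shape[0] != image.shape[1]:
        raise ValueError(f"image must be square, got {image.shape}")
    size = image.shape[0]
    rng = np.random.default_rng(seed)
    img = image.astype(np.float64, copy=True)
    out = list(boxes)

    if rng.random() < spec.p_hflip:
        img = img[:, ::-1]
        out = [
            Box2D(b.row_min, size - b.col_max, b.row_max, size - b.col_min)
            for b in out
        ]
    if rng.random() < spec.p_vflip:
        img = img[::-1, :]
        out = [
            Box2D(size - b.row_max, b.col_min, size - b.row_min, b.col_max)
            for b in out
        ]
    if rng.random() < spec.p_rot90:
        # numpy rot90 (CCW): new_row = size - old_col_max, new_col = old_row
        img = np.rot90(img)
        out = [
            Box2D(size - b.col_max, b.row_min, size - b.col_min, b.row_max)
            for b in out
        ]
    delta = rng.uniform(-spec.max_brightness_delta, spec.max_brightness_delta)
    img = img + delta
    factor = rng.uniform(*spec.contrast_range)
    img = img.mean() + factor * (img - img.mean())
    return img, out


def schedule_summary(
    params: ScheduleParams,
    aug: AugmentationSpec | None = None,
    n_lr_samples: int = 11,
) -> dict:
    """Plain-dict training-config summary (YAML-serializable) for audit."""
    aug = aug or AugmentationSpec()
    lr_table = [
        {
            "step": s,
            "lr": round(cosine_lr(s, params.total_steps, params.base_lr), 6),
        }
        for s in np.linspace(0, params.total_steps, n_lr_samples, dtype=int).tolist()
    ]
    return {
        "total_steps": params.total_steps,
        "batch_size": params.batch_size,
        "train_set_size": params.train_set_size,
        "epochs": round(epochs(params), 2),
        "epochs_rounded": round(epochs(params)),
        "base_lr": params.base_lr,
        "lr_schedule": lr_table,
        "augmentation": {
            "p_hflip": aug.p_hflip,
            "p_vflip": aug.p_vflip,
            "p_rot90": aug.p_rot90,
            "max_brightness_delta": aug.max_brightness_delta,
            "contrast_range": list(aug.contrast_range),
        },
    }
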