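"""Training loop: soft-Dice loss, Adam updates, flip augmentation, seeding."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..preprocess import ChannelStack
from ..volume import Volume3D
from . import autograd as ag
from .model import DualPathwayNet, NetworkConfig, build_model
from .sampling import augment_flips, prepare_case, sample_patches

__all__ = ["dice_loss", "Adam", "train_fold", "save_loss_log"]


def dice_loss(pred, target, smooth: float = 1.0):
    """Soft Dice loss ``1 − (2·Σ p·t + s)/(Σ p + Σ t + s)``.

    Accepts a plain array (returns a float) or an autograd tensor (returns a
    differentiable scalar node).
    """
    if isinstance(pred, ag.Tensor):
        return ag.soft_dice_loss(pred, target, smooth)
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"dice shape mismatch: pred {pred.shape}, target {target.shape}")
    inter = float((pred * target).sum())
    denom = float(pred.sum() + target.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


class Adam:
    """Adam with optional decoupled weight decay."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.wd:
                p.data -= self.lr * self.wd * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _stack_batch(pairs):
    x_hi = np.stack([p.image_segment for p in pairs])
    x_lo = np.stack([p.context_segment for p in pairs])
    y = np.stack([p.label_segment for p in pairs]).astype(np.float32)
    return x_hi, x_lo, y


def train_fold(
    cases: list[tuple[ChannelStack, Volume3D]],
    config: NetworkConfig,
    model: DualPathwayNet | None = None,
) -> DualPathwayNet:
    """Train one sub-model on the given cases.

    Runs ``config.epochs`` epochs of ``config.batches_per_epoch`` batches of
    sampled, flip-augmented segment pairs with batch normalization active;
    the per-epoch mean loss is recorded in ``model.loss_log``. Fully seeded:
    identical config and cases give an identical final model.
    """
    if not cases:
        raise ValueError("train_fold needs at least one case")
    if model is None:
        model = build_model(config)
    opt = Adam(
        model.parameters(),
        lr=config.learning_rate,
        beta1=config.adam_beta1,
        beta2=config.adam_beta2,
        weight_decay=config.weight_decay,
    )
    rng = np.random.default_rng(config.seed)
    preps = [
        prepare_case(stack.as_array(), config.out_window, config.downsample_factor)
        for stack, _ in cases
    ]
    for epoch in range(config.epochs):
        losses = []
        for _ in range(config.batches_per_epoch):
            ci = int(rng.integers(len(cases)))
            stack, labels = cases[ci]
            pairs = sample_patches(
                stack,
                labels,
                config,
                config.batch_size,
                seed=int(rng.integers(2**31 - 1)),
                prep=preps[ci],
            )
            pairs = [augment_flips(p, int(rng.integers(2**31 - 1))) for p in pairs]
            x_hi, x_lo, y = _stack_batch(pairs)
            model.zero_grad()
            logits = model.forward(x_hi, x_lo, training=True)
            prob = ag.foreground_prob(logits)
            loss = ag.soft_dice_loss(prob, y, config.dice_smooth)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, case {ci} "
                    f"(lr={config.learning_rate}, batch={config.batch_size})"
                )
            loss.backward()
            opt.step()
            losses.append(value)
        model.loss_log.append(float(np.mean(losses)))
    return model


def save_loss_log(model: DualPathwayNet, path: str | Path) -> None:
    """Write the training trajectory as CSV (epoch, mean_loss)."""
    pd.DataFrame(
        {"epoch": np.arange(1, len(model.loss_log) + 1), "mean_loss": model.loss_log}
    ).to_csv(path, index=False)
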