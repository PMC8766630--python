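"""Training loop: Adam with batch size 1 and a fixed learning rate.

Convergence is declared when the residual — the absolute change of the
window-5 smoothed training cost between successive iterations — stays
below 1e-5 for 30 consecutive iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SliceDataset
from .losses import (
    LossConfig,
    balanced_focal_loss,
    bfl_grad_logits,
    cbce_grad_logits,
    class_balanced_cross_entropy,
)
from .network import CNNSpec, SegmentationCNN

RESIDUAL_TOL = 1e-5
RESIDUAL_STREAK = 30
SMOOTH_WINDOW = 5


@dataclass
class TrainingHistory:
    cost: list = field(default_factory=list)
    converged: bool = False
    convergence_iteration: int | None = None
    diverged: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.cost)


class Adam:
    """Standard Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, model: SegmentationCNN, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.parameters()]
        self.v = [np.zeros_like(p) for p, _ in model.parameters()]

    def step(self, model: SegmentationCNN) -> None:
        self.t += 1
        for k, (p, g) in enumerate(model.parameters()):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _loss_and_grad(model, image, label, cfg):
    if cfg.mode == "cbce":
        if label.shape[0] != 2:
            raise ValueError("cbce expects a 2-class one-hot stack")
        y = label[1]
        P = model.forward(image)
        cost = class_balanced_cross_entropy(P, y, eps=cfg.eps)
        dz = cbce_grad_logits(P, y, eps=cfg.eps)[None]
    else:
        P = model.forward(image)
        cost = balanced_focal_loss(P, label, cfg)
        dz = bfl_grad_logits(P, label, cfg)
    return cost, dz


def train(
    model: SegmentationCNN,
    ds: SliceDataset,
    cfg: LossConfig,
    spec: CNNSpec | None = None,
    rng_seed: int = 0,
    max_iterations: int = 2000,
) -> tuple[SegmentationCNN, TrainingHistory]:
    """Train in-place with Adam (batch size 1) and record the history.

    Iterations visit the dataset in a seeded random order, one slice per
    iteration.  Training stops at convergence (see module docstring), on
    divergence (non-finite cost), or after ``max_iterations``.
    """
    spec = spec or model.spec
    n_out = 1 if spec.n_classes == 2 else spec.n_classes
    if ds.n_classes != spec.n_classes:
        raise ValueError("dataset and model class counts disagree")
    rng = np.random.default_rng(rng_seed)
    opt = Adam(model, lr=spec.learning_rate)
    hist = TrainingHistory()
    smoothed_prev = None
    streak = 0
    order = []
    for it in range(max_iterations):
        if not order:
            order = list(rng.permutation(ds.N))
        idx = order.pop()
        cost, dz = _loss_and_grad(model, ds.images[idx], ds.labels[idx], cfg)
        if not np.isfinite(cost):
            hist.diverged = True
            break
        hist.cost.append(cost)
        model.zero_grads()
        model.backward(dz.reshape(n_out, spec.roi_size, spec.roi_size))
        if spec.learning_rate > 0:
            opt.step(model)
        window = hist.cost[-SMOOTH_WINDOW:]
        smoothed = float(np.mean(window))
        if smoothed_prev is not None:
            streak = streak + 1 if abs(smoothed - smoothed_prev) < RESIDUAL_TOL else 0
        smoothed_prev = smoothed
        if streak >= RESIDUAL_STREAK:
            hist.converged = True
            hist.convergence_iteration = it + 1
            break
    return model, hist
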