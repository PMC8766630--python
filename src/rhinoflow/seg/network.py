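"""Segmentation CNN: multi-scale conv/pool trunk with upsampled branches.

The network repeats ``3x3 conv -> ReLU -> 2x2 max-pool -> specialized 3x3
conv -> ReLU`` blocks.  Each block's specialized-conv output is resized
back to the full region-of-interest (ROI) size by bilinear interpolation
(no corner alignment); the resized branches are concatenated along the
depth dimension into a feature volume.  A per-class 1x1 linear combination
of the feature volume yields the prediction stack: a single sigmoid
probability map in binary mode, or a softmax over the depth dimension in
multi-class mode.  All weights are drawn from a truncated normal
distribution.

Because every layer is convolutional, the parameter count is independent
of the ROI size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BilinearResize, Conv1x1, Conv3x3, MaxPool2x2, ReLU


@dataclass(frozen=True)
class CNNSpec:
    """Hyperparameters of the segmentation CNN.

    The admissible ranges reflect the intended small-network regime:
    1..4 conv layers with 5..20 filters each, fixed 3x3 kernels, Adam with
    a fixed learning rate of 0.01 and batch size 1.
    """

    n_conv_layers: int = 2
    filters_per_layer: int = 8
    n_classes: int = 9
    roi_size: int = 400
    learning_rate: float = 0.01
    batch_size: int = 1
    kernel: int = 3
    init: str = "truncated-normal"

    def __post_init__(self) -> None:
        if not 1 <= self.n_conv_layers <= 4:
            raise ValueError("n_conv_layers must be in 1..4")
        if not 5 <= self.filters_per_layer <= 20:
            raise ValueError("filters_per_layer must be in 5..20")
        if self.n_classes not in (2, 9):
            raise ValueError("n_classes must be 2 or 9")
        if self.kernel != 3:
            raise ValueError("kernel is fixed at 3x3")
        if self.batch_size != 1:
            raise ValueError("batch size is fixed at 1")


class SegmentationCNN:
    """Forward/backward network for one (H, W) image (batch size 1)."""

    def __init__(self, spec: CNNSpec, rng_seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(rng_seed)
        F = spec.filters_per_layer
        self.blocks = []
        c_in = 1
        for _ in range(spec.n_conv_layers):
            block = {
                "conv": Conv3x3(c_in, F, rng),
                "relu1": ReLU(),
                "pool": MaxPool2x2(),
                "spec": Conv3x3(F, F, rng),
                "relu2": ReLU(),
                "up": BilinearResize((spec.roi_size, spec.roi_size)),
            }
            self.blocks.append(block)
            c_in = F
        n_out = 1 if spec.n_classes == 2 else spec.n_classes
        self.head = Conv1x1(spec.n_conv_layers * F, n_out, rng)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        layers = [b["conv"] for b in self.blocks] + [b["spec"] for b in self.blocks]
        layers.append(self.head)
        for lay in layers:
            yield from zip(lay.params, lay.grads)

    def zero_grads(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0

    # -- passes -------------------------------------------------------------
    def forward_logits(self, image: np.ndarray) -> np.ndarray:
        """(H, W) image -> logits (1, H, W) binary or (S, H, W) multi-class."""
        if image.shape != (self.spec.roi_size, self.spec.roi_size):
            raise ValueError(
                f"image shape {image.shape} does not match ROI "
                f"{self.spec.roi_size} px"
            )
        x = image[None].astype(float)
        branches = []
        for b in self.blocks:
            x = b["relu1"].forward(b["conv"].forward(x))
            p = b["pool"].forward(x)
            s = b["relu2"].forward(b["spec"].forward(p))
            branches.append(b["up"].forward(s))
            x = p
        feat = np.concatenate(branches, axis=0)
        self._split = [br.shape[0] for br in branches]
        return self.head.forward(feat)

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Class probabilities: (H, W) sigmoid map or (S, H, W) softmax."""
        z = self.forward_logits(image)
        if self.spec.n_classes == 2:
            return 1.0 / (1.0 + np.exp(-z[0]))
        z = z - z.max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        dfeat = self.head.backward(dlogits)
        pieces = np.split(dfeat, np.cumsum(self._split)[:-1], axis=0)
        dx_next = None
        for b, dbr in zip(reversed(self.blocks), reversed(pieces)):
            ds = b["up"].backward(dbr)
            dp = b["spec"].backward(b["relu2"].backward(ds))
            if dx_next is not None:
                dp = dp + dx_next
            dt = b["relu1"].backward(b["pool"].backward(dp))
            dx_next = b["conv"].backward(dt)

    def parameter_count(self) -> int:
        return sum(p.size for p, _ in self.parameters())


def build_cnn(spec: CNNSpec, rng_seed: int = 0) -> SegmentationCNN:
    """Construct a segmentation CNN from its hyperparameter spec."""
    return SegmentationCNN(spec, rng_seed=rng_seed)
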