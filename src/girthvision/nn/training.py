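"""Training utilities for the tiny-scale segmentation smoke tests: softmax
cross-entropy, Adam, and a bounded-step training loop."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .metrics import segmentation_metrics
from .modules import Module

__all__ = ["softmax_cross_entropy", "Adam", "train_segmenter"]


def softmax_cross_entropy(scores: Tensor, targets: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy of (N, K, H, W) scores vs int targets."""
    x = scores.data
    t = np.asarray(targets, dtype=np.int64)
    xs = x - x.max(axis=1, keepdims=True)
    e = np.exp(xs)
    p = e / e.sum(axis=1, keepdims=True)
    n, k = x.shape[0], x.shape[1]
    onehot = np.moveaxis(np.eye(k, dtype=np.float32)[t], -1, 1)
    npix = t.size
    loss = -np.sum(onehot * np.log(np.maximum(p, 1e-12))) / npix

    def backward(g):
        if scores.requires_grad:
            scores._accum((p - onehot) * (np.float32(g) / npix))

    return Tensor._make(np.float32(loss), (scores,), backward)


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def train_segmenter(
    model: Module,
    fixtures: list,
    steps: int = 120,
    batch_size: int = 8,
    lr: float = 3e-3,
    seed: int = 0,
) -> list:
    """Train a segmentation net on (image, mask) fixtures; returns the loss
    trace.  Bounded number of Adam steps with random mini-batches."""
    rng = np.random.default_rng(seed)
    images = np.stack([f[0] for f in fixtures])
    masks = np.stack([f[1] for f in fixtures])
    opt = Adam(model.parameters(), lr=lr)
    losses = []
    model.train()
    for _ in range(steps):
        idx = rng.choice(len(images), size=min(batch_size, len(images)), replace=False)
        x = Tensor(images[idx])
        scores = model(x)
        loss = softmax_cross_entropy(scores, masks[idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    calibrate_batchnorm(model, images)
    return losses


def calibrate_batchnorm(model, images: np.ndarray) -> None:
    """Refresh BatchNorm running statistics with frozen weights.

    During optimisation the running estimates lag the rapidly changing
    activations; one gradient-free forward pass over the whole calibration
    set with momentum 1 replaces them by the exact dataset statistics, so
    inference-mode predictions match training behaviour.
    """
    from .autograd import no_grad
    from .modules import BatchNorm2d

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0
    model.train()
    with no_grad():
        model(Tensor(images))
    for bn, mom in zip(bns, saved):
        bn.momentum = mom
    model.eval()


def evaluate_segmenter(model, fixtures, num_classes: int = 2):
    """Mean (PA, MPA, MIOU) of a model over a fixture list."""
    images = np.stack([f[0] for f in fixtures])
    masks = np.stack([f[1] for f in fixtures])
    pred = model.predict(images)
    return segmentation_metrics(pred, masks, num_classes)
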