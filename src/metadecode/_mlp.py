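"""Numpy internals for the ReLU MLP: forward pass, per-sample gradients, Adam.

Parameters are a list of (W, b) tuples. Hidden layers use ReLU; the output
layer is linear and feeds a softmax cross-entropy loss. Backprop is written
batched so that *per-sample* gradients (one gradient tensor per row of the
batch) come out of a single pass — the meta-gradient needs per-sample
training gradients, not just their mean.
"""

from __future__ import annotations

import numpy as np

Params = list[tuple[np.ndarray, np.ndarray]]


def init_params(
    layer_sizes: tuple[int, ...], rng: np.random.Generator
) -> Params:
    """Uniform fan-in initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    params: Params = []
    for d_in, d_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        bound = 1.0 / np.sqrt(d_in)
        W = rng.uniform(-bound, bound, size=(d_in, d_out))
        b = rng.uniform(-bound, bound, size=d_out)
        params.append((W, b))
    return params


def forward(params: Params, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Return (logits, activations) with activations[0] = x (pre-ReLU cached
    implicitly: hidden activations are post-ReLU)."""
    acts = [x]
    h = x
    last = len(params) - 1
    for k, (W, b) in enumerate(params):
        h = h @ W + b
        if k != last:
            h = np.maximum(h, 0.0)
        acts.append(h)
    return h, acts


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def per_sample_ce(logits: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cross entropy of each row, numerically stable."""
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    return lse - z[np.arange(len(y)), y]


def _backprop_deltas(
    params: Params, acts: list[np.ndarray], delta_out: np.ndarray
) -> list[np.ndarray]:
    """Propagate output-layer deltas back through the ReLU stack.

    Returns deltas per layer (same order as params); ``delta_out`` has one
    row per sample and is *not* averaged, so the result supports both
    per-sample and weighted-mean gradients.
    """
    deltas = [None] * len(params)
    delta = delta_out
    for k in range(len(params) - 1, -1, -1):
        deltas[k] = delta
        if k > 0:
            delta = (delta @ params[k][0].T) * (acts[k] > 0)
    return deltas


def per_sample_grads(
    params: Params, x: np.ndarray, y: np.ndarray
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Gradient of each sample's own cross entropy w.r.t. every parameter.

    Returns (grads, losses): grads[k] = (gW, gb) with leading batch axis
    (gW shape (n, d_in, d_out), gb shape (n, d_out)).
    """
    logits, acts = forward(params, x)
    losses = per_sample_ce(logits, y)
    delta = softmax(logits)
    delta[np.arange(len(y)), y] -= 1.0
    deltas = _backprop_deltas(params, acts, delta)
    grads = [
        (np.einsum("ni,nj->nij", acts[k], deltas[k]), deltas[k])
        for k in range(len(params))
    ]
    return grads, losses


def mean_grad(
    params: Params, x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[Params, float]:
    """Gradient of the (weighted) mean/sum cross entropy.

    With ``weights`` None the plain mean over the batch is used; otherwise
    the loss is ``sum_i weights_i * CE_i`` (weights are used as given, no
    renormalization).
    """
    logits, acts = forward(params, x)
    losses = per_sample_ce(logits, y)
    delta = softmax(logits)
    delta[np.arange(len(y)), y] -= 1.0
    if weights is None:
        delta = delta / len(y)
        loss = float(losses.mean())
    else:
        delta = delta * weights[:, None]
        loss = float(weights @ losses)
    deltas = _backprop_deltas(params, acts, delta)
    grads = [
        (acts[k].T @ deltas[k], deltas[k].sum(axis=0)) for k in range(len(params))
    ]
    return grads, loss


def grad_inner_products(
    sample_grads: list[tuple[np.ndarray, np.ndarray]], ref_grad: Params
) -> np.ndarray:
    """<g_i, g_ref> for every sample i, summed over all parameter tensors."""
    n = sample_grads[0][1].shape[0]
    out = np.zeros(n)
    for (gW, gb), (rW, rb) in zip(sample_grads, ref_grad):
        out += gW.reshape(n, -1) @ rW.ravel()
        out += gb @ rb
    return out


def weighted_combination(
    sample_grads: list[tuple[np.ndarray, np.ndarray]], weights: np.ndarray
) -> Params:
    """sum_i weights_i * g_i, per parameter tensor."""
    return [
        (np.einsum("n,nij->ij", weights, gW), weights @ gb)
        for gW, gb in sample_grads
    ]


def sgd_step(params: Params, grads: Params, lr: float) -> Params:
    """One explicit (non-in-place) gradient-descent step; used by oracles."""
    return [(W - lr * gW, b - lr * gb) for (W, b), (gW, gb) in zip(params, grads)]


class Adam:
    """Standard Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        params: Params,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        self.v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]

    def step(self, params: Params, grads: Params) -> Params:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        new_params: Params = []
        for k, ((W, b), (gW, gb)) in enumerate(zip(params, grads)):
            mW = b1 * self.m[k][0] + (1 - b1) * gW
            mb = b1 * self.m[k][1] + (1 - b1) * gb
            vW = b2 * self.v[k][0] + (1 - b2) * gW**2
            vb = b2 * self.v[k][1] + (1 - b2) * gb**2
            self.m[k] = (mW, mb)
            self.v[k] = (vW, vb)
            W = W - self.lr * (mW / c1) / (np.sqrt(vW / c2) + self.eps)
            b = b - self.lr * (mb / c1) / (np.sqrt(vb / c2) + self.eps)
            new_params.append((W, b))
        return new_params
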