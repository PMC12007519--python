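"""Encoder-decoder CNNs for OOV detection and prediction.

Both tasks share one fully-convolutional architecture operating on complex
time-domain signals presented as two real channels: contracting (strided)
convolutional encoder blocks, expanding (upsample + convolution) decoder
blocks with residual connections from the encoder, batch normalization and
leaky-ReLU activations, he-normal initialization, and a task head — sigmoid
for point-wise detection masks, linear for echo (10x-amplified) regression.

The implementation is pure NumPy with hand-written forward/backward passes
and an Adam optimizer, so training is CPU-only and fully deterministic given
a seed.  It is intended for smoke-scale experiments (hundreds of steps on a
few thousand examples), not full-scale training.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "Network",
    "build_network",
    "dice_loss",
    "weighted_mse_loss",
    "make_training_tensors",
    "train",
    "TrainResult",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    ``channels`` is the encoder width schedule (the decoder mirrors it);
    each encoder stage after the first halves the time resolution.
    """

    n_points: int = 2048
    channels: tuple = (16, 32, 64)
    kernel: int = 3
    leaky_alpha: float = 0.1
    batch_size: int = 60
    seed: int = 0


# --- layers ----------------------------------------------------------------


class _Conv1d:
    """'Same'-padded 1-D convolution with optional stride (he-normal init)."""

    def __init__(self, cin, cout, kernel, stride, rng):
        scale = np.sqrt(2.0 / (cin * kernel))
        self.w = rng.standard_normal((cout, cin, kernel)) * scale
        self.b = np.zeros(cout)
        self.stride = stride
        self.kernel = kernel
        self._cache = None

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def set_param(self, name, value):
        setattr(self, name, value)

    def forward(self, x, train):
        k, s = self.kernel, self.stride
        pad = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        l_out = (x.shape[2] + 2 * pad - k) // s + 1
        idx = s * np.arange(l_out)[None, :] + np.arange(k)[:, None]
        win = xp[:, :, idx]  # (B, C, K, L_out)
        out = np.einsum("ock,bckl->bol", self.w, win, optimize=True) + self.b[None, :, None]
        self._cache = (win, x.shape[2], l_out)
        return out

    def backward(self, dout):
        win, l_in, l_out = self._cache
        k, s = self.kernel, self.stride
        pad = (k - 1) // 2
        self.dw = np.einsum("bol,bckl->ock", dout, win, optimize=True)
        self.db = dout.sum(axis=(0, 2))
        dxp = np.zeros((dout.shape[0], self.w.shape[1], l_in + 2 * pad))
        pos = s * np.arange(l_out)
        for kk in range(k):
            dxp[:, :, kk + pos] += np.einsum("bol,oc->bcl", dout, self.w[:, :, kk], optimize=True)
        return dxp[:, :, pad : pad + l_in]

    def grads(self):
        return [("w", self.dw), ("b", self.db)]


class _BatchNorm1d:
    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def set_param(self, name, value):
        setattr(self, name, value)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dout):
        xhat, inv, shape = self._cache
        n = shape[0] * shape[2]
        self.dgamma = (dout * xhat).sum(axis=(0, 2))
        self.dbeta = dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / n
        ) * inv[None, :, None]
        return dx

    def grads(self):
        return [("gamma", self.dgamma), ("beta", self.dbeta)]


class _LeakyReLU:
    def __init__(self, alpha):
        self.alpha = alpha

    def params(self):
        return []

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)

    def grads(self):
        return []


class _Upsample2x:
    def params(self):
        return []

    def forward(self, x, train):
        return np.repeat(x, 2, axis=2)

    def backward(self, dout):
        return dout[:, :, ::2] + dout[:, :, 1::2]

    def grads(self):
        return []


def _block(cin, cout, stride, alpha, rng, kernel):
    return [
        _Conv1d(cin, cout, kernel, stride, rng),
        _BatchNorm1d(cout),
        _LeakyReLU(alpha),
    ]


class Network:
    """Fully-convolutional encoder-decoder (see module docstring).

    ``head`` is ``"detection"`` (1 sigmoid channel) or ``"prediction"``
    (2 linear channels: real/imaginary echo).
    """

    def __init__(self, spec: NetworkSpec, head: str):
        if head not in ("detection", "prediction"):
            raise ValueError(f"unknown head {head!r}")
        if spec.n_points % 2 ** (len(spec.channels) - 1):
            raise ValueError(
                f"n_points={spec.n_points} not divisible by the encoder "
                f"downsampling factor {2 ** (len(spec.channels) - 1)}"
            )
        self.spec = spec
        self.head = head
        rng = np.random.default_rng(spec.seed)
        ch = spec.channels
        a, k = spec.leaky_alpha, spec.kernel

        self.enc = [_block(2, ch[0], 1, a, rng, k)]
        for i in range(1, len(ch)):
            self.enc.append(_block(ch[i - 1], ch[i], 2, a, rng, k))
        self.mid = _block(ch[-1], ch[-1], 1, a, rng, k)
        self.dec = []
        for i in range(len(ch) - 1, 0, -1):
            self.dec.append([_Upsample2x()] + _block(ch[i], ch[i - 1], 1, a, rng, k))
        out_channels = 1 if head == "detection" else 2
        self.out = _Conv1d(ch[0], out_channels, k, 1, rng)

    # -- graph traversal ---------------------------------------------------

    def _layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.mid
        for blk in self.dec:
            yield from blk
        yield self.out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self._layers() for _, p in layer.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """``x``: (batch, n_points, 2) real/imaginary input.

        Returns (batch, n_points) detection probabilities or
        (batch, n_points, 2) predicted echo channels.
        """
        h = np.ascontiguousarray(np.moveaxis(np.asarray(x, dtype=float), 2, 1))
        skips = []
        for blk in self.enc:
            for layer in blk:
                h = layer.forward(h, train)
            skips.append(h)
        pre_mid = h
        for layer in self.mid:
            h = layer.forward(h, train)
        h = h + pre_mid  # residual around the bottleneck
        for i, blk in enumerate(self.dec):
            for layer in blk:
                h = layer.forward(h, train)
            h = h + skips[-(i + 2)]  # residual connection from the encoder
        h = self.out.forward(h, train)
        if self.head == "detection":
            self._sig = 1.0 / (1.0 + np.exp(-h[:, 0, :]))
            return self._sig
        return np.moveaxis(h, 1, 2)

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate parameter gradients from the loss gradient ``dout``
        (same shape as the forward output)."""
        if self.head == "detection":
            d = (dout * self._sig * (1.0 - self._sig))[:, None, :]
        else:
            d = np.moveaxis(dout, 2, 1)
        d = self.out.backward(d)
        for i, blk in zip(range(len(self.dec) - 1, -1, -1), reversed(self.dec)):
            # the residual add after this block also feeds the skip source;
            # stash the gradient to add when the encoder stage is reached
            self._skip_grads[i] = d
            for layer in reversed(blk):
                d = layer.backward(d)
        d_mid_out = d
        for layer in reversed(self.mid):
            d = layer.backward(d)
        d = d + d_mid_out  # bottleneck residual
        for si in range(len(self.enc) - 1, -1, -1):
            if si < len(self.enc) - 1:
                d = d + self._skip_grads[len(self.enc) - 2 - si]
            for layer in reversed(self.enc[si]):
                d = layer.backward(d)

    def loss_and_grad(self, x, target, mask=None, weight: float = 10.0):
        """Forward pass, task loss, and backward pass in one call."""
        pred = self.forward(x, train=True)
        self._skip_grads = {}
        if self.head == "detection":
            loss, dpred = dice_loss(pred, target, with_grad=True)
        else:
            loss, dpred = weighted_mse_loss(pred, target, mask, weight, with_grad=True)
        self.backward(dpred)
        return loss, pred

    # -- parameter access ---------------------------------------------------

    def get_state(self):
        return copy.deepcopy(
            [
                {name: p.copy() for name, p in layer.params()}
                | (
                    {"running_mean": layer.running_mean.copy(), "running_var": layer.running_var.copy()}
                    if isinstance(layer, _BatchNorm1d)
                    else {}
                )
                for layer in self._layers()
            ]
        )

    def set_state(self, state):
        for layer, st in zip(self._layers(), state):
            for name, val in st.items():
                setattr(layer, name, val.copy())


def build_network(spec: NetworkSpec, head: str) -> Network:
    """Construct a detection or prediction network from ``spec``."""
    net = Network(spec, head)
    net._skip_grads = {}
    return net


# --- losses ----------------------------------------------------------------


def dice_loss(pred: np.ndarray, truth: np.ndarray, with_grad: bool = False):
    """1 - soft Dice with the +1 denominator guard.

    ``pred`` may be soft probabilities; ``truth`` is binary (or soft).
    Computed globally over the batch.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    inter = float(np.sum(pred * truth))
    denom = float(np.sum(pred) + np.sum(truth) + 1.0)
    loss = 1.0 - 2.0 * inter / denom
    if not with_grad:
        return loss
    grad = -(2.0 * truth * denom - 2.0 * inter) / denom**2
    return loss, grad


def weighted_mse_loss(
    pred: np.ndarray,
    target: np.ndarray,
    mask: np.ndarray | None,
    weight: float = 10.0,
    with_grad: bool = False,
):
    """Mean squared error with per-point weight ``weight`` inside the
    ground-truth mask and 1 outside (weighted mean over all points)."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if mask is None:
        w = np.ones(pred.shape)
    else:
        mask = np.asarray(mask, dtype=float)
        while mask.ndim < pred.ndim:
            mask = mask[..., None]
        w = 1.0 + (weight - 1.0) * np.broadcast_to(mask, pred.shape)
    err = pred - target
    wsum = float(w.sum())
    loss = float(np.sum(w * err**2)) / wsum
    if not with_grad:
        return loss
    return loss, 2.0 * w * err / wsum


# --- training --------------------------------------------------------------


def make_training_tensors(injections, task: str, n_points: int = 2048):
    """Stack :class:`~mrsynth.oov.Injection` records into training arrays.

    Returns ``(x, y)`` with ``x``: (n, n_points, 2) normalized inputs and
    ``y``: detection masks (n, n_points) or 10x-amplified echo targets
    (n, n_points, 2); plus the boolean masks for loss weighting.
    """
    if not injections:
        raise ValueError("no injections supplied")
    x = np.stack(
        [np.stack([inj.input_fid[:n_points].real, inj.input_fid[:n_points].imag], axis=1) for inj in injections]
    )
    masks = np.stack([inj.mask[:n_points] for inj in injections])
    if task == "detection":
        y = masks.astype(float)
    elif task == "prediction":
        y = np.stack(
            [
                np.stack(
                    [inj.target_amplified[:n_points].real, inj.target_amplified[:n_points].imag],
                    axis=1,
                )
                for inj in injections
            ]
        )
    else:
        raise ValueError(f"unknown task {task!r}")
    return x, y, masks


class _Adam:
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, layers):
        self.t += 1
        for li, layer in enumerate(layers):
            for (name, p), (_, g) in zip(layer.params(), layer.grads()):
                key = (li, name)
                m = self.m.get(key, np.zeros_like(p))
                v = self.v.get(key, np.zeros_like(p))
                m = self.b1 * m + (1 - self.b1) * g
                v = self.b2 * v + (1 - self.b2) * g**2
                self.m[key], self.v[key] = m, v
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                layer.set_param(name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


@dataclass
class TrainResult:
    losses: list = field(default_factory=list)  # per-step training loss
    epoch_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    best_state: object = None
    best_val: float = np.inf
    n_checkpoints: int = 0


def train(
    model: Network,
    data,
    lr: float = 3e-4,
    steps: int = 200,
    batch_size: int | None = None,
    eval_every: int = 7200,
    val_data=None,
    seed: int = 0,
    weight: float = 10.0,
) -> TrainResult:
    """Adam training loop with periodic validation checkpoints.

    ``data`` is ``(x, y, masks)`` from :func:`make_training_tensors`.  A
    checkpoint (deep copy of the weights) is kept only when the validation
    loss improves; with no validation data the final weights are the
    checkpoint.  Fully deterministic given ``seed``.
    """
    x, y, masks = data
    if len(x) == 0:
        raise ValueError("empty training set")
    batch_size = batch_size or min(model.spec.batch_size, len(x))
    rng = np.random.default_rng(seed)
    opt = _Adam(lr)
    layers = list(model._layers())
    result = TrainResult()

    def evaluate():
        vx, vy, vmasks = val_data
        pred = model.forward(vx, train=False)
        if model.head == "detection":
            return dice_loss(pred, vy)
        return weighted_mse_loss(pred, vy, vmasks, weight)

    order = rng.permutation(len(x))
    pos = 0
    epoch_accum = []
    decisions = 0
    for step in range(1, steps + 1):
        if pos + batch_size > len(x):
            order = rng.permutation(len(x))
            pos = 0
            result.epoch_losses.append(float(np.mean(epoch_accum)))
            epoch_accum = []
        idx = order[pos : pos + batch_size]
        pos += batch_size
        loss, _ = model.loss_and_grad(
            x[idx], y[idx], mask=masks[idx] if model.head == "prediction" else None, weight=weight
        )
        opt.step(layers)
        result.losses.append(float(loss))
        epoch_accum.append(float(loss))
        if val_data is not None and step % eval_every == 0:
            decisions += 1
            val = evaluate()
            result.val_losses.append(float(val))
            if val < result.best_val:
                result.best_val = float(val)
                result.best_state = model.get_state()
                result.n_checkpoints += 1
    if epoch_accum:
        result.epoch_losses.append(float(np.mean(epoch_accum)))
    if val_data is not None and decisions == 0:
        # eval interval longer than the run: exactly one checkpoint decision
        val = evaluate()
        result.val_losses.append(float(val))
        result.best_val = float(val)
        result.best_state = model.get_state()
        result.n_checkpoints = 1
    if result.best_state is None:
        result.best_state = model.get_state()
    return result
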