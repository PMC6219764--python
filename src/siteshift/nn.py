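"""A small convolutional network with a CAM-compatible linear head.

Pure NumPy, single CPU: three conv/batchnorm/ReLU/max-pool blocks and a
final conv/batchnorm/ReLU layer produce a K-channel g x g feature grid;
global average pooling, a linear bottleneck (n = 15 by default), and a
linear classification head follow. Because both post-pool layers are
linear, the map from pooled features to logits is a single effective
linear read-out, which is what makes exact class activation maps possible
(each grid cell's scores average to the model's own logits).

Convolutions are 3 x 3, stride 1, zero-padded, implemented via im2col and
BLAS matmuls; everything is float32. Batch normalization (batch statistics
in training, running statistics at inference) is what lets a from-scratch
net converge within the few productive epochs the plateau-decay schedule
allows. Optimisation is plain SGD with momentum and weight decay (PyTorch
update convention: v <- mu v + g + wd p; p <- p - lr v).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32
BN_EPS = 1e-5
BN_MOMENTUM = 0.1


def _conv_forward(x: np.ndarray, w: np.ndarray):
    """3x3 same-padding convolution. x: (N,C,H,W), w: (F,C,3,3)."""
    n, c, h, wd = x.shape
    f = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * wd, c * 9)
    out = cols @ w.reshape(f, -1).T
    return np.ascontiguousarray(out.reshape(n, h, wd, f).transpose(0, 3, 1, 2)), cols


def _conv_backward(dy: np.ndarray, cols: np.ndarray, w: np.ndarray, x_shape):
    n, c, h, wd = x_shape
    f = w.shape[0]
    dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * wd, f)
    dw = (dyf.T @ cols).reshape(w.shape)
    dcols = (dyf @ w.reshape(f, -1)).reshape(n, h, wd, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, wd + 2), dtype=dy.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1], dw


def _pool_forward(x: np.ndarray):
    """2x2 max pool, stride 2."""
    n, c, h, wd = x.shape
    xr = x.reshape(n, c, h // 2, 2, wd // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, wd // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dy: np.ndarray, idx: np.ndarray, x_shape):
    n, c, h, wd = x_shape
    dxr = np.zeros((n, c, h // 2, wd // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, wd // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx).reshape(n, c, h, wd)


def _bn_forward_train(x, gamma, beta, running_mean, running_var):
    """Per-channel batch normalization over (N, H, W); updates running stats."""
    mu = x.mean(axis=(0, 2, 3))
    var = x.var(axis=(0, 2, 3))
    running_mean *= 1 - BN_MOMENTUM
    running_mean += BN_MOMENTUM * mu
    running_var *= 1 - BN_MOMENTUM
    running_var += BN_MOMENTUM * var
    inv_std = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return out.astype(F32), (xhat, inv_std)


def _bn_forward_eval(x, gamma, beta, running_mean, running_var):
    scale = gamma / np.sqrt(running_var + BN_EPS)
    shift = beta - running_mean * scale
    return x * scale[None, :, None, None] + shift[None, :, None, None]


def _bn_backward(dy, gamma, cache):
    xhat, inv_std = cache
    m = dy.shape[0] * dy.shape[2] * dy.shape[3]
    dgamma = (dy * xhat).sum(axis=(0, 2, 3))
    dbeta = dy.sum(axis=(0, 2, 3))
    dxhat = dy * gamma[None, :, None, None]
    dx = (
        dxhat
        - dxhat.mean(axis=(0, 2, 3), keepdims=True)
        - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
    ) * inv_std[None, :, None, None]
    return dx.astype(F32), dgamma, dbeta


class SmallCAMNet:
    """Conv-BN blocks down to a K x g x g grid, GAP, linear-15, linear head.

    With a 64 x 64 input and three pools the final grid is 8 x 8.
    """

    def __init__(
        self,
        n_outputs: int,
        task: str = "multilabel",
        channels: tuple[int, ...] = (8, 16, 32, 32),
        bottleneck_dim: int = 15,
        input_size: int = 64,
        seed: int = 0,
    ) -> None:
        if task not in ("multilabel", "multiclass"):
            raise ValueError(f"unknown task {task!r}")
        if input_size % 8 != 0:
            raise ValueError("input size must be divisible by 8 (three pools)")
        if len(channels) != 4:
            raise ValueError("expected four conv channel counts")
        self.task = task
        self.n_outputs = n_outputs
        self.channels = tuple(channels)
        self.bottleneck_dim = bottleneck_dim
        self.input_size = input_size
        self.grid = input_size // 8
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

        prev = 1
        for i, ch in enumerate(channels, start=1):
            fan_in = 9 * prev
            self.params[f"w{i}"] = (
                rng.standard_normal((ch, prev, 3, 3)) * np.sqrt(2.0 / fan_in)
            ).astype(F32)
            self.params[f"g{i}"] = np.ones(ch, dtype=F32)
            self.params[f"be{i}"] = np.zeros(ch, dtype=F32)
            self.buffers[f"rm{i}"] = np.zeros(ch, dtype=np.float64)
            self.buffers[f"rv{i}"] = np.ones(ch, dtype=np.float64)
            prev = ch
        k = channels[-1]
        self.params["wb"] = (rng.standard_normal((bottleneck_dim, k)) * np.sqrt(2.0 / k)).astype(F32)
        self.params["bb"] = np.zeros(bottleneck_dim, dtype=F32)
        self.params["wh"] = (
            rng.standard_normal((n_outputs, bottleneck_dim)) * np.sqrt(2.0 / bottleneck_dim)
        ).astype(F32)
        self.params["bh"] = np.zeros(n_outputs, dtype=F32)
        self._velocity = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    # -- forward -----------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[-1] != self.input_size or x.shape[-2] != self.input_size:
            raise ValueError(
                f"expected {self.input_size}x{self.input_size} images, got {x.shape[-2:]}"
            )
        return x

    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False):
        p, bufs = self.params, self.buffers
        x = self._check_input(x)
        ctx: dict = {"x": x}
        cur = x
        for i in range(1, 5):
            a, cols = _conv_forward(cur, p[f"w{i}"])
            if train:
                bn, bn_cache = _bn_forward_train(
                    a, p[f"g{i}"], p[f"be{i}"], bufs[f"rm{i}"], bufs[f"rv{i}"]
                )
            else:
                bn = _bn_forward_eval(
                    a, p[f"g{i}"], p[f"be{i}"], bufs[f"rm{i}"], bufs[f"rv{i}"]
                ).astype(F32)
                bn_cache = None
            r = np.maximum(bn, 0)
            if cache:
                ctx[f"in{i}"] = cur
                ctx[f"cols{i}"] = cols
                ctx[f"bn_cache{i}"] = bn_cache
                ctx[f"bn{i}"] = bn
            if i < 4:
                cur, idx = _pool_forward(r)
                if cache:
                    ctx[f"idx{i}"] = idx
                    ctx[f"r_shape{i}"] = r.shape
            else:
                cur = r
        fmap = cur  # (N, K, g, g)
        gap = fmap.mean(axis=(2, 3))
        z = gap @ p["wb"].T + p["bb"]
        logits = z @ p["wh"].T + p["bh"]
        if not cache:
            return logits, fmap
        ctx.update(fmap=fmap, gap=gap, z=z)
        return logits, ctx

    def predict_logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = self._check_input(x)
        outs = []
        for i in range(0, len(x), batch_size):
            logits, _ = self.forward(x[i : i + batch_size])
            outs.append(logits)
        return np.concatenate(outs, axis=0)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        logits = self.predict_logits(x, batch_size).astype(np.float64)
        if self.task == "multilabel":
            return 1.0 / (1.0 + np.exp(-logits))
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)

    # -- loss & backward ---------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy over the batch and gradients for all params."""
        logits, ctx = self.forward(x, train=True, cache=True)
        n = logits.shape[0]
        logits64 = logits.astype(np.float64)
        if self.task == "multilabel":
            yf = np.asarray(y, dtype=np.float64)
            # stable BCE-with-logits, summed over findings, averaged over batch
            loss = np.mean(
                np.sum(
                    np.maximum(logits64, 0)
                    - logits64 * yf
                    + np.log1p(np.exp(-np.abs(logits64))),
                    axis=1,
                )
            )
            probs = 1.0 / (1.0 + np.exp(-logits64))
            dlogits = ((probs - yf) / n).astype(F32)
        else:
            yi = np.asarray(y, dtype=int)
            shifted = logits64 - logits64.max(axis=1, keepdims=True)
            logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
            logp = shifted - logz
            loss = -np.mean(logp[np.arange(n), yi])
            probs = np.exp(logp)
            probs[np.arange(n), yi] -= 1.0
            dlogits = (probs / n).astype(F32)

        p = self.params
        g: dict[str, np.ndarray] = {}
        g["wh"] = dlogits.T @ ctx["z"]
        g["bh"] = dlogits.sum(axis=0)
        dz = dlogits @ p["wh"]
        g["wb"] = dz.T @ ctx["gap"]
        g["bb"] = dz.sum(axis=0)
        dgap = dz @ p["wb"]
        gsz = self.grid
        dcur = (
            np.broadcast_to(dgap[:, :, None, None] / (gsz * gsz), ctx["fmap"].shape)
            * (ctx["bn4"] > 0)
        ).astype(F32)
        for i in range(4, 0, -1):
            if i < 4:
                dcur = (_pool_backward(dcur, ctx[f"idx{i}"], ctx[f"r_shape{i}"])
                        * (ctx[f"bn{i}"] > 0)).astype(F32)
            dbn, g[f"g{i}"], g[f"be{i}"] = _bn_backward(dcur, p[f"g{i}"], ctx[f"bn_cache{i}"])
            dcur, g[f"w{i}"] = _conv_backward(
                dbn, ctx[f"cols{i}"], p[f"w{i}"], ctx[f"in{i}"].shape
            )
        return float(loss), g

    def sgd_step(self, grads: dict, lr: float, momentum: float, weight_decay: float) -> None:
        for name, p in self.params.items():
            g = grads[name].astype(F32) + F32(weight_decay) * p
            v = self._velocity[name]
            v *= F32(momentum)
            v += g
            p -= F32(lr) * v

    def tune_loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
        logits = self.predict_logits(x, batch_size).astype(np.float64)
        if self.task == "multilabel":
            yf = np.asarray(y, dtype=np.float64)
            return float(
                np.mean(
                    np.sum(
                        np.maximum(logits, 0)
                        - logits * yf
                        + np.log1p(np.exp(-np.abs(logits))),
                        axis=1,
                    )
                )
            )
        yi = np.asarray(y, dtype=int)
        shifted = logits - logits.max(axis=1, keepdims=True)
        logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        return float(-np.mean((shifted - logz)[np.arange(len(yi)), yi]))

    # -- CAM access --------------------------------------------------------

    def final_feature_map(self, x: np.ndarray) -> np.ndarray:
        """Post-ReLU activations of the final conv layer, (N, K, g, g)."""
        _, fmap = self.forward(self._check_input(x))
        return fmap

    def effective_head(self) -> tuple[np.ndarray, np.ndarray]:
        """Compose bottleneck and head into one linear read-out over channels.

        Returns (B, B0) with B of shape (n_outputs, K) such that
        logits = B @ pooled_features + B0 exactly.
        """
        p = self.params
        b = p["wh"].astype(np.float64) @ p["wb"].astype(np.float64)
        b0 = (
            p["wh"].astype(np.float64) @ p["bb"].astype(np.float64)
            + p["bh"].astype(np.float64)
        )
        return b, b0

    # -- state -------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.params.items()}
        state.update({f"buf_{k}": v.copy() for k, v in self.buffers.items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].astype(F32).copy()
        for k in self.buffers:
            self.buffers[k] = state[f"buf_{k}"].astype(np.float64).copy()
        self._velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
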