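"""Compact CPU-sized convolutional-network engine.

Implements the few pieces the two-stage pipeline needs — strided 3x3
convolutions, identity residual blocks, global average pooling, a softmax
head, SGD with Nesterov momentum and a reduce-on-plateau schedule — in plain
NumPy (NHWC layout, float32).  Networks are small (tens of thousands of
parameters) so that a full training run fits in CPU minutes; the architecture
is configured by a plain dict and is therefore pluggable up to much deeper
residual nets.

Convolutions are evaluated as a sum over the k*k kernel offsets of strided
slice x weight matrix products, which keeps everything inside BLAS without
materialising a full im2col buffer.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = [
    "ConvNet",
    "SGDNesterov",
    "ReduceLROnPlateau",
    "softmax",
    "cross_entropy",
    "default_patch_arch",
    "default_slide_arch",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Layer:
    """Base layer: parameters and gradients live in parallel dicts.

    ``backward(dy, need_input_grad=False)`` may skip the input-gradient
    computation — used for the first layer of a net, where it is never
    consumed.
    """

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # state saved but not trained

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray, need_input_grad: bool = True):  # pragma: no cover
        raise NotImplementedError


class AvgPool(Layer):
    """Non-overlapping mean pooling by an integer factor.

    Inputs whose extent is not a multiple of the factor are edge-padded, so
    any input size is accepted (needed for the free-input-size slide model).
    uint8 input is accepted as a fast path for images stored as bytes: the
    pooled output is additionally scaled by 1/255, i.e. it equals (to float32
    rounding) pooling the float image ``x / 255``.
    """

    def __init__(self, factor: int) -> None:
        super().__init__()
        self.f = int(factor)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.f
        n, h, w, c = x.shape
        ho, wo = -(-h // f), -(-w // f)
        ph, pw = ho * f - h, wo * f - w
        self._shape = (n, h, w, c)
        scale = 1.0 / (f * f)
        if x.dtype == np.uint8:
            scale /= 255.0
        xp = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="edge") if (ph or pw) else x
        xp = np.ascontiguousarray(xp)
        # two separable passes of contiguous column adds: cheaper than axis-tuple mean
        v = xp.reshape(n * (ho * f) * wo, f * c)
        acc_w = v[:, 0:c].astype(np.result_type(xp.dtype, np.float32))
        for j in range(1, f):
            acc_w += v[:, j * c:(j + 1) * c]
        u = acc_w.reshape(n, ho, f, wo * c)
        acc = u[:, :, 0, :].copy()
        for i in range(1, f):
            acc += u[:, :, i, :]
        acc *= scale
        return acc.reshape(n, ho, wo, c)

    def backward(self, dy: np.ndarray, need_input_grad: bool = True):
        if not need_input_grad:
            return None
        f = self.f
        n, h, w, c = self._shape
        ho, wo = dy.shape[1], dy.shape[2]
        d = (dy / (f * f))[:, :, None, :, None, :]
        dxp = np.broadcast_to(d, (n, ho, f, wo, f, c)).reshape(n, ho * f, wo * f, c)
        dx = dxp[:, :h, :w, :].copy()
        if ho * f > h:
            dx[:, h - 1, :, :] += dxp[:, h:, :w, :].sum(axis=1)
        if wo * f > w:
            dx[:, :, w - 1, :] += dxp[:, :h, w:, :].sum(axis=2)
        if ho * f > h and wo * f > w:
            dx[:, h - 1, w - 1, :] += dxp[:, h:, w:, :].sum(axis=(1, 2))
        return dx


class Conv2d(Layer):
    """k x k convolution, zero padding k//2, arbitrary stride, NHWC."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, *,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, cin, cout))
        self.params = {"w": w.astype(np.float32), "b": np.zeros(cout, dtype=np.float32)}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.k, self.stride, self.k // 2
        n, h, w, cin = x.shape
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((n * ho * wo, k * k, cin), dtype=xp.dtype)
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, ki:ki + s * (ho - 1) + 1:s, kj:kj + s * (wo - 1) + 1:s, :]
                cols[:, ki * k + kj, :] = xs.reshape(n * ho * wo, cin)
        cols = cols.reshape(n * ho * wo, k * k * cin)
        self._cols, self._in_shape, self._out_hw = cols, (n, h, w, cin), (ho, wo)
        wflat = self.params["w"].reshape(k * k * cin, self.cout)
        y = cols @ wflat + self.params["b"]
        return y.reshape(n, ho, wo, self.cout)

    def backward(self, dy: np.ndarray, need_input_grad: bool = True):
        k, s, p = self.k, self.stride, self.k // 2
        n, h, w, cin = self._in_shape
        ho, wo = self._out_hw
        dyf = dy.reshape(-1, self.cout)
        wflat = self.params["w"].reshape(k * k * cin, self.cout)
        self.grads = {
            "w": (self._cols.T @ dyf).reshape(self.params["w"].shape),
            "b": dyf.sum(axis=0),
        }
        self._cols = None
        if not need_input_grad:
            return None
        dcols = (dyf @ wflat.T).reshape(n * ho * wo, k * k, cin)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, cin), dtype=dcols.dtype)
        for ki in range(k):
            for kj in range(k):
                sl = np.s_[:, ki:ki + s * (ho - 1) + 1:s, kj:kj + s * (wo - 1) + 1:s, :]
                dxp[sl] += dcols[:, ki * k + kj, :].reshape(n, ho, wo, cin)
        return dxp[:, p:p + h, p:p + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dy: np.ndarray, need_input_grad: bool = True):
        return np.where(self._mask, dy, np.float32(0.0))


class BatchNorm(Layer):
    """Per-channel batch normalization (NHWC), with running statistics.

    Training uses batch statistics and updates the running mean/variance;
    inference uses the running buffers, so evaluation is deterministic and
    independent of batch composition.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(channels, dtype=np.float32),
                       "beta": np.zeros(channels, dtype=np.float32)}
        self.buffers = {"running_mean": np.zeros(channels, dtype=np.float32),
                        "running_var": np.ones(channels, dtype=np.float32)}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"] = ((1 - m) * self.buffers["running_mean"]
                                            + m * mean).astype(np.float32)
            self.buffers["running_var"] = ((1 - m) * self.buffers["running_var"]
                                           + m * var).astype(np.float32)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train_mode = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray, need_input_grad: bool = True):
        axes = tuple(range(dy.ndim - 1))
        xhat = self._xhat
        self.grads = {"gamma": (dy * xhat).sum(axis=axes), "beta": dy.sum(axis=axes)}
        if not need_input_grad:
            return None
        dxhat = dy * self.params["gamma"]
        if not self._train_mode:
            return dxhat / self._std
        n = dy.size // dy.shape[-1]
        return (dxhat - dxhat.mean(axis=axes)
                - xhat * (dxhat * xhat).mean(axis=axes)) / self._std


class ResidualBlock(Layer):
    """Two conv+BN pairs with an identity skip: y = relu(x + F(x))."""

    def __init__(self, channels: int, *, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, 1, rng=rng)
        self.bn1 = BatchNorm(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, 1, rng=rng)
        self.bn2 = BatchNorm(channels)
        self.relu_out = ReLU()
        self.sublayers = [self.conv1, self.bn1, self.conv2, self.bn2]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.conv1.forward(x, train)
        f = self.relu1.forward(self.bn1.forward(f, train), train)
        f = self.bn2.forward(self.conv2.forward(f, train), train)
        return self.relu_out.forward(x + f, train)

    def backward(self, dy: np.ndarray, need_input_grad: bool = True):
        d = self.relu_out.backward(dy)
        df = self.bn2.backward(d)
        df = self.conv2.backward(df)
        df = self.bn1.backward(self.relu1.backward(df))
        df = self.conv1.backward(df)
        return d + df


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray, need_input_grad: bool = True):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).copy()


class Linear(Layer):
    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(1.0 / cin), size=(cin, cout))
        self.params = {"w": w.astype(np.float32), "b": np.zeros(cout, dtype=np.float32)}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy: np.ndarray, need_input_grad: bool = True):
        self.grads = {"w": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["w"].T


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def default_patch_arch() -> dict:
    """~50k-parameter residual net for 256x256 RGB patches (3-way head)."""
    return {
        "in_channels": 3,
        "num_classes": 3,
        "stem_pool": 4,
        "stem": {"channels": 16, "stride": 4},
        "stages": [
            {"channels": 24, "stride": 2, "blocks": 0},
            {"channels": 32, "stride": 1, "blocks": 2},
        ],
    }


def default_slide_arch() -> dict:
    """Free-input-size residual net for 6-channel slide inputs (2-way head)."""
    return {
        "in_channels": 6,
        "num_classes": 2,
        "stem_pool": 4,
        "stem": {"channels": 16, "stride": 4},
        "stages": [
            {"channels": 24, "stride": 2, "blocks": 1},
            {"channels": 32, "stride": 2, "blocks": 1},
        ],
    }


class ConvNet:
    """Residual conv net with global average pooling and a softmax head.

    Global average pooling before the head makes the classifier accept any
    spatial input size.  The last pre-pooling activation is retained on
    request so gradient-weighted class-activation maps can be computed.
    """

    def __init__(self, arch: dict, seed: int = 0) -> None:
        self.arch = json.loads(json.dumps(arch))  # defensive copy
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        layers: list[Layer] = []
        if arch.get("stem_pool", 0) and arch["stem_pool"] > 1:
            layers.append(AvgPool(arch["stem_pool"]))
        cin = arch["in_channels"]
        stem = arch["stem"]
        layers += [Conv2d(cin, stem["channels"], 3, stem["stride"], rng=rng),
                   BatchNorm(stem["channels"]), ReLU()]
        cin = stem["channels"]
        for stage in arch["stages"]:
            layers += [Conv2d(cin, stage["channels"], 3, stage["stride"], rng=rng),
                       BatchNorm(stage["channels"]), ReLU()]
            cin = stage["channels"]
            for _ in range(stage.get("blocks", 1)):
                layers.append(ResidualBlock(cin, rng=rng))
        self.feature_index = len(layers)  # activations entering GAP
        layers += [GlobalAvgPool(), Linear(cin, arch["num_classes"], rng=rng)]
        self.layers = layers
        self.step = 0

    # -- parameter plumbing -------------------------------------------------

    def _flat_layers(self) -> list[Layer]:
        out: list[Layer] = []
        for lyr in self.layers:
            if isinstance(lyr, ResidualBlock):
                out.extend(lyr.sublayers)
            else:
                out.append(lyr)
        return out

    def parameters(self) -> list[tuple[str, Layer]]:
        named = []
        for i, lyr in enumerate(self._flat_layers()):
            for key in lyr.params:
                named.append((f"layer{i}.{key}", lyr))
        return named

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, lyr in enumerate(self._flat_layers()):
            for key in lyr.params:
                out[f"layer{i}.{key}"] = lyr.params[key].copy()
            for key in lyr.buffers:
                out[f"layer{i}.{key}"] = lyr.buffers[key].copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, lyr in enumerate(self._flat_layers()):
            for key in lyr.params:
                lyr.params[key] = np.asarray(state[f"layer{i}.{key}"], dtype=np.float32).copy()
            for key in lyr.buffers:
                lyr.buffers[key] = np.asarray(state[f"layer{i}.{key}"], dtype=np.float32).copy()

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, *, retain_features: bool = False,
                train: bool = False) -> np.ndarray:
        a = np.asarray(x)
        if a.dtype == np.uint8:
            if not isinstance(self.layers[0], AvgPool):
                a = a.astype(np.float32) / 255.0
        else:
            a = a.astype(np.float32, copy=False)
        for i, lyr in enumerate(self.layers):
            a = lyr.forward(a, train)
            if retain_features and i == self.feature_index - 1:
                self.features_ = a
        return a

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate logit gradients into every parameter's ``grads``.

        The input gradient of the first layer is not computed (nothing
        upstream consumes it).
        """
        d = dlogits
        for i, lyr in enumerate(reversed(self.layers)):
            d = lyr.backward(d, need_input_grad=i < len(self.layers) - 1)

    def grad_wrt_features(self, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of ``sum(dlogits * logits)`` w.r.t. the pre-GAP activations."""
        d = dlogits
        for lyr in reversed(self.layers[self.feature_index:]):
            d = lyr.backward(d)
        return d

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        meta = json.dumps({"arch": self.arch, "seed": self.seed, "step": self.step})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "ConvNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            net = cls(meta["arch"], seed=meta["seed"])
            net.step = int(meta["step"])
            net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return net


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------


class SGDNesterov:
    """SGD with Nesterov momentum: v <- mu v + g;  w <- w - lr (g + mu v)."""

    def __init__(self, net: ConvNet, lr: float, momentum: float = 0.95) -> None:
        self.net = net
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._velocity: dict[str, np.ndarray] = {}

    def step(self) -> None:
        mu = self.momentum
        for i, lyr in enumerate(self.net._flat_layers()):
            for key, g in lyr.grads.items():
                name = f"layer{i}.{key}"
                v = self._velocity.get(name)
                if v is None:
                    v = np.zeros_like(lyr.params[key])
                v = mu * v + g
                self._velocity[name] = v
                lyr.params[key] -= (self.lr * (g + mu * v)).astype(np.float32)


class ReduceLROnPlateau:
    """Decay the learning rate when a monitored loss stops improving.

    After ``patience`` consecutive evaluations without improvement the
    optimizer's rate is multiplied by ``factor`` (floored at ``min_lr``) and
    the counter resets.
    """

    def __init__(self, optimizer: SGDNesterov, factor: float = 0.1,
                 patience: int = 5, min_lr: float = 1e-6, eps: float = 1e-8) -> None:
        self.optimizer = optimizer
        self.factor, self.patience, self.min_lr, self.eps = factor, patience, min_lr, eps
        self.best = np.inf
        self.num_bad = 0

    def step(self, metric: float) -> bool:
        """Record one evaluation; returns True if the rate was reduced."""
        if metric < self.best - self.eps:
            self.best = metric
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad >= self.patience:
            self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
            self.num_bad = 0
            return True
        return False
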