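"""A compact NumPy implementation of the segmentation U-Net.

The architecture is a U-Net variant whose basic unit, the BSConv2
block, is two repeats of [reflection-padded 3x3 convolution (linear) ->
batch normalization -> trainable Swish].  Down-scaling uses stride-2
convolutions and up-scaling stride-2 transposed convolutions instead of
pooling/upsampling; skip connections concatenate encoder features into
the decoder; the head is a 1x1 convolution with a per-pixel softmax
over the five wall classes.  Filter counts double at each level below
the surface (base 32 at the surface means 256 at level three for a
depth-3 network).  Weights are He-normal initialized.

Layers are written directly in NumPy with explicit ``forward`` /
``backward`` methods (im2col convolutions), sized for desk-scale
experiments and tests on CPU; the design and defaults mirror the
full-scale configuration.  Tensors are NCHW throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit

from .classes import N_CLASSES

__all__ = [
    "NetworkConfig",
    "swish",
    "Param",
    "Conv2D",
    "ConvTranspose2x2",
    "BatchNorm2D",
    "TrainableSwish",
    "BSConv2Block",
    "UNet",
    "build_unet",
]


def swish(x: np.ndarray | float, beta: float = 1.0) -> np.ndarray | float:
    """Swish activation ``x * logistic(beta * x)``."""
    x = np.asarray(x, dtype=float)
    out = x * expit(beta * x)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``depth`` counts the levels below the surface; level k uses
    ``base_filters * 2**k`` filters per convolution.  The input tile
    edge must be divisible by ``2**depth`` so strided down-scaling
    divides evenly.
    """

    depth: int = 3
    base_filters: int = 32
    n_classes: int = N_CLASSES
    tile_size: int = 384
    in_channels: int = 3
    swish_beta_init: float = 1.0
    bn_momentum: float = 0.9
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.tile_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"tile_size {self.tile_size} not divisible by 2**depth = {2 ** self.depth}"
            )

    @property
    def scaling(self) -> int:
        return 2 ** self.depth

    def filters_at(self, level: int) -> int:
        return self.base_filters * 2 ** level

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__))


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    train_mode: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _reflect_pad_nchw(x: np.ndarray, p: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")


def _reflect_pad_backward(dxp: np.ndarray, p: int) -> np.ndarray:
    """Fold gradients at reflect-padded positions back onto the interior.

    Uses the same index map as ``np.pad(mode='reflect')`` so the fold is
    exact by construction: pad the row/column index vectors, then
    scatter-add the padded gradient back through them.
    """
    if p == 0:
        return dxp
    n, c, hp, wp = dxp.shape
    h, w = hp - 2 * p, wp - 2 * p
    ry = np.pad(np.arange(h), p, mode="reflect")
    rx = np.pad(np.arange(w), p, mode="reflect")
    cols = np.zeros((n, c, hp, w))
    np.add.at(cols, (Ellipsis, rx), dxp)
    out = np.zeros((n, c, w, h))
    np.add.at(out, (Ellipsis, ry), cols.transpose(0, 1, 3, 2))
    return out.transpose(0, 1, 3, 2)


class Conv2D(Layer):
    """k x k convolution with reflection padding (k odd) or valid (k=1)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = ""):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        # He normal initialization
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k)),
                       f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self.k, self.stride, self.pad = k, stride, (k - 1) // 2
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = _reflect_pad_nchw(x, self.pad) if self.pad else x
        n, c, hp, wp = xp.shape
        k, s = self.k, self.stride
        oh, ow = (hp - k) // s + 1, (wp - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, oh, ow, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        out = cols @ wmat.T + self.b.value
        self._cache = (cols, xp.shape, x.shape, oh, ow)
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, x_shape, oh, ow = self._cache
        n, c, hp, wp = xp_shape
        k, s = self.k, self.stride
        c_out = dy.shape[1]
        dyc = dy.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.w.grad += (dyc.T @ cols).reshape(self.w.value.shape)
        self.b.grad += dyc.sum(axis=0)
        dcols = dyc @ self.w.value.reshape(c_out, -1)
        dcols = dcols.reshape(n, oh, ow, c, k, k)
        dxp = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + oh * s : s, j : j + ow * s : s] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        if self.pad:
            return _reflect_pad_backward(dxp, self.pad)
        return dxp


class ConvTranspose2x2(Layer):
    """Stride-2, 2x2 transposed convolution (non-overlapping up-scaling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None,
                 name: str = ""):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / c_in), (c_in, c_out, 2, 2)),
                       f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        out = np.einsum("nchw,cdkl->ndhkwl", x, self.w.value, optimize=True)
        out = out.reshape(n, -1, 2 * h, 2 * w) + self.b.value[None, :, None, None]
        self._cache = x
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        n, c, h, w = x.shape
        d = dy.shape[1]
        dyr = dy.reshape(n, d, h, 2, w, 2)
        self.w.grad += np.einsum("nchw,ndhkwl->cdkl", x, dyr, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return np.einsum("ndhkwl,cdkl->nchw", dyr, self.w.value, optimize=True)


class BatchNorm2D(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, name: str = ""):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not self.train_mode:
            return dy * g * inv[None, :, None, None]
        dxhat = dy * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        )
        return term * inv[None, :, None, None]


class TrainableSwish(Layer):
    """Swish with one learnable beta per activation layer."""

    def __init__(self, beta_init: float = 1.0, name: str = ""):
        self.beta = Param(np.array(beta_init), f"{name}.beta")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b = float(self.beta.value)
        s = expit(b * x)
        self._cache = (x, s)
        return x * s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s = self._cache
        b = float(self.beta.value)
        ds = s * (1.0 - s)
        self.beta.grad += float((dy * x * x * ds).sum())
        return dy * (s + b * x * ds)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            l.train_mode = self.train_mode
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def bsconv2_block(c_in: int, filters: int, rng: np.random.Generator,
                  beta_init: float = 1.0, momentum: float = 0.9,
                  eps: float = 1e-5, name: str = "bsconv2") -> Sequential:
    """Two repeats of reflection-padded 3x3 conv -> BN -> trainable Swish."""
    return Sequential(
        Conv2D(c_in, filters, 3, rng=rng, name=f"{name}.conv1"),
        BatchNorm2D(filters, momentum, eps, name=f"{name}.bn1"),
        TrainableSwish(beta_init, name=f"{name}.swish1"),
        Conv2D(filters, filters, 3, rng=rng, name=f"{name}.conv2"),
        BatchNorm2D(filters, momentum, eps, name=f"{name}.bn2"),
        TrainableSwish(beta_init, name=f"{name}.swish2"),
    )


class UNet:
    """Encoder/decoder with concatenating skips and softmax output.

    ``forward`` returns per-pixel class probabilities (NCHW, channels
    summing to 1); ``backward`` expects the gradient w.r.t. the softmax
    *logits* is handled internally — pass the gradient w.r.t. the
    probabilities and the softmax Jacobian is applied here.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.train_mode = True

        self.enc_blocks: list[Sequential] = []
        self.down: list[Conv2D] = []
        c_prev = cfg.in_channels
        for level in range(cfg.depth + 1):
            f = cfg.filters_at(level)
            if level > 0:
                # strided 3x3 convolution halves the spatial dims
                self.down.append(Conv2D(c_prev, f, 3, stride=2, rng=rng,
                                        name=f"down{level}"))
                c_prev = f
            self.enc_blocks.append(
                bsconv2_block(c_prev, f, rng, cfg.swish_beta_init, cfg.bn_momentum,
                              cfg.bn_eps, name=f"enc{level}")
            )
            c_prev = f

        self.up: list[ConvTranspose2x2] = []
        self.dec_blocks: list[Sequential] = []
        for level in range(cfg.depth, 0, -1):
            f_hi, f_lo = cfg.filters_at(level), cfg.filters_at(level - 1)
            self.up.append(ConvTranspose2x2(f_hi, f_lo, rng=rng, name=f"up{level}"))
            self.dec_blocks.append(
                bsconv2_block(2 * f_lo, f_lo, rng, cfg.swish_beta_init, cfg.bn_momentum,
                              cfg.bn_eps, name=f"dec{level - 1}")
            )
        self.head = Conv2D(cfg.base_filters, cfg.n_classes, 1, rng=rng, name="head")
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    def _layers(self) -> list[Layer]:
        return [*self.enc_blocks, *self.down, *self.up, *self.dec_blocks, self.head]

    def params(self) -> list[Param]:
        return [p for l in self._layers() for p in l.params()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode
        for l in self._layers():
            l.train_mode = mode

    def _flat_layers(self) -> list[Layer]:
        out: list[Layer] = []
        for l in self._layers():
            out.extend(l.layers if isinstance(l, Sequential) else [l])
        return out

    def _batchnorms(self) -> list["BatchNorm2D"]:
        return [l for l in self._flat_layers() if isinstance(l, BatchNorm2D)]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"{i}:{p.name}": p.value.copy() for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._batchnorms()):
            state[f"buffer:{i}:mean"] = bn.running_mean.copy()
            state[f"buffer:{i}:var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        bns = self._batchnorms()
        param_items = sorted(
            ((k, v) for k, v in state.items() if not k.startswith("buffer:")),
            key=lambda kv: int(kv[0].split(":")[0]),
        )
        if len(param_items) != len(params):
            raise ValueError("state dict does not match the architecture")
        for (key, value), p in zip(param_items, params):
            if p.value.shape != value.shape:
                raise ValueError(f"shape mismatch for {key}")
            p.value[...] = value
        for i, bn in enumerate(bns):
            if f"buffer:{i}:mean" in state:
                bn.running_mean[...] = state[f"buffer:{i}:mean"]
                bn.running_var[...] = state[f"buffer:{i}:var"]

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.state_dict())
        sidecar = Path(path).with_suffix(".yaml")
        self.cfg.to_yaml(sidecar)

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        cfg = NetworkConfig(**yaml.safe_load(Path(path).with_suffix(".yaml").read_text()))
        model = cls(cfg)
        with np.load(path) as data:
            model.load_state_dict(dict(data))
        return model

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.set_train(self.train_mode)
        h = np.asarray(x, dtype=np.float64)
        skips = []
        for level, block in enumerate(self.enc_blocks):
            if level > 0:
                h = self.down[level - 1].forward(h)
            h = block.forward(h)
            if level < self.cfg.depth:
                skips.append(h)
        # decoder i handles level depth - i, concatenating the skip from
        # level depth - 1 - i
        for i, (up, dec) in enumerate(zip(self.up, self.dec_blocks)):
            h = up.forward(h)
            h = np.concatenate([skips[self.cfg.depth - 1 - i], h], axis=1)
            h = dec.forward(h)
        logits = self.head.forward(h)
        # stable softmax over the class axis
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        self._cache = probs
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        probs = self._cache
        # softmax Jacobian: dz = p * (dp - sum_c dp * p)
        dz = probs * (dprobs - (dprobs * probs).sum(axis=1, keepdims=True))
        dh = self.head.backward(dz)
        dskips: list[np.ndarray | None] = [None] * self.cfg.depth
        for i in reversed(range(self.cfg.depth)):
            d = self.dec_blocks[i].backward(dh)
            f_lo = self.cfg.filters_at(self.cfg.depth - 1 - i)
            dskips[self.cfg.depth - 1 - i] = d[:, :f_lo]
            dh = self.up[i].backward(d[:, f_lo:])
        for level in reversed(range(self.cfg.depth + 1)):
            if level < self.cfg.depth:
                dh = dh + dskips[level]
            dh = self.enc_blocks[level].backward(dh)
            if level > 0:
                dh = self.down[level - 1].backward(dh)


def build_unet(cfg: NetworkConfig, rng: np.random.Generator | None = None) -> UNet:
    """Construct a U-Net for a config (He-normal initialized)."""
    return UNet(cfg, rng)
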