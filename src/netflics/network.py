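"""The Net-FLICS network: direct CNN reconstruction from raw CS data.

Maps a (n_gates x n_meas) time-resolved compressed-sensing measurement
array straight to a 32x32 intensity image (counts) and a 32x32 lifetime
image (ns), with no inverse solver and no curve fitting.  Three segments:

* **common** — a fully connected measurement->pixel mapping shared across
  all time gates (equivalently a kernel-size-1 Conv1D over the gate
  sequence), whose output is transposed into a pixel-leading
  (gates x 32 x 32) feature block, followed by a 1x1 convolutional mixing
  layer;
* **intensity head** — one ResBlock and one ReconBlock on the mixed
  features;
* **lifetime head** — a 1D convolution along the gate axis of the feature
  block, then two ResBlocks and two ReconBlocks.

ResBlocks are two 3x3 conv+BN+ReLU layers with an identity skip;
ReconBlocks are the ReconNet-style triple conv stack (wide kernel ->
1x1 bottleneck -> single-channel output).  Training minimizes
``MSE(intensity) + 1e5 * MSE(lifetime)`` with RMSprop, halving the
learning rate every 10 epochs from 1e-3 and early-stopping on the
validation lifetime MAE.

Everything here is plain NumPy: layers implement ``forward``/``backward``
explicitly and the optimizer updates parameter arrays in place, which
keeps runs bit-reproducible on one device.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .forward import MeasurementSet, PatternBank
from .phantoms import LifetimeScene
from .tvrecon import ReconResult

__all__ = [
    "NetConfig",
    "PRESETS",
    "NetFLICS",
    "TrainedModel",
    "build_model",
    "loss_and_grads",
    "learning_rate",
    "train",
    "predict",
    "make_training_arrays",
]


@dataclass
class NetConfig:
    """Architecture and optimization settings.

    Kernel counts/sizes default to the ReconNet recipe for ReconBlocks
    (64@11x11 -> 32@1x1 -> 1@7x7) and 3x3 ResBlocks; all are exposed so
    scaled-down presets can trade capacity for CPU time.
    """

    n_gates: int = 256
    n_meas: int = 512
    img_side: int = 32
    lifetime_loss_weight: float = 1e5
    base_lr: float = 1e-3
    lr_halving_period: int = 10
    patience: int = 10
    batch_size: int = 25
    max_epochs: int = 100
    rng_seed: int = 0
    # architecture widths
    common_channels: int = 32  # channels after the 1x1 mixing conv
    gate_filters: int = 4  # lifetime-head Conv1D filters
    gate_kernel: int = 32  # ... kernel length along gates
    gate_stride: int = 32  # ... stride along gates
    res_kernel: int = 3
    recon_c1: int = 64
    recon_c2: int = 32
    recon_k1: int = 11
    recon_k3: int = 7
    # fixed output scales: heads predict in units of the generator maxima,
    # so batch-normalized features only need O(1) final-layer weights
    intensity_scale: float = 1600.0
    lifetime_scale: float = 1.5

    def __post_init__(self) -> None:
        if self.lifetime_loss_weight <= 0:
            raise ValueError("lifetime_loss_weight must be positive")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.n_meas < 1 or self.n_gates < 1:
            raise ValueError("n_meas and n_gates must be >= 1")
        if (self.n_gates - self.gate_kernel) % self.gate_stride:
            raise ValueError(
                "gate_kernel/gate_stride must tile n_gates exactly "
                f"(got gates={self.n_gates}, kernel={self.gate_kernel}, "
                f"stride={self.gate_stride})"
            )

    @property
    def n_pixels(self) -> int:
        return self.img_side * self.img_side

    @property
    def gate_windows(self) -> int:
        return (self.n_gates - self.gate_kernel) // self.gate_stride + 1


#: named training presets: config overrides plus dataset sizes
PRESETS: dict[str, dict] = {
    # the full-scale recipe (GPU-class budgets)
    "full": {"n_train": 32000, "n_val": 8000, "max_epochs": 200},
    # CPU desk-scale run
    "desk": {
        "n_train": 2000, "n_val": 500, "max_epochs": 30,
        "common_channels": 16, "gate_filters": 4, "batch_size": 50,
        "recon_c1": 16, "recon_c2": 8, "recon_k1": 5, "recon_k3": 5,
    },
    # minutes-scale run for tests and quick experiments
    "smoke": {
        "n_train": 800, "n_val": 200, "max_epochs": 14, "patience": 6,
        "common_channels": 16, "gate_filters": 4, "batch_size": 50,
        "recon_c1": 16, "recon_c2": 8, "recon_k1": 5, "recon_k3": 5,
    },
}


def preset_config(name: str, **overrides) -> tuple[NetConfig, int, int]:
    """Return (NetConfig, n_train, n_val) for a named preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = dict(PRESETS[name])
    n_train = spec.pop("n_train")
    n_val = spec.pop("n_val")
    spec.update(overrides)
    return NetConfig(**spec), n_train, n_val


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _he(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class _Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}


class Dense(_Layer):
    """Gate-shared fully connected map: (B, G, M) -> (B, G, P)."""

    def __init__(self, in_dim, out_dim, rng, dtype=np.float32, weight=None,
                 need_input_grad=True):
        super().__init__()
        if weight is not None:
            W = np.asarray(weight, dtype=dtype)
            if W.shape != (in_dim, out_dim):
                raise ValueError(f"initial weight shape {W.shape} != {(in_dim, out_dim)}")
        else:
            W = _he(rng, (in_dim, out_dim), in_dim, dtype)
        self.params = {"W": W, "b": np.zeros(out_dim, dtype=dtype)}
        self.need_input_grad = need_input_grad

    def forward(self, x, training=False):
        self._x = x
        lead = x.shape[:-1]
        y = x.reshape(-1, x.shape[-1]) @ self.params["W"] + self.params["b"]
        return y.reshape(*lead, -1)

    def backward(self, dout):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.grads = {"W": x2.T @ d2, "b": d2.sum(axis=0)}
        if not self.need_input_grad:
            return None
        return (d2 @ self.params["W"].T).reshape(self._x.shape)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Channels-last (B,H,W,C) -> (B*H*W, k*k*C) patch matrix ('same' pad).

    Filled by k*k large block copies whose inner (W, C) extents are
    contiguous, so the GEMM that follows dominates the cost.
    """
    B, H, Wd, C = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = np.empty((B, H, Wd, k, k, C), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = xp[:, i : i + H, j : j + Wd, :]
    return cols.reshape(B * H * Wd, k * k * C)


def _conv_same(x: np.ndarray, W2: np.ndarray, k: int, cols=None):
    """Stride-1 'same' correlation; channels-last x, W2 of shape (k*k*C, F)."""
    B, H, Wd, C = x.shape
    if cols is None:
        cols = _im2col(x, k) if k > 1 else x.reshape(B * H * Wd, C)
    y = cols @ W2  # (B*H*W, F)
    return y.reshape(B, H, Wd, -1), cols


class Conv2d(_Layer):
    """Stride-1 'same' 2D convolution, channels-last, odd kernel size.

    The kernel is stored flat as (k*k*cin, cout) with spatial offsets in
    row-major (di, dj) order.
    """

    def __init__(self, cin, cout, k, rng, dtype=np.float32, need_input_grad=True):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, k
        self.params = {
            "W": _he(rng, (k * k * cin, cout), cin * k * k, dtype),
            "b": np.zeros(cout, dtype=dtype),
        }
        self.need_input_grad = need_input_grad

    def forward(self, x, training=False):
        self._shape = x.shape
        y, cols = _conv_same(x, self.params["W"], self.k)
        if training:
            self._cols = cols
        return y + self.params["b"]

    def backward(self, dout):
        B, H, Wd, C = self._shape
        d2 = dout.reshape(-1, self.cout)
        self.grads = {"W": self._cols.T @ d2, "b": d2.sum(axis=0)}
        del self._cols
        if not self.need_input_grad:
            return None
        # input gradient = 'same' convolution with flipped, transposed kernels
        k = self.k
        W4 = self.params["W"].reshape(k, k, self.cin, self.cout)
        Wf = W4[::-1, ::-1].transpose(0, 1, 3, 2).reshape(k * k * self.cout, self.cin)
        return _conv_same(dout, np.ascontiguousarray(Wf), k)[0]


class Conv1dGate(_Layer):
    """1D convolution along the gate axis of a channels-last (B,H,W,G) block.

    Applies F temporal filters of length ``k`` with stride ``s`` at every
    pixel (weights shared across pixels) and stacks windows x filters into
    the channel dimension: output (B, H, W, G' * F).
    """

    def __init__(self, filters, k, stride, rng, dtype=np.float32):
        super().__init__()
        self.f, self.k, self.s = filters, k, stride
        self.params = {
            "W": _he(rng, (filters, k), k, dtype),
            "b": np.zeros(filters, dtype=dtype),
        }

    def forward(self, x, training=False):
        B, H, W, G = x.shape
        self._shape = x.shape
        if self.s == self.k and G % self.k == 0:
            # non-overlapping windows tile the gate axis: a pure reshape
            win = x.reshape(B, H, W, -1, self.k)
        else:
            win = sliding_window_view(x, self.k, axis=3)[:, :, :, :: self.s]
        if training:
            self._win = win
        y = np.tensordot(win, self.params["W"], axes=([4], [1]))  # (B,H,W,G',F)
        y += self.params["b"]
        return y.reshape(B, H, W, -1)

    def backward(self, dout):
        B, H, W, G = self._shape
        Gp = (G - self.k) // self.s + 1
        d5 = dout.reshape(B, H, W, Gp, self.f)
        self.grads = {
            "W": np.tensordot(d5, self._win, axes=([0, 1, 2, 3], [0, 1, 2, 3])),
            "b": d5.sum(axis=(0, 1, 2, 3)),
        }
        del self._win
        tmp = np.tensordot(d5, self.params["W"], axes=([4], [0]))  # (B,H,W,G',k)
        if self.s == self.k and G % self.k == 0:
            return np.ascontiguousarray(tmp).reshape(self._shape)
        dx = np.zeros(self._shape, dtype=dout.dtype)
        pos = self.s * np.arange(Gp)
        for t in range(self.k):
            np.add.at(dx, (slice(None), slice(None), slice(None), pos + t),
                      tmp[..., t])
        return dx


class BatchNorm2d(_Layer):
    """Per-channel batch normalization over (B, H, W), channels last."""

    def __init__(self, c, dtype=np.float32, momentum=0.9, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(c, dtype=dtype), "beta": np.zeros(c, dtype=dtype)}
        self.buffers = {
            "running_mean": np.zeros(c, dtype=dtype),
            "running_var": np.ones(c, dtype=dtype),
        }

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            rm, rv = self.buffers["running_mean"], self.buffers["running_var"]
            rm *= self.momentum
            rm += (1 - self.momentum) * mean
            rv *= self.momentum
            rv += (1 - self.momentum) * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        ivstd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * ivstd
        if training:
            self._xhat, self._ivstd = xhat, ivstd
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, ivstd = self._xhat, self._ivstd
        n = dout.shape[0] * dout.shape[1] * dout.shape[2]
        dg = (dout * xhat).sum(axis=(0, 1, 2))
        db = dout.sum(axis=(0, 1, 2))
        self.grads = {"gamma": dg, "beta": db}
        dx = (self.params["gamma"] * ivstd) / n * (n * dout - db - xhat * dg)
        del self._xhat
        return dx


class ReLU(_Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class ResBlock(_Layer):
    """conv-BN-ReLU-conv-BN with identity skip, ReLU on the sum."""

    def __init__(self, c, k, rng, dtype=np.float32):
        super().__init__()
        self.conv1 = Conv2d(c, c, k, rng, dtype)
        self.bn1 = BatchNorm2d(c, dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c, c, k, rng, dtype)
        self.bn2 = BatchNorm2d(c, dtype)
        self.relu_out = ReLU()
        self.children = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu_out]

    def forward(self, x, training=False):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training)
        h = self.bn2.forward(self.conv2.forward(h, training), training)
        return self.relu_out.forward(h + x, training)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dh = self.conv2.backward(self.bn2.backward(d))
        dh = self.conv1.backward(self.bn1.backward(self.relu1.backward(dh)))
        return dh + d


class ReconBlock(_Layer):
    """ReconNet-style stack: wide conv -> 1x1 bottleneck -> 1-channel output."""

    def __init__(self, cin, c1, c2, k1, k3, rng, dtype=np.float32):
        super().__init__()
        self.conv1 = Conv2d(cin, c1, k1, rng, dtype)
        self.bn1 = BatchNorm2d(c1, dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c1, c2, 1, rng, dtype)
        self.bn2 = BatchNorm2d(c2, dtype)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(c2, 1, k3, rng, dtype)
        # near-zero output init: heads start at their physics baseline (or 0)
        # and learn corrections, instead of swamping them with random output
        self.conv3.params["W"] *= 0.01
        self.children = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2,
                         self.relu2, self.conv3]

    def forward(self, x, training=False):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training)
        h = self.relu2.forward(self.bn2.forward(self.conv2.forward(h, training), training), training)
        return self.conv3.forward(h, training)

    def backward(self, dout):
        d = self.conv3.backward(dout)
        d = self.conv2.backward(self.bn2.backward(self.relu2.backward(d)))
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(d)))


def _walk(layer) -> list[_Layer]:
    kids = getattr(layer, "children", None)
    if kids is None:
        return [layer]
    out = []
    for k in kids:
        out.extend(_walk(k))
    return out


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def physics_init_weight(bank: PatternBank) -> np.ndarray:
    """Measurement->pixel initial mapping from the Hadamard structure.

    The least-squares backprojection of k orthogonal signed rows is
    ``H_sel^T y / order`` with ``y = 2 s - s_dc`` for binarized patterns,
    which is linear in ``s`` — so it can seed the common segment's fully
    connected layer instead of a random matrix.  The 1/order
    normalization is deliberately dropped: batch norm downstream absorbs
    the scale, while O(1) weight entries survive the optimizer's
    per-parameter step size far longer than O(1/order) entries would.
    """
    H = bank.signed_matrix  # (k, n_px)
    if bank.source == "hadamard_pair":
        return H.copy()
    dc = np.flatnonzero(bank.matrix.min(axis=1) > 0)
    W = 2.0 * H  # (k, n_px)
    if dc.size == 1:
        W[dc[0]] -= H.sum(axis=0)
    return W  # (n_meas, n_pixels)


class NetFLICS:
    """The three-segment reconstruction network (NumPy implementation)."""

    def __init__(self, cfg: NetConfig, bank: PatternBank | None = None,
                 dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(cfg.rng_seed)
        init_w = None
        if bank is not None:
            if bank.k != cfg.n_meas or bank.n_pixels != cfg.n_pixels:
                raise ValueError(
                    f"bank ({bank.k} patterns, {bank.n_pixels} px) inconsistent with "
                    f"config ({cfg.n_meas} measurements, {cfg.n_pixels} px)"
                )
            init_w = physics_init_weight(bank)
        self.dense = Dense(cfg.n_meas, cfg.n_pixels, rng, dtype,
                           weight=init_w, need_input_grad=False)
        cc = cfg.common_channels
        self.mix_conv = Conv2d(cfg.n_gates, cc, 1, rng, dtype)
        self.mix_bn = BatchNorm2d(cc, dtype)
        self.mix_relu = ReLU()
        self.int_res = ResBlock(cc, cfg.res_kernel, rng, dtype)
        self.int_recon = ReconBlock(cc, cfg.recon_c1, cfg.recon_c2,
                                    cfg.recon_k1, cfg.recon_k3, rng, dtype)
        self.life_conv = Conv1dGate(cfg.gate_filters, cfg.gate_kernel,
                                    cfg.gate_stride, rng, dtype)
        cl = cfg.gate_filters * cfg.gate_windows
        self.life_bn = BatchNorm2d(cl, dtype)
        self.life_relu = ReLU()
        self.life_res1 = ResBlock(cl, cfg.res_kernel, rng, dtype)
        self.life_res2 = ResBlock(cl, cfg.res_kernel, rng, dtype)
        self.life_recon1 = ReconBlock(cl, cfg.recon_c1, cfg.recon_c2,
                                      cfg.recon_k1, cfg.recon_k3, rng, dtype)
        self.life_recon2 = ReconBlock(1, max(cfg.recon_c1 // 4, 4),
                                      max(cfg.recon_c2 // 4, 4),
                                      cfg.recon_k1, cfg.recon_k3, rng, dtype)
        self.children = [
            self.dense, self.mix_conv, self.mix_bn, self.mix_relu,
            self.int_res, self.int_recon, self.life_conv, self.life_bn,
            self.life_relu, self.life_res1, self.life_res2,
            self.life_recon1, self.life_recon2,
        ]

    # -- parameter plumbing -------------------------------------------------

    def named_arrays(self, kind: str) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(_walk(self)):
            for name, arr in getattr(layer, kind).items():
                out[f"l{i:02d}.{name}"] = arr
        return out

    def parameters(self) -> dict[str, np.ndarray]:
        return self.named_arrays("params")

    def gradients(self) -> dict[str, np.ndarray]:
        return self.named_arrays("grads")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p:{k}": v for k, v in self.named_arrays("params").items()}
        state.update({f"b:{k}": v for k, v in self.named_arrays("buffers").items()})
        return {k: v.copy() for k, v in state.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_arrays("params")
        buffers = self.named_arrays("buffers")
        for key, arr in state.items():
            tag, name = key.split(":", 1)
            target = params if tag == "p" else buffers
            if name not in target:
                raise KeyError(f"unknown parameter {key!r} in state dict")
            target[name][...] = arr

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False):
        cfg = self.cfg
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (cfg.n_gates, cfg.n_meas):
            raise ValueError(
                f"input shape {x.shape[1:]} != (n_gates, n_meas) = "
                f"({cfg.n_gates}, {cfg.n_meas})"
            )
        x = np.ascontiguousarray(x, dtype=self.dtype)
        B = x.shape[0]
        h = self.dense.forward(x, training)  # (B, G, n_px)
        # transpose so pixel maps lead: channels-last (B, H, W, G) block
        block = np.ascontiguousarray(h.transpose(0, 2, 1)).reshape(
            B, cfg.img_side, cfg.img_side, cfg.n_gates)
        f0 = self.mix_relu.forward(
            self.mix_bn.forward(self.mix_conv.forward(block, training), training), training)
        # residual intensity head: the gate-sum of the common-segment block
        # is (with the backprojection-seeded dense layer) already an unbiased
        # intensity estimate, so the head only learns a correction
        baseline = block.sum(axis=3) / cfg.n_pixels
        intensity = baseline + self.int_recon.forward(
            self.int_res.forward(f0, training), training)[..., 0] * cfg.intensity_scale
        l = self.life_relu.forward(
            self.life_bn.forward(self.life_conv.forward(block, training), training), training)
        l = self.life_res2.forward(self.life_res1.forward(l, training), training)
        tau = self.life_recon2.forward(
            self.life_recon1.forward(l, training), training)[..., 0]
        return intensity, tau * cfg.lifetime_scale

    def backward(self, d_int: np.ndarray, d_tau: np.ndarray) -> None:
        cfg = self.cfg
        B = d_int.shape[0]
        d_int = (d_int * cfg.intensity_scale).astype(self.dtype)
        d_tau = (d_tau * cfg.lifetime_scale).astype(self.dtype)
        dl = self.life_recon1.backward(self.life_recon2.backward(d_tau[..., None]))
        dl = self.life_res1.backward(self.life_res2.backward(dl))
        dblock_l = self.life_conv.backward(
            self.life_bn.backward(self.life_relu.backward(dl)))
        di = self.int_res.backward(self.int_recon.backward(d_int[..., None]))
        dblock_i = self.mix_conv.backward(
            self.mix_bn.backward(self.mix_relu.backward(di)))
        dblock = dblock_l + dblock_i
        # gradient through the residual intensity baseline (gate-sum / n_px)
        dblock += (d_int / (cfg.intensity_scale * cfg.n_pixels))[..., None]
        dblock = dblock.reshape(B, cfg.n_pixels, cfg.n_gates)
        self.dense.backward(np.ascontiguousarray(dblock.transpose(0, 2, 1)))


def build_model(cfg: NetConfig, bank: PatternBank | None = None) -> NetFLICS:
    """Construct an untrained network (optionally physics-initialized)."""
    return NetFLICS(cfg, bank=bank)


# ---------------------------------------------------------------------------
# loss, optimizer, schedule
# ---------------------------------------------------------------------------

def loss_value(pred_int, pred_tau, true_int, true_tau, weight: float = 1e5) -> float:
    """``MSE(intensity) + weight * MSE(lifetime)``, means over batch and pixels."""
    if pred_int.shape != true_int.shape or pred_tau.shape != true_tau.shape:
        raise ValueError("prediction/target shape mismatch")
    mse_i = float(np.mean((np.asarray(pred_int, np.float64) - true_int) ** 2))
    mse_t = float(np.mean((np.asarray(pred_tau, np.float64) - true_tau) ** 2))
    return mse_i + weight * mse_t


def loss_and_grads(pred_int, pred_tau, true_int, true_tau, weight: float = 1e5):
    """Loss plus its gradients with respect to the two predictions."""
    if pred_int.shape != true_int.shape or pred_tau.shape != true_tau.shape:
        raise ValueError("prediction/target shape mismatch")
    n = pred_int.size
    ri = pred_int - true_int
    rt = pred_tau - true_tau
    loss = float(np.mean(ri.astype(np.float64) ** 2)
                 + weight * np.mean(rt.astype(np.float64) ** 2))
    return loss, (2.0 / n) * ri, (2.0 * weight / n) * rt


def learning_rate(base_lr: float, epoch: int, halving_period: int = 10) -> float:
    """Step schedule: lr(e) = base_lr * 0.5 ** floor(e / period)."""
    return base_lr * 0.5 ** (epoch // halving_period)


class RMSprop:
    """Keras-convention RMSprop: cache = rho*cache + (1-rho)*g^2."""

    def __init__(self, params: dict[str, np.ndarray], rho=0.9, eps=1e-7):
        self.rho, self.eps = rho, eps
        self.cache = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, lr: float) -> None:
        for k, p in params.items():
            g = grads[k].astype(p.dtype)
            c = self.cache[k]
            c *= self.rho
            c += (1 - self.rho) * g * g
            p -= lr * g / (np.sqrt(c) + self.eps)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def make_training_arrays(
    samples: Sequence[tuple[MeasurementSet, LifetimeScene]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (measurements, scene) pairs into network input/target arrays.

    Targets are the ground-truth images with background lifetime exactly 0,
    so the network learns to silence background pixels itself.
    """
    X = np.stack([m.data for m, _ in samples]).astype(np.float32)
    Yi = np.stack([s.intensity for _, s in samples]).astype(np.float32)
    Yt = np.stack([s.lifetime for _, s in samples]).astype(np.float32)
    return X, Yi, Yt


@dataclass
class TrainedModel:
    """Best-epoch parameters plus the full training history."""

    model: NetFLICS
    config: NetConfig
    history: list[dict]
    best_epoch: int

    def save(self, path: str) -> None:
        np.savez(path if path.endswith(".npz") else path + ".npz",
                 **self.model.state_dict())
        side = (path[:-4] if path.endswith(".npz") else path) + ".json"
        with open(side, "w") as fh:
            json.dump({"config": asdict(self.config), "history": self.history,
                       "best_epoch": self.best_epoch}, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json") as fh:
            meta = json.load(fh)
        cfg = NetConfig(**meta["config"])
        model = NetFLICS(cfg)
        with np.load(base + ".npz") as arc:
            model.load_state_dict(dict(arc))
        return cls(model=model, config=cfg, history=meta["history"],
                   best_epoch=meta["best_epoch"])


def _eval_mae(model: NetFLICS, X, Yi, Yt, batch: int) -> tuple[float, float]:
    n = X.shape[0]
    se_i = se_t = 0.0
    for i in range(0, n, batch):
        pi, pt = model.forward(X[i : i + batch], training=False)
        se_i += float(np.abs(pi - Yi[i : i + batch]).sum())
        se_t += float(np.abs(pt - Yt[i : i + batch]).sum())
    px = Yi[0].size
    return se_i / (n * px), se_t / (n * px)


def train(
    model: NetFLICS,
    train_set: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray, np.ndarray],
    cfg: NetConfig | None = None,
    verbose: bool = False,
    resample_noise: bool = False,
) -> TrainedModel:
    """RMSprop training with the step LR schedule and early stopping.

    Stops when the validation lifetime MAE has not improved for
    ``cfg.patience`` consecutive epochs and restores the best-epoch state
    (the model with the lowest validation lifetime error).

    With ``resample_noise`` the training inputs are treated as noiseless
    photon means and a fresh Poisson realization is drawn every epoch —
    each draw comes from exactly the acquisition noise model, so a small
    scene set yields an effectively unlimited stream of noisy samples.
    """
    cfg = cfg or model.cfg
    Xtr, Yi_tr, Yt_tr = train_set
    Xva, Yi_va, Yt_va = val_set
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("training and validation sets must be non-empty")
    params = model.parameters()
    opt = RMSprop(params)
    rng = np.random.default_rng(cfg.rng_seed + 1)
    history: list[dict] = []
    best = (np.inf, -1, None)  # (val tau MAE, epoch, state)
    n = len(Xtr)
    px = Yi_tr[0].size
    for epoch in range(cfg.max_epochs):
        lr = learning_rate(cfg.base_lr, epoch, cfg.lr_halving_period)
        order = rng.permutation(n)
        if resample_noise:
            Xep = rng.poisson(Xtr).astype(np.float32)
        else:
            Xep = Xtr
        run_loss = run_ai = run_at = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            pi, pt = model.forward(Xep[idx], training=True)
            loss, d_int, d_tau = loss_and_grads(
                pi, pt, Yi_tr[idx], Yt_tr[idx], cfg.lifetime_loss_weight)
            model.backward(d_int, d_tau)
            opt.step(params, model.gradients(), lr)
            run_loss += loss * len(idx)
            run_ai += float(np.abs(pi - Yi_tr[idx]).sum())
            run_at += float(np.abs(pt - Yt_tr[idx]).sum())
        val_ai, val_at = _eval_mae(model, Xva, Yi_va, Yt_va, cfg.batch_size)
        entry = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": run_loss / n,
            "train_intensity_mae": run_ai / (n * px),
            "train_lifetime_mae": run_at / (n * px),
            "val_intensity_mae": val_ai,
            "val_lifetime_mae": val_at,
        }
        history.append(entry)
        if verbose:
            print(
                f"epoch {epoch:3d} lr {lr:.2e} loss {entry['train_loss']:.4f} "
                f"val int MAE {val_ai:.3f} val tau MAE {val_at:.4f}"
            )
        if val_at < best[0]:
            best = (val_at, epoch, model.state_dict())
        elif epoch - best[1] >= cfg.patience:
            break
    if best[2] is not None:
        model.load_state_dict(best[2])
    return TrainedModel(model=model, config=cfg, history=history, best_epoch=best[1])


def predict(
    trained: TrainedModel | NetFLICS,
    measurements: MeasurementSet | Sequence[MeasurementSet] | np.ndarray,
) -> list[ReconResult]:
    """Single forward pass; no post-processing.  Returns one result per sample."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    if isinstance(measurements, MeasurementSet):
        mlist = [measurements]
    elif isinstance(measurements, np.ndarray):
        mlist = None
        X = measurements if measurements.ndim == 3 else measurements[None]
        ids = [""] * len(X)
    else:
        mlist = list(measurements)
    if mlist is not None:
        X = np.stack([m.data for m in mlist]).astype(np.float32)
        ids = [m.scene_id for m in mlist]
    results = []
    bs = model.cfg.batch_size
    for i in range(0, len(X), bs):
        pi, pt = model.forward(X[i : i + bs], training=False)
        for j in range(len(pi)):
            results.append(
                ReconResult(
                    intensity=np.asarray(pi[j], dtype=np.float64),
                    lifetime=np.asarray(pt[j], dtype=np.float64),
                    method="netflics",
                    scene_id=ids[i + j],
                )
            )
    return results
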