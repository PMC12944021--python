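"""Dense (per-frame) sequence labellers: 1D CNN, GRU, and the two hybrids.

Every architecture maps an n-channel window of T frames to a T x C matrix of
per-frame class probabilities, for arbitrary T — no input padding is used to
equalise window lengths.  Models are built from a small NumPy layer engine
with hand-written backward passes (convolution, GRU backprop-through-time,
batch normalisation, dropout, per-frame affine head), so the forward
arithmetic is exactly the textbook equations:

convolution, per output feature and valid position t (then striding):

    o_t = ReLU( sum_{i=1..k} w_i . x_{t+i-1} + b )

GRU cell, per time step:

    z_t = A(Wz x_t + Uz h_{t-1} + bz)          (update gate)
    r_t = A(Wr x_t + Ur h_{t-1} + br)          (reset gate)
    h~_t = tanh(Wh x_t + Uh (r_t * h_{t-1}) + bh)
    h_t = (1 - z_t) * h_{t-1} + z_t * h~_t

with A the logistic sigmoid and * elementwise.  Stride-shortened conv feature
sequences are edge-padded to ceil(T/stride) and restored to length T by
nearest-neighbour upsampling before the next block and before the softmax
head, so every family preserves the frame count.  Argmax ties break to the
lowest class index.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import SignalWindow

FAMILIES = ("cnn", "gru", "convrec", "reconv")


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvLayerSpec:
    """One 1-D convolutional layer: kernel bank, stride, regularisation."""

    kernel_count: int
    kernel_size: int
    stride: int = 1
    dropout_rate: float = 0.3
    batch_norm: bool = True
    weights: np.ndarray | None = None  # (kernel_count, in_channels, kernel_size)
    bias: np.ndarray | None = None  # (kernel_count,)

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.stride < 1 or self.kernel_count < 1:
            raise ValueError("kernel_count, kernel_size and stride must be >= 1")


@dataclass(frozen=True)
class GRUCellParams:
    """Explicit GRU cell parameters; matrices act on column vectors (W @ x)."""

    Wz: np.ndarray
    Wr: np.ndarray
    Wh: np.ndarray
    Uz: np.ndarray
    Ur: np.ndarray
    Uh: np.ndarray
    bz: np.ndarray
    br: np.ndarray
    bh: np.ndarray
    activation: Callable[[np.ndarray], np.ndarray] = sigmoid

    def __post_init__(self) -> None:
        H, F = np.shape(self.Wz)
        for name in ("Wr", "Wh"):
            if np.shape(getattr(self, name)) != (H, F):
                raise ValueError(f"{name} must have shape {(H, F)}")
        for name in ("Uz", "Ur", "Uh"):
            if np.shape(getattr(self, name)) != (H, H):
                raise ValueError(f"{name} must have shape {(H, H)}")
        for name in ("bz", "br", "bh"):
            if np.shape(getattr(self, name)) != (H,):
                raise ValueError(f"{name} must have shape {(H,)}")

    @property
    def hidden_size(self) -> int:
        return self.Wz.shape[0]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture family plus hyperparameters.

    ``conv_specs`` configures the convolutional block (cnn / convrec / reconv);
    ``gru_units`` the recurrent block (gru / convrec / reconv).  Hybrids must
    have both blocks non-empty.
    """

    family: str
    input_channels: int
    class_count: int
    conv_specs: tuple[ConvLayerSpec, ...] = ()
    gru_units: tuple[int, ...] = ()
    bidirectional: bool = True
    dropout_rate: float = 0.3
    learning_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected {FAMILIES}")
        if self.family in ("cnn", "convrec", "reconv") and not self.conv_specs:
            raise ValueError(f"family {self.family} requires conv_specs")
        if self.family in ("gru", "convrec", "reconv") and not self.gru_units:
            raise ValueError(f"family {self.family} requires gru_units")
        if self.family == "cnn" and self.gru_units:
            raise ValueError("cnn family takes no gru_units")
        if self.class_count < 2 or self.input_channels < 1:
            raise ValueError("need class_count >= 2 and input_channels >= 1")

    @property
    def min_window_len(self) -> int:
        return max((s.kernel_size for s in self.conv_specs), default=1)


@dataclass(frozen=True)
class FramePredictions:
    """Row-stochastic T x C probabilities plus the argmax label per frame."""

    probabilities: np.ndarray
    argmax_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", probs)
        if probs.ndim != 2:
            raise ValueError("probabilities must be T x C")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        if self.argmax_labels is None:
            object.__setattr__(self, "argmax_labels", probs.argmax(axis=1))

    @property
    def n_frames(self) -> int:
        return self.probabilities.shape[0]


# ---------------------------------------------------------------------------
# functional forms of the two core operations
# ---------------------------------------------------------------------------

def conv1d(
    window: SignalWindow | np.ndarray, spec: ConvLayerSpec, pad: bool = True
) -> np.ndarray:
    """Strided valid 1-D convolution with ReLU over a channels x time matrix.

    Output feature at valid position t is ReLU of the kernel-window inner
    product (summed over channels and the k in-window frames) plus bias;
    positions advance by ``spec.stride``.  With ``pad=True`` the feature
    sequence is symmetrically edge-padded to length ceil(T / stride).
    ``spec.weights`` may be (kernel_count, n, k) or, for a single kernel on a
    single channel, a length-k vector.
    """
    x = window.values if isinstance(window, SignalWindow) else np.asarray(window, float)
    if x.ndim == 1:
        x = x[None, :]
    n, T = x.shape
    k, stride = spec.kernel_size, spec.stride
    if T < k:
        raise ValueError(
            f"window length {T} is below the minimum window length {k} "
            f"(kernel size) for this layer"
        )
    W = np.asarray(spec.weights, dtype=float)
    if W.ndim == 1:
        W = W.reshape(1, 1, -1)
    if W.shape != (spec.kernel_count, n, k):
        raise ValueError(f"weights must have shape {(spec.kernel_count, n, k)}")
    b = np.zeros(spec.kernel_count) if spec.bias is None else np.atleast_1d(spec.bias)

    xw = sliding_window_view(x, k, axis=1)[:, ::stride]  # (n, V, k)
    out = np.maximum(np.einsum("nvk,onk->ov", xw, W) + b[:, None], 0.0)
    if pad:
        P = -(-T // stride)
        total = P - out.shape[1]
        left = total // 2
        out = np.pad(out, ((0, 0), (left, total - left)), mode="edge")
    return out


def gru_step(
    x_t: np.ndarray, h_prev: np.ndarray, params: GRUCellParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One GRU update on vectors; returns (h_t, z_t, r_t, h_candidate)."""
    x_t = np.asarray(x_t, float)
    h_prev = np.asarray(h_prev, float)
    H, F = params.Wz.shape
    if x_t.shape != (F,) or h_prev.shape != (H,):
        raise ValueError(
            f"expected x_t of shape {(F,)} and h_prev of shape {(H,)}; "
            f"got {x_t.shape} and {h_prev.shape}"
        )
    A = params.activation
    z = A(params.Wz @ x_t + params.Uz @ h_prev + params.bz)
    r = A(params.Wr @ x_t + params.Ur @ h_prev + params.br)
    h_cand = np.tanh(params.Wh @ x_t + params.Uh @ (r * h_prev) + params.bh)
    h_t = (1.0 - z) * h_prev + z * h_cand
    return h_t, z, r, h_cand


# ---------------------------------------------------------------------------
# layer engine: forward caches what backward needs; grads accumulate per batch
# ---------------------------------------------------------------------------

class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def out_features(self) -> int:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-1], shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv1DLayer(Layer):
    """Valid strided conv + ReLU + edge-pad to ceil(T/stride) + nearest
    upsample back to the layer's input length, so frame count is preserved."""

    def __init__(self, in_channels: int, spec: ConvLayerSpec, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.spec = spec
        O, k = spec.kernel_count, spec.kernel_size
        W = (
            np.asarray(spec.weights, float)
            if spec.weights is not None
            else _glorot(rng, (O, in_channels, k)).reshape(O, in_channels, k)
        )
        b = np.asarray(spec.bias, float) if spec.bias is not None else np.zeros(O)
        self.params = {"W": W, "b": b}
        self.zero_grads()

    @property
    def out_features(self) -> int:
        return self.spec.kernel_count

    def forward(self, x, training, rng):
        B, T, F = x.shape
        k, stride = self.spec.kernel_size, self.spec.stride
        if T < k:
            raise ValueError(
                f"window length {T} is below the minimum window length {k} "
                "(kernel size) for this conv layer"
            )
        xw = sliding_window_view(x, k, axis=1)[:, ::stride]  # (B, V, F, k)
        z = np.einsum("bvfk,ofk->bvo", xw, self.params["W"]) + self.params["b"]
        a = np.maximum(z, 0.0)
        P = -(-T // stride)
        V = a.shape[1]
        left = (P - V) // 2
        padded = np.pad(a, ((0, 0), (left, P - V - left), (0, 0)), mode="edge")
        up_idx = np.minimum((np.arange(T) * P) // T, P - 1)
        out = padded[:, up_idx]
        self._cache = (x.shape, xw, z, V, left, P, up_idx)
        return out

    def backward(self, dy):
        (B, T, F), xw, z, V, left, P, up_idx = self._cache
        k, stride = self.spec.kernel_size, self.spec.stride
        # undo nearest upsample: scatter-add over source positions
        dP = np.zeros((P, B, dy.shape[2]))
        np.add.at(dP, up_idx, dy.transpose(1, 0, 2))
        dP = dP.transpose(1, 0, 2)
        # undo edge padding: edge gradients fold into the first/last valid position
        da = dP[:, left : left + V].copy()
        if left:
            da[:, 0] += dP[:, :left].sum(axis=1)
        if left + V < P:
            da[:, -1] += dP[:, left + V :].sum(axis=1)
        dz = da * (z > 0.0)
        self.grads["W"] += np.einsum("bvfk,bvo->ofk", xw, dz)
        self.grads["b"] += dz.sum(axis=(0, 1))
        dxw = np.einsum("bvo,ofk->bvfk", dz, self.params["W"])
        dxt = np.zeros((T, B, F))
        starts = np.arange(V) * stride
        for i in range(k):
            np.add.at(dxt, starts + i, dxw[:, :, :, i].transpose(1, 0, 2))
        return dxt.transpose(1, 0, 2)


class _GRUDirection:
    """One direction of a GRU layer; batched over windows of equal length."""

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        p = {}
        for g in "zrh":
            p[f"W{g}"] = _glorot(rng, (hidden, in_features)).T  # stored (F, H)
            p[f"U{g}"] = _glorot(rng, (hidden, hidden)).T
            p[f"b{g}"] = np.zeros(hidden)
        self.params = p
        self.zero_grads()

    def zero_grads(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def cell_params(self) -> GRUCellParams:
        p = self.params
        return GRUCellParams(
            Wz=p["Wz"].T, Wr=p["Wr"].T, Wh=p["Wh"].T,
            Uz=p["Uz"].T, Ur=p["Ur"].T, Uh=p["Uh"].T,
            bz=p["bz"], br=p["br"], bh=p["bh"],
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, F = x.shape
        H = self.hidden
        p = self.params
        xz = x @ p["Wz"] + p["bz"]
        xr = x @ p["Wr"] + p["br"]
        xh = x @ p["Wh"] + p["bh"]
        hs = np.zeros((T + 1, B, H))
        z = np.empty((T, B, H))
        r = np.empty((T, B, H))
        hc = np.empty((T, B, H))
        for t in range(T):
            h_prev = hs[t]
            z[t] = sigmoid(xz[:, t] + h_prev @ p["Uz"])
            r[t] = sigmoid(xr[:, t] + h_prev @ p["Ur"])
            hc[t] = np.tanh(xh[:, t] + (r[t] * h_prev) @ p["Uh"])
            hs[t + 1] = (1.0 - z[t]) * h_prev + z[t] * hc[t]
        self._cache = (x, hs, z, r, hc)
        return hs[1:].transpose(1, 0, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, hs, z, r, hc = self._cache
        B, T, F = x.shape
        p, g = self.params, self.grads
        dx = np.empty_like(x)
        dh_next = np.zeros((B, self.hidden))
        for t in range(T - 1, -1, -1):
            dh = dy[:, t] + dh_next
            h_prev = hs[t]
            dz = dh * (hc[t] - h_prev)
            dhc = dh * z[t]
            dhp = dh * (1.0 - z[t])
            dhc_pre = dhc * (1.0 - hc[t] ** 2)
            xt = x[:, t]
            g["Wh"] += xt.T @ dhc_pre
            g["Uh"] += (r[t] * h_prev).T @ dhc_pre
            g["bh"] += dhc_pre.sum(axis=0)
            drh = dhc_pre @ p["Uh"].T
            dr = drh * h_prev
            dhp = dhp + drh * r[t]
            dz_pre = dz * z[t] * (1.0 - z[t])
            dr_pre = dr * r[t] * (1.0 - r[t])
            g["Wz"] += xt.T @ dz_pre
            g["Uz"] += h_prev.T @ dz_pre
            g["bz"] += dz_pre.sum(axis=0)
            g["Wr"] += xt.T @ dr_pre
            g["Ur"] += h_prev.T @ dr_pre
            g["br"] += dr_pre.sum(axis=0)
            dhp = dhp + dz_pre @ p["Uz"].T + dr_pre @ p["Ur"].T
            dx[:, t] = dz_pre @ p["Wz"].T + dr_pre @ p["Wr"].T + dhc_pre @ p["Wh"].T
            dh_next = dhp
        return dx


class GRULayer(Layer):
    """(Bi)directional GRU over the full window; outputs per-frame states.

    Bidirectional runs a second cell on the time-reversed window and
    concatenates forward and backward states per frame.
    """

    def __init__(self, in_features: int, hidden: int, bidirectional: bool,
                 rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.bidirectional = bidirectional
        self.fwd = _GRUDirection(in_features, hidden, rng)
        self.bwd = _GRUDirection(in_features, hidden, rng) if bidirectional else None
        self._sync_params()

    def _sync_params(self):
        self.params = {f"fwd_{k}": v for k, v in self.fwd.params.items()}
        self.grads = {f"fwd_{k}": v for k, v in self.fwd.grads.items()}
        if self.bwd is not None:
            self.params.update({f"bwd_{k}": v for k, v in self.bwd.params.items()})
            self.grads.update({f"bwd_{k}": v for k, v in self.bwd.grads.items()})

    def zero_grads(self):
        self.fwd.zero_grads()
        if self.bwd is not None:
            self.bwd.zero_grads()
        self._sync_params()

    @property
    def out_features(self) -> int:
        return self.hidden * (2 if self.bidirectional else 1)

    def forward(self, x, training, rng):
        out = self.fwd.forward(x)
        if self.bwd is not None:
            out_b = self.bwd.forward(x[:, ::-1])[:, ::-1]
            out = np.concatenate([out, out_b], axis=2)
        return out

    def backward(self, dy):
        if self.bwd is None:
            dx = self.fwd.backward(dy)
        else:
            H = self.hidden
            dx = self.fwd.backward(dy[:, :, :H])
            dx = dx + self.bwd.backward(dy[:, ::-1, H:])[:, ::-1]
        self._sync_params()
        return dx


class BatchNormLayer(Layer):
    """Per-feature normalisation with statistics pooled over batch and time;
    running statistics are frozen and used at evaluation."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.n_features = n_features
        self.zero_grads()

    @property
    def out_features(self) -> int:
        return self.n_features

    def forward(self, x, training, rng):
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._cache = (xhat, ivar, x.shape[0] * x.shape[1], training)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, ivar, N, training = self._cache
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] += dy.sum(axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        if not training:
            return dxhat * ivar
        return (ivar / N) * (
            N * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )


class DropoutLayer(Layer):
    """Inverted dropout; identity at evaluation."""

    def __init__(self, rate: float, n_features: int):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.n_features = n_features

    @property
    def out_features(self) -> int:
        return self.n_features

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class DenseLayer(Layer):
    """Per-frame affine map (shared across frames) — the softmax head's logits."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": _glorot(rng, (out_features, in_features)).T,
            "b": np.zeros(out_features),
        }
        self._out = out_features
        self.zero_grads()

    @property
    def out_features(self) -> int:
        return self._out

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] += np.einsum("btf,btc->fc", self._x, dy)
        self.grads["b"] += dy.sum(axis=(0, 1))
        return dy @ self.params["W"].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def named_parameters(self):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"layer{i}.{name}", layer.params[name], layer.grads[name]


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

class DenseLabeller:
    """A frame-level activity classifier: config + layer stack + softmax head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        layers: list[Layer] = []
        width = config.input_channels

        def conv_block():
            nonlocal width
            for spec in config.conv_specs:
                layers.append(Conv1DLayer(width, spec, rng))
                width = spec.kernel_count
                layers.append(DropoutLayer(spec.dropout_rate, width))
                if spec.batch_norm:
                    layers.append(BatchNormLayer(width))

        def gru_block():
            nonlocal width
            for units in config.gru_units:
                layers.append(GRULayer(width, units, config.bidirectional, rng))
                width = layers[-1].out_features
                layers.append(DropoutLayer(config.dropout_rate, width))
                layers.append(BatchNormLayer(width))

        if config.family == "cnn":
            conv_block()
        elif config.family == "gru":
            gru_block()
        elif config.family == "convrec":
            conv_block()
            gru_block()
        else:  # reconv
            gru_block()
            conv_block()
        layers.append(DenseLayer(width, config.class_count, rng))
        self.net = Sequential(layers)

    # -- inference ---------------------------------------------------------

    def _check_window(self, values: np.ndarray) -> None:
        n, T = values.shape
        if n != self.config.input_channels:
            raise ValueError(
                f"model expects {self.config.input_channels} channels, window has {n}"
            )
        if T < self.config.min_window_len:
            raise ValueError(
                f"window length {T} is below the minimum window length "
                f"{self.config.min_window_len} (largest kernel size)"
            )

    def forward_logits(
        self, x: np.ndarray, training: bool, rng: np.random.Generator
    ) -> np.ndarray:
        return self.net.forward(x, training, rng)

    def predict(self, window: SignalWindow | np.ndarray) -> FramePredictions:
        """Evaluation-mode forward on one variable-length window (any T)."""
        values = window.values if isinstance(window, SignalWindow) else np.asarray(window, float)
        self._check_window(values)
        logits = self.net.forward(values.T[None], training=False, rng=None)
        probs = softmax(logits[0])
        return FramePredictions(probabilities=probs)

    # -- serialisation -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {name: arr for name, arr, _ in self.net.named_parameters()}
        for i, layer in enumerate(self.net.layers):
            if isinstance(layer, BatchNormLayer):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for name, arr, _ in self.net.named_parameters():
            arr[...] = state[name]
        for i, layer in enumerate(self.net.layers):
            if isinstance(layer, BatchNormLayer):
                layer.running_mean = np.array(state[f"layer{i}.running_mean"])
                layer.running_var = np.array(state[f"layer{i}.running_var"])

    def save(self, path: str | Path) -> Path:
        """Single-archive model state: config JSON + flat named arrays."""
        path = Path(path)
        cfg = json.loads(json.dumps(self.config, default=_config_encoder))
        np.savez_compressed(
            path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            **self.state_arrays(),
        )
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "DenseLabeller":
        with np.load(path) as archive:
            cfg = json.loads(bytes(archive["__config__"]).decode())
            model = cls(config_from_dict(cfg))
            model.load_state_arrays({k: archive[k] for k in archive.files if k != "__config__"})
        return model


def _config_encoder(obj):
    if isinstance(obj, ModelConfig):
        d = obj.__dict__.copy()
        d["conv_specs"] = [s.__dict__ for s in obj.conv_specs]
        return d
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(type(obj))


def config_from_dict(d: dict) -> ModelConfig:
    specs = tuple(
        ConvLayerSpec(**{
            **s,
            "weights": np.array(s["weights"]) if s.get("weights") is not None else None,
            "bias": np.array(s["bias"]) if s.get("bias") is not None else None,
        })
        for s in d.get("conv_specs", [])
    )
    return ModelConfig(**{**d, "conv_specs": specs, "gru_units": tuple(d.get("gru_units", ()))})


def forward(model: DenseLabeller, window: SignalWindow | np.ndarray) -> FramePredictions:
    """Evaluation-mode per-frame class probabilities for one window."""
    return model.predict(window)


def assemble_hybrid(family: str, config: ModelConfig, seed: int = 0) -> DenseLabeller:
    """Build a ConvRec (conv block then GRU) or ReConv (GRU then conv) model."""
    if family not in ("convrec", "reconv"):
        raise ValueError(f"hybrid family must be convrec or reconv, got {family!r}")
    if config.family != family:
        config = replace(config, family=family)
    return DenseLabeller(config, seed=seed)


# ---------------------------------------------------------------------------
# named presets
# ---------------------------------------------------------------------------

def gru_preset(
    input_channels: int = 6,
    class_count: int = 9,
    reading: str = "three_layer",
) -> ModelConfig:
    """The tuned bidirectional GRU architecture.

    The published description of the block structure admits two readings;
    both are selectable: ``three_layer`` (a two-layer first block followed by
    a one-layer second block, all 128 units) and ``two_layer`` (one layer per
    block, 128 units each).
    """
    units = {"three_layer": (128, 128, 128), "two_layer": (128, 128)}
    if reading not in units:
        raise ValueError(f"reading must be one of {sorted(units)}")
    return ModelConfig(
        family="gru", input_channels=input_channels, class_count=class_count,
        gru_units=units[reading], bidirectional=True, dropout_rate=0.3,
        learning_rate=0.01,
    )


def reduced_gru_preset(
    input_channels: int = 6, class_count: int = 9, hidden: int = 32
) -> ModelConfig:
    """Narrow single-layer bidirectional GRU for desk-scale CPU runs."""
    return ModelConfig(
        family="gru", input_channels=input_channels, class_count=class_count,
        gru_units=(hidden,), bidirectional=True, dropout_rate=0.3,
        learning_rate=0.01,
    )


def reduced_family_preset(
    family: str, input_channels: int = 6, class_count: int = 9
) -> ModelConfig:
    """Small members of each architecture family for desk-scale comparisons."""
    conv = (ConvLayerSpec(kernel_count=32, kernel_size=5, stride=1),)
    if family == "cnn":
        return ModelConfig(
            family="cnn", input_channels=input_channels, class_count=class_count,
            conv_specs=(
                ConvLayerSpec(kernel_count=32, kernel_size=7, stride=1),
                ConvLayerSpec(kernel_count=32, kernel_size=5, stride=1),
            ),
            learning_rate=0.01,
        )
    if family == "gru":
        return reduced_gru_preset(input_channels, class_count)
    if family in ("convrec", "reconv"):
        return ModelConfig(
            family=family, input_channels=input_channels, class_count=class_count,
            conv_specs=conv, gru_units=(32,), bidirectional=True, learning_rate=0.01,
        )
    raise ValueError(f"unknown family {family!r}")
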