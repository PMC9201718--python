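"""SparNet: a region-parallel 1-D convolutional network with
squeeze-and-excitation (SE) channel attention, in pure numpy.

Architecture (frequency representation, feature length 40):

  per region (C, F, O, P, T):   SE(r=2) -> Conv1d(width 5, 1 filter, valid)
                                -> ReLU -> MaxPool(2, stride 2)
  merge:                        concatenate the five branch outputs as a
                                5-channel map
  global:                       SE(r=2) -> Conv1d(5 in-channels, width 2)
                                -> ReLU -> MaxPool(2, stride 2)
                                -> Dense(2) -> softmax

Every layer implements ``forward`` and ``backward`` (analytic gradients);
training uses RMSprop.  The SE bottleneck layers carry no biases; conv and
dense layers do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SEBlock",
    "Conv1d",
    "MaxPool1d",
    "Dense",
    "SparNet",
    "ArchitectureSpec",
    "se_forward",
    "softmax",
    "cross_entropy",
    "RMSprop",
]

EPS_LOGP = 1e-12


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Layers


class SEBlock:
    """Squeeze-and-excitation attention over channels of a (B, C, L) map.

    squeeze: per-channel mean over length; excitation: sigmoid(W2 relu(W1 z))
    through a bottleneck of width floor(C/r); scale: multiply each channel by
    its gate.  No bias terms.
    """

    def __init__(self, channels: int, reduction: int = 2, rng: np.random.Generator | None = None):
        self.channels = channels
        self.reduction = reduction
        hidden = max(channels // reduction, 1)
        self.hidden = hidden
        rng = rng or np.random.default_rng(0)
        b1 = 1.0 / np.sqrt(channels)
        b2 = 1.0 / np.sqrt(hidden)
        self.params = {
            "W1": rng.uniform(-b1, b1, size=(hidden, channels)),
            "W2": rng.uniform(-b2, b2, size=(channels, hidden)),
        }
        self._cache = None

    def forward(self, u: np.ndarray) -> np.ndarray:
        if u.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {u.shape[1]}")
        W1, W2 = self.params["W1"], self.params["W2"]
        z = u.mean(axis=2)                     # (B, C) squeeze
        a = z @ W1.T                           # (B, H)
        h = np.maximum(a, 0.0)                 # ReLU
        b = h @ W2.T                           # (B, C)
        s = _sigmoid(b)                        # gates in (0, 1)
        out = u * s[:, :, None]
        self._cache = (u, z, a, h, s)
        return out

    @property
    def last_gates(self) -> np.ndarray:
        return self._cache[4]

    def backward(self, g: np.ndarray):
        u, z, a, h, s = self._cache
        L = u.shape[2]
        du = g * s[:, :, None]
        ds = np.einsum("bcl,bcl->bc", g, u)
        db = ds * s * (1.0 - s)
        dW2 = db.T @ h
        dh = db @ self.params["W2"]
        da = dh * (a > 0)
        dW1 = da.T @ z
        dz = da @ self.params["W1"]
        du += dz[:, :, None] / L
        return du, {"W1": dW1, "W2": dW2}

    def count_params(self) -> int:
        return self.params["W1"].size + self.params["W2"].size


class Conv1d:
    """Valid (no padding) 1-D convolution over a (B, C_in, L) map, stride 1."""

    def __init__(self, in_channels: int, width: int, n_filters: int = 1,
                 rng: np.random.Generator | None = None):
        self.in_channels = in_channels
        self.width = width
        self.n_filters = n_filters
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_channels * width)
        self.params = {
            "W": rng.uniform(-bound, bound, size=(n_filters, in_channels, width)),
            "b": np.zeros(n_filters),
        }
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        if x.shape[2] < self.width:
            raise ValueError("input shorter than kernel width")
        xs = sliding_window_view(x, self.width, axis=2)  # (B, C, L_out, K)
        out = np.einsum("bclk,fck->bfl", xs, self.params["W"]) + self.params["b"][None, :, None]
        self._cache = (x, xs)
        return out

    def backward(self, g: np.ndarray):
        x, xs = self._cache
        W = self.params["W"]
        dW = np.einsum("bclk,bfl->fck", xs, g)
        db = g.sum(axis=(0, 2))
        K = self.width
        gpad = np.pad(g, ((0, 0), (0, 0), (K - 1, K - 1)))
        gs = sliding_window_view(gpad, K, axis=2)  # (B, F, L_in, K)
        dx = np.einsum("bflk,fck->bcl", gs, W[:, :, ::-1])
        return dx, {"W": dW, "b": db}

    def count_params(self) -> int:
        return self.params["W"].size + self.params["b"].size


class ReLU:
    params: dict = {}

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask, {}

    def count_params(self):
        return 0


class MaxPool1d:
    """Max pooling with window ``size`` and equal stride; trailing remainder dropped."""

    def __init__(self, size: int = 2):
        self.size = size
        self.params: dict = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        L2 = L // self.size
        xr = x[:, :, : L2 * self.size].reshape(B, C, L2, self.size)
        self._arg = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, g: np.ndarray):
        B, C, L = self._in_shape
        L2 = g.shape[2]
        dxr = np.zeros((B, C, L2, self.size))
        bi, ci, li = np.meshgrid(
            np.arange(B), np.arange(C), np.arange(L2), indexing="ij"
        )
        dxr[bi, ci, li, self._arg] = g
        dx = np.zeros((B, C, L))
        dx[:, :, : L2 * self.size] = dxr.reshape(B, C, L2 * self.size)
        return dx, {}

    def count_params(self):
        return 0


class Dense:
    """Fully connected layer with bias on a flat (B, n_in) input."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(n_in)
        self.params = {
            "W": rng.uniform(-bound, bound, size=(n_out, n_in)),
            "b": np.zeros(n_out),
        }

    def forward(self, x):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, g):
        dW = g.T @ self._x
        db = g.sum(axis=0)
        dx = g @ self.params["W"]
        return dx, {"W": dW, "b": db}

    def count_params(self):
        return self.params["W"].size + self.params["b"].size


# ---------------------------------------------------------------------------
# Functional pieces


def se_forward(u: np.ndarray, W1: np.ndarray, W2: np.ndarray):
    """Single-sample SE transform of a (C, L) map; returns (scaled map, gates)."""
    block = SEBlock(u.shape[0])
    block.params["W1"], block.params["W2"] = W1, W2
    out = block.forward(u[None])
    return out[0], block.last_gates[0]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(p: np.ndarray, onehot: np.ndarray, reduction: str = "sum") -> float:
    """Categorical cross-entropy -sum_i sum_j L_ij log p_ij (natural log).

    ``reduction="mean"`` divides by the number of samples (the variant used
    for optimisation).  Zero probabilities at a true class are clamped at
    1e-12 with a warning.
    """
    p = np.asarray(p, dtype=float)
    onehot = np.asarray(onehot, dtype=float)
    if np.any((p < EPS_LOGP) & (onehot > 0)):
        import warnings

        warnings.warn("probability 0 at a true class; clamping log argument")
    total = -float(np.sum(onehot * np.log(np.clip(p, EPS_LOGP, None))))
    if reduction == "mean":
        return total / p.shape[0]
    return total


# ---------------------------------------------------------------------------
# The assembled network


@dataclass
class ArchitectureSpec:
    """Hyperparameters of the assembled network."""

    region_channels: tuple = (12, 25, 12, 12, 12)
    feature_length: int = 40
    reduction: int = 2
    branch_kernel: int = 5
    global_kernel: int = 2
    pool: int = 2
    n_classes: int = 2
    use_senet: bool = True
    ablation_flags: dict = field(default_factory=dict)


class SparNet:
    """The full model: five SE+conv branches, a global SE+conv stage, dense softmax.

    Input is a list of five region tensors, each shaped (B, C_region, L).
    With ``use_senet=False`` every SE gate is the identity (ablation).
    Weight initialisation is uniform fan-in scaled with a per-layer seed
    stream derived from ``seed``.
    """

    def __init__(self, arch: ArchitectureSpec | None = None, seed: int = 0):
        self.arch = arch or ArchitectureSpec()
        a = self.arch
        streams = iter(np.random.SeedSequence([seed, 1423]).spawn(
            2 * len(a.region_channels) + 3
        ))
        self.branches = []
        for C in a.region_channels:
            se = SEBlock(C, a.reduction, np.random.default_rng(next(streams)))
            conv = Conv1d(C, a.branch_kernel, 1, np.random.default_rng(next(streams)))
            self.branches.append(
                {"se": se, "conv": conv, "relu": ReLU(), "pool": MaxPool1d(a.pool)}
            )
        n_regions = len(a.region_channels)
        self.global_se = SEBlock(n_regions, a.reduction, np.random.default_rng(next(streams)))
        self.global_conv = Conv1d(n_regions, a.global_kernel, 1, np.random.default_rng(next(streams)))
        self.global_relu = ReLU()
        self.global_pool = MaxPool1d(a.pool)
        branch_len = (a.feature_length - a.branch_kernel + 1) // a.pool
        dense_in = (branch_len - a.global_kernel + 1) // a.pool
        self.dense = Dense(dense_in, a.n_classes, np.random.default_rng(next(streams)))
        self._layer_index = self._build_index()

    def _build_index(self):
        idx = {}
        for i, br in enumerate(self.branches):
            idx[f"branch{i}.se"] = br["se"]
            idx[f"branch{i}.conv"] = br["conv"]
        idx["global.se"] = self.global_se
        idx["global.conv"] = self.global_conv
        idx["dense"] = self.dense
        return idx

    # -- parameter plumbing -------------------------------------------------

    def get_params(self) -> dict:
        return {
            f"{lname}.{p}": arr.copy()
            for lname, layer in self._layer_index.items()
            for p, arr in layer.params.items()
        }

    def set_params(self, flat: dict) -> None:
        for key, arr in flat.items():
            lname, p = key.rsplit(".", 1)
            self._layer_index[lname].params[p] = arr.copy()

    def count_params(self, breakdown: bool = False):
        """Exact count of trainable scalars; SE layers excluded when disabled."""
        per_layer = {}
        for lname, layer in self._layer_index.items():
            if not self.arch.use_senet and lname.endswith(".se"):
                continue
            per_layer[lname] = layer.count_params()
        total = sum(per_layer.values())
        return (total, per_layer) if breakdown else total

    # -- forward / backward -------------------------------------------------

    def forward(self, regions: list[np.ndarray]) -> np.ndarray:
        """Class probabilities, shape (B, n_classes)."""
        a = self.arch
        if len(regions) != len(a.region_channels):
            raise ValueError(
                f"expected {len(a.region_channels)} region tensors, got {len(regions)}"
            )
        feats = []
        for br, x in zip(self.branches, regions):
            h = br["se"].forward(x) if a.use_senet else x
            h = br["conv"].forward(h)
            h = br["relu"].forward(h)
            h = br["pool"].forward(h)
            feats.append(h)  # (B, 1, branch_len)
        merged = np.concatenate(feats, axis=1)  # (B, 5, branch_len)
        h = self.global_se.forward(merged) if a.use_senet else merged
        h = self.global_conv.forward(h)
        h = self.global_relu.forward(h)
        h = self.global_pool.forward(h)
        B = h.shape[0]
        self._flat_shape = h.shape
        logits = self.dense.forward(h.reshape(B, -1))
        self._probs = softmax(logits)
        return self._probs

    def loss_and_grads(self, regions: list[np.ndarray], onehot: np.ndarray):
        """Mean cross-entropy and analytic gradients for every parameter."""
        probs = self.forward(regions)
        B = probs.shape[0]
        loss = cross_entropy(probs, onehot, reduction="mean")
        grads = {}
        g = (probs - onehot) / B  # softmax + CE combined gradient
        g, gl = self.dense.backward(g)
        grads.update({f"dense.{k}": v for k, v in gl.items()})
        g = g.reshape(self._flat_shape)
        g, _ = self.global_pool.backward(g)
        g, _ = self.global_relu.backward(g)
        g, gl = self.global_conv.backward(g)
        grads.update({f"global.conv.{k}": v for k, v in gl.items()})
        if self.arch.use_senet:
            g, gl = self.global_se.backward(g)
            grads.update({f"global.se.{k}": v for k, v in gl.items()})
        # split merged gradient back into branches
        for i, br in enumerate(self.branches):
            gb = g[:, i : i + 1, :]
            gb, _ = br["pool"].backward(gb)
            gb, _ = br["relu"].backward(gb)
            gb, gl = br["conv"].backward(gb)
            grads.update({f"branch{i}.conv.{k}": v for k, v in gl.items()})
            if self.arch.use_senet:
                _, gl = br["se"].backward(gb)
                grads.update({f"branch{i}.se.{k}": v for k, v in gl.items()})
        return loss, grads

    def predict_proba(self, regions: list[np.ndarray]) -> np.ndarray:
        return self.forward(regions)


class RMSprop:
    """RMSprop: v <- rho v + (1-rho) g^2 ; p <- p - lr g / (sqrt(v) + eps)."""

    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._v: dict = {}

    def step(self, model: SparNet, grads: dict) -> None:
        for key, g in grads.items():
            v = self._v.get(key)
            if v is None:
                v = np.zeros_like(g)
            v = self.rho * v + (1.0 - self.rho) * g * g
            self._v[key] = v
            lname, p = key.rsplit(".", 1)
            model._layer_index[lname].params[p] -= self.lr * g / (np.sqrt(v) + self.eps)
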