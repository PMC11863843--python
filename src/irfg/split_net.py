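"""The split two-head network for multi-label functional-group detection.

An IR spectrum carries qualitatively different information below and above
~1800 cm^-1: the fingerprint region is dense with overlapping
molecule-specific bands, while the functional-group region holds the cleaner
characteristic stretches. The model encodes the two regions with separate
fully connected heads and fuses them in a joint classifier:

    y = f_joint(h1, h2),   h1 = f_FP(x_FP),   h2 = f_FG(x_FG)

where x_FP / x_FG are the spectrum segments at / above the split boundary
(default 1800 cm^-1; points exactly at the boundary belong to the
fingerprint side). Each head is

    dense(n -> n) + batchnorm + ReLU + dropout(0.2)
    dense(n -> 256) + batchnorm + ReLU + dropout(0.3)

and the joint part concatenates the two 256-wide features, applies one
dense(512 -> 512) + ReLU layer (no batchnorm, no dropout) and a
dense(512 -> 17) output with logistic activation, giving independent
per-group presence probabilities. Training minimizes mean binary
cross-entropy; the split is what injects the inductive bias that the two
spectral regions should be summarized independently before being combined.

The implementation is a small self-contained numpy stack (dense, batchnorm,
inverted dropout, ReLU) with hand-written backpropagation, Glorot-uniform
initialization and an explicit seed so parameter initialization and dropout
are bit-reproducible on a platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .catalog import DEFAULT_CATALOG, N_GROUPS, catalog_hash
from .errors import CatalogMismatchError
from .preprocess import Spectrum, default_grid

__all__ = [
    "SplitNetConfig",
    "SplitNet",
    "split_spectrum",
    "split_index",
    "predict_labels",
    "save_checkpoint",
    "load_checkpoint",
]

_F = np.float32


@dataclass
class SplitNetConfig:
    """Architecture hyperparameters (sizes per the fixed configuration)."""

    boundary: float = 1800.0  # cm^-1; fingerprint side is <= boundary
    head_hidden: int = 256
    dropout_in: float = 0.2
    dropout_hidden: float = 0.3
    concat_size: int = 512
    n_outputs: int = N_GROUPS
    threshold: float = 0.5
    seed: int = 0

    def validate(self, grid: np.ndarray) -> None:
        if not (grid[0] < self.boundary < grid[-1]):
            raise ValueError(
                f"boundary {self.boundary} must lie strictly inside the grid "
                f"({grid[0]}..{grid[-1]})"
            )
        if min(self.head_hidden, self.concat_size, self.n_outputs) <= 0:
            raise ValueError("layer sizes must be positive")


def split_index(grid: np.ndarray, boundary: float) -> int:
    """Number of grid points on the fingerprint side (grid <= boundary)."""
    grid = np.asarray(grid)
    if not (grid[0] < boundary < grid[-1]):
        raise ValueError(f"boundary {boundary} outside grid interior")
    return int(np.searchsorted(grid, boundary, side="right"))


def split_spectrum(
    spectrum: Spectrum, boundary: float = 1800.0
) -> tuple[np.ndarray, np.ndarray]:
    """Partition intensities into (x_FP, x_FG) at the boundary wavenumber."""
    k = split_index(spectrum.grid, boundary)
    return spectrum.intensities[:k], spectrum.intensities[k:]


def predict_labels(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize probabilities; a probability equal to the threshold counts as 1."""
    return (np.asarray(probabilities) >= threshold).astype(np.int8)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 input_grad: bool = True):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(_F)
        self.b = np.zeros(n_out, dtype=_F)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.input_grad = input_grad  # False for input layers: dx is never used
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        np.matmul(self._x.T, g, out=self.dW)
        g.sum(axis=0, out=self.db)
        if not self.input_grad:
            return g
        return g @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _BatchNorm:
    """Per-feature normalization; batch statistics in training, running in eval."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n, dtype=_F)
        self.beta = np.zeros(n, dtype=_F)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n, dtype=_F)
        self.running_var = np.ones(n, dtype=_F)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._cache = (xhat, inv)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = g.shape[0]
        self.dgamma[...] = (g * xhat).sum(axis=0)
        self.dbeta[...] = g.sum(axis=0)
        gx = g * self.gamma
        return (inv / n) * (n * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0))

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask

    def params(self):
        return []


class _Dropout:
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(_F) / _F(keep)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        return g * self._mask

    def params(self):
        return []


def _run(layers, x, training):
    for layer in layers:
        x = layer.forward(x, training)
    return x


def _back(layers, g):
    for layer in reversed(layers):
        g = layer.backward(g)
    return g


class SplitNet:
    """The two-head split network; owns all parameters (theta_FP, theta_FG,
    theta_joint) and exposes forward/backward passes over batches."""

    def __init__(self, config: SplitNetConfig | None = None, grid: np.ndarray | None = None):
        self.config = config or SplitNetConfig()
        self.grid = default_grid() if grid is None else np.asarray(grid, dtype=np.float64)
        self.config.validate(self.grid)
        self.n_fp = split_index(self.grid, self.config.boundary)
        self.n_fg = self.grid.size - self.n_fp
        c = self.config
        init_rng = np.random.default_rng(c.seed)
        self._dropout_rng = np.random.default_rng((c.seed, 0xD0))

        def head(n_in):
            return [
                _Dense(n_in, n_in, init_rng, input_grad=False),
                _BatchNorm(n_in),
                _ReLU(),
                _Dropout(c.dropout_in, self._dropout_rng),
                _Dense(n_in, c.head_hidden, init_rng),
                _BatchNorm(c.head_hidden),
                _ReLU(),
                _Dropout(c.dropout_hidden, self._dropout_rng),
            ]

        self.head_fp = head(self.n_fp)
        self.head_fg = head(self.n_fg)
        self.joint = [
            _Dense(2 * c.head_hidden, c.concat_size, init_rng),
            _ReLU(),
            _Dense(c.concat_size, c.n_outputs, init_rng),
        ]

    # -- passes -----------------------------------------------------------

    def _as_batch(self, x) -> tuple[np.ndarray, bool]:
        if isinstance(x, Spectrum):
            x = x.intensities
        x = np.asarray(x, dtype=_F)
        if x.ndim == 1:
            return x[None, :], True
        return x, False

    def forward_logits(self, x, training: bool = False) -> np.ndarray:
        xb, squeeze = self._as_batch(x)
        if xb.shape[1] != self.grid.size:
            raise ValueError(
                f"input length {xb.shape[1]} does not match grid ({self.grid.size})"
            )
        h1 = _run(self.head_fp, xb[:, : self.n_fp], training)
        h2 = _run(self.head_fg, xb[:, self.n_fp :], training)
        z = _run(self.joint, np.concatenate([h1, h2], axis=1), training)
        return z[0] if squeeze else z

    def forward(self, x, training: bool = False) -> np.ndarray:
        """Per-group presence probabilities in (0, 1)."""
        return _sigmoid(self.forward_logits(x, training))

    def backward(self, dlogits: np.ndarray) -> None:
        g = _back(self.joint, dlogits)
        h = self.config.head_hidden
        _back(self.head_fp, g[:, :h])
        _back(self.head_fg, g[:, h:])

    def head_outputs(self, x) -> tuple[np.ndarray, np.ndarray]:
        """(h1, h2) learned features, inference mode."""
        xb, squeeze = self._as_batch(x)
        h1 = _run(self.head_fp, xb[:, : self.n_fp], False)
        h2 = _run(self.head_fg, xb[:, self.n_fp :], False)
        return (h1[0], h2[0]) if squeeze else (h1, h2)

    def predict(self, x) -> np.ndarray:
        return predict_labels(self.forward(x), self.config.threshold)

    # -- parameter access --------------------------------------------------

    def _layers(self):
        return self.head_fp + self.head_fg + self.joint

    def parameters(self):
        """Flat list of (value, gradient) array pairs, stable order."""
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable parameters plus batchnorm running statistics."""
        arrays = {}
        for i, layer in enumerate(self._layers()):
            for j, (value, _) in enumerate(layer.params()):
                arrays[f"p{i}_{j}"] = value
            if isinstance(layer, _BatchNorm):
                arrays[f"p{i}_rm"] = layer.running_mean
                arrays[f"p{i}_rv"] = layer.running_var
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for key, value in self.state_arrays().items():
            value[...] = arrays[key]


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(net: SplitNet, path) -> None:
    """Single-file checkpoint: config JSON + grid + parameters + catalog hash."""
    meta = {"config": asdict(net.config), "catalog_hash": catalog_hash(DEFAULT_CATALOG)}
    np.savez_compressed(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        __grid__=net.grid,
        **net.state_arrays(),
    )


def load_checkpoint(path, expected_catalog=DEFAULT_CATALOG) -> SplitNet:
    """Rebuild a network from a checkpoint; refuses on catalog hash mismatch."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["catalog_hash"] != catalog_hash(expected_catalog):
            raise CatalogMismatchError(
                "checkpoint was trained under a different functional-group catalog"
            )
        net = SplitNet(SplitNetConfig(**meta["config"]), data["__grid__"])
        net.load_state_arrays({k: data[k] for k in data.files})
    return net
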