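"""A small, dependency-free convolutional age-bin classifier.

This is a deliberately compact numpy implementation (conv -> ReLU ->
maxpool stacks, adaptive average pooling, two dense layers, softmax
cross-entropy, Adam) standing in for a full-scale deep residual network:
the encoding, the age-bin classes and the median-of-top-3 aggregation
are the substance; the backbone is configurable desk-scale machinery.

Training is deterministic for a fixed seed (pure numpy, no threading
nondeterminism in practice for these sizes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from gutmaz.image_cnn.encoder import AgeBinScheme, MicrobiotaImage
from gutmaz.maturity_rf import HealthyReference, MazResult, compute_maz

__all__ = [
    "CnnConfig",
    "CnnAgeModel",
    "train_cnn_age",
    "predict_age_cnn",
    "compute_maz_cnn",
]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple:
    """Same-padding 3x3 convolution.  x: (N,C,H,W), w: (F,C,k,k)."""
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    wins = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    out = np.einsum("nchwij,fcij->nfhw", wins, w, optimize=True)
    out += b[None, :, None, None]
    return out, (x, wins, w)


def _conv_backward(dout: np.ndarray, cache: tuple) -> tuple:
    x, wins, w = cache
    k = w.shape[-1]
    p = k // 2
    dw = np.einsum("nchwij,nfhw->fcij", wins, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dp = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
    dwins = sliding_window_view(dp, (k, k), axis=(2, 3))  # (N,F,H,W,k,k)
    wflip = w[:, :, ::-1, ::-1]
    dx = np.einsum("nfhwij,fcij->nchw", dwins, wflip, optimize=True)
    return dx, dw, db


def _maxpool_forward(x: np.ndarray) -> tuple:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    return out, (mask, x.shape)


def _maxpool_backward(dout: np.ndarray, cache: tuple) -> np.ndarray:
    mask, shape = cache
    d = mask * dout[:, :, :, None, :, None]
    return d.reshape(shape)


def _avgpool_forward(x: np.ndarray, p: int) -> tuple:
    if p == 1:
        return x, (1, x.shape)
    n, c, h, w = x.shape
    out = x.reshape(n, c, h // p, p, w // p, p).mean(axis=(3, 5))
    return out, (p, x.shape)


def _avgpool_backward(dout: np.ndarray, cache: tuple) -> np.ndarray:
    p, shape = cache
    if p == 1:
        return dout
    d = np.repeat(np.repeat(dout, p, axis=2), p, axis=3) / (p * p)
    return d


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class CnnConfig:
    conv_channels: tuple[int, ...] = (8, 16)
    pooled_grid: int = 8
    hidden: int = 64
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    weight_decay: float = 1e-4

    def __post_init__(self) -> None:
        if len(self.conv_channels) < 1:
            raise ValueError("need at least one conv layer")
        if self.pooled_grid < 1:
            raise ValueError("pooled_grid must be >= 1")


@dataclass
class CnnAgeModel:
    """Trained classifier over age bins plus the label -> midpoint map."""

    config: CnnConfig
    bins: AgeBinScheme
    params: dict[str, np.ndarray]
    input_side: int
    loss_history: list[float] = field(default_factory=list)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Softmax class probabilities; images (N, 3, L, L) in 0-255."""
        if images.ndim == 3:
            images = images[None]
        if images.shape[-1] != self.input_side:
            raise ValueError(
                f"model expects side {self.input_side}, got {images.shape[-1]}"
            )
        logits, _ = _forward(images.astype(float) / 255.0, self.params, self.config)
        return _softmax(logits)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": self.config.__dict__ | {
                "conv_channels": list(self.config.conv_channels)
            },
            "edges": self.bins.edges.tolist(),
            "input_side": self.input_side,
            "loss_history": self.loss_history,
            "params": sorted(self.params),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        for name, arr in self.params.items():
            np.savetxt(d / f"{name}.txt", arr.reshape(arr.shape[0], -1))
            (d / f"{name}.shape").write_text(json.dumps(list(arr.shape)))

    @classmethod
    def load(cls, directory: str | Path) -> "CnnAgeModel":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        cfg_d = dict(manifest["config"])
        cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
        config = CnnConfig(**cfg_d)
        params = {}
        for name in manifest["params"]:
            shape = json.loads((d / f"{name}.shape").read_text())
            arr = np.loadtxt(d / f"{name}.txt")
            params[name] = arr.reshape(shape)
        return cls(
            config,
            AgeBinScheme(np.asarray(manifest["edges"])),
            params,
            manifest["input_side"],
            manifest["loss_history"],
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_params(
    config: CnnConfig, n_classes: int, side: int, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], int]:
    params: dict[str, np.ndarray] = {}
    c_in = 3
    for i, c_out in enumerate(config.conv_channels):
        fan_in = c_in * 9
        params[f"wc{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3))
        params[f"bc{i}"] = np.zeros(c_out)
        c_in = c_out
    side_after = side // (2 ** len(config.conv_channels))
    if side_after < config.pooled_grid or side_after % config.pooled_grid:
        raise ValueError(
            f"image side {side} incompatible with {len(config.conv_channels)} "
            f"pool stages and pooled grid {config.pooled_grid}"
        )
    n_feat = config.conv_channels[-1] * config.pooled_grid**2
    params["w1"] = rng.normal(0, np.sqrt(2.0 / n_feat), (n_feat, config.hidden))
    params["b1"] = np.zeros(config.hidden)
    params["w2"] = rng.normal(
        0, np.sqrt(2.0 / config.hidden), (config.hidden, n_classes)
    )
    params["b2"] = np.zeros(n_classes)
    return params, side_after // config.pooled_grid


def _forward(
    x: np.ndarray, params: dict[str, np.ndarray], config: CnnConfig
) -> tuple[np.ndarray, list]:
    caches: list = []
    h = x
    for i in range(len(config.conv_channels)):
        h, cc = _conv_forward(h, params[f"wc{i}"], params[f"bc{i}"])
        relu_mask = h > 0
        h = h * relu_mask
        h, pc = _maxpool_forward(h)
        caches.append((cc, relu_mask, pc))
    p = h.shape[2] // config.pooled_grid
    h, ac = _avgpool_forward(h, p)
    caches.append(ac)
    flat_shape = h.shape
    f = h.reshape(h.shape[0], -1)
    z1 = f @ params["w1"] + params["b1"]
    r1 = z1 > 0
    a1 = z1 * r1
    logits = a1 @ params["w2"] + params["b2"]
    caches.append((flat_shape, f, r1, a1))
    return logits, caches


def _backward(
    logits: np.ndarray,
    labels: np.ndarray,
    params: dict[str, np.ndarray],
    config: CnnConfig,
    caches: list,
) -> tuple[float, dict[str, np.ndarray]]:
    n = logits.shape[0]
    probs = _softmax(logits)
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n

    flat_shape, f, r1, a1 = caches[-1]
    grads: dict[str, np.ndarray] = {}
    grads["w2"] = a1.T @ dlogits
    grads["b2"] = dlogits.sum(axis=0)
    da1 = dlogits @ params["w2"].T
    dz1 = da1 * r1
    grads["w1"] = f.T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    dh = (dz1 @ params["w1"].T).reshape(flat_shape)
    dh = _avgpool_backward(dh, caches[-2])
    for i in reversed(range(len(config.conv_channels))):
        cc, relu_mask, pc = caches[i]
        dh = _maxpool_backward(dh, pc)
        dh = dh * relu_mask
        dh, dw, db = _conv_backward(dh, cc)
        grads[f"wc{i}"] = dw
        grads[f"bc{i}"] = db
    return loss, grads


def train_cnn_age(
    images: Sequence[MicrobiotaImage] | np.ndarray,
    bin_labels: Sequence[int],
    bins: AgeBinScheme,
    config: CnnConfig | None = None,
    seed: int = 0,
    min_per_class: int = 1,
) -> CnnAgeModel:
    """Train the classifier on encoded images against age-bin labels.

    ``bin_labels`` are integer bin indices into ``bins``.  Every class
    in the scheme must be present in training.  Per-epoch mean loss is
    recorded on the returned model.
    """
    config = config or CnnConfig()
    if isinstance(images, np.ndarray):
        x = images.astype(float)
    else:
        x = np.stack([im.pixels for im in images]).astype(float)
    labels = np.asarray(bin_labels, dtype=int)
    present = np.bincount(labels, minlength=bins.n_bins)
    if (present < min_per_class).any():
        missing = np.flatnonzero(present < min_per_class).tolist()
        raise ValueError(f"classes absent or underfilled in training: {missing}")
    if bins.n_bins < 2:
        raise ValueError("need at least 2 bins")
    side = x.shape[-1]
    rng = np.random.default_rng(seed)
    params, _ = _init_params(config, bins.n_bins, side, rng)
    x = x / 255.0

    # Adam state
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(vv) for k, vv in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = x.shape[0]
    history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits, caches = _forward(x[idx], params, config)
            loss, grads = _backward(logits, labels[idx], params, config, caches)
            epoch_loss += loss
            n_batches += 1
            t += 1
            for k in params:
                g = grads[k]
                if k.startswith("w"):
                    g = g + config.weight_decay * params[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                params[k] -= config.lr * mhat / (np.sqrt(vhat) + eps)
        history.append(epoch_loss / max(n_batches, 1))
    return CnnAgeModel(config, bins, params, side, history)


def predict_age_cnn(
    model: CnnAgeModel, image: MicrobiotaImage | np.ndarray
) -> tuple[list[int], float]:
    """Top-3 predicted bins and the median of their midpoints.

    Returns ``(top3_bin_indices, microbiota_age)`` where the microbiota
    age is the median of the three highest-probability bin midpoints.
    """
    pixels = image.pixels if isinstance(image, MicrobiotaImage) else image
    probs = model.predict_proba(np.asarray(pixels, dtype=float))[0]
    if len(probs) != model.bins.n_bins:
        raise ValueError("model output size does not match the bin scheme")
    k = min(3, len(probs))
    top = np.argsort(-probs, kind="stable")[:k]
    midpoints = model.bins.midpoints[top]
    return top.tolist(), float(np.median(midpoints))


def predict_ages_cnn(
    model: CnnAgeModel, images: Sequence[MicrobiotaImage] | np.ndarray
) -> np.ndarray:
    """Vectorized median-of-top-3 microbiota age for many images."""
    if isinstance(images, np.ndarray):
        x = images.astype(float)
    else:
        x = np.stack([im.pixels for im in images]).astype(float)
    probs = model.predict_proba(x)
    k = min(3, probs.shape[1])
    top = np.argsort(-probs, axis=1, kind="stable")[:, :k]
    return np.median(model.bins.midpoints[top], axis=1)


def compute_maz_cnn(
    microbiota_ages: Sequence[float],
    chronological_ages: Sequence[float],
    reference: HealthyReference,
    sample_ids: Sequence[str] | None = None,
) -> list[MazResult]:
    """MAZ from CNN microbiota ages; same formula as the RF route."""
    return compute_maz(microbiota_ages, chronological_ages, reference, sample_ids)
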