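"""Per-pixel decay classifier: a small convolutional encoder-decoder in numpy.

The network follows the encoder-decoder-with-skip-connections pattern of
semantic segmentation: three resolution levels (48 -> 24 -> 12 for the
default patch size), 3x3 convolutions with ReLU, 2x2 max pooling, nearest-
neighbor upsampling, channel concatenation of the matching encoder feature
map, and a 1x1 convolution with a sigmoid producing a per-pixel decay
probability. It is trained with binary cross-entropy and Adam. Forward and
backward passes are written directly in numpy (the gradients are verified
numerically in the unit tests), which keeps the model dependency-free and
fully deterministic under a seed.

The model contract is what the rest of the pipeline relies on: a normalized
patch in, a same-shape probability grid in [0, 1] out, serializable, with
the training seed and a config digest recorded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..ctvolume import ParameterError


class DataError(ValueError):
    """The annotation set cannot support training."""


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (all of them; nothing is hidden in code)."""

    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 3e-3
    n_patches: int = 200
    patch_size: int = 48
    base_channels: int = 8
    augment: bool = True  # random flips / 90-degree rotations
    balance: bool = True  # half the patches centered on decay pixels
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class AnnotationSet:
    """Pixel-wise annotated slices: (image, binary mask) pairs with splits.

    ``split`` assigns each pair to a fold / partition name ("train",
    "val", or a CV fold index as a string); empty means unassigned.
    """

    images: list[np.ndarray]
    masks: list[np.ndarray]
    split: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.masks):
            raise DataError("images and masks must pair up")
        for img, msk in zip(self.images, self.masks):
            if img.shape != msk.shape:
                raise DataError("image/mask shape mismatch")
            vals = np.unique(msk)
            if not set(vals.tolist()) <= {0, 1}:
                raise DataError("masks must be binary (0 = background, 1 = decay)")
        if not self.split:
            self.split = [""] * len(self.images)

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, names: set[str]) -> "AnnotationSet":
        idx = [i for i, s in enumerate(self.split) if s in names]
        return AnnotationSet(
            images=[self.images[i] for i in idx],
            masks=[self.masks[i] for i in idx],
            split=[self.split[i] for i in idx],
        )

    def assign_folds(self, n_folds: int = 5, seed: int = 0) -> None:
        """Random fold assignment over slices (not patches), avoiding
        leakage between overlapping patches of the same slice."""
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(self.images))
        self.split = [""] * len(self.images)
        for k, i in enumerate(order):
            self.split[i] = str(k % n_folds)


def annotation_set_from_volume(norm_values: np.ndarray, decay_mask: np.ndarray,
                               step: int = 1) -> AnnotationSet:
    """Build an annotation set from a normalized volume and its decay mask."""
    images = [norm_values[z].astype(np.float32) for z in range(0, norm_values.shape[0], step)]
    masks = [decay_mask[z].astype(np.uint8) for z in range(0, decay_mask.shape[0], step)]
    return AnnotationSet(images=images, masks=masks)


# ---------------------------------------------------------------------------
# numpy layers (NHWC layout)
# ---------------------------------------------------------------------------


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 (or 1x1) same-padding convolution via shifted matmuls."""
    kh, kw = w.shape[:2]
    if kh == 1:
        return x @ w[0, 0] + b
    n, h, wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.empty((n, h, wd, w.shape[3]), dtype=x.dtype)
    out[:] = b
    for i in range(kh):
        for j in range(kw):
            out += xp[:, i : i + h, j : j + wd, :] @ w[i, j]
    return out


def _conv_backward(x, w, g):
    kh, kw = w.shape[:2]
    if kh == 1:
        dw = np.zeros_like(w)
        dw[0, 0] = np.tensordot(x, g, axes=([0, 1, 2], [0, 1, 2]))
        db = g.sum(axis=(0, 1, 2))
        dx = g @ w[0, 0].T
        return dx, dw, db
    n, h, wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for i in range(kh):
        for j in range(kw):
            dw[i, j] = np.tensordot(xp[:, i : i + h, j : j + wd, :], g,
                                    axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, i : i + h, j : j + wd, :] += g @ w[i, j].T
    db = g.sum(axis=(0, 1, 2))
    return dxp[:, 1:-1, 1:-1, :], dw, db


def _pool_forward(x):
    n, h, w, c = x.shape
    r = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = r.max(axis=(2, 4))
    mask = r == out[:, :, None, :, None, :]
    return out, mask


def _pool_backward(g, mask):
    n, hh, ww, c = g.shape
    expanded = mask * g[:, :, None, :, None, :]
    return expanded.reshape(n, hh * 2, ww * 2, c)


def _upsample(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample_backward(g):
    n, h, w, c = g.shape
    return g.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SegmentationNet:
    """Three-level convolutional encoder-decoder with skip connections."""

    #: (name, kernel, in-channels multiplier spec) resolved in __init__
    def __init__(self, base_channels: int = 8, seed: int = 0):
        c = base_channels
        self.base_channels = c
        rng = np.random.default_rng(seed)
        shapes = {
            "c1a": (3, 3, 1, c),
            "c1b": (3, 3, c, c),
            "c2": (3, 3, c, 2 * c),
            "c3": (3, 3, 2 * c, 4 * c),
            "u2": (3, 3, 6 * c, 2 * c),
            "u1": (3, 3, 3 * c, c),
            "out": (1, 1, c, 1),
        }
        self.params: dict[str, np.ndarray] = {}
        for name, shape in shapes.items():
            fan_in = shape[0] * shape[1] * shape[2]
            self.params[f"{name}.w"] = rng.normal(
                0, np.sqrt(2.0 / fan_in), size=shape
            ).astype(np.float64)
            self.params[f"{name}.b"] = np.zeros(shape[3], dtype=np.float64)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (n, h, w) with h, w divisible by 4. Returns logits (n, h, w)."""
        p = self.params
        x4 = x[..., None].astype(np.float64)
        z1a = _conv_forward(x4, p["c1a.w"], p["c1a.b"]); a1a = np.maximum(z1a, 0)
        z1b = _conv_forward(a1a, p["c1b.w"], p["c1b.b"]); a1 = np.maximum(z1b, 0)
        p1, m1 = _pool_forward(a1)
        z2 = _conv_forward(p1, p["c2.w"], p["c2.b"]); a2 = np.maximum(z2, 0)
        p2, m2 = _pool_forward(a2)
        z3 = _conv_forward(p2, p["c3.w"], p["c3.b"]); a3 = np.maximum(z3, 0)
        cat2 = np.concatenate([_upsample(a3), a2], axis=-1)
        z4 = _conv_forward(cat2, p["u2.w"], p["u2.b"]); a4 = np.maximum(z4, 0)
        cat1 = np.concatenate([_upsample(a4), a1], axis=-1)
        z5 = _conv_forward(cat1, p["u1.w"], p["u1.b"]); a5 = np.maximum(z5, 0)
        logits = _conv_forward(a5, p["out.w"], p["out.b"])[..., 0]
        if not want_cache:
            return logits
        cache = dict(x4=x4, z1a=z1a, a1a=a1a, z1b=z1b, a1=a1, m1=m1, p1=p1,
                     z2=z2, a2=a2, m2=m2, p2=p2, z3=z3, a3=a3, cat2=cat2,
                     z4=z4, a4=a4, cat1=cat1, z5=z5, a5=a5)
        return logits, cache

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean binary cross-entropy and gradients w.r.t. every parameter."""
        return _loss_and_grads(self, x, y)


def _loss_and_grads(net: SegmentationNet, x: np.ndarray, y: np.ndarray):
    p = net.params
    c = net.base_channels
    logits, cc = net.forward(x, want_cache=True)
    prob = _sigmoid(logits)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
    grads: dict[str, np.ndarray] = {}
    g = ((prob - y) / y.size)[..., None]

    da5, grads["out.w"], grads["out.b"] = _conv_backward(cc["a5"], p["out.w"], g)
    dz5 = da5 * (cc["z5"] > 0)
    dcat1, grads["u1.w"], grads["u1.b"] = _conv_backward(cc["cat1"], p["u1.w"], dz5)
    # cat1 = [upsample(a4): 2c channels | a1: c channels]
    da4 = _upsample_backward(dcat1[..., : 2 * c])
    da1 = dcat1[..., 2 * c :]
    dz4 = da4 * (cc["z4"] > 0)
    dcat2, grads["u2.w"], grads["u2.b"] = _conv_backward(cc["cat2"], p["u2.w"], dz4)
    # cat2 = [upsample(a3): 4c channels | a2: 2c channels]
    da3 = _upsample_backward(dcat2[..., : 4 * c])
    da2 = dcat2[..., 4 * c :]
    dz3 = da3 * (cc["z3"] > 0)
    dp2, grads["c3.w"], grads["c3.b"] = _conv_backward(cc["p2"], p["c3.w"], dz3)
    da2 = da2 + _pool_backward(dp2, cc["m2"])
    dz2 = da2 * (cc["z2"] > 0)
    dp1, grads["c2.w"], grads["c2.b"] = _conv_backward(cc["p1"], p["c2.w"], dz2)
    da1 = da1 + _pool_backward(dp1, cc["m1"])
    dz1b = da1 * (cc["z1b"] > 0)
    da1a, grads["c1b.w"], grads["c1b.b"] = _conv_backward(cc["a1a"], p["c1b.w"], dz1b)
    dz1a = da1a * (cc["z1a"] > 0)
    _, grads["c1a.w"], grads["c1a.b"] = _conv_backward(cc["x4"], p["c1a.w"], dz1a)
    return loss, grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class DecayModel:
    """Trained per-pixel decay predictor.

    ``predict`` maps a batch of normalized patches ``(n, s, s)`` to decay
    probabilities of the same shape, all values in [0, 1].
    """

    net: SegmentationNet
    config: TrainConfig
    digest: str = ""

    def __post_init__(self) -> None:
        if not self.digest:
            self.digest = self.config.digest()

    def predict(self, patches: np.ndarray, chunk: int = 64) -> np.ndarray:
        patches = np.asarray(patches, dtype=np.float64)
        single = patches.ndim == 2
        if single:
            patches = patches[None]
        out = np.concatenate(
            [_sigmoid(self.net.forward(patches[i : i + chunk]))
             for i in range(0, len(patches), chunk)]
        )
        return out[0] if single else out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.params)
        path.with_suffix(".json").write_text(
            json.dumps({"config": asdict(self.config), "digest": self.digest}, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "DecayModel":
        path = Path(path)
        info = json.loads(path.with_suffix(".json").read_text())
        config = TrainConfig(**info["config"])
        net = SegmentationNet(config.base_channels, seed=config.seed)
        with np.load(path.with_suffix(".npz")) as data:
            net.params = {k: data[k] for k in data.files}
        return cls(net=net, config=config, digest=info["digest"])


def _sample_patches(annotations: AnnotationSet, config: TrainConfig, rng):
    s = config.patch_size
    usable = [i for i, img in enumerate(annotations.images)
              if img.shape[0] >= s and img.shape[1] >= s]
    if not usable:
        raise DataError(f"no annotated slice can host a {s}x{s} patch")
    xs, ys = [], []
    for k in range(config.n_patches):
        i = usable[int(rng.integers(0, len(usable)))]
        img, msk = annotations.images[i], annotations.masks[i]
        h, w = img.shape
        centered = config.balance and k % 2 == 1 and msk.any()
        if centered:
            pos = np.argwhere(msk > 0)
            py, px = pos[int(rng.integers(0, len(pos)))]
            r = int(np.clip(py - s // 2, 0, h - s))
            c = int(np.clip(px - s // 2, 0, w - s))
        else:
            r = int(rng.integers(0, h - s + 1))
            c = int(rng.integers(0, w - s + 1))
        xs.append(img[r : r + s, c : c + s])
        ys.append(msk[r : r + s, c : c + s])
    return np.asarray(xs, dtype=np.float64), np.asarray(ys, dtype=np.float64)


def _augment_batch(xb, yb, rng):
    k = int(rng.integers(0, 4))
    if k:
        xb = np.rot90(xb, k, axes=(1, 2))
        yb = np.rot90(yb, k, axes=(1, 2))
    if rng.integers(0, 2):
        xb, yb = xb[:, ::-1], yb[:, ::-1]
    if rng.integers(0, 2):
        xb, yb = xb[:, :, ::-1], yb[:, :, ::-1]
    return np.ascontiguousarray(xb), np.ascontiguousarray(yb)


def train_decay_model(
    annotations: AnnotationSet, config: TrainConfig | None = None
) -> tuple[DecayModel, list[float]]:
    """Train the segmentation net on patches sampled from annotated slices.

    Returns the model and the per-epoch mean training loss. Deterministic
    given ``config.seed``: patch sampling, shuffling, augmentation and
    weight initialization all derive from it.
    """
    config = config or TrainConfig()
    if len(annotations) == 0:
        raise DataError("empty annotation set")
    if config.patch_size % 4 != 0:
        raise ParameterError("patch_size must be divisible by 4 (two pooling levels)")
    rng = np.random.default_rng(config.seed)
    x, y = _sample_patches(annotations, config, rng)
    net = SegmentationNet(config.base_channels, seed=config.seed)
    opt = _Adam(net.params, config.learning_rate)
    history: list[float] = []
    n = len(x)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            if config.augment:
                xb, yb = _augment_batch(xb, yb, rng)
            loss, grads = net.loss_and_grads(xb, yb)
            opt.step(net.params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return DecayModel(net=net, config=config), history
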