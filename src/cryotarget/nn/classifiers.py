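"""CNN classifiers for square and hole crops.

The square classifier scores fixed-size resampled square crops.  For holes,
two variants share every hyperparameter except how they cope with variable
crop sizes: ``padded`` zero-pads all crops to one side length and uses a
fully connected head on the flattened final map, while ``average_pool``
averages the final map over its spatial dimensions — treating the crop as a
bag of regions, so the score depends on what features are present, not where
they sit or how large the crop is.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cryotarget.nn import functional as F
from cryotarget.nn.autograd import Tensor, no_grad
from cryotarget.nn.modules import Adam, Conv2d, Linear, Module

__all__ = [
    "SquareCNNConfig",
    "SquareCNN",
    "train_square_cnn",
    "square_cnn_score",
    "HoleCNNConfig",
    "HoleCNN",
    "train_hole_cnn",
    "hole_cnn_forward",
    "resize_to",
    "save_classifier",
    "load_classifier",
]


def resize_to(image: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resample a 2-D array to side x side."""
    H, W = image.shape
    rows = np.linspace(0, H - 1, side)
    cols = np.linspace(0, W - 1, side)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(np.asarray(image, float),
                                   np.stack([rr.ravel(), cc.ravel()]),
                                   order=1).reshape(side, side)


def _crop_array(crop) -> np.ndarray:
    return crop.normalized_pixels if hasattr(crop, "normalized_pixels") else np.asarray(crop, float)


def _class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-frequency weight per sample."""
    labels = np.asarray(labels, bool)
    n_pos = max(int(labels.sum()), 1)
    n_neg = max(int((~labels).sum()), 1)
    w = np.where(labels, len(labels) / (2.0 * n_pos), len(labels) / (2.0 * n_neg))
    return w


# ---------------------------------------------------------------------------
# Square CNN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SquareCNNConfig:
    input_side: int = 64
    channels: tuple[int, ...] = (8, 16, 32)
    epochs: int = 20
    batch_size: int = 16
    lr: float = 3e-3
    seed: int = 0


class SquareCNN(Module):
    """Conv-pool stack with global average head; input is a resampled crop."""

    def __init__(self, config: SquareCNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.convs = []
        cin = 1
        for c in config.channels:
            self.convs.append(Conv2d(cin, c, 3, rng))
            cin = c
        self.fc = Linear(cin, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).relu()
            h = F.max_pool2d(h)
        h = F.global_avg_pool(h)
        return self.fc(h).sigmoid()

    def score(self, crop) -> float:
        arr = resize_to(_crop_array(crop), self.config.input_side)
        with no_grad():
            out = self.forward(Tensor(arr[None, None]))
        return float(out.data[0, 0])


def train_square_cnn(crops, labels, config: SquareCNNConfig | None = None) -> SquareCNN:
    """Train the square CNN on crops with binary collect/skip labels.

    Crops of any size are resampled to ``config.input_side``; class imbalance
    is handled by inverse-frequency loss weights.  Fully seeded.
    """
    config = config or SquareCNNConfig()
    labels = np.asarray(labels, bool)
    if labels.all() or (~labels).all():
        raise ValueError("need both classes to train a classifier")
    X = np.stack([resize_to(_crop_array(c), config.input_side) for c in crops])
    w = _class_weights(labels)
    model = SquareCNN(config)
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    t = labels.astype(float)
    for _ in range(config.epochs):
        order = rng.permutation(len(X))
        for s in range(0, len(X), config.batch_size):
            idx = order[s:s + config.batch_size]
            out = model.forward(Tensor(X[idx][:, None]))
            loss = F.binary_cross_entropy(out, t[idx][:, None], weights=w[idx][:, None])
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


def square_cnn_score(model: SquareCNN, crop) -> float:
    return model.score(crop)


# ---------------------------------------------------------------------------
# Hole CNNs (padded vs average-pool)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HoleCNNConfig:
    """``mode`` is the only field that may differ between the two variants."""

    mode: str = "average_pool"      # or "padded"
    channels: tuple[int, ...] = (8, 16, 32)
    pad_side: int = 64              # padded-mode canvas; also max crop side
    epochs: int = 10
    batch_size: int = 16
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("padded", "average_pool"):
            raise ValueError("mode must be 'padded' or 'average_pool'")

    def hyperparameters(self) -> dict:
        """All hyperparameters except the padding/pooling mode."""
        d = dataclasses.asdict(self)
        d.pop("mode")
        return d


class HoleCNN(Module):
    """Stride-1 conv stack; head depends on mode.

    No spatial pooling inside the stack, so in ``average_pool`` mode the
    score of a local pattern far from the crop border is independent of where
    the pattern sits.
    """

    def __init__(self, config: HoleCNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.convs = []
        cin = 1
        for c in config.channels:
            self.convs.append(Conv2d(cin, c, 3, rng))
            cin = c
        if config.mode == "padded":
            self.fc = Linear(cin * config.pad_side ** 2, 1, rng)
        else:
            self.fc = Linear(cin, 1, rng)

    @property
    def min_side(self) -> int:
        # receptive field of the conv stack
        return 2 * len(self.config.channels) + 1

    def _prepare(self, arr: np.ndarray) -> np.ndarray:
        H, W = arr.shape
        if self.config.mode == "padded":
            S = self.config.pad_side
            if H > S or W > S:
                raise ValueError(f"crop {H}x{W} exceeds padded canvas {S}")
            out = np.zeros((S, S))
            out[:H, :W] = arr
            return out
        if H < self.min_side or W < self.min_side:
            raise ValueError(
                f"crop {H}x{W} smaller than the conv stack's receptive "
                f"field ({self.min_side})"
            )
        return arr

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).relu()
        if self.config.mode == "padded":
            n = h.shape[0]
            h = h.reshape(n, -1)
        else:
            h = F.global_avg_pool(h)
        return self.fc(h).sigmoid()

    def score(self, crop) -> float:
        arr = self._prepare(_crop_array(crop))
        with no_grad():
            out = self.forward(Tensor(arr[None, None]))
        return float(out.data[0, 0])


def hole_cnn_forward(model: HoleCNN, crop, mode: str | None = None) -> float:
    """Scalar collect-probability for one hole crop."""
    if mode is not None and mode != model.config.mode:
        raise ValueError(f"model was built in mode {model.config.mode!r}")
    return model.score(crop)


def train_hole_cnn(crops, labels, config: HoleCNNConfig | None = None) -> HoleCNN:
    """Train a hole classifier on crops with clean/contaminated labels.

    Class imbalance (collected holes heavily outnumber skipped ones in real
    sessions) is handled by inverse-frequency loss weighting.
    """
    config = config or HoleCNNConfig()
    labels = np.asarray(labels, bool)
    if labels.all() or (~labels).all():
        raise ValueError("need both classes to train a classifier")
    model = HoleCNN(config)
    arrs = [model._prepare(_crop_array(c)) for c in crops]
    shapes = {a.shape for a in arrs}
    if len(shapes) == 1:
        batches_same_shape = True
        X = np.stack(arrs)
    else:
        batches_same_shape = False
    w = _class_weights(labels)
    t = labels.astype(float)
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    for _ in range(config.epochs):
        order = rng.permutation(len(arrs))
        if batches_same_shape:
            for s in range(0, len(arrs), config.batch_size):
                idx = order[s:s + config.batch_size]
                out = model.forward(Tensor(X[idx][:, None]))
                loss = F.binary_cross_entropy(out, t[idx][:, None],
                                              weights=w[idx][:, None])
                opt.zero_grad()
                loss.backward()
                opt.step()
        else:  # variable crop sizes: per-sample steps
            for i in order:
                out = model.forward(Tensor(arrs[i][None, None]))
                loss = F.binary_cross_entropy(out, np.array([[t[i]]]),
                                              weights=np.array([[w[i]]]))
                opt.zero_grad()
                loss.backward()
                opt.step()
    return model


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

_KINDS = {"square_cnn": (SquareCNN, SquareCNNConfig),
          "hole_cnn": (HoleCNN, HoleCNNConfig)}


def save_classifier(path, model) -> None:
    kind = "square_cnn" if isinstance(model, SquareCNN) else "hole_cnn"
    header = {"kind": kind, "config": dataclasses.asdict(model.config)}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(),
                                            dtype=np.uint8),
             **model.state_dict())


def load_classifier(path):
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        cls, cfg_cls = _KINDS[header["kind"]]
        cfg = header["config"]
        if "channels" in cfg:
            cfg["channels"] = tuple(cfg["channels"])
        model = cls(cfg_cls(**cfg))
        model.load_state_dict({k: data[k] for k in data.files if k != "__header__"})
    return model
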