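"""U-Net heatmap regressor for hole centers.

The network maps a normalized medium-magnification image to a same-size map
of per-pixel hole-center probabilities.  Training targets are sparse binary
maps with 1 at operator-selected pixels and 0 elsewhere; because operators
click near (not exactly at) hole centers, the model *output* is blurred with
a Gaussian of trainable bandwidth sigma before the cross-entropy is taken,
letting the model learn hole centers rather than per-image click offsets,
and letting training itself find the right amount of smoothing.

Augmentation: random quarter-turns applied to image and target jointly, and
random inversion of the normalized pixels (image only) so carbon grids with
contrast-inverted holes are handled by the same model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from cryotarget.lattice import ProbabilityMap, normalize_medium_mag
from cryotarget.nn import functional as F
from cryotarget.nn.autograd import Tensor, no_grad
from cryotarget.nn.modules import Adam, Conv2d, Module, Parameter

__all__ = [
    "UNetConfig",
    "UNet",
    "TargetMap",
    "TrainResult",
    "build_target_map",
    "blurred_output_loss",
    "augment",
    "train_unet",
    "unet_predict",
    "save_unet",
    "load_unet",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture and training-setup knobs.

    ``depth`` counts resolution levels including the bottleneck (depth - 1
    poolings); each level applies two 3x3 convolutions with ReLU.  The
    bottleneck receptive field must exceed the largest expected hole
    diameter so whole holes fit inside it; set ``max_hole_diameter_px`` to
    have this checked at construction.
    """

    depth: int = 5
    base_channels: int = 16
    sigma_init: float = 2.0
    learn_sigma: bool = True
    seed: int = 0
    max_hole_diameter_px: float | None = None

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.sigma_init <= 0:
            raise ValueError("sigma_init must be positive")
        if (self.max_hole_diameter_px is not None
                and self.receptive_field < self.max_hole_diameter_px):
            raise ValueError(
                f"bottleneck receptive field {self.receptive_field} px is "
                f"smaller than max hole diameter {self.max_hole_diameter_px} px; "
                "increase depth"
            )

    @property
    def receptive_field(self) -> int:
        """Receptive field of one bottleneck neuron, in input pixels."""
        rf, jump = 1, 1
        for _ in range(self.depth - 1):
            rf += 2 * 2 * jump       # two 3x3 convs
            rf += 1 * jump           # 2x2 pool
            jump *= 2
        rf += 2 * 2 * jump           # bottleneck convs
        return rf

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.depth - 1)


@dataclass
class TargetMap:
    """Binary map: 1 at operator-selected pixels, 0 elsewhere."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("target map must be binary")
        self.values = v.astype(np.float64)


def build_target_map(shape: tuple[int, int], points: np.ndarray) -> TargetMap:
    """Rasterize operator points (rounded to nearest pixel) into a TargetMap."""
    t = np.zeros(shape, np.float64)
    for r, c in np.asarray(points, float).reshape(-1, 2):
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < shape[0] and 0 <= ci < shape[1]):
            raise ValueError(f"operator point ({r}, {c}) outside image")
        t[ri, ci] = 1.0
    return TargetMap(values=t)


class UNet(Module):
    """Encoder-decoder with skip connections and per-pixel sigmoid output."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = [config.base_channels * 2 ** i for i in range(config.depth)]
        self.enc: list[list[Conv2d]] = []
        cin = 1
        for c in ch:
            self.enc.append([Conv2d(cin, c, 3, rng), Conv2d(c, c, 3, rng)])
            cin = c
        self.dec: list[list[Conv2d]] = []
        for i in range(config.depth - 2, -1, -1):
            c = ch[i]
            self.dec.append([Conv2d(cin + c, c, 3, rng), Conv2d(c, c, 3, rng)])
            cin = c
        self.head = Conv2d(cin, 1, 1, rng)
        # flatten conv lists so Module.parameters() finds them
        self._blocks = [conv for lvl in self.enc + self.dec for conv in lvl]

    def forward_logits(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for i, (c1, c2) in enumerate(self.enc):
            h = c2(c1(h).relu()).relu()
            if i < len(self.enc) - 1:
                skips.append(h)
                h = F.max_pool2d(h)
        for (c1, c2), skip in zip(self.dec, reversed(skips)):
            h = F.upsample2(h)
            h = F.concat_channels(h, skip)
            h = c2(c1(h).relu()).relu()
        return self.head(h)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward_logits(x).sigmoid()


def unet_predict(model: UNet, image: np.ndarray) -> ProbabilityMap:
    """Predict the hole-center probability map for one image.

    The image is normalized, reflect-padded to a multiple of the network's
    downsampling factor, and the padding is removed from the output.
    """
    img = normalize_medium_mag(image)
    H, W = img.shape
    f = model.config.downsample_factor
    ph = (-H) % f
    pw = (-W) % f
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    with no_grad():
        out = model(Tensor(img[None, None]))
    return ProbabilityMap(values=out.data[0, 0, :H, :W])


def blurred_output_loss(prediction, target, sigma) -> float:
    """Binary cross-entropy between the Gaussian-blurred prediction and the
    binary target, averaged over pixels.

    ``prediction`` may be a ProbabilityMap, array or Tensor; ``sigma`` a
    float or Tensor.  Returns a float for plain inputs and a Tensor (for
    backprop) when given Tensors.
    """
    tensors_in = isinstance(prediction, Tensor)
    if isinstance(prediction, ProbabilityMap):
        prediction = prediction.values
    if isinstance(target, TargetMap):
        target = target.values
    p = prediction if tensors_in else Tensor(np.asarray(prediction, float))
    s = sigma if isinstance(sigma, Tensor) else Tensor(float(sigma))
    blurred = F.gaussian_blur(p, s)
    loss = F.binary_cross_entropy(blurred, np.asarray(target, float))
    return loss if tensors_in else loss.item()


def augment(image: np.ndarray, target: np.ndarray, seed=None,
            rng: np.random.Generator | None = None):
    """Random quarter-turn (image and target jointly) and random pixel
    inversion (image only, probability 1/2)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    k = int(rng.integers(0, 4))
    img = np.rot90(image, k).copy()
    tgt = np.rot90(target, k).copy()
    if rng.random() < 0.5:
        img = -img
    return img, tgt


@dataclass
class TrainResult:
    """Training outcome: the fitted model plus per-epoch diagnostics."""

    model: UNet
    sigma_trace: np.ndarray        # sigma value at the end of each epoch
    loss_history: np.ndarray       # mean training loss per epoch
    sigma_final: float = field(init=False)

    def __post_init__(self):
        self.sigma_final = float(self.sigma_trace[-1])

    def __iter__(self):  # allows: model, sigma_trace = train_unet(...)
        return iter((self.model, self.sigma_trace))


def train_unet(scenes, config: UNetConfig, epochs: int = 10,
               batch_size: int = 4, lr: float = 5e-3,
               use_augmentation: bool = True,
               sigma_min: float = 0.3, sigma_lr: float = 10.0) -> TrainResult:
    """Train the U-Net on (image, operator_points) pairs.

    Images are normalized per image; targets are built per
    :func:`build_target_map`.  Weights are trained by Adam; the blur
    bandwidth sigma descends its own gradient (bounded below by
    ``sigma_min``) in the same loop when ``config.learn_sigma``.  Fully
    seeded: weight init, shuffling and augmentation all derive from
    ``config.seed``.
    """
    pairs = []
    for item in scenes:
        if hasattr(item, "image") and hasattr(item, "operator_points"):
            img, pts = item.image, item.operator_points
        else:
            img, pts = item
        pairs.append((normalize_medium_mag(np.asarray(img, float)),
                      np.asarray(pts, float).reshape(-1, 2)))
    if not pairs:
        raise ValueError("no training scenes")
    if all(len(p) == 0 for _, p in pairs):
        raise ValueError("refusing to train: no operator points in any scene")
    shapes = {img.shape for img, _ in pairs}
    if len(shapes) != 1:
        raise ValueError("all training images must share one shape")
    shape = shapes.pop()
    f = 2 ** (config.depth - 1)
    if shape[0] % f or shape[1] % f:
        raise ValueError(f"training image shape {shape} must be divisible by {f}")

    targets = [build_target_map(shape, pts).values for _, pts in pairs]
    images = [img for img, _ in pairs]

    model = UNet(config)
    # prior-probability init of the head bias: starting the output at the
    # positive-pixel base rate keeps the heavily imbalanced loss from driving
    # the sigmoid into deep saturation in the first epochs
    pos_rate = float(np.mean([t.mean() for t in targets]))
    pos_rate = min(max(pos_rate, 1e-6), 0.5)
    model.head.bias.data = np.array([np.log(pos_rate / (1.0 - pos_rate))])
    sigma = Parameter(np.array(config.sigma_init))
    opt = Adam(model.parameters(), lr=lr)

    rng = np.random.default_rng(config.seed + 1)
    n = len(images)
    sigma_trace = []
    loss_history = []
    for epoch in range(epochs):
        # sigma follows plain gradient descent with a squared-cosine-annealed
        # step: the step is proportional to the (shrinking) gradient and the
        # schedule, so the smoothing bandwidth settles as training converges
        lr_sig = sigma_lr * (0.5 * (1.0 + np.cos(np.pi * epoch / epochs))) ** 2
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xs, ts = [], []
            for i in idx:
                img, tgt = images[i], targets[i]
                if use_augmentation:
                    img, tgt = augment(img, tgt, rng=rng)
                xs.append(img)
                ts.append(tgt)
            x = Tensor(np.stack(xs)[:, None])
            t = np.stack(ts)[:, None]
            prob = model(x)
            blurred = F.gaussian_blur(prob, sigma)
            loss = F.binary_cross_entropy(blurred, t)
            opt.zero_grad()
            sigma.zero_grad()
            loss.backward()
            opt.step()
            if config.learn_sigma:
                sigma.data = np.maximum(sigma.data - lr_sig * sigma.grad,
                                        sigma_min)
            losses.append(loss.item())
        sigma_trace.append(float(sigma.data))
        loss_history.append(float(np.mean(losses)))

    return TrainResult(model=model, sigma_trace=np.array(sigma_trace),
                       loss_history=np.array(loss_history))


# ---------------------------------------------------------------------------
# Checkpoints: single .npz file with a JSON header
# ---------------------------------------------------------------------------

def save_unet(path, result_or_model, sigma: float | None = None) -> None:
    if isinstance(result_or_model, TrainResult):
        model = result_or_model.model
        sigma = result_or_model.sigma_final
    else:
        model = result_or_model
        sigma = sigma if sigma is not None else model.config.sigma_init
    header = {"config": dataclasses.asdict(model.config), "sigma": float(sigma),
              "kind": "unet"}
    state = model.state_dict()
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **state)


def load_unet(path) -> tuple[UNet, float]:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("kind") != "unet":
            raise ValueError("not a U-Net checkpoint")
        config = UNetConfig(**header["config"])
        model = UNet(config)
        model.load_state_dict({k: data[k] for k in data.files if k != "__header__"})
    return model, float(header["sigma"])
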