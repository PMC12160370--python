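"""Tongue segmentation: U-Net, nested U-Net (U-Net++), and an improved
nested U-Net (ISE-UNet++) whose interior decoder nodes replace the dense
double convolution with two tandem Inception depthwise extraction layers
followed by squeeze-and-excitation channel attention.

The nested-skip lattice is indexed X[i][j]: row i is the resolution level
(i = 0 full resolution), column j the nesting depth.  Column 0 is the plain
encoder; node X[i][j] consumes every same-row predecessor plus the upsampled
X[i+1][j-1].  With deep supervision each row-0 nested node X[0][j], j >= 1,
carries its own sigmoid output head and the training loss is the uniform mean
of the per-head losses.

Segmentation quality is reported as MIoU = TP / (TP + FP + FN) for the tongue
class, MPA = (TP + TN) / N, and pixel accuracy, all from pixel-level
confusion counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, concat
from .synthetic import TongueSample

__all__ = [
    "SegConfig",
    "SegMetrics",
    "TrainingHistory",
    "build_model",
    "train_segmenter",
    "segment",
    "seg_metrics",
    "improvement_report",
    "TINY_SEG_PRESET",
]


@dataclass
class SegConfig:
    variant: str = "ise_unetpp"  # unet | unetpp | ise_unetpp
    depth: int = 2
    base_channels: int = 8
    se_reduction: int = 16
    deep_supervision: bool = True
    epochs: int = 20
    batch_size: int = 10
    learning_rate: float = 0.1
    momentum: float = 0.9
    seed: int = 0
    #: 1 = operate at full resolution (default); 2 = average-pool the input
    #: once and upsample the head output, quartering the compute of every
    #: lattice node (used by the tiny CPU preset).
    stem_pool: int = 1

    def __post_init__(self):
        if self.variant not in ("unet", "unetpp", "ise_unetpp"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")


def TINY_SEG_PRESET(variant: str, seed: int = 0, epochs: int = 20) -> SegConfig:
    """CPU-trainable preset used throughout the tests and examples."""
    return SegConfig(
        variant=variant, depth=2, base_channels=8, epochs=epochs, seed=seed, stem_pool=2
    )


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    miou: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class SegMetrics:
    miou: float
    mpa: float
    accuracy: float


# --------------------------------------------------------------------------
# architectures
# --------------------------------------------------------------------------


class UNet(nn.Module):
    """Plain encoder-decoder with skip connections and one sigmoid head."""

    def __init__(self, cfg: SegConfig, *, rng: np.random.Generator):
        d, b = cfg.depth, cfg.base_channels
        self.depth = d
        self.stem_pool = cfg.stem_pool
        self.enc = [nn.ConvBlock(3 if i == 0 else b * 2 ** (i - 1), b * 2**i, rng=rng) for i in range(d + 1)]
        self.dec = [
            nn.ConvBlock(b * 2**i + b * 2 ** (i + 1), b * 2**i, rng=rng) for i in reversed(range(d))
        ]
        self.head = nn.Conv2d(b, 1, 1, rng=rng)

    def forward_logits(self, x: Tensor) -> list[Tensor]:
        if self.stem_pool == 2:
            x = x.avgpool2x2()
        feats = []
        for i, blk in enumerate(self.enc):
            if i > 0:
                x = x.maxpool2x2()
            x = blk(x)
            feats.append(x)
        y = feats[-1]
        for blk, skip in zip(self.dec, reversed(feats[:-1])):
            y = blk(concat([skip, y.upsample2x()], axis=1))
        out = self.head(y)
        if self.stem_pool == 2:
            out = out.upsample2x()
        return [out]

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_logits(x)[-1]


class UNetPP(nn.Module):
    """Nested-skip U-Net; ``ise=True`` swaps interior nodes to the improved
    extraction block (tandem Inception depthwise + SE attention)."""

    def __init__(self, cfg: SegConfig, *, rng: np.random.Generator, ise: bool = False):
        d, b = cfg.depth, cfg.base_channels
        self.depth = d
        self.stem_pool = cfg.stem_pool
        self.deep_supervision = cfg.deep_supervision
        self.blocks: list[nn.Module] = []
        self._grid: dict[tuple[int, int], nn.Module] = {}
        for i in range(d + 1):  # encoder column
            c_in = 3 if i == 0 else b * 2 ** (i - 1)
            blk = nn.ConvBlock(c_in, b * 2**i, rng=rng)
            self._grid[(i, 0)] = blk
            self.blocks.append(blk)
        for j in range(1, d + 1):  # nested columns
            for i in range(d + 1 - j):
                c_out = b * 2**i
                c_in = j * c_out + b * 2 ** (i + 1)
                if ise:
                    blk = nn.ISEExtractionBlock(c_in, c_out, cfg.se_reduction, rng=rng)
                else:
                    blk = nn.ConvBlock(c_in, c_out, rng=rng)
                self._grid[(i, j)] = blk
                self.blocks.append(blk)
        self.heads = [nn.Conv2d(b, 1, 1, rng=rng) for _ in range(d)]

    def forward_logits(self, x: Tensor) -> list[Tensor]:
        d = self.depth
        if self.stem_pool == 2:
            x = x.avgpool2x2()
        nodes: dict[tuple[int, int], Tensor] = {}
        for i in range(d + 1):
            x_in = x if i == 0 else nodes[(i - 1, 0)].maxpool2x2()
            nodes[(i, 0)] = self._grid[(i, 0)](x_in)
        for j in range(1, d + 1):
            for i in range(d + 1 - j):
                inputs = [nodes[(i, jj)] for jj in range(j)]
                inputs.append(nodes[(i + 1, j - 1)].upsample2x())
                nodes[(i, j)] = self._grid[(i, j)](concat(inputs, axis=1))
        if self.deep_supervision:
            outs = [head(nodes[(0, j)]) for j, head in enumerate(self.heads, start=1)]
        else:
            outs = [self.heads[-1](nodes[(0, d)])]
        if self.stem_pool == 2:
            outs = [o.upsample2x() for o in outs]
        return outs

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_logits(x)[-1]


def build_model(config: SegConfig) -> nn.Module:
    """Construct the segmentation network named by ``config.variant``."""
    rng = np.random.default_rng(config.seed)
    if config.variant == "unet":
        return UNet(config, rng=rng)
    if config.variant == "unetpp":
        return UNetPP(config, rng=rng, ise=False)
    return UNetPP(config, rng=rng, ise=True)


# --------------------------------------------------------------------------
# training and inference
# --------------------------------------------------------------------------


def _to_batch(samples: list[TongueSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    x = x.transpose(0, 3, 1, 2)
    t = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    return x, t


def train_segmenter(
    samples: list[TongueSample], config: SegConfig
) -> tuple[nn.Module, TrainingHistory]:
    """Train a segmenter with BCE + soft-Dice loss; history per epoch."""
    if len(samples) < 2:
        raise ValueError("need at least 2 training samples")
    if any(s.mask.max() == 0 for s in samples):
        warnings.warn("dataset contains all-background masks; continuing")
    model = build_model(config)
    history = TrainingHistory()
    if config.epochs == 0:
        return model, history
    x_all, t_all = _to_batch(samples)
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(model.parameters(), lr=config.learning_rate, momentum=config.momentum)
    n = len(samples)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        conf = np.zeros(3)  # TP, FP, FN over the epoch's training predictions
        model.train()
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = Tensor(x_all[idx], requires_grad=True)
            tb = t_all[idx]
            logits = model.forward_logits(xb)
            # deep supervision: uniform mean of per-head losses
            loss = None
            for lg in logits:
                term = nn.bce_with_logits(lg, tb) + nn.soft_dice_loss(lg, tb)
                loss = term if loss is None else loss + term
            loss = loss * (1.0 / len(logits))
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
            pred = logits[-1].data > 0.0
            truth = tb > 0.5
            conf[0] += np.sum(pred & truth)
            conf[1] += np.sum(pred & ~truth)
            conf[2] += np.sum(~pred & truth)
        history.loss.append(epoch_loss / n)
        tp, fp, fn = conf
        history.miou.append(float(tp / (tp + fp + fn)) if (tp + fp + fn) else 1.0)
    return model, history


def segment(model: nn.Module, image: np.ndarray) -> np.ndarray:
    """Predict binary tongue mask(s) by thresholding at probability 0.5."""
    single = image.ndim == 3
    if single:
        image = image[None]
    h, w = image.shape[1], image.shape[2]
    factor = 2 ** model.depth * getattr(model, "stem_pool", 1)
    if h % factor or w % factor:
        raise ValueError(
            f"image size {h}x{w} incompatible with model depth "
            f"{model.depth} (must be divisible by {factor})"
        )
    x = Tensor(image.astype(np.float32).transpose(0, 3, 1, 2) / 255.0)
    model.eval()
    logits = model.forward(x)
    model.train()
    mask = (logits.data[:, 0] > 0.0).astype(np.uint8)  # sigmoid(z) > .5 <=> z > 0
    return mask[0] if single else mask


def seg_metrics(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Pixel-level MIoU / MPA / accuracy from confusion counts."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(truth, (0, 1)).all()):
        raise ValueError("masks must be binary")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    n = tp + tn + fp + fn
    miou = tp / (fn + tp + fp) if (fn + tp + fp) else 1.0
    mpa = (tp + tn) / n
    acc = (tp + tn) / n
    return SegMetrics(miou=float(miou), mpa=float(mpa), accuracy=float(acc))


def improvement_report(results: dict[str, dict[str, float]], reference: str) -> dict[str, dict[str, float]]:
    """Metric deltas of every model against ``reference`` (same units as input).

    ``results`` maps model name -> {metric name -> value}; the report maps the
    other model names -> {metric -> value - reference value}, rounded to 2
    decimals (the precision the metrics are printed at).
    """
    if reference not in results:
        raise ValueError(f"reference model {reference!r} not in results")
    ref = results[reference]
    report: dict[str, dict[str, float]] = {}
    for name, vals in results.items():
        if name == reference:
            continue
        report[name] = {m: round(v - ref[m], 2) for m, v in vals.items() if m in ref}
    return report
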