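"""Deep tongue features from a residual CNN classifier.

A bottleneck residual network (the 50-layer layout by default, a tiny
2-stage preset for CPU tests) is trained to classify constitutions from
*segmented* tongue images — pixels outside the mask are zeroed, so the
network never sees background.  Training uses SGD (default learning rate
1e-3, momentum 0.9) with class-weighted categorical cross-entropy, the
weights inversely proportional to class frequency.  After training, the
globally average-pooled activations of the last stage (the penultimate
layer, ahead of the linear classifier) are exported as the deep feature
embedding — 2048 values per image in the default configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .constitutions import Constitution, CONSTITUTION_ORDER
from .synthetic import TongueSample

__all__ = [
    "BackboneConfig",
    "TINY_BACKBONE_PRESET",
    "EmbeddingMatrix",
    "class_weights",
    "masked_input",
    "build_backbone",
    "train_backbone",
    "extract_embeddings",
]


@dataclass
class BackboneConfig:
    stage_blocks: tuple[int, ...] = (3, 4, 6, 3)
    embedding_dim: int = 2048
    expansion: int = 4
    n_classes: int = 5
    epochs: int = 10
    batch_size: int = 16
    learning_rate: float = 1e-3
    momentum: float = 0.9
    seed: int = 0
    class_weights: tuple[float, ...] | None = None  # None = inverse-frequency
    #: one-step learning-rate decay: multiply lr by `lr_decay_factor` after
    #: `lr_decay_at` of the epochs (1.0 disables)
    lr_decay_factor: float = 0.3
    lr_decay_at: float = 2 / 3

    def __post_init__(self):
        if self.embedding_dim < 8:
            raise ValueError("embedding_dim must be >= 8")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        n = len(self.stage_blocks)
        if self.embedding_dim % 2 ** (n - 1):
            raise ValueError("embedding_dim must be divisible by 2**(n_stages-1)")

    @property
    def stage_channels(self) -> list[int]:
        n = len(self.stage_blocks)
        return [self.embedding_dim // 2 ** (n - 1 - i) for i in range(n)]


def TINY_BACKBONE_PRESET(seed: int = 0, epochs: int = 10, lr: float = 0.05) -> BackboneConfig:
    """2-stage width-16 preset (embedding 64, 64x64 inputs) for CPU runs."""
    return BackboneConfig(
        stage_blocks=(2, 2), embedding_dim=64, expansion=4,
        epochs=epochs, batch_size=25, learning_rate=lr, seed=seed,
    )


@dataclass
class EmbeddingMatrix:
    sample_ids: list[str]
    matrix: np.ndarray  # (N, D)

    @property
    def feature_names(self) -> list[str]:
        return [f"DL_{i}" for i in range(self.matrix.shape[1])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.feature_names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="sample_id")


def class_weights(class_counts: dict | list) -> np.ndarray:
    """Inverse-frequency class weights, count-weighted mean normalized to 1."""
    counts = np.asarray(
        list(class_counts.values()) if isinstance(class_counts, dict) else class_counts,
        dtype=np.float64,
    )
    if (counts < 1).any():
        raise ValueError("all class counts must be >= 1")
    k = len(counts)
    return counts.sum() / (k * counts)


def masked_input(sample: TongueSample) -> np.ndarray:
    """Segmented image: background zeroed outside the mask, scaled to [0,1]."""
    img = sample.image.astype(np.float32) / 255.0
    return img * sample.mask[:, :, None]


class _Bottleneck(nn.Module):
    def __init__(self, c_in: int, c_mid: int, c_out: int, *, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(c_in, c_mid, 1, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_mid)
        self.conv2 = nn.Conv2d(c_mid, c_mid, 3, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_mid)
        self.conv3 = nn.Conv2d(c_mid, c_out, 1, rng=rng)
        self.bn3 = nn.BatchNorm2d(c_out)
        self.proj = None if c_in == c_out else nn.Conv2d(c_in, c_out, 1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        shortcut = x if self.proj is None else self.proj(x)
        return (y + shortcut).relu()


class ResidualBackbone(nn.Module):
    """Bottleneck residual classifier; ``features`` exposes the embedding."""

    def __init__(self, cfg: BackboneConfig, *, rng: np.random.Generator):
        chans = cfg.stage_channels
        stem_w = max(8, chans[0] // cfg.expansion)
        self.stem = nn.Conv2d(3, stem_w, 3, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem_w)
        self.stages: list[list[nn.Module]] = []
        c_in = stem_w
        for blocks, c_out in zip(cfg.stage_blocks, chans):
            c_mid = max(4, c_out // cfg.expansion)
            stage = []
            for _ in range(blocks):
                stage.append(_Bottleneck(c_in, c_mid, c_out, rng=rng))
                c_in = c_out
            self.stages.append(stage)
        self.embedding_dim = chans[-1]
        self.classifier = nn.Linear(self.embedding_dim, cfg.n_classes, rng=rng)
        self.class_labels: list[Constitution] = []
        #: retained activations of the last convolutional stage (Grad-CAM)
        self.last_conv_act: Tensor | None = None

    def features(self, x: Tensor, *, keep_conv: bool = False) -> Tensor:
        y = self.stem_bn(self.stem(x)).relu().maxpool2x2()
        for si, stage in enumerate(self.stages):
            if si > 0:
                y = y.maxpool2x2()
            for blk in stage:
                y = blk(y)
        self.last_conv_act = y if keep_conv else None
        return y.global_avg_pool()

    def forward(self, x: Tensor, *, keep_conv: bool = False) -> Tensor:
        return self.classifier(self.features(x, keep_conv=keep_conv))


def build_backbone(config: BackboneConfig) -> ResidualBackbone:
    return ResidualBackbone(config, rng=np.random.default_rng(config.seed))


def _batchify(samples: list[TongueSample]) -> np.ndarray:
    return np.stack([masked_input(s) for s in samples]).transpose(0, 3, 1, 2)


def train_backbone(
    samples: list[TongueSample], config: BackboneConfig
) -> tuple[ResidualBackbone, "TrainingHistory"]:
    """Fit the residual classifier on segmented images; deterministic per seed."""
    from .segmentation import TrainingHistory  # shared history container

    labels_present = sorted({s.label for s in samples}, key=CONSTITUTION_ORDER.index)
    if config.epochs > 0 and len(labels_present) < 2:
        raise ValueError("training requires samples from at least 2 classes")
    model = build_backbone(config)
    model.class_labels = labels_present
    history = TrainingHistory()
    if config.epochs == 0:
        return model, history
    label_to_idx = {c: i for i, c in enumerate(labels_present)}
    y = np.array([label_to_idx[s.label] for s in samples])
    if config.class_weights is not None:
        w = np.asarray(config.class_weights, dtype=np.float64)
    else:
        counts = np.bincount(y, minlength=len(labels_present))
        w = class_weights(counts.tolist())
    x_all = _batchify(samples)
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(model.parameters(), lr=config.learning_rate, momentum=config.momentum)
    n = len(samples)
    decay_epoch = int(config.epochs * config.lr_decay_at)
    for epoch in range(config.epochs):
        if config.lr_decay_factor != 1.0 and epoch == decay_epoch and epoch > 0:
            opt.lr *= config.lr_decay_factor
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        model.train()
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = Tensor(x_all[idx], requires_grad=True)
            logits = model(xb)
            loss = nn.softmax_cross_entropy(logits, y[idx], w)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {len(history.loss) + 1}; "
                    f"lr={config.learning_rate}, batch={idx.tolist()}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
            correct += int((logits.data.argmax(1) == y[idx]).sum())
        history.loss.append(epoch_loss / n)
        history.miou.append(correct / n)  # training accuracy per epoch
    return model, history


def extract_embeddings(
    model: ResidualBackbone, samples: list[TongueSample], batch_size: int = 32
) -> EmbeddingMatrix:
    """Penultimate-layer (post-GAP) activations, one row per input sample."""
    model.eval()
    rows = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        feats = model.features(Tensor(_batchify(chunk)))
        rows.append(feats.data.copy())
    model.train()
    mat = np.concatenate(rows, axis=0)
    if not np.isfinite(mat).all():
        raise RuntimeError("non-finite embedding values")
    ids = [s.sample_id or f"s{i:04d}" for i, s in enumerate(samples)]
    return EmbeddingMatrix(ids, mat)
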