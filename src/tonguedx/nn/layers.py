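"""Neural-network building blocks on the numpy autograd tape.

Includes the two blocks specific to the improved nested U-Net used for tongue
segmentation: a squeeze-and-excitation (SE) channel-attention unit and an
Inception-style depthwise extraction layer that splits channels into an
identity branch, a small square depthwise convolution, and two orthogonal band
depthwise convolutions (1xk and kx1) whose long kernels capture coating
texture and the overall tongue contour cheaply.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "Linear",
    "SEBlock",
    "InceptionDWConv2d",
    "ConvBlock",
    "ISEExtractionBlock",
    "Sequential",
    "save_params",
    "load_params",
]


def save_params(model: "Module", path) -> None:
    """Serialize parameters and batch-norm running statistics to ``.npz``.

    Arrays are stored in module-traversal order, so the checkpoint can be
    restored into a freshly built model of the identical configuration.
    """
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"p{i}"] = p.data
    for i, m in enumerate(model.modules()):
        if isinstance(m, BatchNorm2d):
            arrays[f"bn{i}_mean"] = m.running_mean
            arrays[f"bn{i}_var"] = m.running_var
    np.savez(path, **arrays)


def load_params(model: "Module", path) -> "Module":
    """Restore a checkpoint written by :func:`save_params` (in place)."""
    data = np.load(path)
    for i, p in enumerate(model.parameters()):
        saved = data[f"p{i}"]
        if saved.shape != p.data.shape:
            raise ValueError(
                f"checkpoint mismatch at parameter {i}: {saved.shape} vs {p.data.shape}"
            )
        p.data = saved.astype(np.float32)
    for i, m in enumerate(model.modules()):
        if isinstance(m, BatchNorm2d):
            m.running_mean = data[f"bn{i}_mean"].astype(np.float32)
            m.running_var = data[f"bn{i}_var"].astype(np.float32)
    return model


class Module:
    """Tiny module base: parameter discovery + train/eval mode propagation."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, bias: bool = True, *, rng: np.random.Generator):
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, (c_out, c_in, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: tuple[int, int], *, rng: np.random.Generator):
        kh, kw = kernel
        scale = np.sqrt(2.0 / (kh * kw))
        self.weight = Tensor(rng.normal(0.0, scale, (channels, kh, kw)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.depthwise_conv2d(self.weight)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, with running stats.

    Training mode differentiates through the batch statistics (fused op);
    evaluation mode normalizes with the running statistics as constants.
    """

    def __init__(self, channels: int, momentum: float = 0.2, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            invstd = 1.0 / np.sqrt(var + self.eps)
            return x.batchnorm(self.gamma, self.beta, mu, invstd, batch_stats=True)
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        return x.batchnorm(self.gamma, self.beta, self.running_mean, invstd, batch_stats=False)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class SEBlock(Module):
    """Squeeze-and-excitation: gate each channel by a scalar in (0, 1).

    The gate is computed from globally average-pooled activations through a
    bottleneck of width ``channels // reduction`` (at least 1).
    """

    def __init__(self, channels: int, reduction: int = 16, *, rng: np.random.Generator):
        if channels < reduction:
            reduction = channels
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.channels = channels

    def gates(self, x: Tensor) -> Tensor:
        z = x.global_avg_pool()
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        g = self.gates(x).reshape(n, self.channels, 1, 1)
        return x * g


class InceptionDWConv2d(Module):
    """Four-branch depthwise extraction layer.

    Channels split into: identity passthrough, a square ``square_k`` depthwise
    convolution, a 1 x ``band_k`` band depthwise convolution, and a
    ``band_k`` x 1 band depthwise convolution, then concatenated.  Each
    convolutional branch receives ``channels * branch_ratio`` channels.
    """

    def __init__(
        self,
        channels: int,
        square_k: int = 3,
        band_k: int = 11,
        branch_ratio: float = 0.125,
        *,
        rng: np.random.Generator,
    ):
        gc = int(channels * branch_ratio)
        if gc < 1 or channels - 3 * gc < 1 or channels * branch_ratio != gc:
            raise ValueError(
                f"channel count {channels} not divisible for Inception branch split "
                f"(need channels * {branch_ratio} to be a positive integer with a "
                "nonempty identity branch; channels must be a multiple of "
                f"{int(round(1 / branch_ratio))})"
            )
        self.gc = gc
        self.channels = channels
        self.dw_square = DepthwiseConv2d(gc, (square_k, square_k), rng=rng)
        self.dw_band_h = DepthwiseConv2d(gc, (1, band_k), rng=rng)
        self.dw_band_w = DepthwiseConv2d(gc, (band_k, 1), rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        gc = self.gc
        ident = x.slice_channels(0, self.channels - 3 * gc)
        a = self.dw_square(x.slice_channels(self.channels - 3 * gc, self.channels - 2 * gc))
        b = self.dw_band_h(x.slice_channels(self.channels - 2 * gc, self.channels - gc))
        c = self.dw_band_w(x.slice_channels(self.channels - gc, self.channels))
        return concat([ident, a, b, c], axis=1)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ConvBlock(Module):
    """Plain double 3x3 convolution block: [conv-BN-ReLU] x 2."""

    def __init__(self, c_in: int, c_out: int, *, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng)
        self.bn2 = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class ISEExtractionBlock(Module):
    """Extraction layer of the improved nested U-Net interior nodes.

    A pointwise mixing convolution maps the concatenated skip channels to the
    node width, then two Inception depthwise layers in tandem enlarge the
    receptive field at depthwise cost, and an SE unit reweights the channels.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        se_reduction: int = 16,
        square_k: int = 3,
        band_k: int = 11,
        *,
        rng: np.random.Generator,
    ):
        self.mix = Conv2d(c_in, c_out, 1, rng=rng)
        self.bn0 = BatchNorm2d(c_out)
        self.incep1 = InceptionDWConv2d(c_out, square_k, band_k, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.incep2 = InceptionDWConv2d(c_out, square_k, band_k, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.se = SEBlock(c_out, se_reduction, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn0(self.mix(x)).relu()
        x = self.bn1(self.incep1(x)).relu()
        x = self.bn2(self.incep2(x)).relu()
        return self.se(x)
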