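"""Residual convolutional trunks (18/34-layer basic-block configurations).

The trunk is the standard residual-network layout with two changes needed
for range-Doppler input: a single-channel stem and no classification head
(the trunk ends at global average pooling).  ``base_channels`` scales the
stage widths uniformly so a narrow trunk can be trained on one CPU.
"""

from __future__ import annotations

import numpy as np

from .core import Module, Sequential
from .layers import BatchNorm2d, Conv2d, GlobalAvgPool2d, MaxPool2d, ReLU

#: basic-block counts per stage
DEPTH_CONFIGS = {18: (2, 2, 2, 2), 34: (3, 4, 6, 3)}


class BasicBlock(Module):
    """Two 3x3 conv/BN pairs with an identity (or 1x1-projected) shortcut."""

    def __init__(self, in_channels, out_channels, stride, rng, dtype=np.float32,
                 zero_init_residual=False):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride, 1, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(out_channels, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, 1, 1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(out_channels, dtype=dtype)
        if zero_init_residual:
            # each block starts as (near-)identity: faster short-budget training
            self.bn2.gamma.value[...] = 0.0
        self.relu2 = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.downsample = Sequential(
                Conv2d(in_channels, out_channels, 1, stride, 0, rng=rng, dtype=dtype),
                BatchNorm2d(out_channels, dtype=dtype),
            )
        else:
            self.downsample = None

    def forward(self, x):
        identity = self.downsample.forward(x) if self.downsample is not None else x
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        h = self.bn2.forward(self.conv2.forward(h))
        return self.relu2.forward(h + identity)

    def backward(self, grad):
        g = self.relu2.backward(grad)
        gh = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(g))))
        )
        gid = self.downsample.backward(g) if self.downsample is not None else g
        return gh + gid


class ResNetTrunk(Module):
    """Headless residual network mapping (B, in_channels, H, W) -> (B, 8*base_channels)."""

    def __init__(self, depth=34, in_channels=1, base_channels=64, rng=None,
                 dtype=np.float32, zero_init_residual=False):
        super().__init__()
        if depth not in DEPTH_CONFIGS:
            raise ValueError(f"unsupported depth {depth}; choose from {sorted(DEPTH_CONFIGS)}")
        rng = rng if rng is not None else np.random.default_rng(0)
        blocks_per_stage = DEPTH_CONFIGS[depth]
        widths = [base_channels * m for m in (1, 2, 4, 8)]

        layers: list[Module] = [
            Conv2d(in_channels, widths[0], 7, 2, 3, rng=rng, dtype=dtype),
            BatchNorm2d(widths[0], dtype=dtype),
            ReLU(),
            MaxPool2d(3, 2, 1),
        ]
        prev = widths[0]
        for stage, (width, n_blocks) in enumerate(zip(widths, blocks_per_stage)):
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                layers.append(BasicBlock(prev, width, stride, rng, dtype=dtype,
                                         zero_init_residual=zero_init_residual))
                prev = width
        layers.append(GlobalAvgPool2d())
        self.body = Sequential(*layers)
        self.depth = depth
        self.in_channels = in_channels
        self.base_channels = base_channels
        self.out_dim = widths[-1]

    def forward(self, x):
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (B, {self.in_channels}, H, W) input, got shape {x.shape}"
            )
        return self.body.forward(x)

    def backward(self, grad):
        return self.body.backward(grad)

    def conv_layers(self):
        """All convolution layers, stem first (for architecture inventory checks)."""
        return [m for m in self.modules() if isinstance(m, Conv2d)]
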