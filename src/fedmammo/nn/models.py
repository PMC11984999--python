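"""Network architectures: a UNet for breast-area segmentation and a compact
CNN for BIRADS classification.

Both are deliberately small — the classification model is kept under two
million parameters so that shipping it between federated clients every round
is cheap, and the UNet defaults suit desk-scale training on synthetic
phantoms. Scale (base channels, depth) is configurable.
"""

from __future__ import annotations

import numpy as np

from .engine import (
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2,
    Module,
    ReLU,
    Upsample2,
)


class _DoubleConv:
    """Two 3x3 conv+ReLU pairs registered on a parent module."""

    def __init__(self, module: Module, name: str, cin: int, cout: int, rng):
        self.c1 = module.add(f"{name}.conv1", Conv2d(cin, cout, 3, rng))
        self.r1 = module.add(f"{name}.relu1", ReLU())
        self.c2 = module.add(f"{name}.conv2", Conv2d(cout, cout, 3, rng))
        self.r2 = module.add(f"{name}.relu2", ReLU())

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, g):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(g))))


class UNet(Module):
    """Encoder-decoder segmentation network with skip connections.

    ``depth`` down/up levels with ``base`` channels at the top; input height
    and width must be divisible by ``2**depth``. ``forward`` returns logits of
    shape (N, 1, H, W).
    """

    def __init__(self, in_channels: int = 1, base: int = 8, depth: int = 3, seed: int = 0):
        super().__init__()
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
        self.depth = depth
        self.base = base
        self.in_channels = in_channels
        chans = [base * 2**i for i in range(depth + 1)]
        self.enc = []
        self.pools = []
        cin = in_channels
        for i in range(depth):
            self.enc.append(_DoubleConv(self, f"enc{i}", cin, chans[i], rng))
            self.pools.append(self.add(f"pool{i}", MaxPool2()))
            cin = chans[i]
        self.bottleneck = _DoubleConv(self, "bottleneck", chans[depth - 1], chans[depth], rng)
        self.ups = []
        self.upconvs = []
        self.dec = []
        for i in reversed(range(depth)):
            above = chans[i + 1]
            self.ups.append(self.add(f"up{i}", Upsample2()))
            self.upconvs.append(self.add(f"upconv{i}", Conv2d(above, chans[i], 3, rng)))
            self.dec.append(_DoubleConv(self, f"dec{i}", 2 * chans[i], chans[i], rng))
        self.final = self.add("final", Conv2d(base, 1, 1, rng))
        self._chans = chans

    def forward(self, x):
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2] % 2**self.depth or x.shape[3] % 2**self.depth:
            raise ValueError(
                f"input size {x.shape[2:]} must be divisible by {2**self.depth}"
            )
        skips = []
        h = x
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        for j, i in enumerate(reversed(range(self.depth))):
            h = self.ups[j].forward(h)
            h = self.upconvs[j].forward(h)
            h = np.concatenate([h, skips[i]], axis=1)
            h = self.dec[j].forward(h)
        return self.final.forward(h)

    def backward(self, gout):
        g = self.final.backward(gout)
        skip_grads: dict[int, np.ndarray] = {}
        # decode stages ran stage = 0..depth-1 over levels depth-1..0
        for stage in reversed(range(self.depth)):
            level = self.depth - 1 - stage
            g = self.dec[stage].backward(g)
            c = self._chans[level]
            g_up, g_skip = g[:, :c], g[:, c:]
            skip_grads[level] = g_skip
            g = self.upconvs[stage].backward(np.ascontiguousarray(g_up))
            g = self.ups[stage].backward(g)
        g = self.bottleneck.backward(g)
        for i in reversed(range(self.depth)):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)
        return g


class SmallCNN(Module):
    """Conv-pool stack with global average pooling and a linear head.

    The classification architecture: ``n_blocks`` conv+ReLU+maxpool stages
    doubling channels from ``base``, global average pooling, then a linear
    layer with one output per class. Input height/width must be divisible by
    ``2**n_blocks``.
    """

    def __init__(
        self,
        n_classes: int = 5,
        in_channels: int = 1,
        base: int = 8,
        n_blocks: int = 3,
        seed: int = 0,
    ):
        super().__init__()
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
        self.n_classes = n_classes
        self.n_blocks = n_blocks
        self._seq = []
        cin = in_channels
        for i in range(n_blocks):
            cout = base * 2**i
            self._seq.append(self.add(f"conv{i}", Conv2d(cin, cout, 3, rng)))
            self._seq.append(self.add(f"relu{i}", ReLU()))
            self._seq.append(self.add(f"pool{i}", MaxPool2()))
            cin = cout
        self._seq.append(self.add("gap", GlobalAvgPool()))
        self._seq.append(self.add("head", Linear(cin, n_classes, rng)))

    def forward(self, x):
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2] % 2**self.n_blocks or x.shape[3] % 2**self.n_blocks:
            raise ValueError(
                f"input size {x.shape[2:]} must be divisible by {2**self.n_blocks}"
            )
        h = x
        for layer in self._seq:
            h = layer.forward(h)
        return h

    def backward(self, gout):
        g = gout
        for layer in reversed(self._seq):
            g = layer.backward(g)
        return g
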