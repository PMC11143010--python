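"""Encoder blocks (plain / residual / dense) and the U-net graph.

All three architectures share the plain U-net decoder (transpose-convolution
upsampling, skip concatenation, two conv-BN-ReLU stages); they differ only in
the encoder/bottleneck block type:

* plain: two conv-BN-ReLU stages;
* residual: the two-stage path plus an identity shortcut (1x1 projection
  when the channel count changes), ReLU after the sum;
* dense: two 3x3 stages whose inputs are the concatenation of all previous
  outputs in the block, fused by a 1x1 transition back to the block width.

For a fixed width the parameter counts order strictly dense > residual >
plain, since residual adds the 1x1 projection and dense additionally widens
the second 3x3 stage and adds the transition.
"""

from __future__ import annotations

import numpy as np

from echoquant.nn.layers import BatchNorm2d, Conv2d, ConvTranspose2, MaxPool2, ReLU


class ConvBNReLU:
    def __init__(self, cin, cout, k=3, rng=None):
        self.conv = Conv2d(cin, cout, k=k, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def buffers(self):
        return self.bn.buffers()

    def forward(self, x, train=True):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dout):
        return self.conv.backward(self.bn.backward(self.relu.backward(dout)))


class PlainBlock:
    """Two 3x3 conv-BN-ReLU stages (the classic U-net block)."""

    def __init__(self, cin, cout, rng=None):
        self.s1 = ConvBNReLU(cin, cout, rng=rng)
        self.s2 = ConvBNReLU(cout, cout, rng=rng)

    def params(self):
        return self.s1.params() + self.s2.params()

    def buffers(self):
        return self.s1.buffers() + self.s2.buffers()

    def forward(self, x, train=True):
        return self.s2.forward(self.s1.forward(x, train), train)

    def backward(self, dout):
        return self.s1.backward(self.s2.backward(dout))


class ResBlock:
    """Residual block: conv-BN-ReLU, conv-BN, + shortcut, ReLU."""

    def __init__(self, cin, cout, rng=None):
        self.s1 = ConvBNReLU(cin, cout, rng=rng)
        self.conv2 = Conv2d(cout, cout, k=3, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.proj = Conv2d(cin, cout, k=1, bias=False, rng=rng) if cin != cout else None
        self.relu = ReLU()

    def params(self):
        p = self.s1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            p += self.proj.params()
        return p

    def buffers(self):
        return self.s1.buffers() + self.bn2.buffers()

    def forward(self, x, train=True):
        main = self.bn2.forward(self.conv2.forward(self.s1.forward(x, train), train), train)
        short = x if self.proj is None else self.proj.forward(x, train)
        return self.relu.forward(main + short, train)

    def backward(self, dout):
        d = self.relu.backward(dout)
        dmain = self.s1.backward(self.conv2.backward(self.bn2.backward(d)))
        dshort = d if self.proj is None else self.proj.backward(d)
        return dmain + dshort


class DenseBlock:
    """Dense block: two 3x3 stages on growing concatenations + 1x1 fuse."""

    def __init__(self, cin, cout, rng=None):
        self.s1 = ConvBNReLU(cin, cout, rng=rng)
        self.s2 = ConvBNReLU(cin + cout, cout, rng=rng)
        self.fuse = ConvBNReLU(cin + 2 * cout, cout, k=1, rng=rng)
        self.cin, self.cout = cin, cout

    def params(self):
        return self.s1.params() + self.s2.params() + self.fuse.params()

    def buffers(self):
        return self.s1.buffers() + self.s2.buffers() + self.fuse.buffers()

    def forward(self, x, train=True):
        h1 = self.s1.forward(x, train)
        h2 = self.s2.forward(np.concatenate([x, h1], axis=1), train)
        return self.fuse.forward(np.concatenate([x, h1, h2], axis=1), train)

    def backward(self, dout):
        c, g = self.cin, self.cout
        dcat3 = self.fuse.backward(dout)
        dx = dcat3[:, :c].copy()
        dh1 = dcat3[:, c:c + g].copy()
        dh2 = dcat3[:, c + g:]
        dcat2 = self.s2.backward(np.ascontiguousarray(dh2))
        dx += dcat2[:, :c]
        dh1 += dcat2[:, c:]
        dx += self.s1.backward(np.ascontiguousarray(dh1))
        return dx


_BLOCKS = {"unet": PlainBlock, "res_unet": ResBlock, "dense_unet": DenseBlock}


class UNet:
    """Encoder-decoder with skip connections; encoder block type per arch."""

    def __init__(self, arch: str, levels: int, base_channels: int, n_classes: int,
                 in_channels: int = 1, rng: np.random.Generator | None = None):
        if arch not in _BLOCKS:
            raise ValueError(f"unknown arch {arch!r}; expected one of {sorted(_BLOCKS)}")
        if levels < 1:
            raise ValueError("levels must be >= 1")
        rng = rng or np.random.default_rng(0)
        Block = _BLOCKS[arch]
        self.arch, self.levels = arch, levels
        widths = [base_channels * 2**l for l in range(levels)]

        self.enc, self.pools = [], []
        cin = in_channels
        for c in widths:
            self.enc.append(Block(cin, c, rng=rng))
            self.pools.append(MaxPool2())
            cin = c
        self.bottleneck = Block(cin, base_channels * 2**levels, rng=rng)
        self.ups, self.dec = [], []
        cin = base_channels * 2**levels
        for c in reversed(widths):
            self.ups.append(ConvTranspose2(cin, c, rng=rng))
            self.dec.append(PlainBlock(2 * c, c, rng=rng))
            cin = c
        self.head = Conv2d(base_channels, n_classes, k=1, bias=True, rng=rng)
        self._skip_channels = list(reversed(widths))

    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for up, dec in zip(self.ups, self.dec):
            out += up.params() + dec.params()
        out += self.head.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.v.size for p in self.params())

    def buffers(self):
        """Non-trainable state (BatchNorm running statistics), in param order."""
        out = []
        for blk in self.enc:
            out += blk.buffers()
        out += self.bottleneck.buffers()
        for up, dec in zip(self.ups, self.dec):
            out += up.buffers() + dec.buffers()
        out += self.head.buffers()
        return out

    def get_weights(self):
        """Snapshot of all trainable parameters and BatchNorm running stats."""
        return [p.v.copy() for p in self.params()] + [b.copy() for b in self.buffers()]

    def set_weights(self, weights):
        params = self.params()
        buffers = self.buffers()
        if len(weights) != len(params) + len(buffers):
            raise ValueError("weight list does not match network structure")
        for p, w in zip(params, weights[:len(params)]):
            p.v[...] = w
        for b, w in zip(buffers, weights[len(params):]):
            b[...] = w

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError("input must be (N, C, H, W)")
        h, w = x.shape[2], x.shape[3]
        if h % 2**self.levels or w % 2**self.levels:
            raise ValueError(f"input size {h}x{w} not divisible by 2^levels={2**self.levels}")
        skips = []
        out = np.ascontiguousarray(x, dtype=np.float32)
        for blk, pool in zip(self.enc, self.pools):
            out = blk.forward(out, train)
            skips.append(out)
            out = pool.forward(out, train)
        out = self.bottleneck.forward(out, train)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            out = up.forward(out, train)
            out = dec.forward(np.concatenate([skip, out], axis=1), train)
        return self.head.forward(out, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for up, dec, c in zip(reversed(self.ups), reversed(self.dec),
                              reversed(self._skip_channels)):
            dcat = dec.backward(d)
            dskips.append(np.ascontiguousarray(dcat[:, :c]))
            d = up.backward(np.ascontiguousarray(dcat[:, c:]))
        d = self.bottleneck.backward(d)
        # dskips were collected shallow-to-deep; the encoder unwinds deepest-first
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            d = pool.backward(d) + dskip
            d = blk.backward(d)
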