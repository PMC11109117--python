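"""U-Net and tiny residual classifier built from the engine's layers.

Both models expose ``forward``/``backward`` (training), ``params`` (for the
optimizer), ``state_dict``/``load_state_dict`` (npz-serializable), and
inference helpers operating on single uint8 HWC images.
"""

from __future__ import annotations

import numpy as np

from scoredfu.nn.layers import (
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2,
    ReLU,
    Upsample2,
)
from scoredfu.nn.losses import softmax

#: Per-channel normalization constants applied to uint8 images scaled to [0,1].
NORM_MEAN = 0.5
NORM_STD = 0.25


def normalize_image(img: np.ndarray) -> np.ndarray:
    """uint8 HWC image -> standardized float32 CHW tensor."""
    x = img.astype(np.float32) / 255.0
    x = (x - NORM_MEAN) / NORM_STD
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def normalize_batch(imgs) -> np.ndarray:
    return np.stack([normalize_image(im) for im in imgs])


class ConvBlock:
    """Conv-ReLU-Conv-ReLU."""

    def __init__(self, c_in, c_out, rng):
        self.conv1 = Conv2d(c_in, c_out, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, rng=rng)
        self.relu2 = ReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x):
        return self.relu2.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(x))))

    def backward(self, dy):
        return self.conv1.backward(self.relu1.backward(self.conv2.backward(self.relu2.backward(dy))))


class UNet:
    """Encoder-decoder segmenter with skip connections.

    ``depth`` down/up-sampling levels, ``base`` channels at the top level,
    ``classes`` output maps (2 for the binary stage, 7 for the subcategory
    stage). Output spatial dims equal input dims; input dims must be
    divisible by 2**depth.
    """

    def __init__(self, classes: int, base: int = 8, depth: int = 2,
                 in_channels: int = 3, seed: int = 0):
        if classes < 2:
            raise ValueError(f"classes must be >= 2, got {classes}")
        rng = np.random.default_rng(seed)
        self.classes = classes
        self.base = base
        self.depth = depth
        self.in_channels = in_channels
        self.seed = seed

        self.enc = []
        c = in_channels
        for d in range(depth):
            self.enc.append(ConvBlock(c, base * 2**d, rng))
            c = base * 2**d
        self.bottleneck = ConvBlock(c, base * 2**depth, rng)
        self.pools = [MaxPool2() for _ in range(depth)]
        self.ups = [Upsample2() for _ in range(depth)]
        self.dec = []
        for d in reversed(range(depth)):
            skip_c = base * 2**d
            up_c = base * 2 ** (d + 1)
            self.dec.append(ConvBlock(skip_c + up_c, skip_c, rng))
        self.head = Conv2d(base, classes, k=1, rng=rng)

    def params(self):
        ps = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for blk in self.dec:
            ps += blk.params()
        ps += self.head.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = []
        for blk, up, skip in zip(self.dec, self.ups, reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.head.backward(dlogits)
        dskips = []
        for blk, up, sc in zip(reversed(self.dec), reversed(self.ups),
                               reversed(self._skip_channels)):
            d = blk.backward(dh)
            dskips.append(d[:, :sc])
            dh = up.backward(d[:, sc:])
        dh = self.bottleneck.backward(dh)
        # dskips were collected shallow-first; encoder unwinds deep-first
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            dh = pool.backward(dh) + dskip
            dh = blk.backward(dh)
        return dh

    # inference -------------------------------------------------------------
    def predict_logits(self, image: np.ndarray) -> np.ndarray:
        """uint8 HWC image -> (classes, H, W) logits."""
        x = normalize_image(image)[None]
        return self.forward(x)[0]

    def predict_labelmap(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel argmax codes; ``np.argmax`` keeps the lowest code on ties."""
        return self.predict_logits(image).argmax(axis=0).astype(np.uint8)

    # serialization ---------------------------------------------------------
    def config(self) -> dict:
        return {
            "kind": "unet",
            "classes": self.classes,
            "base": self.base,
            "depth": self.depth,
            "in_channels": self.in_channels,
            "seed": self.seed,
        }

    def named_params(self):
        out = {}
        for i, blk in enumerate(self.enc):
            out[f"enc{i}.conv1.w"], out[f"enc{i}.conv1.b"] = blk.conv1.params()
            out[f"enc{i}.conv2.w"], out[f"enc{i}.conv2.b"] = blk.conv2.params()
        out["bott.conv1.w"], out["bott.conv1.b"] = self.bottleneck.conv1.params()
        out["bott.conv2.w"], out["bott.conv2.b"] = self.bottleneck.conv2.params()
        for i, blk in enumerate(self.dec):
            out[f"dec{i}.conv1.w"], out[f"dec{i}.conv1.b"] = blk.conv1.params()
            out[f"dec{i}.conv2.w"], out[f"dec{i}.conv2.b"] = blk.conv2.params()
        out["head.w"], out["head.b"] = self.head.params()
        return out

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_params().items()}

    def load_state_dict(self, state: dict):
        for k, p in self.named_params().items():
            p.data[...] = state[k]

    def encoder_params(self):
        """Encoder + bottleneck params, for warm-starting (transfer) runs."""
        ps = []
        for blk in self.enc:
            ps += blk.params()
        return ps + self.bottleneck.params()


class ResBlock:
    """conv-relu-conv plus identity (or 1x1 projection) skip, then ReLU."""

    def __init__(self, c_in, c_out, rng):
        self.conv1 = Conv2d(c_in, c_out, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, rng=rng)
        self.proj = Conv2d(c_in, c_out, k=1, rng=rng) if c_in != c_out else None
        self.relu_out = ReLU()

    def params(self):
        ps = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x):
        main = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        skip = self.proj.forward(x) if self.proj is not None else x
        return self.relu_out.forward(main + skip)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dmain = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        dskip = self.proj.backward(d) if self.proj is not None else d
        return dmain + dskip


class ResNetTiny:
    """Small residual classifier: stem, two residual stages, GAP, linear head.

    The activation after the last residual block is cached on every forward
    pass (and its gradient on every backward pass) so class-activation maps
    can be formed without re-running the network.
    """

    def __init__(self, num_classes: int = 4, base: int = 8, in_channels: int = 3,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.num_classes = num_classes
        self.base = base
        self.in_channels = in_channels
        self.seed = seed

        self.stem = Conv2d(in_channels, base, rng=rng)
        self.stem_relu = ReLU()
        self.pool1 = MaxPool2()
        self.block1 = ResBlock(base, base, rng)
        self.pool2 = MaxPool2()
        self.block2 = ResBlock(base, 2 * base, rng)
        self.pool3 = MaxPool2()
        self.gap = GlobalAvgPool()
        self.fc = Linear(2 * base, num_classes, rng=rng)

        self.features = None       # last conv-block activation (N, C, h, w)
        self.feature_grad = None   # its gradient from the last backward pass

    def params(self):
        return (self.stem.params() + self.block1.params() + self.block2.params()
                + self.fc.params())

    def param_count(self) -> int:
        return sum(p.data.size for p in self.params())

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.pool1.forward(self.stem_relu.forward(self.stem.forward(x)))
        h = self.pool2.forward(self.block1.forward(h))
        h = self.block2.forward(h)
        self.features = h
        h = self.pool3.forward(h)
        return self.fc.forward(self.gap.forward(h))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.gap.backward(self.fc.backward(dlogits))
        dh = self.pool3.backward(dh)
        self.feature_grad = dh
        dh = self.block2.backward(dh)
        dh = self.pool2.backward(dh)
        dh = self.block1.backward(dh)
        dh = self.pool1.backward(dh)
        return self.stem.backward(self.stem_relu.backward(dh))

    # inference -------------------------------------------------------------
    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        x = normalize_image(image)[None]
        return softmax(self.forward(x), axis=1)[0]

    # serialization ---------------------------------------------------------
    def config(self) -> dict:
        return {
            "kind": "resnet_tiny",
            "num_classes": self.num_classes,
            "base": self.base,
            "in_channels": self.in_channels,
            "seed": self.seed,
        }

    def named_params(self):
        out = {"stem.w": self.stem.weight, "stem.b": self.stem.bias}
        for name, blk in (("block1", self.block1), ("block2", self.block2)):
            out[f"{name}.conv1.w"], out[f"{name}.conv1.b"] = blk.conv1.params()
            out[f"{name}.conv2.w"], out[f"{name}.conv2.b"] = blk.conv2.params()
            if blk.proj is not None:
                out[f"{name}.proj.w"], out[f"{name}.proj.b"] = blk.proj.params()
        out["fc.w"], out["fc.b"] = self.fc.params()
        return out

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_params().items()}

    def load_state_dict(self, state: dict):
        for k, p in self.named_params().items():
            p.data[...] = state[k]

    def backbone_params(self):
        """All params except the classification head, for warm starts."""
        return self.stem.params() + self.block1.params() + self.block2.params()
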