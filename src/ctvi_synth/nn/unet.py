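"""2D U-Net for image-to-image regression of ventilation from CT slices.

Topology: at each encoder level two 3x3 ReLU convolutions followed by 2x2
max pooling; a two-convolution bottleneck; at each decoder level a 2x2
stride-2 transposed convolution, concatenation with the matching encoder
feature map, and two 3x3 ReLU convolutions; a final 1x1 sigmoid convolution
producing one channel in (0, 1).  All convolutions use 'same' padding and
He initialization.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2D, ConvTranspose2, MaxPool2, Param

#: Encoder widths and bottleneck width of the full-scale network.  This
#: near-doubling schedule realizes the published trainable-parameter budget
#: of the reference architecture exactly: 1,962,901 trainable, 0 non-trainable.
FULL_SCALE_ENCODER_FILTERS = (14, 28, 54, 108)
FULL_SCALE_BOTTLENECK_FILTERS = 310


class UNet:
    """A trainable U-Net built from the NumPy layers in this package."""

    def __init__(
        self,
        in_channels: int = 3,
        encoder_filters: tuple[int, ...] = (8, 16, 32),
        bottleneck_filters: int = 64,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.encoder_filters = tuple(int(f) for f in encoder_filters)
        self.bottleneck_filters = int(bottleneck_filters)
        self.depth = len(self.encoder_filters)

        self.enc_blocks: list[list[Conv2D]] = []
        self.pools: list[MaxPool2] = []
        c = in_channels
        for lvl, f in enumerate(self.encoder_filters):
            block = [
                Conv2D(c, f, rng, name=f"enc{lvl}a"),
                Conv2D(f, f, rng, name=f"enc{lvl}b"),
            ]
            self.enc_blocks.append(block)
            self.pools.append(MaxPool2())
            c = f
        fb = self.bottleneck_filters
        self.bottleneck = [
            Conv2D(c, fb, rng, name="bot_a"),
            Conv2D(fb, fb, rng, name="bot_b"),
        ]
        c = fb
        self.ups: list[ConvTranspose2] = []
        self.dec_blocks: list[list[Conv2D]] = []
        for lvl in reversed(range(self.depth)):
            f = self.encoder_filters[lvl]
            self.ups.append(ConvTranspose2(c, f, rng, name=f"up{lvl}"))
            self.dec_blocks.append([
                Conv2D(2 * f, f, rng, name=f"dec{lvl}a"),
                Conv2D(f, f, rng, name=f"dec{lvl}b"),
            ])
            c = f
        self.head = Conv2D(c, 1, rng, kernel=1, activation="sigmoid", name="head")

    # -- bookkeeping ---------------------------------------------------
    def params(self) -> list[Param]:
        out = []
        for block in self.enc_blocks:
            for layer in block:
                out.extend(layer.params())
        for layer in self.bottleneck:
            out.extend(layer.params())
        for up, block in zip(self.ups, self.dec_blocks):
            out.extend(up.params())
            for layer in block:
                out.extend(layer.params())
        out.extend(self.head.params())
        return out

    def freeze_all(self) -> None:
        for p in self.params():
            p.trainable = False

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def check_input_shape(self, h: int, w: int) -> None:
        d = 2 ** self.depth
        if h % d or w % d:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth={d}; choose a "
                "compatible crop shape"
            )

    # -- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (B, C, H, W) float32 -> (B, 1, H, W) predictions in (0, 1)."""
        self.check_input_shape(x.shape[2], x.shape[3])
        skips = []
        # channels-last internally
        h = np.ascontiguousarray(
            np.asarray(x, dtype=np.float32).transpose(0, 2, 3, 1)
        )
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                h = layer.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        for layer in self.bottleneck:
            h = layer.forward(h, train)
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h, train)
            h = np.concatenate([skip, h], axis=-1)
            for layer in block:
                h = layer.forward(h, train)
        out = self.head.forward(h, train)
        return out.transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients given d(loss)/d(prediction)."""
        g = self.head.backward(
            np.ascontiguousarray(np.asarray(dy, np.float32).transpose(0, 2, 3, 1))
        )
        skip_grads = []
        for up, block in zip(reversed(self.ups), reversed(self.dec_blocks)):
            for layer in reversed(block):
                g = layer.backward(g)
            f = up.c_out
            skip_grads.append(g[..., :f])
            g = up.backward(np.ascontiguousarray(g[..., f:]))
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        # skip_grads were collected shallow-to-deep; encoder backward runs
        # deep-to-shallow
        for block, pool, gs in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g) + gs
            for layer in reversed(block):
                g = layer.backward(g)

    # -- persistence -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"missing weight {p.name}")
            if state[p.name].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value[...] = state[p.name]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})
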