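"""A compact 3D U-Net assembled from the numpy layers.

Encoder: ``depth`` levels of (conv–norm–ReLU ×2) + 2× max-pool, channel
width doubling per level; a bottleneck double-conv; decoder: trilinear
up, skip concatenation, double-conv; a final 1×1×1 conv to the output
logits.  Tensors are channels-last; the input cube side must be divisible by ``2**depth``.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv3d, InstanceNorm3d, MaxPool3d, ReLU, Sequential, TrilinearUp3d

__all__ = ["UNet3D"]


def _double_conv(c_in: int, c_out: int, rng) -> Sequential:
    return Sequential(
        Conv3d(c_in, c_out, 3, rng),
        InstanceNorm3d(c_out),
        ReLU(),
        Conv3d(c_out, c_out, 3, rng),
        InstanceNorm3d(c_out),
        ReLU(),
    )


class UNet3D:
    def __init__(self, in_channels: int = 1, out_channels: int = 2, base_channels: int = 8, depth: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.base_channels, self.depth = base_channels, depth
        self.enc = []
        self.pools = []
        c = in_channels
        for level in range(depth):
            width = base_channels * 2**level
            self.enc.append(_double_conv(c, width, rng))
            self.pools.append(MaxPool3d())
            c = width
        self.bottleneck = _double_conv(c, base_channels * 2**depth, rng)
        self.ups = []
        self.dec = []
        for level in reversed(range(depth)):
            width = base_channels * 2**level
            self.ups.append(TrilinearUp3d())
            self.dec.append(_double_conv(base_channels * 2 ** (level + 1) + width, width, rng))
        self.head = Conv3d(base_channels, out_channels, 1, rng)

    # --- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Channels-last (B, D, H, W, C_in) → logits (B, D, H, W, C_out)."""
        if any(s % 2**self.depth for s in x.shape[1:4]):
            raise ValueError(f"input spatial shape {x.shape[1:4]} not divisible by 2^{self.depth}")
        skips = []
        h = x
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append(skip.shape[-1])
            h = dec.forward(np.concatenate([skip, h], axis=-1))
        return self.head.forward(h)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        skip_grads = []
        for dec, up, c_skip in zip(reversed(self.dec), reversed(self.ups), reversed(self._skip_channels)):
            g_cat = dec.backward(g)
            skip_grads.append(g_cat[..., :c_skip])
            g = up.backward(g_cat[..., c_skip:])
        g = self.bottleneck.backward(g)
        # skip_grads were collected shallowest-first; encoders unwind deepest-first
        for enc, pool, g_skip in zip(reversed(self.enc), reversed(self.pools), reversed(skip_grads)):
            g = pool.backward(g)
            g = enc.backward(g + g_skip)

    # --- parameter access -------------------------------------------------------

    def modules(self):
        for i, m in enumerate(self.enc):
            yield f"enc{i}.", m
        yield "bottleneck.", self.bottleneck
        for i, m in enumerate(self.dec):
            yield f"dec{i}.", m
        yield "head.", self.head

    def named_params(self):
        """Yields (name, layer, key) for every learnable array."""
        for prefix, module in self.modules():
            layers = module.layers if isinstance(module, Sequential) else [module]
            for j, layer in enumerate(layers):
                for key in layer.params:
                    yield f"{prefix}{j}.{key}", layer, key

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: layer.params[key].copy() for name, layer, key in self.named_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, key in self.named_params():
            layer.params[key] = np.asarray(state[name], dtype=np.float32).reshape(layer.params[key].shape)

    def checksum(self) -> float:
        return float(sum(np.abs(v).sum() for v in self.state_dict().values()))
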