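"""Small UNet-style noise predictor for the diffusion model.

Three resolutions (HxW, H/2, H/4), a sinusoidal timestep embedding projected
into each block as a per-channel bias, nearest-neighbour up/average-pool
down sampling and skip connections by channel concatenation.  The output
convolution is zero-initialized so the untrained model predicts zero noise.
"""

from __future__ import annotations

import numpy as np

from .layers import (AvgPool2, Conv2d, Dense, SiLU, Upsample2,
                     sinusoidal_embedding)


class ConvBlock:
    """conv -> +time bias -> SiLU -> conv -> SiLU."""

    def __init__(self, cin: int, cout: int, temb_dim: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, rng=rng)
        self.tproj = Dense(temb_dim, cout, rng=rng)
        self.conv2 = Conv2d(cout, cout, rng=rng)
        self.act1 = SiLU()
        self.act2 = SiLU()

    def parameters(self):
        return self.conv1.parameters() + self.tproj.parameters() + self.conv2.parameters()

    def forward(self, x: np.ndarray, temb: np.ndarray) -> np.ndarray:
        h = self.conv1.forward(x)
        h = h + self.tproj.forward(temb)[:, :, None, None]
        h = self.act1.forward(h)
        h = self.conv2.forward(h)
        return self.act2.forward(h)

    def backward(self, dy: np.ndarray, param_grads: bool = True) -> np.ndarray:
        dh = self.act2.backward(dy)
        dh = self.conv2.backward(dh, param_grads)
        dh = self.act1.backward(dh)
        self.tproj.backward(dh.sum(axis=(2, 3)), param_grads)
        return self.conv1.backward(dh, param_grads)


class SmallUNet:
    """(x_t, t) -> predicted noise, same shape as x_t."""

    def __init__(self, in_channels: int, base_channels: int = 8, temb_dim: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        c1, c2 = base_channels, 2 * base_channels
        self.in_channels = in_channels
        self.base_channels = base_channels
        self.temb_dim = temb_dim
        self.tmlp = Dense(temb_dim, temb_dim, rng=rng)
        self.tact = SiLU()
        self.enc1 = ConvBlock(in_channels, c1, temb_dim, rng)
        self.enc2 = ConvBlock(c1, c2, temb_dim, rng)
        self.mid = ConvBlock(c2, c2, temb_dim, rng)
        self.dec2 = ConvBlock(2 * c2, c2, temb_dim, rng)
        self.dec1 = ConvBlock(c2 + c1, c1, temb_dim, rng)
        self.out = Conv2d(c1, in_channels, zero_init=True)
        self.pool1, self.pool2 = AvgPool2(), AvgPool2()
        self.up1, self.up2 = Upsample2(), Upsample2()
        self._c1, self._c2 = c1, c2

    def parameters(self):
        ps = self.tmlp.parameters()
        for b in (self.enc1, self.enc2, self.mid, self.dec2, self.dec1):
            ps += b.parameters()
        return ps + self.out.parameters()

    def forward(self, x: np.ndarray, t: np.ndarray) -> np.ndarray:
        temb = sinusoidal_embedding(t, self.temb_dim)
        temb = self.tact.forward(self.tmlp.forward(temb))
        e1 = self.enc1.forward(x, temb)
        e2 = self.enc2.forward(self.pool1.forward(e1), temb)
        m = self.mid.forward(self.pool2.forward(e2), temb)
        d2 = self.dec2.forward(np.concatenate([self.up2.forward(m), e2], axis=1), temb)
        d1 = self.dec1.forward(np.concatenate([self.up1.forward(d2), e1], axis=1), temb)
        return self.out.forward(d1)

    def backward(self, dy: np.ndarray, param_grads: bool = True) -> np.ndarray:
        """Input gradient (VJP); reuses the cache of the last forward call and
        may be invoked several times with different cotangents."""
        c1, c2 = self._c1, self._c2
        dd1 = self.out.backward(dy, param_grads)
        dcat1 = self.dec1.backward(dd1, param_grads)
        dup1, de1_skip = dcat1[:, :c2], dcat1[:, c2:]
        dd2 = self.up1.backward(dup1)
        dcat2 = self.dec2.backward(dd2, param_grads)
        dup2, de2_skip = dcat2[:, :c2], dcat2[:, c2:]
        dm = self.up2.backward(dup2)
        dpool2 = self.mid.backward(dm, param_grads)
        de2 = self.pool2.backward(dpool2) + de2_skip
        dpool1 = self.enc2.backward(de2, param_grads)
        de1 = self.pool1.backward(dpool1) + de1_skip
        return self.enc1.backward(de1, param_grads)

    # -- checkpointing ------------------------------------------------------
    def get_state(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.v.copy() for i, p in enumerate(self.parameters())}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.v[...] = state[f"p{i}"]
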