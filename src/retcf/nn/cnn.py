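"""Small convolutional K-class classifier network."""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, Dense, MaxPool2, SiLU


class SmallCNN:
    """conv-SiLU-maxpool x3, global mean+max pooled head.

    Max pooling (and the global-max head component) preserves the response
    of small localized structures such as dot lesions, which plain average
    pooling washes out.  Works on any square input whose side is divisible
    by 8.
    """

    def __init__(self, in_channels: int, n_classes: int, channels=(8, 16, 32),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.channels = tuple(channels)
        cs = [in_channels, *channels]
        self.convs = [Conv2d(cs[i], cs[i + 1], rng=rng) for i in range(3)]
        self.acts = [SiLU() for _ in range(3)]
        self.pools = [MaxPool2() for _ in range(3)]
        self.head = Dense(2 * channels[-1], n_classes, rng=rng)

    def parameters(self):
        ps = []
        for c in self.convs:
            ps += c.parameters()
        return ps + self.head.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for conv, act, pool in zip(self.convs, self.acts, self.pools):
            h = pool.forward(act.forward(conv.forward(h)))
        self._feat_shape = h.shape
        n, c, hh, ww = h.shape
        flat = h.reshape(n, c, hh * ww)
        self._max_arg = flat.argmax(axis=2)
        g = np.concatenate([flat.mean(axis=2), flat.max(axis=2)], axis=1)
        return self.head.forward(g)

    def backward(self, dlogits: np.ndarray, param_grads: bool = True) -> np.ndarray:
        dg = self.head.backward(dlogits, param_grads)
        n, c, hh, ww = self._feat_shape
        dmean, dmax = dg[:, :c], dg[:, c:]
        dflat = np.broadcast_to(dmean[:, :, None] / (hh * ww),
                                (n, c, hh * ww)).astype(np.float32).copy()
        np.put_along_axis(dflat, self._max_arg[..., None],
                          np.take_along_axis(dflat, self._max_arg[..., None], axis=2)
                          + dmax[..., None], axis=2)
        dh = dflat.reshape(n, c, hh, ww)
        for conv, act, pool in zip(reversed(self.convs), reversed(self.acts), reversed(self.pools)):
            dh = conv.backward(act.backward(pool.backward(dh)), param_grads)
        return dh

    def get_state(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.v.copy() for i, p in enumerate(self.parameters())}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.v[...] = state[f"p{i}"]
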