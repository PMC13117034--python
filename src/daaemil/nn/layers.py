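"""Layer primitives and parameter containers for the numpy NN core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, avg_pool3d, conv3d

__all__ = ["Parameter", "Module", "Linear", "Conv3dBlock", "glorot_uniform"]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Parameter(rng.uniform(-limit, limit, size=shape))


class Parameter(Tensor):
    """A tensor that is always tracked by the tape and the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny container protocol: recursively exposes Parameters."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Parameter):
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.array(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = glorot_uniform(rng, (out_features, in_features),
                                     in_features, out_features)
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight.T + self.bias


class Conv3dBlock(Module):
    """3x3x3 'same' convolution + instance norm + ReLU + average pooling.

    The normalization standardizes each channel over a sample's spatial
    positions (learnable per-channel scale and shift), which keeps the
    activations well-scaled without batch statistics, so inference is
    deterministic for a single volume.
    """

    def __init__(self, in_ch: int, out_ch: int, pool, rng: np.random.Generator,
                 kernel: int = 3, norm: bool = True):
        fan_in = in_ch * kernel ** 3
        fan_out = out_ch * kernel ** 3
        self.weight = glorot_uniform(rng, (out_ch, in_ch, kernel, kernel, kernel),
                                     fan_in, fan_out)
        self.bias = Parameter(np.zeros(out_ch))
        self.norm = norm
        if norm:
            self.gamma = Parameter(np.ones(out_ch))
            self.beta = Parameter(np.zeros(out_ch))
        self.pool = tuple(pool)
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        out = conv3d(x, self.weight, self.bias, padding=self.kernel // 2)
        if self.norm:
            # per-slice statistics (channel x depth position, over H and W):
            # per-volume statistics would couple every slice to the others
            # and leak bag-level intensity information into each instance
            c = out.shape[1]
            mu = out.mean(axis=(2, 3), keepdims=True)
            var = ((out - mu) ** 2.0).mean(axis=(2, 3), keepdims=True)
            out = (out - mu) * ((var + 1e-5) ** -0.5)
            out = out * self.gamma.reshape(1, c, 1, 1, 1) \
                + self.beta.reshape(1, c, 1, 1, 1)
        out = out.relu()
        # adapt pooling to remaining extent so thin inputs stay valid
        _, _, h, w, d = out.shape
        eff = (min(self.pool[0], h), min(self.pool[1], w), min(self.pool[2], d))
        if eff != (1, 1, 1):
            out = avg_pool3d(out, eff)
        return out
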