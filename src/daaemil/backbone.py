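"""Volume normalization and the 3D-convolutional instance feature extractor.

The extractor is a small headless 3D CNN: stacked 3x3x3 convolution blocks
with ReLU and average pooling, no classifier layers.  Its final feature map
is turned into a bag of instance vectors, by default one instance per depth
position of the feature map (each depth position summarizes a contiguous
window of input slices), so the slice-as-instance premise of the MIL setup
is preserved while the convolution still sees 3D context.  Spatial extents
of each depth position are flattened and linearly projected to a fixed
feature dimension ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DomainError
from .nn import Conv3dBlock, Linear, Module, Tensor

__all__ = ["Volume", "BackboneConfig", "C3dFeatureExtractor",
           "InstanceFeatureSet", "minmax_normalize", "build_backbone",
           "extract_instances"]


@dataclass
class Volume:
    """A height x width x depth intensity array; depth is the slice axis."""

    data: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DomainError("volume must be a 3-D array")
        if self.data.shape[2] < 1:
            raise DomainError("volume needs at least one slice")
        if not np.isfinite(self.data).all():
            raise DomainError("volume contains non-finite values")

    @property
    def shape(self):
        return self.data.shape


def minmax_normalize(volume: Volume | np.ndarray,
                     symmetric: bool = False) -> Volume:
    """Linearly rescale intensities to [0, 1]: (x - min) / (max - min).

    ``symmetric=True`` applies the optional post-scale x -> 2x - 1, mapping
    onto [-1, 1].  A constant volume has no defined rescaling.
    """
    vol = volume if isinstance(volume, Volume) else Volume(volume)
    lo, hi = vol.data.min(), vol.data.max()
    if hi == lo:
        raise DomainError("constant volume cannot be min-max normalized")
    out = (vol.data - lo) / (hi - lo)
    if symmetric:
        out = 2.0 * out - 1.0
    return Volume(out, normalized=True)


@dataclass
class BackboneConfig:
    in_channels: int = 1
    widths: tuple = (8, 16, 32)
    # per-block (height, width, depth) pooling factors
    pools: tuple = ((2, 2, 2), (2, 2, 1), (2, 2, 1))
    kernel: int = 3
    feature_dim: int = 32
    granularity: str = "per-depth-position"   # or "per-slice-window"
    window: int = 1                            # slices per window (window mode)
    include_classifier: bool = False
    seed: int = 0

    def validate(self):
        if self.in_channels != 1:
            raise ConfigurationError("extractor takes single-channel volumes")
        if self.feature_dim < 1:
            raise ConfigurationError("feature_dim must be positive")
        if len(self.widths) != len(self.pools):
            raise ConfigurationError("one pooling spec per block required")
        if self.include_classifier:
            raise ConfigurationError(
                "the extractor is headless; classifier layers are not part "
                "of its contract")
        if self.granularity not in ("per-depth-position", "per-slice-window"):
            raise ConfigurationError(f"unknown granularity {self.granularity!r}")

    def map_shape(self, volume_shape):
        """Closed-form feature-map shape for an input volume."""
        h, w, d = volume_shape
        for (fh, fw, fd) in self.pools:
            if h < fh or w < fw or d < fd:
                raise ConfigurationError("downsampling collapses a dimension")
            h, w, d = h // fh, w // fw, d // fd
        return self.widths[-1], h, w, d

    def depth_downsampling(self) -> int:
        total = 1
        for (_, _, fd) in self.pools:
            total *= fd
        return total


@dataclass
class InstanceFeatureSet:
    features: np.ndarray        # k x d
    provenance: list            # per instance: (start_slice, stop_slice)
    k: int = field(init=False)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.k = self.features.shape[0]
        if self.k < 1:
            raise DomainError("instance set must be nonempty")
        if not np.isfinite(self.features).all():
            raise DomainError("non-finite instance features")


class C3dFeatureExtractor(Module):
    """Headless 3D CNN mapping a 1-channel volume to instance features."""

    def __init__(self, config: BackboneConfig, input_shape):
        config.validate()
        self.config = config
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(config.seed)
        blocks = []
        in_ch = config.in_channels
        for width, pool in zip(config.widths, config.pools):
            blocks.append(Conv3dBlock(in_ch, width, pool, rng, config.kernel))
            in_ch = width
        self.blocks = blocks
        c, h, w, d = config.map_shape(self.input_shape)
        if config.granularity == "per-depth-position":
            per_instance = c * h * w
        else:
            per_instance = c * h * w  # window mode mean-pools depth first
        self.project = Linear(per_instance, config.feature_dim, rng)

    # -- forward pieces ------------------------------------------------------
    def feature_map(self, x: Tensor) -> Tensor:
        """(B, 1, H, W, D) -> (B, C, H', W', D')."""
        out = x
        for block in self.blocks:
            out = block(out)
        return out

    def instance_features(self, x: Tensor) -> list:
        """Batch of volumes -> list of (k, d) instance-feature tensors."""
        cfg = self.config
        if cfg.granularity == "per-slice-window":
            return [self._window_instances(x, i) for i in range(x.shape[0])]
        fmap = self.feature_map(x)
        b, c, h, w, d = fmap.shape
        feats = []
        for i in range(b):
            # depth positions become instances: (d, c*h*w)
            sample = fmap.gather_rows([i]).reshape(c, h, w, d)
            rows = sample.reshape(c * h * w, d).T
            feats.append(self.project(rows))
        return feats

    def _window_instances(self, x: Tensor, i: int) -> Tensor:
        cfg = self.config
        depth = x.shape[-1]
        vol = x.gather_rows([i])  # (1, 1, H, W, D)
        rows = []
        for start in range(0, depth, cfg.window):
            stop = min(start + cfg.window, depth)
            sl = Tensor(vol.data[..., start:stop])
            sl.requires_grad = vol.requires_grad
            if vol.requires_grad:
                def bw(g, lo=start, hi=stop, parent=vol):
                    acc = np.zeros_like(parent.data)
                    acc[..., lo:hi] = g
                    parent._accumulate(acc)
                sl._backward = bw
                sl._prev = (vol,)
            fmap = self.feature_map(sl)
            b, c, h, w, d = fmap.shape
            pooled = fmap.mean(axis=4).reshape(1, c * h * w)
            rows.append(self.project(pooled))
        from .nn import concat
        return concat(rows, axis=0)

    def provenance(self, depth: int) -> list:
        cfg = self.config
        if cfg.granularity == "per-slice-window":
            return [(s, min(s + cfg.window, depth))
                    for s in range(0, depth, cfg.window)]
        r = cfg.depth_downsampling()
        k = depth // r
        return [(j * r, (j + 1) * r) for j in range(k)]


def build_backbone(config: BackboneConfig,
                   input_shape=(32, 32, 16)) -> C3dFeatureExtractor:
    """Construct the extractor with deterministic seeded initialization."""
    config.validate()
    config.map_shape(input_shape)  # raises if downsampling is incompatible
    return C3dFeatureExtractor(config, input_shape)


def extract_instances(volume: Volume, extractor: C3dFeatureExtractor,
                      granularity: str | None = None,
                      allow_unnormalized: bool = False) -> InstanceFeatureSet:
    """Run the extractor on one volume and package the instance rows."""
    if not volume.normalized and not allow_unnormalized:
        raise DomainError("volume must be normalized first "
                          "(or pass allow_unnormalized=True)")
    if granularity is not None and granularity != extractor.config.granularity:
        raise DomainError("granularity differs from the extractor's config")
    x = Tensor(volume.data[None, None])
    feats = extractor.instance_features(x)[0]
    prov = extractor.provenance(volume.shape[2])
    return InstanceFeatureSet(feats.data, prov)
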