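"""Reference and conditional target encoder–decoder networks.

Two sub-models make up the morphology stack:

* ``M_R`` — an unconditional beta-VAE over the two reference channels
  (membrane dye, nucleus dye) capturing cell and nuclear shape;
* ``M_T`` — a conditional beta-VAE over the single tagged-structure channel,
  conditioned at every residual layer on a linearly resized copy of the
  reference image and on the one-hot structure label.

Each residual layer pairs a strided 4-kernel convolution (transposed in the
decoder) followed by a 3-kernel convolution with a 1-kernel bypass routed
through average pooling (down) or linear upsampling (up); the branches are
summed.  Spectral weight normalization wraps every convolutional and fully
connected operation; batch normalization follows each body convolution and
each conditional projection.  The encoder ends in two parallel fully
connected heads producing the posterior mean and scale; the decoder starts
with a batch-normalized fully connected expansion of the latent code.

At full scale (channel progression 32..512, latent 512, 24 structure
classes, bottleneck 5x3(x2)) the trainable parameter totals are the
published ones: 122,627,829 for the 3D pair M_R + M_T and 22,279,054 for
the 2D reference model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.layers import (
    DTYPE,
    AvgPool2x,
    BatchNorm,
    ConvNd,
    ConvTransposeNd,
    Layer,
    Linear,
    LinearUpsample2x,
    ReLU,
)
from .nn import functional as F

# Structure classes: 19 biological + 5 synthetic controls, fixed ordering.
STRUCTURE_CLASSES: tuple[str, ...] = (
    "Actin filaments",
    "Actomyosin bundles",
    "Adherens junctions",
    "Centrioles",
    "Desmosomes",
    "Endoplasmic reticulum",
    "Endosomes",
    "Gap junctions",
    "Golgi",
    "Lysosomes",
    "Matrix adhesions",
    "Microtubules",
    "Mitochondria",
    "Nuclear envelope",
    "Nucleoli (Dense Fibrillar Component)",
    "Nucleoli (Granular Component)",
    "Peroxisomes",
    "Plasma membrane",
    "Tight junctions",
    "Control - Blank",
    "Control - DNA",
    "Control - Memb",
    "Control - Noise",
    "Control - Random",
)


@dataclass(frozen=True)
class StructureLabel:
    """Categorical structure class with a fixed index<->name bijection."""

    index: int

    def __post_init__(self):
        if not 0 <= self.index < len(STRUCTURE_CLASSES):
            raise ValueError(
                f"label index {self.index} outside [0, {len(STRUCTURE_CLASSES)})"
            )

    @property
    def name(self) -> str:
        return STRUCTURE_CLASSES[self.index]

    @classmethod
    def from_name(cls, name: str) -> "StructureLabel":
        return cls(STRUCTURE_CLASSES.index(name))


def one_hot(indices: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(indices), n_classes), dtype=DTYPE)
    out[np.arange(len(indices)), np.asarray(indices, dtype=int)] = 1.0
    return out


@dataclass
class GaussianLatent:
    """Diagonal-Gaussian posterior q(z|x) = N(mu, diag(sigma^2))."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.atleast_2d(self.mu)
        self.sigma = np.atleast_2d(self.sigma)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma shapes differ")
        if not np.all(np.isfinite(self.mu)) or not np.all(np.isfinite(self.sigma)):
            raise ValueError("non-finite latent parameters")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")

    @property
    def n_dim(self) -> int:
        return self.mu.shape[1]

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        eps = rng.standard_normal((n,) + self.mu.shape).astype(self.mu.dtype)
        return self.mu[None] + self.sigma[None] * eps


@dataclass(frozen=True)
class NetworkSpec:
    """Configuration of one sub-model (reference or target)."""

    dimensionality: int = 2
    input_shape: tuple = (160, 96)
    input_channels: int = 2
    channels: tuple = (32, 64, 128, 256, 512)
    latent_dim: int = 512
    n_classes: int = 24
    n_ref_channels: int = 2
    conditional: bool = False
    final_stride1: bool = False  # alternate reading of the last decoder layer
    seed: int = 0

    def __post_init__(self):
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if len(self.input_shape) != self.dimensionality:
            raise ValueError("input_shape rank must equal dimensionality")
        if not self.channels or any(c <= 0 for c in self.channels):
            raise ValueError("channel progression must be non-empty and positive")
        if self.latent_dim < 1:
            raise ValueError("latent size must be >= 1")
        n_half = len(self.channels)
        for s in self.input_shape:
            if s % (2**n_half):
                raise ValueError(
                    f"input axis {s} not divisible by 2^{n_half}; choose a shape "
                    f"divisible by {2 ** n_half} or shorten the channel progression"
                )

    @property
    def compressed_shape(self) -> tuple:
        n_half = len(self.channels)
        return tuple(s // 2**n_half for s in self.input_shape)

    @property
    def flat_dim(self) -> int:
        return int(self.channels[-1] * np.prod(self.compressed_shape))


class _CondPaths(Layer):
    """Reference-image and label projections injected into a residual layer."""

    def __init__(self, rng, cout, n_ref, n_classes):
        self.proj_ref = ConvNd(rng, n_ref, cout, k=1)
        self.bn_ref = BatchNorm(cout)
        self.proj_label = ConvNd(rng, n_classes, cout, k=1)
        self.bn_label = BatchNorm(cout)

    def build(self, d):
        self.proj_ref.build(d)
        self.proj_label.build(d)
        return self

    def forward(self, out, x_ref, label, train=False):
        d = out.ndim - 2
        self._out_spatial = out.shape[2:]
        ref_rs = F.resize_linear(x_ref.astype(out.dtype), self._out_spatial)
        out = out + self.bn_ref.forward(self.proj_ref.forward(ref_rs, train), train)
        lbl_img = label.reshape(label.shape + (1,) * d).astype(out.dtype)
        lbl_map = self.bn_label.forward(self.proj_label.forward(lbl_img, train), train)
        return out + lbl_map  # broadcast over pixels

    def backward(self, dy):
        d_lbl = dy.sum(axis=tuple(range(2, dy.ndim)), keepdims=True)
        self.proj_label.backward(self.bn_label.backward(d_lbl))
        self.proj_ref.backward(self.bn_ref.backward(dy))
        return dy  # pass-through for the main branch


class DownResidualBlock(Layer):
    """Stride-2 residual layer of the encoder."""

    def __init__(self, rng, cin, cout, conditional=False, n_ref=2, n_classes=24):
        self.conv4 = ConvNd(rng, cin, cin, k=4, stride=2, pad=1)
        self.bn1 = BatchNorm(cin)
        self.relu1 = ReLU()
        self.conv3 = ConvNd(rng, cin, cout, k=3, stride=1, pad=1)
        self.bn2 = BatchNorm(cout)
        self.relu2 = ReLU()
        self.bypass_conv = ConvNd(rng, cin, cout, k=1)
        self.pool = AvgPool2x()
        self.cond = _CondPaths(rng, cout, n_ref, n_classes) if conditional else None

    def build(self, d):
        for c in (self.conv4, self.conv3, self.bypass_conv):
            c.build(d)
        if self.cond is not None:
            self.cond.build(d)
        return self

    def forward(self, x, x_ref=None, label=None, train=False):
        for s in x.shape[2:]:
            if s % 2:
                raise ValueError(f"odd spatial size {s} fed to a stride-2 layer")
        h = self.relu1.forward(self.bn1.forward(self.conv4.forward(x, train), train))
        h = self.relu2.forward(self.bn2.forward(self.conv3.forward(h, train), train))
        b = self.pool.forward(self.bypass_conv.forward(x, train))
        out = h + b
        if self.cond is not None:
            out = self.cond.forward(out, x_ref, label, train)
        return out

    def backward(self, dy):
        if self.cond is not None:
            dy = self.cond.backward(dy)
        dxb = self.bypass_conv.backward(self.pool.backward(dy))
        dh = self.conv3.backward(self.bn2.backward(self.relu2.backward(dy)))
        dxm = self.conv4.backward(self.bn1.backward(self.relu1.backward(dh)))
        return dxm + dxb


class UpResidualBlock(Layer):
    """Stride-2 (transposed) residual layer of the decoder."""

    def __init__(
        self, rng, cin, cout, conditional=False, n_ref=2, n_classes=24, upsample=True
    ):
        self.upsample = upsample
        if upsample:
            self.conv4 = ConvTransposeNd(rng, cin, cin, k=4, stride=2, pad=1)
        else:  # stride-1 reading: channel reduction only
            self.conv4 = ConvNd(rng, cin, cin, k=3, stride=1, pad=1)
        self.bn1 = BatchNorm(cin)
        self.relu1 = ReLU()
        self.conv3 = ConvNd(rng, cin, cout, k=3, stride=1, pad=1)
        self.bn2 = BatchNorm(cout)
        self.relu2 = ReLU()
        self.bypass_conv = ConvNd(rng, cin, cout, k=1)
        self.up = LinearUpsample2x() if upsample else None
        self.cond = _CondPaths(rng, cout, n_ref, n_classes) if conditional else None

    def build(self, d):
        for c in (self.conv4, self.conv3, self.bypass_conv):
            c.build(d)
        if self.cond is not None:
            self.cond.build(d)
        return self

    def forward(self, x, x_ref=None, label=None, train=False):
        h = self.relu1.forward(self.bn1.forward(self.conv4.forward(x, train), train))
        h = self.relu2.forward(self.bn2.forward(self.conv3.forward(h, train), train))
        b = self.bypass_conv.forward(x, train)
        if self.up is not None:
            b = self.up.forward(b)
        out = h + b
        if self.cond is not None:
            out = self.cond.forward(out, x_ref, label, train)
        return out

    def backward(self, dy):
        if self.cond is not None:
            dy = self.cond.backward(dy)
        db = dy if self.up is None else self.up.backward(dy)
        dxb = self.bypass_conv.backward(db)
        dh = self.conv3.backward(self.bn2.backward(self.relu2.backward(dy)))
        dxm = self.conv4.backward(self.bn1.backward(self.relu1.backward(dh)))
        return dxm + dxb


class Encoder(Layer):
    def __init__(self, spec: NetworkSpec, rng):
        self.spec = spec
        blocks = []
        cin = spec.input_channels
        for cout in spec.channels:
            blocks.append(
                DownResidualBlock(
                    rng, cin, cout, spec.conditional, spec.n_ref_channels, spec.n_classes
                ).build(spec.dimensionality)
            )
            cin = cout
        self.blocks = blocks
        self.fc_mu = Linear(rng, spec.flat_dim, spec.latent_dim)
        self.fc_logvar = Linear(rng, spec.flat_dim, spec.latent_dim)

    def forward(self, x, x_ref=None, label=None, train=False):
        h = x
        for blk in self.blocks:
            h = blk.forward(h, x_ref, label, train=train)
        self._h_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        mu = self.fc_mu.forward(flat, train)
        logvar = self.fc_logvar.forward(flat, train)
        return mu, logvar

    def backward(self, dmu, dlogvar):
        dflat = self.fc_mu.backward(dmu) + self.fc_logvar.backward(dlogvar)
        dh = dflat.reshape(self._h_shape)
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        return dh


class Decoder(Layer):
    def __init__(self, spec: NetworkSpec, rng, out_channels: int):
        self.spec = spec
        self.bn_z = BatchNorm(spec.latent_dim)
        self.fc = Linear(rng, spec.latent_dim, spec.flat_dim)
        chans = list(spec.channels[::-1])  # 512, 256, 128, 64, 32
        blocks = []
        seq = chans[1:] + [out_channels]
        cin = chans[0]
        for i, cout in enumerate(seq):
            last = i == len(seq) - 1
            upsample = not (last and spec.final_stride1)
            blocks.append(
                UpResidualBlock(
                    rng,
                    cin,
                    cout,
                    spec.conditional,
                    spec.n_ref_channels,
                    spec.n_classes,
                    upsample=upsample,
                ).build(spec.dimensionality)
            )
            cin = cout
        self.blocks = blocks

    def forward(self, z, x_ref=None, label=None, train=False):
        zn = self.bn_z.forward(z, train)
        flat = self.fc.forward(zn, train)
        top = self.spec.channels[-1]
        h = flat.reshape(z.shape[0], top, *self.spec.compressed_shape)
        for blk in self.blocks:
            h = blk.forward(h, x_ref, label, train=train)
        return h

    def backward(self, dxhat):
        dh = dxhat
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        dflat = dh.reshape(dh.shape[0], -1)
        dz = self.bn_z.backward(self.fc.backward(dflat))
        return dz


class VAEModel(Layer):
    """One sub-model: encoder, reparameterized sampling, decoder."""

    def __init__(self, spec: NetworkSpec, out_channels: int | None = None):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.encoder = Encoder(spec, rng)
        self.decoder = Decoder(spec, rng, out_channels or spec.input_channels)
        self.rng = np.random.default_rng(spec.seed + 1)

    # -- inference ---------------------------------------------------------
    def _check_cond(self, x_ref, label):
        if self.spec.conditional and (x_ref is None or label is None):
            raise TypeError(
                "conditional model requires both the reference image x_ref and "
                "the structure label t"
            )

    def encode(self, x, x_ref=None, label=None, train=False) -> GaussianLatent:
        self._check_cond(x_ref, label)
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 2 + self.spec.dimensionality - 1:
            x = x[None]
        if x.shape[1] != self.spec.input_channels:
            raise ValueError(
                f"expected {self.spec.input_channels} input channels, got {x.shape[1]}"
            )
        mu, logvar = self.encoder.forward(x, x_ref, label, train=train)
        return GaussianLatent(mu=mu, sigma=np.exp(0.5 * logvar))

    def decode(self, z, x_ref=None, label=None, train=False) -> np.ndarray:
        self._check_cond(x_ref, label)
        z = np.atleast_2d(np.asarray(z, dtype=DTYPE))
        if z.shape[1] != self.spec.latent_dim:
            raise ValueError(
                f"latent length {z.shape[1]} != spec latent size {self.spec.latent_dim}"
            )
        return self.decoder.forward(z, x_ref, label, train=train)

    def sample(self, n: int, seed: int, x_ref=None, label=None) -> np.ndarray:
        """Decode n independent standard-normal latent draws."""
        if n < 0:
            raise ValueError("n must be >= 0")
        if n == 0:
            shape = (0, self.decoder.blocks[-1].conv3._cout) + self.spec.input_shape
            return np.zeros(shape, dtype=DTYPE)
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.spec.latent_dim)).astype(DTYPE)
        return self.decode(z, x_ref, label)

    # -- training-time pass with caches ------------------------------------
    def forward_train(self, x, x_ref=None, label=None, sample_rng=None):
        lat = self.encode(x, x_ref, label, train=True)
        rng = sample_rng or self.rng
        eps = rng.standard_normal(lat.mu.shape).astype(DTYPE)
        self._eps, self._sigma = eps, lat.sigma
        z = lat.mu + lat.sigma * eps
        xhat = self.decode(z, x_ref, label, train=True)
        return lat, z, xhat

    def backward_train(self, dxhat, dmu_direct=None, dlogvar_direct=None):
        """Backprop through decoder, reparameterization and encoder.

        ``dmu_direct``/``dlogvar_direct`` carry the KL term's gradients,
        which bypass the decoder.
        """
        dz = self.decoder.backward(dxhat)
        dmu = dz.copy()
        dlogvar = 0.5 * dz * self._sigma * self._eps
        if dmu_direct is not None:
            dmu += dmu_direct
        if dlogvar_direct is not None:
            dlogvar += dlogvar_direct
        self.encoder.backward(dmu, dlogvar)


def build_reference_model(spec: NetworkSpec) -> VAEModel:
    if spec.conditional:
        raise ValueError("reference model spec must have conditional=False")
    return VAEModel(spec, out_channels=spec.input_channels)


def build_target_model(spec: NetworkSpec) -> VAEModel:
    if not spec.conditional:
        raise ValueError("target model spec must have conditional=True")
    return VAEModel(spec, out_channels=spec.input_channels)


def count_parameters(model: Layer) -> int:
    """Number of trainable scalars (spectral-norm u/v buffers excluded)."""
    return int(sum(p.size for p in model.params()))


# -- published full-scale configurations -----------------------------------

def full_scale_spec(dimensionality: int, conditional: bool, seed: int = 0) -> NetworkSpec:
    """Full-scale spec: channels 32..512, latent 512, bottleneck 5x3(x2)."""
    shape = (160, 96) if dimensionality == 2 else (160, 96, 64)
    return NetworkSpec(
        dimensionality=dimensionality,
        input_shape=shape,
        input_channels=1 if conditional else 2,
        conditional=conditional,
        seed=seed,
    )


def full_scale_parameter_counts(seed: int = 0) -> dict[str, int]:
    """Build the full-scale models and count trainable parameters.

    Returns counts for each sub-model and the totals quoted for the 3D
    (reference + target) and 2D (reference) instantiations.
    """
    out: dict[str, int] = {}
    for d in (3, 2):
        mr = build_reference_model(full_scale_spec(d, False, seed))
        out[f"reference_{d}d"] = count_parameters(mr)
        del mr
        mt = build_target_model(full_scale_spec(d, True, seed))
        out[f"target_{d}d"] = count_parameters(mt)
        del mt
    out["total_3d"] = out["reference_3d"] + out["target_3d"]
    out["total_2d"] = out["reference_2d"] + out["target_2d"]
    return out
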