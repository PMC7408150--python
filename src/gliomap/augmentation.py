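"""DCGAN training-set augmentation for tumor slices.

One DCGAN is trained per (modality, class) subset so synthesized images
carry clean labels. The generator maps a 100-dim uniform noise vector
through a dense reshape and three stride-2 transposed convolutions to a
Tanh image; the discriminator is a stack of stride-2 5x5 convolutions
with batch norm and LeakyReLU(0.2) ending in a sigmoid probability.
Training minimizes the standard binary cross-entropy adversarial
objective (non-saturating generator form by default) and stops early
once the discriminator's mean outputs on real and fake batches both
approach the 0.5 equilibrium point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import (BatchNorm, Conv2d, ConvTranspose2d, Dense, Flatten,
                  LeakyReLU, ReLU, Reshape, Sequential, Sigmoid, Tanh)

_EPS = 1e-7


@dataclass
class DCGANSpec:
    """Architecture + training hyperparameters.

    Defaults: z ~ Uniform(-1,1)^100, dense to (image_size/8)^2 x 1024
    (16x16x1024 = 262,144 units at the default 128), transposed convs
    (512, 256, 128) with 4x4 kernels, final 4x4 conv to 3 channels +
    Tanh; discriminator convs (128, 256, 512, 1024) with 5x5 kernels,
    dense + sigmoid. Adam lr 0.002, batch 64, binary cross-entropy.
    The discriminator input size defaults to the generator output size.
    """

    z_dim: int = 100
    image_size: int = 128
    channels: int = 3
    gen_base_filters: int = 1024
    gen_filters: tuple = (512, 256, 128)
    disc_filters: tuple = (128, 256, 512, 1024)
    gen_kernel: int = 4
    disc_kernel: int = 5
    leaky_slope: float = 0.2
    lr: float = 0.002
    betas: tuple = (0.5, 0.999)
    batch_size: int = 64
    max_epochs: int = 50
    #: a freshly initialized sigmoid discriminator sits at ~0.5 trivially,
    #: so the equilibrium stopping rule only engages after this warm-up
    min_epochs: int = 3
    equilibrium_tol: float = 0.05
    saturating: bool = False
    seed: int = 0

    @classmethod
    def tiny(cls, image_size=16, seed=0, max_epochs=5, batch_size=16):
        return cls(image_size=image_size, gen_base_filters=32,
                   gen_filters=(16, 8, 8), disc_filters=(8, 16, 16, 32),
                   batch_size=batch_size, max_epochs=max_epochs, seed=seed)

    @property
    def base_size(self) -> int:
        return self.image_size // 8

    def validate(self):
        if self.image_size % 8 != 0:
            raise ValueError("image_size must be divisible by 8 "
                             "(three stride-2 upsamplings)")


@dataclass
class DCGANState:
    spec: DCGANSpec
    G: Sequential
    D: Sequential
    #: per-epoch mean D(real), D(fake)
    history: list = field(default_factory=list)
    trained: bool = False


def build_generator(spec: DCGANSpec, rng) -> Sequential:
    base = spec.base_size
    layers = [Dense(spec.z_dim, base * base * spec.gen_base_filters,
                    rng=rng, init_std=0.02),
              ReLU(),
              Reshape((spec.gen_base_filters, base, base))]
    cin = spec.gen_base_filters
    for cout in spec.gen_filters:
        layers += [ConvTranspose2d(cin, cout, spec.gen_kernel, stride=2,
                                   pad=1, rng=rng, init_std=0.02),
                   BatchNorm(cout), ReLU()]
        cin = cout
    # even kernel at stride 1 needs asymmetric 'same' padding
    pad = (spec.gen_kernel - 1) // 2 if spec.gen_kernel % 2 \
        else (spec.gen_kernel // 2 - 1, spec.gen_kernel // 2)
    layers += [Conv2d(cin, spec.channels, spec.gen_kernel, stride=1, pad=pad,
                      rng=rng, init_std=0.02), Tanh()]
    return Sequential(layers)


def build_discriminator(spec: DCGANSpec, rng) -> Sequential:
    layers = []
    cin = spec.channels
    size = spec.image_size
    for i, cout in enumerate(spec.disc_filters):
        layers.append(Conv2d(cin, cout, spec.disc_kernel, stride=2, pad=2,
                             rng=rng, init_std=0.02))
        if i > 0:
            layers.append(BatchNorm(cout))
        layers.append(LeakyReLU(spec.leaky_slope))
        cin = cout
        size = (size + 1) // 2
    layers += [Flatten(), Dense(size * size * cin, 1, rng=rng, init_std=0.02),
               Sigmoid()]
    return Sequential(layers)


def dcgan_loss(d_real, d_fake, saturating: bool = False):
    """Binary cross-entropy GAN losses from probabilities.

    loss_D = -mean log D(real) - mean log(1 - D(fake))
    loss_G = -mean log D(fake)          (non-saturating, default)
           =  mean log(1 - D(fake))     (saturating option)
    Probabilities at exactly 0/1 are epsilon-clamped.
    """
    d_real = np.clip(np.asarray(d_real, dtype=np.float64), _EPS, 1 - _EPS)
    d_fake = np.clip(np.asarray(d_fake, dtype=np.float64), _EPS, 1 - _EPS)
    loss_d = float(-np.mean(np.log(d_real)) - np.mean(np.log(1.0 - d_fake)))
    if saturating:
        loss_g = float(np.mean(np.log(1.0 - d_fake)))
    else:
        loss_g = float(-np.mean(np.log(d_fake)))
    return loss_d, loss_g


def train_dcgan(images: np.ndarray, spec: DCGANSpec,
                freeze_generator: bool = False) -> DCGANState:
    """Alternating D/G Adam updates with equilibrium early stopping.

    ``images``: (N,H,W) in [0,1], one modality (and, per policy, one
    class). Stops when the running-mean |D(real)-0.5| and |D(fake)-0.5|
    both fall below ``equilibrium_tol``, or at ``max_epochs``.

    ``freeze_generator`` trains only the discriminator against the
    fixed initial generator — the reference point showing how far from
    the 0.5 equilibrium an unchallenged discriminator moves.
    """
    spec.validate()
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 3 or x.shape[1] != spec.image_size:
        raise ValueError(f"expected (N,{spec.image_size},{spec.image_size}) images")
    batch = spec.batch_size
    if len(x) < batch:
        warnings.warn(f"only {len(x)} images < batch {batch}; shrinking batch",
                      stacklevel=2)
        batch = max(1, len(x))
    x = x[:, None].repeat(spec.channels, axis=1) * 2.0 - 1.0

    rng = np.random.default_rng(spec.seed)
    G = build_generator(spec, rng)
    D = build_discriminator(spec, rng)
    opt_g = _nn.Adam(G, spec.lr, betas=spec.betas)
    opt_d = _nn.Adam(D, spec.lr, betas=spec.betas)

    n_iter = max(1, len(x) // batch)
    history = []
    for epoch in range(1, spec.max_epochs + 1):
        mean_real, mean_fake = 0.0, 0.0
        for _ in range(n_iter):
            idx = rng.integers(0, len(x), batch)
            real = x[idx]
            z = rng.uniform(-1, 1, (batch, spec.z_dim)).astype(np.float32)
            fake = G.forward(z)

            # discriminator step
            opt_d.zero_grad()
            p_real = D.forward(real)
            _, g = _nn.bce_loss(p_real, np.ones_like(p_real))
            D.backward(g)
            p_fake = D.forward(fake)
            _, g = _nn.bce_loss(p_fake, np.zeros_like(p_fake))
            D.backward(g)
            opt_d.step()

            # generator step; D stays in train mode (batch statistics of
            # the fake batch) but its parameters are not updated
            if not freeze_generator:
                opt_g.zero_grad()
                z = rng.uniform(-1, 1, (batch, spec.z_dim)).astype(np.float32)
                fake = G.forward(z)
                p = D.forward(fake)
                pc = np.clip(p, _EPS, 1 - _EPS)
                if spec.saturating:
                    g = (-1.0 / (1.0 - pc)) / p.size
                else:
                    g = (-1.0 / pc) / p.size
                G.backward(D.backward(g.astype(np.float32)))
                opt_g.step()

            mean_real += float(np.mean(p_real)) / n_iter
            mean_fake += float(np.mean(p_fake)) / n_iter
        history.append({"epoch": epoch, "d_real": mean_real, "d_fake": mean_fake})
        if (epoch >= spec.min_epochs
                and abs(mean_real - 0.5) < spec.equilibrium_tol
                and abs(mean_fake - 0.5) < spec.equilibrium_tol):
            break
    return DCGANState(spec=spec, G=G, D=D, history=history, trained=True)


def sample_augmented(state: DCGANState, n: int, seed: int = 0,
                     batch_size: int = 32) -> np.ndarray:
    """Draw n images from z ~ Uniform(-1,1)^z_dim through G, in [0,1].

    Deterministic under ``seed``; returns (n, H, W) grayscale.
    """
    if not state.trained:
        raise RuntimeError("DCGAN state is untrained")
    if n == 0:
        s = state.spec.image_size
        return np.zeros((0, s, s), dtype=np.float32)
    rng = np.random.default_rng(seed)
    z = rng.uniform(-1, 1, (n, state.spec.z_dim)).astype(np.float32)
    out = []
    for i in range(0, n, batch_size):
        y = state.G.forward(z[i:i + batch_size], train=False)
        out.append(np.clip((y.mean(axis=1) + 1.0) / 2.0, 0.0, 1.0))
    return np.concatenate(out).astype(np.float32)
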