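"""Unpaired CycleGAN mapping a source scanner domain A onto a target B.

Two generators (G_B: A->B, G_A: B->A) and two patch discriminators are
trained jointly on the least-squares adversarial objective

    L = L_GAN(G_B, D_B, A, B) + L_GAN(G_A, D_A, B, A) + lambda * L_cyc

where the discriminator form of L_GAN is E[(D(real)-1)^2] + E[D(fake)^2],
the generator form is E[(D(fake)-1)^2], and L_cyc is the mean L1 cycle
reconstruction error in both directions. Generators are residual-block
encoder/decoder nets with instance normalization, reflection padding
and a Tanh output; discriminators are PatchGAN stacks of 4x4 strided
convolutions with LeakyReLU and a sigmoid patch output (the
least-squares loss is applied to the sigmoid outputs). After training,
mapped slices Ã = G_B(A) are pooled with B into the combined dataset
D = Ã ∪ B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import (Conv2d, ConvTranspose2d, InstanceNorm2d, LeakyReLU, ReLU,
                  Residual, Sequential, Sigmoid, Tanh)


@dataclass
class CycleGANSpec:
    """Architecture + training hyperparameters.

    Defaults reproduce the full-scale setup: 128x128 inputs replicated
    to 3 channels, generator encoder (32, 64, 128) + 9 residual blocks
    of 128 filters + decoder (64, 32, 3), PatchGAN discriminator
    (64, 128, 256, 512, 1) with 4x4 kernels, lr 2e-4 linearly decayed to
    zero after epoch 100 of 150, Adam betas (0.5, 0.999), lambda = 10.
    """

    image_size: int = 128
    channels: int = 3
    gen_enc_filters: tuple = (32, 64, 128)
    gen_res_blocks: int = 9
    gen_dec_filters: tuple = (64, 32)
    disc_filters: tuple = (64, 128, 256, 512)
    disc_kernel: int = 4
    #: per-layer strides; None -> stride 2 except the last two layers
    disc_strides: tuple | None = None
    leaky_slope: float = 0.2
    lambda_cyc: float = 10.0
    #: weight of the identity term |G_B(b)-b| + |G_A(a)-a| (0 disables);
    #: used at toy scale to keep the mapping content-preserving
    lambda_identity: float = 0.0
    lr: float = 2.0e-4
    epochs: int = 150
    lr_decay_start: int = 100
    betas: tuple = (0.5, 0.999)
    batch_size: int = 1
    seed: int = 0

    @classmethod
    def tiny(cls, image_size=32, seed=0, epochs=2):
        """Scaled-down spec for CPU-budget experiments and tests."""
        return cls(image_size=image_size, channels=3,
                   gen_enc_filters=(8, 16), gen_res_blocks=1,
                   gen_dec_filters=(8,), disc_filters=(8, 16),
                   epochs=epochs, lr_decay_start=max(1, epochs // 2),
                   lambda_cyc=10.0, seed=seed)

    def validate(self):
        down = len(self.gen_enc_filters) - 1
        if self.image_size % (2 ** down) != 0:
            raise ValueError("image_size incompatible with generator strides")


@dataclass
class CycleGANState:
    """Trained parameter sets + per-epoch loss history."""

    spec: CycleGANSpec
    G_A: Sequential   # B -> A
    G_B: Sequential   # A -> B
    D_A: Sequential
    D_B: Sequential
    history: list = field(default_factory=list)
    trained: bool = False


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

def build_generator(spec: CycleGANSpec, rng) -> Sequential:
    """Reflection-padded residual generator; spatial size preserved."""
    fs = spec.gen_enc_filters
    layers = [Conv2d(spec.channels, fs[0], 7, pad=3, padding_mode="reflect",
                     rng=rng, init_std=0.02),
              InstanceNorm2d(fs[0]), ReLU()]
    for cin, cout in zip(fs[:-1], fs[1:]):
        layers += [Conv2d(cin, cout, 3, stride=2, rng=rng, init_std=0.02),
                   InstanceNorm2d(cout), ReLU()]
    for _ in range(spec.gen_res_blocks):
        body = Sequential([
            Conv2d(fs[-1], fs[-1], 3, padding_mode="reflect", rng=rng, init_std=0.02),
            InstanceNorm2d(fs[-1]), ReLU(),
            Conv2d(fs[-1], fs[-1], 3, padding_mode="reflect", rng=rng, init_std=0.02),
            InstanceNorm2d(fs[-1])])
        layers.append(Residual(body))
    cin = fs[-1]
    for cout in spec.gen_dec_filters:
        layers += [ConvTranspose2d(cin, cout, 3, stride=2, pad=1, rng=rng,
                                   init_std=0.02),
                   InstanceNorm2d(cout), ReLU()]
        cin = cout
    layers += [Conv2d(cin, spec.channels, 7, pad=3, padding_mode="reflect",
                      rng=rng, init_std=0.02), Tanh()]
    return Sequential(layers)


def build_discriminator(spec: CycleGANSpec, rng) -> Sequential:
    """PatchGAN: strided 4x4 convs, LeakyReLU, sigmoid patch scores."""
    k = spec.disc_kernel
    fs = spec.disc_filters
    if spec.disc_strides is None:
        strides = [2 if i < len(fs) - 1 else 1 for i in range(len(fs))]
    else:
        strides = list(spec.disc_strides)
    layers = [Conv2d(spec.channels, fs[0], k, stride=strides[0], pad=1, rng=rng,
                     init_std=0.02), LeakyReLU(spec.leaky_slope)]
    for i, (cin, cout) in enumerate(zip(fs[:-1], fs[1:])):
        layers += [Conv2d(cin, cout, k, stride=strides[i + 1], pad=1, rng=rng,
                          init_std=0.02),
                   InstanceNorm2d(cout), LeakyReLU(spec.leaky_slope)]
    layers += [Conv2d(fs[-1], 1, k, stride=1, pad=1, rng=rng, init_std=0.02),
               Sigmoid()]
    return Sequential(layers)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def lsgan_loss(d_real, d_fake=None, which: str = "discriminator") -> float:
    """Least-squares adversarial loss on patch scores.

    discriminator form: mean (d_real - 1)^2 + mean d_fake^2
    generator form:     mean (d_fake - 1)^2  (pass fake scores as d_real)
    """
    if which == "generator":
        scores = np.asarray(d_real, dtype=np.float64)
        return float(np.mean((scores - 1.0) ** 2))
    if d_fake is None:
        raise ValueError("discriminator form needs both score sets")
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    if not (np.all(np.isfinite(d_real)) and np.all(np.isfinite(d_fake))):
        raise ValueError("non-finite discriminator scores")
    return float(np.mean((d_real - 1.0) ** 2) + np.mean(d_fake ** 2))


def cycle_loss(a_batch, b_batch, G_A, G_B) -> float:
    """Mean L1 round-trip error: |G_A(G_B(a)) - a| + |G_B(G_A(b)) - b|."""
    a = np.asarray(a_batch, dtype=np.float32)
    b = np.asarray(b_batch, dtype=np.float32)
    ra = G_A.forward(G_B.forward(a, train=False), train=False)
    rb = G_B.forward(G_A.forward(b, train=False), train=False)
    return float(np.mean(np.abs(ra - a)) + np.mean(np.abs(rb - b)))


def total_objective(gan_ab: float, gan_ba: float, cyc: float,
                    lambda_cyc: float = 10.0) -> float:
    """L = L_GAN(G_B,D_B,A,B) + L_GAN(G_A,D_A,B,A) + lambda * L_cyc."""
    if lambda_cyc < 0:
        raise ValueError("lambda must be >= 0")
    return gan_ab + gan_ba + lambda_cyc * cyc


def lr_schedule(epoch: int, spec: CycleGANSpec) -> float:
    """Constant lr, then linear decay to 0 between decay_start and epochs."""
    if epoch <= spec.lr_decay_start:
        return spec.lr
    frac = (epoch - spec.lr_decay_start) / (spec.epochs - spec.lr_decay_start)
    return spec.lr * max(0.0, 1.0 - frac)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _to_net(x: np.ndarray, channels: int) -> np.ndarray:
    """[0,1] grayscale (N,H,W) -> [-1,1] (N,C,H,W) replicated channels."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    x = x[:, None].repeat(channels, axis=1)
    return x * 2.0 - 1.0


def _from_net(x: np.ndarray) -> np.ndarray:
    """[-1,1] (N,C,H,W) -> [0,1] grayscale (N,H,W), channel-averaged."""
    return np.clip((x.mean(axis=1) + 1.0) / 2.0, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_cyclegan(domain_a: np.ndarray, domain_b: np.ndarray,
                   spec: CycleGANSpec) -> CycleGANState:
    """Alternating generator/discriminator Adam updates.

    ``domain_a`` / ``domain_b`` are unpaired (N,H,W) stacks in [0,1].
    Per epoch the loss components (both adversarial directions, cycle,
    discriminator losses) are averaged and recorded.
    """
    a_all = _to_net(domain_a, spec.channels)
    b_all = _to_net(domain_b, spec.channels)
    if a_all.shape[0] == 0 or b_all.shape[0] == 0:
        raise ValueError("both domains must be non-empty")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    G_A = build_generator(spec, rng)
    G_B = build_generator(spec, rng)
    D_A = build_discriminator(spec, rng)
    D_B = build_discriminator(spec, rng)
    opt_g = _nn.Adam([G_A, G_B], spec.lr, betas=spec.betas)
    opt_d = _nn.Adam([D_A, D_B], spec.lr, betas=spec.betas)

    n_iter = max(len(a_all), len(b_all)) // spec.batch_size
    n_iter = max(n_iter, 1)
    history = []
    for epoch in range(1, spec.epochs + 1):
        lr = lr_schedule(epoch, spec)
        ep = {"loss_gan_ab": 0.0, "loss_gan_ba": 0.0, "loss_cyc": 0.0,
              "loss_d_a": 0.0, "loss_d_b": 0.0}
        for _ in range(n_iter):
            ia = rng.integers(0, len(a_all), spec.batch_size)
            ib = rng.integers(0, len(b_all), spec.batch_size)
            a, b = a_all[ia], b_all[ib]

            # --- generator update (discriminators frozen) ---
            opt_g.zero_grad()
            # adversarial A->B: (D_B(G_B(a)) - 1)^2
            fake_b = G_B.forward(a)
            s = D_B.forward(fake_b, train=False)
            loss_ab = float(np.mean((s - 1.0) ** 2))
            dfake_b = D_B.backward((2.0 / s.size) * (s - 1.0))
            G_B.backward(dfake_b)
            # adversarial B->A
            fake_a = G_A.forward(b)
            s2 = D_A.forward(fake_a, train=False)
            loss_ba = float(np.mean((s2 - 1.0) ** 2))
            dfake_a = D_A.backward((2.0 / s2.size) * (s2 - 1.0))
            G_A.backward(dfake_a)
            # cycle a -> b~ -> a
            fb = G_B.forward(a)
            ra = G_A.forward(fb)
            l1a = float(np.mean(np.abs(ra - a)))
            g = (spec.lambda_cyc / ra.size) * np.sign(ra - a).astype(np.float32)
            G_B.backward(G_A.backward(g))
            # cycle b -> a~ -> b
            fa = G_A.forward(b)
            rb = G_B.forward(fa)
            l1b = float(np.mean(np.abs(rb - b)))
            g = (spec.lambda_cyc / rb.size) * np.sign(rb - b).astype(np.float32)
            G_A.backward(G_B.backward(g))
            # identity terms: G_B should leave target-domain images alone
            if spec.lambda_identity > 0:
                ib = G_B.forward(b)
                g = (spec.lambda_identity / ib.size) * np.sign(ib - b).astype(np.float32)
                G_B.backward(g)
                ia = G_A.forward(a)
                g = (spec.lambda_identity / ia.size) * np.sign(ia - a).astype(np.float32)
                G_A.backward(g)
            opt_g.step(lr=lr)

            # --- discriminator update (generators frozen) ---
            opt_d.zero_grad()
            s_real_b = D_B.forward(b)
            D_B.backward((2.0 / s_real_b.size) * (s_real_b - 1.0))
            s_fake_b = D_B.forward(fake_b)  # detached: no G backward
            D_B.backward((2.0 / s_fake_b.size) * s_fake_b)
            loss_db = lsgan_loss(s_real_b, s_fake_b)
            s_real_a = D_A.forward(a)
            D_A.backward((2.0 / s_real_a.size) * (s_real_a - 1.0))
            s_fake_a = D_A.forward(fake_a)
            D_A.backward((2.0 / s_fake_a.size) * s_fake_a)
            loss_da = lsgan_loss(s_real_a, s_fake_a)
            opt_d.step(lr=lr)

            ep["loss_gan_ab"] += loss_ab / n_iter
            ep["loss_gan_ba"] += loss_ba / n_iter
            ep["loss_cyc"] += (l1a + l1b) / n_iter
            ep["loss_d_a"] += loss_da / n_iter
            ep["loss_d_b"] += loss_db / n_iter
        ep["epoch"] = epoch
        ep["lr"] = lr
        history.append(ep)
    return CycleGANState(spec=spec, G_A=G_A, G_B=G_B, D_A=D_A, D_B=D_B,
                         history=history, trained=True)


def map_domain(state: CycleGANState, slices_a: np.ndarray,
               batch_size: int = 8) -> np.ndarray:
    """Map source slices to the target domain: ã = G_B(a), back in [0,1]."""
    if not state.trained:
        raise RuntimeError("CycleGAN state is untrained")
    x = np.asarray(slices_a, dtype=np.float32)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    out = []
    for i in range(0, len(x), batch_size):
        xb = _to_net(x[i:i + batch_size], state.spec.channels)
        out.append(_from_net(state.G_B.forward(xb, train=False)))
    mapped = np.concatenate(out)
    return mapped[0] if squeeze else mapped


def combine_domains(mapped_a, b):
    """Concatenate two patient cohorts into D = Ã ∪ B.

    Patient ids must be disjoint across the two sources.
    """
    ids_a = {p.patient_id for p in mapped_a}
    ids_b = {p.patient_id for p in b}
    dup = ids_a & ids_b
    if dup:
        raise ValueError(f"duplicate patient ids across domains: {sorted(dup)[:5]}")
    return list(mapped_a) + list(b)


def map_patients(state: CycleGANState, patients, modality_states: dict | None = None):
    """Map every slice of a patient list through G_B, preserving labels.

    ``modality_states`` optionally gives one trained CycleGAN per
    modality (the default policy: separate models per modality); when
    omitted, ``state`` is applied to both modalities.
    """
    from copy import deepcopy

    out = []
    for p in patients:
        q = deepcopy(p)
        for m, slist in q.slices.items():
            st = (modality_states or {}).get(m, state)
            stack = np.stack([s.pixels for s in slist])
            mapped = map_domain(st, stack)
            for s, px in zip(slist, mapped):
                s.pixels = px
        out.append(q)
    return out
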