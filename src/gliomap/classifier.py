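"""Two-stream convolutional autoencoder classifier with bilinear fusion.

Stage 1 (pre-training): each modality stream's CAE is trained
unsupervised to reconstruct GAN-augmented tumor crops (MSE, Adam
lr 0.002, batch 16, L2 1e-4 on conv kernels).

Stage 2 (refinement): the two encoders' terminal feature maps f1, f2
(h x w x c) are fused by element-wise aggregation f = f1 ⊙ f2 followed
by the bilinear map H = FᵀF (F the (h·w) x c flattening of f), passed
through signed-square-root + L2 normalization, two 256-unit fully
connected layers with dropout 0.5 and a 2-way softmax, and the whole
stack (encoders + head) is fine-tuned on categorical cross-entropy with
runtime augmentation (horizontal flips, rotations up to 10 degrees) and
early stopping on best validation accuracy.
"""

from __future__ import annotations

from copy import deepcopy
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import rotate as _nd_rotate

from . import _nn
from ._nn import (BatchNorm, Conv2d, Dense, Dropout, MaxPool2d, ReLU,
                  Sequential, Upsample2d)


@dataclass
class CAESpec:
    """Single-stream CAE architecture (64x64x1 -> 8x8x512 encoder)."""

    input_size: int = 64
    enc_filters: tuple = (64, 128, 128, 256, 256, 512)
    #: 1-based encoder conv indices followed by 2x2 max-pooling
    pool_after: tuple = (2, 3, 5)
    dec_filters: tuple = (256, 256, 128, 128, 1)
    #: 1-based decoder conv indices preceded by 2x upsampling
    upsample_before: tuple = (1, 3, 4)
    l2: float = 1.0e-4
    lr: float = 0.002
    batch_size: int = 16
    epochs: int = 200
    seed: int = 0

    @classmethod
    def tiny(cls, input_size=16, seed=0, epochs=30):
        return cls(input_size=input_size, enc_filters=(8, 16, 16),
                   pool_after=(1, 2), dec_filters=(8, 8, 1),
                   upsample_before=(1, 2), epochs=epochs,
                   batch_size=16, seed=seed)

    @property
    def feature_size(self) -> int:
        return self.input_size // (2 ** len(self.pool_after))

    @property
    def feature_channels(self) -> int:
        return self.enc_filters[-1]


def build_encoder(spec: CAESpec, rng) -> Sequential:
    layers = []
    cin = 1
    for i, cout in enumerate(spec.enc_filters, start=1):
        layers += [Conv2d(cin, cout, 3, rng=rng), BatchNorm(cout), ReLU()]
        if i in spec.pool_after:
            layers.append(MaxPool2d())
        cin = cout
    return Sequential(layers)


def build_decoder(spec: CAESpec, rng) -> Sequential:
    layers = []
    cin = spec.enc_filters[-1]
    for i, cout in enumerate(spec.dec_filters, start=1):
        if i in spec.upsample_before:
            layers.append(Upsample2d())
        layers += [Conv2d(cin, cout, 3, rng=rng), BatchNorm(cout), ReLU()]
        cin = cout
    return Sequential(layers)


@dataclass
class CAE:
    spec: CAESpec
    encoder: Sequential
    decoder: Sequential
    history: list = field(default_factory=list)
    trained: bool = False


def pretrain_cae(images: np.ndarray, spec: CAESpec) -> CAE:
    """Unsupervised reconstruction pre-training of one stream.

    ``images``: (N,H,W) in [0,1] at the spec input size. Minimizes MSE
    with Adam; records the per-epoch mean reconstruction loss.
    """
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 3 or x.shape[1] != spec.input_size or x.shape[2] != spec.input_size:
        raise ValueError(f"expected (N,{spec.input_size},{spec.input_size}) images")
    if len(x) == 0:
        raise ValueError("empty image set")
    rng = np.random.default_rng(spec.seed)
    enc = build_encoder(spec, rng)
    dec = build_decoder(spec, rng)
    opt = _nn.Adam([enc, dec], spec.lr, weight_decay=spec.l2)
    x = x[:, None]  # NCHW
    batch = min(spec.batch_size, len(x))
    n_iter = max(1, len(x) // batch)
    history = []
    for epoch in range(1, spec.epochs + 1):
        perm = rng.permutation(len(x))
        ep_loss = 0.0
        for it in range(n_iter):
            xb = x[perm[it * batch:(it + 1) * batch]]
            opt.zero_grad()
            recon = dec.forward(enc.forward(xb))
            loss, g = _nn.mse_loss(recon, xb)
            enc.backward(dec.backward(g))
            opt.step()
            ep_loss += loss / n_iter
        history.append({"epoch": epoch, "mse": ep_loss})
    return CAE(spec=spec, encoder=enc, decoder=dec, history=history, trained=True)


def encode(cae: CAE, images: np.ndarray) -> np.ndarray:
    """Deterministic inference-mode encoding to h x w x c feature maps.

    Accepts (H,W) or (N,H,W); returns (h,w,c) or (N,h,w,c).
    """
    x = np.asarray(images, dtype=np.float32)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.shape[1] != cae.spec.input_size:
        raise ValueError("input dims do not match CAE spec")
    f = cae.encoder.forward(x[:, None], train=False)  # (N,c,h,w)
    f = np.transpose(f, (0, 2, 3, 1))
    return f[0] if squeeze else f


# ---------------------------------------------------------------------------
# fusion operations (public h x w x c contract)
# ---------------------------------------------------------------------------

def aggregate(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Element-wise aggregation f = f1 ⊙ f2 (dims must match)."""
    f1, f2 = np.asarray(f1), np.asarray(f2)
    if f1.shape != f2.shape:
        raise ValueError(f"feature shape mismatch: {f1.shape} vs {f2.shape}")
    return f1 * f2


def bilinear(f: np.ndarray) -> np.ndarray:
    """Bilinear pooling H = FᵀF with F the (h·w) x c flattening of f.

    H is c x c, symmetric positive semidefinite.
    """
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError("expected an h x w x c feature map")
    c = f.shape[2]
    F = f.reshape(-1, c)
    return F.T @ F


def signed_sqrt(h: np.ndarray) -> np.ndarray:
    """Signed square root, the standard bilinear-pooling stabilizer."""
    return np.sign(h) * np.sqrt(np.abs(h))


def l2_normalize(h: np.ndarray, axis=-1, eps=1e-12) -> np.ndarray:
    n = np.sqrt(np.sum(h ** 2, axis=axis, keepdims=True))
    return h / np.maximum(n, eps)


# ---------------------------------------------------------------------------
# fusion head + two-stream classifier
# ---------------------------------------------------------------------------

class FusionHead:
    """Signed-sqrt + L2 normalization, two FC(256) + dropout, softmax head."""

    def __init__(self, channels: int, hidden: int = 256, n_classes: int = 2,
                 dropout: float = 0.5, use_signed_sqrt: bool = True, rng=None):
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.use_signed_sqrt = use_signed_sqrt
        self.net = Sequential([
            Dense(channels * channels, hidden, rng=rng), ReLU(),
            Dropout(dropout, rng=rng),
            Dense(hidden, hidden, rng=rng), ReLU(),
            Dropout(dropout, rng=rng),
            Dense(hidden, n_classes, rng=rng),
        ])

    def forward(self, H: np.ndarray, train: bool = True) -> np.ndarray:
        """(N,c,c) bilinear maps -> (N,n_classes) logits."""
        n = H.shape[0]
        h = H.reshape(n, -1).astype(np.float32)
        if self.use_signed_sqrt:
            self._sqrt_in = h
            h = np.sign(h) * np.sqrt(np.abs(h))
        self._norm_in = h
        self._norms = np.sqrt((h ** 2).sum(axis=1, keepdims=True))
        self._normed = h / np.maximum(self._norms, 1e-12)
        return self.net.forward(self._normed, train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.net.backward(dlogits)
        # back through L2 normalization
        nrm = np.maximum(self._norms, 1e-12)
        y = self._normed
        g = (g - y * (g * y).sum(axis=1, keepdims=True)) / nrm
        # back through signed sqrt: d/dx sign(x)sqrt(|x|) = 1/(2 sqrt(|x|))
        if self.use_signed_sqrt:
            denom = 2.0 * np.sqrt(np.abs(self._sqrt_in))
            g = g / np.maximum(denom, 1e-3)
        n = g.shape[0]
        return g.reshape(n, self.channels, self.channels)

    # parameter plumbing
    def layers_flat(self):
        return self.net.layers_flat()

    def zero_grad(self):
        self.net.zero_grad()

    def state(self):
        return self.net.state()

    def load_state(self, st):
        self.net.load_state(st)


@dataclass
class RefineConfig:
    lr: float = 1.0e-3
    batch_size: int = 16
    epochs: int = 30
    patience: int = 20
    l2: float = 1.0e-4
    dropout: float = 0.5
    hidden: int = 256
    max_rotation_deg: float = 10.0
    augment: bool = True
    freeze_encoders: bool = False
    use_signed_sqrt: bool = True
    seed: int = 0


@dataclass
class TwoStreamClassifier:
    spec: CAESpec
    enc1: Sequential   # T1ce stream
    enc2: Sequential   # FLAIR stream
    head: FusionHead
    history: list = field(default_factory=list)
    best_epoch: int = 0
    trained: bool = False


def _fuse_forward(clf: TwoStreamClassifier, x1, x2, train):
    f1 = clf.enc1.forward(x1, train=train)
    f2 = clf.enc2.forward(x2, train=train)
    f = f1 * f2
    n, c = f.shape[0], f.shape[1]
    Fm = f.reshape(n, c, -1)              # (N, c, hw)
    H = Fm @ Fm.transpose(0, 2, 1)        # (N, c, c) = FᵀF
    logits = clf.head.forward(H, train=train)
    cache = (f1, f2, Fm)
    return logits, cache


def _fuse_backward(clf: TwoStreamClassifier, dlogits, cache,
                   freeze_encoders=False):
    f1, f2, Fm = cache
    dH = clf.head.backward(dlogits)       # (N, c, c)
    dFm = (dH + dH.transpose(0, 2, 1)) @ Fm
    df = dFm.reshape(f1.shape).astype(np.float32)
    if not freeze_encoders:
        clf.enc1.backward(df * f2)
        clf.enc2.backward(df * f1)


def _augment_pair(x1, x2, rng, max_deg):
    """Joint runtime augmentation: same flip/rotation for both streams."""
    x1, x2 = x1.copy(), x2.copy()
    for i in range(x1.shape[0]):
        if rng.random() < 0.5:
            x1[i] = x1[i, :, :, ::-1]
            x2[i] = x2[i, :, :, ::-1]
        ang = rng.uniform(-max_deg, max_deg)
        x1[i, 0] = _nd_rotate(x1[i, 0], ang, reshape=False, order=1,
                              mode="nearest")
        x2[i, 0] = _nd_rotate(x2[i, 0], ang, reshape=False, order=1,
                              mode="nearest")
    return x1, x2


def refine_train(cae1, cae2, train_ds, val_ds,
                 config: RefineConfig | None = None,
                 spec: CAESpec | None = None) -> TwoStreamClassifier:
    """Supervised fine-tuning of both encoders + fusion head.

    ``cae1``/``cae2`` are pre-trained CAEs for the T1ce and FLAIR
    streams, or None for from-scratch encoders (then ``spec`` is
    required). ``train_ds``/``val_ds`` are
    :class:`gliomap.preprocess.SliceDataset` objects with paired
    modality crops. Early stopping keeps the parameters of the best
    validation-accuracy epoch.
    """
    config = config or RefineConfig()
    if cae1 is None or cae2 is None:
        if spec is None:
            raise ValueError("spec required for from-scratch training")
        rng0 = np.random.default_rng(config.seed + 1)
        enc1 = build_encoder(spec, rng0)
        enc2 = build_encoder(spec, rng0)
    else:
        spec = cae1.spec
        enc1 = deepcopy(cae1.encoder)
        enc2 = deepcopy(cae2.encoder)
    if len(train_ds) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    head = FusionHead(spec.feature_channels, hidden=config.hidden,
                      dropout=config.dropout,
                      use_signed_sqrt=config.use_signed_sqrt, rng=rng)
    clf = TwoStreamClassifier(spec=spec, enc1=enc1, enc2=enc2, head=head)

    nets = [head.net] if config.freeze_encoders else [enc1, enc2, head.net]
    opt = _nn.Adam(nets, config.lr, weight_decay=config.l2)

    x1 = train_ds.x_t1ce[:, None].astype(np.float32)
    x2 = train_ds.x_flair[:, None].astype(np.float32)
    y = train_ds.y
    batch = min(config.batch_size, len(y))
    n_iter = max(1, len(y) // batch)

    best_acc, best_state, best_epoch = -1.0, None, 0
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(len(y))
        ep_loss = 0.0
        for it in range(n_iter):
            idx = perm[it * batch:(it + 1) * batch]
            xb1, xb2 = x1[idx], x2[idx]
            if config.augment:
                xb1, xb2 = _augment_pair(xb1, xb2, rng, config.max_rotation_deg)
            opt.zero_grad()
            logits, cache = _fuse_forward(clf, xb1, xb2, train=True)
            loss, dl = _nn.cross_entropy_loss(logits, y[idx])
            _fuse_backward(clf, dl, cache, config.freeze_encoders)
            opt.step()
            ep_loss += loss / n_iter
        val_acc = _accuracy(clf, val_ds) if len(val_ds) else float("nan")
        clf.history.append({"epoch": epoch, "train_loss": ep_loss,
                            "val_acc": val_acc})
        if not np.isnan(val_acc) and val_acc > best_acc:
            best_acc = val_acc
            best_epoch = epoch
            best_state = (enc1.state(), enc2.state(), head.state())
        elif len(val_ds) and epoch - best_epoch >= config.patience:
            break
    if best_state is not None:
        enc1.load_state(best_state[0])
        enc2.load_state(best_state[1])
        head.load_state(best_state[2])
    clf.best_epoch = best_epoch if best_state is not None else len(clf.history)
    clf.trained = True
    return clf


def predict(clf: TwoStreamClassifier, t1ce, flair) -> np.ndarray:
    """Class probabilities for paired slices (dropout/BN in eval mode)."""
    if not clf.trained:
        raise RuntimeError("classifier is untrained")
    return _predict(clf, t1ce, flair)


def _predict(clf, t1ce, flair) -> np.ndarray:
    x1 = np.asarray(t1ce, dtype=np.float32)
    x2 = np.asarray(flair, dtype=np.float32)
    if x1.shape != x2.shape:
        raise ValueError("both modalities must be present with equal shapes")
    squeeze = x1.ndim == 2
    if squeeze:
        x1, x2 = x1[None], x2[None]
    logits, _ = _fuse_forward(clf, x1[:, None], x2[:, None], train=False)
    p = _nn.softmax(logits)
    return p[0] if squeeze else p


def _accuracy(clf, ds, batch: int = 64) -> float:
    correct = 0
    for i in range(0, len(ds), batch):
        p = _predict(clf, ds.x_t1ce[i:i + batch], ds.x_flair[i:i + batch])
        correct += int(np.sum(np.argmax(p, axis=1) == ds.y[i:i + batch]))
    return correct / len(ds)
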