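"""Synthetic two-domain, two-modality, two-class glioma phantom cohorts.

Each simulated patient carries a shared 2-D "anatomy" (a bright brain
ellipse on dark background), an elliptical tumor whose internal
sinusoidal texture frequency encodes the molecular class, two derived
modalities (a FLAIR role with high tumor/background contrast and a T1ce
role with lower contrast), and a scanner-domain transform: a smooth
multiplicative bias field, a gamma/contrast change and additive
Gaussian noise. Ground-truth tumor masks accompany every slice, so the
whole harmonization + classification pipeline can be exercised without
clinical data.

The class-discriminative signal is deliberately a *texture frequency*,
not a global intensity statistic: harmonization must preserve local
structure for downstream classification to work, which is exactly the
property the domain-mapping stage is asked to have.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("T1ce", "FLAIR")
DOMAINS = ("A", "B")
#: phantom class index -> molecular label pair (class 0 plays the
#: codeleted / IDH-mutated role, class 1 the non-codeleted / wild-type role)
CLASS_LABELS = {
    0: {"label_1p19q": "codeleted", "label_idh": "mutated"},
    1: {"label_1p19q": "non-codeleted", "label_idh": "wild-type"},
}


class PhantomConfigError(ValueError):
    """Raised for invalid phantom configuration values."""


@dataclass
class DomainShift:
    """Scanner-domain transform parameters.

    out = clip(contrast_scale * (bias_field * blur(image))**gamma + noise, 0, 1)
    with a smooth multiplicative bias field of peak deviation
    ``bias_amplitude``, an optional Gaussian point-spread blur of width
    ``blur_sigma`` (pixels) modelling scanner resolution differences,
    and i.i.d. Gaussian noise of sd ``noise_sd``.
    """

    gamma: float = 1.0
    bias_amplitude: float = 0.0
    noise_sd: float = 0.0
    contrast_scale: float = 1.0
    blur_sigma: float = 0.0

    def validate(self):
        if self.gamma <= 0:
            raise PhantomConfigError(f"gamma must be > 0, got {self.gamma}")
        if not (0 <= self.bias_amplitude < 1):
            raise PhantomConfigError("bias_amplitude must be in [0, 1)")
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be >= 0")
        if self.contrast_scale <= 0:
            raise PhantomConfigError("contrast_scale must be > 0")
        if self.blur_sigma < 0:
            raise PhantomConfigError("blur_sigma must be >= 0")


@dataclass
class ClassTexture:
    """Sinusoidal tumor texture: cycles/pixel frequency and amplitude."""

    frequency: float
    amplitude: float


@dataclass
class ModalityParams:
    """Base tumor and background intensities of one modality."""

    tumor_intensity: float
    background_intensity: float


def _default_domain_shift():
    # Domain B is the clean "target scanner"; domain A has a mild tone
    # change, a bias field, noise, and - the dominant effect - a wider
    # point-spread function (lower effective resolution), which
    # attenuates the high-frequency class texture domain-conditionally.
    # A classifier trained on B transfers poorly to raw A, and naive
    # pooling of raw A with B destabilizes training, while the blur is
    # approximately invertible by a convolutional generator.
    return {
        "A": DomainShift(gamma=1.3, bias_amplitude=0.15, noise_sd=0.04,
                         contrast_scale=0.9, blur_sigma=1.2),
        "B": DomainShift(),
    }


def _default_class_texture():
    # low vs high spatial frequency, both below Nyquist after ROI
    # resampling; learnable by 3x3 conv stacks
    return {
        0: ClassTexture(frequency=0.08, amplitude=0.25),
        1: ClassTexture(frequency=0.22, amplitude=0.25),
    }


def _default_modality_params():
    # FLAIR role gets higher tumor/background contrast than T1ce role;
    # tumor intensity + texture amplitude stays below 1 so the class
    # texture is never clipped away
    return {
        "T1ce": ModalityParams(tumor_intensity=0.55, background_intensity=0.40),
        "FLAIR": ModalityParams(tumor_intensity=0.70, background_intensity=0.30),
    }


@dataclass
class PhantomConfig:
    """Cohort-level configuration; defaults define the study conditions."""

    image_size: int = 128
    #: patients per (domain, class); keys like ("A", 0)
    n_patients: dict = field(
        default_factory=lambda: {(d, c): 8 for d in DOMAINS for c in (0, 1)})
    slices_per_patient: int = 10
    domain_shift: dict = field(default_factory=_default_domain_shift)
    class_texture: dict = field(default_factory=_default_class_texture)
    modality_params: dict = field(default_factory=_default_modality_params)
    seed: int = 0

    def validate(self):
        n = self.image_size
        if n < 32 or (n & (n - 1)) != 0:
            raise PhantomConfigError("image_size must be a power of two >= 32")
        if self.slices_per_patient < 1:
            raise PhantomConfigError("slices_per_patient must be >= 1")
        for key, cnt in self.n_patients.items():
            if cnt < 1:
                raise PhantomConfigError(f"patient count for {key} must be >= 1")
        for shift in self.domain_shift.values():
            shift.validate()


@dataclass
class Slice2D:
    """A normalized 2-D image slice with its provenance."""

    pixels: np.ndarray
    modality: str
    patient_id: str
    slice_index: int


@dataclass
class SyntheticPatient:
    patient_id: str
    domain: str
    label_1p19q: str
    label_idh: str
    #: modality -> list[Slice2D], one per slice index
    slices: dict
    #: per-slice boolean tumor masks (shared across modalities)
    masks: list

    @property
    def class_index(self) -> int:
        return 0 if self.label_1p19q == "codeleted" else 1


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def _smooth_field(size: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field in [-1, 1] from a few low-order cosine modes."""
    yy, xx = np.mgrid[0:size, 0:size] / size
    f = np.zeros((size, size))
    for _ in range(3):
        fx, fy = rng.uniform(0.5, 1.5, 2)
        phx, phy = rng.uniform(0, 2 * np.pi, 2)
        f += np.cos(2 * np.pi * fx * xx + phx) * np.cos(2 * np.pi * fy * yy + phy)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def apply_domain_shift(image: np.ndarray, shift: DomainShift,
                       rng: np.random.Generator) -> np.ndarray:
    """Apply one scanner-domain intensity transform to an image in [0, 1]."""
    shift.validate()
    size = image.shape[0]
    if shift.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter
        image = gaussian_filter(image, shift.blur_sigma)
    if shift.bias_amplitude > 0:
        bias = 1.0 + shift.bias_amplitude * _smooth_field(size, rng)
    else:
        bias = 1.0
    out = np.clip(bias * image, 0.0, None) ** shift.gamma
    out = shift.contrast_scale * out
    if shift.noise_sd > 0:
        out = out + rng.normal(0.0, shift.noise_sd, image.shape)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _ellipse_mask(size, cy, cx, ry, rx, angle=0.0):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    ca, sa = np.cos(angle), np.sin(angle)
    y, x = yy - cy, xx - cx
    u = ca * x + sa * y
    v = -sa * x + ca * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _make_patient(pid: str, domain: str, cls: int, cfg: PhantomConfig,
                  rng: np.random.Generator) -> SyntheticPatient:
    n = cfg.image_size
    shift = cfg.domain_shift[domain]
    tex = cfg.class_texture[cls]

    # shared anatomy: brain ellipse + gentle intensity modulation
    brain = _ellipse_mask(n, n / 2, n / 2, n * 0.42, n * 0.38,
                          angle=rng.uniform(-0.2, 0.2))
    modulation = 0.06 * _smooth_field(n, rng)

    # tumor geometry: axis-aligned ellipse within the central region
    cy = rng.uniform(0.35, 0.65) * n
    cx = rng.uniform(0.35, 0.65) * n
    ry = rng.uniform(0.10, 0.20) * n
    rx = rng.uniform(0.10, 0.20) * n

    # class texture: oriented sinusoid, random phase/orientation per patient
    theta = rng.uniform(0, np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    carrier = np.sin(2 * np.pi * tex.frequency *
                     (np.cos(theta) * xx + np.sin(theta) * yy) + phase)

    k = cfg.slices_per_patient
    # through-plane tumor size profile (circle cross-sections), kept >= 0.5
    # so every slice is tumor-bearing with mask area > 0
    t = np.linspace(-0.8, 0.8, k) if k > 1 else np.zeros(1)
    scales = np.sqrt(np.clip(1.0 - t ** 2, 0.25, 1.0))

    slices = {m: [] for m in MODALITIES}
    masks = []
    for si in range(k):
        mask = _ellipse_mask(n, cy, cx, max(ry * scales[si], 2.0),
                             max(rx * scales[si], 2.0))
        mask &= brain
        if not mask.any():  # tumor drifted outside brain: clip to center pixel
            mask = _ellipse_mask(n, n / 2, n / 2, 2.0, 2.0)
        masks.append(mask)
        for m in MODALITIES:
            mp = cfg.modality_params[m]
            img = np.zeros((n, n))
            img[brain] = mp.background_intensity
            img += modulation * brain
            img[mask] = mp.tumor_intensity
            img += tex.amplitude * carrier * mask
            img = np.clip(img, 0.0, 1.0)
            img = apply_domain_shift(img, shift, rng)
            slices[m].append(Slice2D(pixels=img, modality=m,
                                     patient_id=pid, slice_index=si))
    labels = CLASS_LABELS[cls]
    return SyntheticPatient(patient_id=pid, domain=domain,
                            label_1p19q=labels["label_1p19q"],
                            label_idh=labels["label_idh"],
                            slices=slices, masks=masks)


def generate_cohort(config: PhantomConfig) -> list:
    """Generate the configured cohort of SyntheticPatient objects.

    Determinism: every patient draws from its own counter-derived
    substream of the cohort seed, so identical configs give
    bit-identical cohorts regardless of generation order.
    """
    config.validate()
    patients = []
    counter = 0
    for (domain, cls), count in sorted(config.n_patients.items()):
        for i in range(count):
            pid = f"{domain}{cls}_{i:03d}"
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(counter,)))
            patients.append(_make_patient(pid, domain, cls, config, rng))
            counter += 1
    return patients


# ---------------------------------------------------------------------------
# on-disk cohort format
# ---------------------------------------------------------------------------

def write_cohort(patients, out_dir, fmt="npz"):
    """Write slices + masks and a `patients.csv` sidecar table.

    fmt 'npz' stores float arrays; 'png' stores 8-bit images (lossy in
    intensity resolution).
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for p in patients:
        pdir = os.path.join(out_dir, p.patient_id)
        os.makedirs(pdir, exist_ok=True)
        for si, mask in enumerate(p.masks):
            mask_path = os.path.join(p.patient_id, f"mask_{si:02d}.npz")
            np.savez_compressed(os.path.join(out_dir, mask_path),
                                mask=mask.astype(np.uint8))
            for m in MODALITIES:
                sl = p.slices[m][si]
                if fmt == "npz":
                    rel = os.path.join(p.patient_id, f"{m}_{si:02d}.npz")
                    np.savez_compressed(os.path.join(out_dir, rel),
                                        pixels=sl.pixels.astype(np.float32))
                elif fmt == "png":
                    from PIL import Image
                    rel = os.path.join(p.patient_id, f"{m}_{si:02d}.png")
                    Image.fromarray(
                        (np.clip(sl.pixels, 0, 1) * 255).astype(np.uint8)
                    ).save(os.path.join(out_dir, rel))
                else:
                    raise ValueError(f"unknown format {fmt!r}")
                rows.append({"patient_id": p.patient_id, "domain": p.domain,
                             "label_1p19q": p.label_1p19q, "label_idh": p.label_idh,
                             "modality": m, "slice_index": si,
                             "slice_path": rel, "mask_path": mask_path})
    with open(os.path.join(out_dir, "patients.csv"), "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        w.writeheader()
        w.writerows(rows)


def read_cohort(in_dir) -> list:
    """Read a cohort written by :func:`write_cohort` (npz or png slices)."""
    import pandas as pd

    table = pd.read_csv(os.path.join(in_dir, "patients.csv"))
    patients = []
    for pid, grp in table.groupby("patient_id", sort=True):
        first = grp.iloc[0]
        n_slices = grp["slice_index"].max() + 1
        masks, slices = [], {m: [None] * n_slices for m in MODALITIES}
        for si in range(n_slices):
            sub = grp[grp.slice_index == si]
            mpath = os.path.join(in_dir, sub.iloc[0]["mask_path"])
            masks.append(np.load(mpath)["mask"].astype(bool))
            for _, row in sub.iterrows():
                spath = os.path.join(in_dir, row["slice_path"])
                if spath.endswith(".npz"):
                    px = np.load(spath)["pixels"]
                else:
                    from PIL import Image
                    px = np.asarray(Image.open(spath), dtype=np.float32) / 255.0
                slices[row["modality"]][si] = Slice2D(
                    pixels=px.astype(np.float32), modality=row["modality"],
                    patient_id=pid, slice_index=si)
        patients.append(SyntheticPatient(
            patient_id=pid, domain=first["domain"],
            label_1p19q=first["label_1p19q"], label_idh=first["label_idh"],
            slices=slices, masks=masks))
    return patients
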