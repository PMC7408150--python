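"""Intensity normalization, tumor bounding boxes, slice selection, splits.

Slices are rescaled (bilinear) to a common square size and min–max
normalized to [0, 1]; tumor regions are extracted via a *tight* rectangular
bounding box and resampled to 64x64; per-patient slices are selected by
tumor area; and train/validation/test partitions are strictly
patient-separated (all slices of a patient share one subset) with class
stratification.

Coordinates are 0-based, half-open, row-major throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.transform import resize as _sk_resize

from .phantom import MODALITIES, Slice2D


class EmptyROIError(ValueError):
    """Raised when a mask contains no foreground pixel."""


@dataclass(frozen=True)
class BoundingBox:
    """Half-open rectangular region [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self):
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError(f"degenerate box {self}")

    @property
    def shape(self):
        return (self.row1 - self.row0, self.col1 - self.col0)

    def union(self, other: "BoundingBox") -> "BoundingBox":
        return BoundingBox(min(self.row0, other.row0), min(self.col0, other.col0),
                           max(self.row1, other.row1), max(self.col1, other.col1))


def normalize_and_resize(image: np.ndarray, size: int = 128) -> np.ndarray:
    """Bilinear resize to size x size, then min–max scale to [0, 1].

    Constant images map to all zeros (divide-by-zero guard).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    if image.shape != (size, size):
        image = _sk_resize(image, (size, size), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
    lo, hi = image.min(), image.max()
    if hi > lo:
        image = (image - lo) / (hi - lo)
    else:
        image = np.zeros_like(image)
    return image.astype(np.float32)


def tight_bbox(mask: np.ndarray) -> BoundingBox:
    """Minimal half-open box containing every foreground pixel."""
    mask = np.asarray(mask).astype(bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyROIError("mask has no foreground pixels (no ROI)")
    return BoundingBox(int(rows[0]), int(cols[0]), int(rows[-1] + 1), int(cols[-1] + 1))


def crop_to_roi(image: np.ndarray, box: BoundingBox, out_size: int = 64) -> np.ndarray:
    """Crop to the box, then bilinear resize to out_size x out_size.

    Intensities are interpolated, never rescaled, so the [0, 1] range is
    preserved; an exact-size crop is returned pixel-identical.
    """
    h, w = image.shape
    if box.row0 < 0 or box.col0 < 0 or box.row1 > h or box.col1 > w:
        raise ValueError(f"box {box} outside image {image.shape}")
    crop = np.asarray(image, dtype=np.float32)[box.row0:box.row1, box.col0:box.col1]
    if crop.shape == (out_size, out_size):
        return crop.copy()
    out = _sk_resize(crop.astype(np.float64), (out_size, out_size), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def select_tumor_slices(patient, k: int, seed: int = 0) -> list:
    """Indices of the k largest-tumor slices (ties -> lower index).

    If fewer than k tumor-bearing slices exist, the remainder is sampled
    with replacement from the available ones, deterministically under
    ``seed``. Returns slice indices into ``patient.masks``.
    """
    areas = np.array([int(m.sum()) for m in patient.masks])
    candidates = np.flatnonzero(areas > 0)
    if candidates.size == 0:
        raise EmptyROIError(f"patient {patient.patient_id} has no tumor slices")
    order = candidates[np.lexsort((candidates, -areas[candidates]))]
    if k <= order.size:
        return list(order[:k])
    rng = np.random.default_rng(seed)
    extra = rng.choice(order, size=k - order.size, replace=True)
    return list(order) + list(extra)


def patient_roi_box(patient) -> BoundingBox:
    """One box per patient: union of per-slice tight boxes.

    Applied identically to both modalities so the two classifier streams
    stay spatially aligned.
    """
    box = None
    for m in patient.masks:
        if not np.any(m):
            continue
        b = tight_bbox(m)
        box = b if box is None else box.union(b)
    if box is None:
        raise EmptyROIError(f"patient {patient.patient_id} has no tumor slices")
    return box


def otsu_roi_box(image: np.ndarray) -> BoundingBox:
    """Fallback ROI heuristic: largest connected component above Otsu."""
    thr = threshold_otsu(image)
    fg = image > thr
    lab = cc_label(fg)
    if lab.max() == 0:
        raise EmptyROIError("no foreground after Otsu thresholding")
    sizes = np.bincount(lab.ravel())[1:]
    fg = lab == (1 + int(np.argmax(sizes)))
    return tight_bbox(fg)


def partition_patients(patients, fractions=(0.6, 0.2, 0.2), seed: int = 0,
                       stratify: bool = True, label_attr: str = "label_1p19q") -> dict:
    """Patient-separated, class-stratified train/val/test assignment.

    Val and test get floor(f * n) patients each (globally); remainders go
    to train. Returns {patient_id: 'train'|'val'|'test'}.
    """
    if len(patients) < 5:
        raise ValueError("need at least 5 patients to partition")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(patients)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    rng = np.random.default_rng(seed)

    by_class = {}
    for p in patients:
        by_class.setdefault(getattr(p, label_attr), []).append(p)
    if stratify and any(len(v) < 3 for v in by_class.values()):
        warnings.warn("a class has < 3 patients; falling back to "
                      "unstratified partitioning", stacklevel=2)
        stratify = False
    if not stratify:
        by_class = {None: list(patients)}

    def _allocate(total, counts):
        # per-class quotas by largest remainder, summing exactly to total
        exact = {c: total * counts[c] / n for c in counts}
        quota = {c: int(np.floor(exact[c])) for c in counts}
        rem = total - sum(quota.values())
        for c in sorted(counts, key=lambda c: -(exact[c] - quota[c]))[:rem]:
            quota[c] += 1
        return quota

    counts = {c: len(v) for c, v in by_class.items()}
    val_q = _allocate(n_val, counts)
    test_q = _allocate(n_test, counts)
    assignment = {}
    for c, plist in sorted(by_class.items(), key=lambda kv: str(kv[0])):
        ids = sorted(p.patient_id for p in plist)
        rng.shuffle(ids)
        nv, nt = val_q[c], test_q[c]
        for pid in ids[:nv]:
            assignment[pid] = "val"
        for pid in ids[nv:nv + nt]:
            assignment[pid] = "test"
        for pid in ids[nv + nt:]:
            assignment[pid] = "train"
    return assignment


# ---------------------------------------------------------------------------
# dataset assembly for the classifier
# ---------------------------------------------------------------------------

@dataclass
class SliceDataset:
    """Paired-modality tumor crops with labels and provenance."""

    x_t1ce: np.ndarray   # (N, s, s) float32 in [0, 1]
    x_flair: np.ndarray  # (N, s, s)
    y: np.ndarray        # (N,) int class ids
    patient_ids: np.ndarray
    domains: np.ndarray

    def __len__(self):
        return self.y.shape[0]

    def subset(self, idx) -> "SliceDataset":
        return SliceDataset(self.x_t1ce[idx], self.x_flair[idx], self.y[idx],
                            self.patient_ids[idx], self.domains[idx])


def extract_patient_crops(patient, k: int, out_size: int = 64,
                          minority_multiplier: int = 1,
                          minority_class: int | None = None,
                          seed: int = 0):
    """Select slices and crop both modalities to the patient ROI box.

    ``minority_multiplier`` multiplies k for patients of
    ``minority_class`` (the imbalanced-cohort oversampling strategy:
    e.g. base 10 slices, multiplier 3 -> 30 slices for the minority).
    Returns (t1ce_crops, flair_crops) arrays of shape (k', s, s).
    """
    k_eff = k
    if minority_class is not None and patient.class_index == minority_class:
        k_eff = k * minority_multiplier
    idx = select_tumor_slices(patient, k_eff, seed=seed)
    box = patient_roi_box(patient)
    t1, fl = [], []
    for si in idx:
        t1.append(crop_to_roi(patient.slices["T1ce"][si].pixels, box, out_size))
        fl.append(crop_to_roi(patient.slices["FLAIR"][si].pixels, box, out_size))
    return np.stack(t1), np.stack(fl)


def build_slice_dataset(patients, k: int = 10, out_size: int = 64,
                        minority_multiplier: int = 1,
                        minority_class: int | None = None,
                        seed: int = 0) -> SliceDataset:
    """Assemble a paired-modality crop dataset over a patient list."""
    xs_t, xs_f, ys, pids, doms = [], [], [], [], []
    for p in patients:
        t1, fl = extract_patient_crops(
            p, k, out_size, minority_multiplier, minority_class, seed=seed)
        xs_t.append(t1)
        xs_f.append(fl)
        ys.extend([p.class_index] * len(t1))
        pids.extend([p.patient_id] * len(t1))
        doms.extend([p.domain] * len(t1))
    return SliceDataset(np.concatenate(xs_t).astype(np.float32),
                        np.concatenate(xs_f).astype(np.float32),
                        np.array(ys, dtype=np.int64),
                        np.array(pids), np.array(doms))
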