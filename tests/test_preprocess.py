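"""Normalization, bounding boxes, slice selection, patient splits."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliomap import phantom as ph
from gliomap import preprocess as pp


# ---------------------------------------------------------------------------
# normalize_and_resize
# ---------------------------------------------------------------------------

def test_normalize_rescales_to_unit_range():
    rng = np.random.default_rng(0)
    img = rng.uniform(10, 20, (256, 256))
    out = pp.normalize_and_resize(img, 128)
    assert out.shape == (128, 128)
    assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)


def test_constant_image_maps_to_zeros():
    out = pp.normalize_and_resize(np.full((64, 64), 3.0), 32)
    assert np.all(out == 0.0)


def test_checkerboard_downsamples_to_half_intensity():
    """Bilinear 4->2 resampling of a {0,1} checkerboard lands every
    output sample midway between a 0 and a 1 pixel."""
    cb = np.indices((4, 4)).sum(axis=0) % 2
    out = pp._sk_resize(cb.astype(float), (2, 2), order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    assert np.allclose(out, 0.5)


def test_normalize_is_idempotent(rng):
    img = rng.uniform(0, 5, (80, 80))
    once = pp.normalize_and_resize(img, 64)
    twice = pp.normalize_and_resize(once, 64)
    assert np.allclose(once, twice, atol=1e-6)


def test_empty_image_raises():
    with pytest.raises(ValueError):
        pp.normalize_and_resize(np.zeros((0, 0)), 32)


# ---------------------------------------------------------------------------
# tight_bbox / crop_to_roi
# ---------------------------------------------------------------------------

def test_tight_bbox_examples():
    mask = np.zeros((128, 128), bool)
    mask[10:21, 30:41] = True
    assert pp.tight_bbox(mask) == pp.BoundingBox(10, 30, 21, 41)
    single = np.zeros((16, 16), bool)
    single[5, 7] = True
    assert pp.tight_bbox(single) == pp.BoundingBox(5, 7, 6, 8)
    assert pp.tight_bbox(np.ones((128, 128), bool)) == pp.BoundingBox(0, 0, 128, 128)


def test_tight_bbox_empty_mask_raises():
    with pytest.raises(pp.EmptyROIError):
        pp.tight_bbox(np.zeros((8, 8), bool))


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_tight_bbox_matches_bruteforce_scan(seed):
    """The box equals the min/max over all foreground coordinates."""
    rng = np.random.default_rng(seed)
    mask = rng.random((20, 20)) < 0.1
    if not mask.any():
        mask[rng.integers(20), rng.integers(20)] = True
    rows, cols = np.nonzero(mask)
    box = pp.tight_bbox(mask)
    assert (box.row0, box.col0, box.row1, box.col1) == \
        (rows.min(), cols.min(), rows.max() + 1, cols.max() + 1)


def test_crop_exact_size_is_pixel_identical(rng):
    img = rng.random((128, 128)).astype(np.float32)
    box = pp.BoundingBox(10, 20, 74, 84)
    out = pp.crop_to_roi(img, box, 64)
    assert np.array_equal(out, img[10:74, 20:84])


def test_crop_resizes_small_box_to_out_size(rng):
    img = rng.random((128, 128)).astype(np.float32)
    out = pp.crop_to_roi(img, pp.BoundingBox(0, 0, 32, 32), 64)
    assert out.shape == (64, 64)
    assert out.min() >= img.min() - 1e-6 and out.max() <= img.max() + 1e-6


def test_crop_upsampling_matches_bilinear_oracle():
    """2x2 -> 4x4 bilinear upsampling against closed-form interpolation."""
    img = np.array([[0.0, 1.0], [1.0, 0.0]], dtype=np.float32)
    out = pp.crop_to_roi(np.pad(img, ((0, 0), (0, 0))), pp.BoundingBox(0, 0, 2, 2), 4)
    # output sample centers map to input coords (i + 0.5)/2 - 0.5
    coords = (np.arange(4) + 0.5) / 2 - 0.5
    expect = np.empty((4, 4))
    for i, y in enumerate(np.clip(coords, 0, 1)):
        for j, x in enumerate(np.clip(coords, 0, 1)):
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, 1), min(x0 + 1, 1)
            fy, fx = y - y0, x - x0
            expect[i, j] = (img[y0, x0] * (1 - fy) * (1 - fx)
                            + img[y1, x0] * fy * (1 - fx)
                            + img[y0, x1] * (1 - fy) * fx
                            + img[y1, x1] * fy * fx)
    assert np.allclose(out, expect, atol=1e-5)


def test_crop_outside_image_raises(rng):
    img = rng.random((32, 32))
    with pytest.raises(ValueError):
        pp.crop_to_roi(img, pp.BoundingBox(0, 0, 40, 40), 16)


# ---------------------------------------------------------------------------
# slice selection
# ---------------------------------------------------------------------------

class _FakePatient:
    def __init__(self, areas, cls=0):
        self.patient_id = "fake"
        self.masks = [np.ones((a, 1), bool) if a else np.zeros((1, 1), bool)
                      for a in areas]
        self.class_index = cls


def test_select_slices_by_largest_area():
    assert pp.select_tumor_slices(_FakePatient([0, 5, 3, 9]), 2) == [3, 1]
    assert pp.select_tumor_slices(_FakePatient([0, 5, 3, 9]), 3) == [3, 1, 2]


def test_select_with_replacement_when_short():
    got = pp.select_tumor_slices(_FakePatient([4, 2]), 5, seed=3)
    assert got[:2] == [0, 1]
    assert len(got) == 5 and set(got) <= {0, 1}
    assert got == pp.select_tumor_slices(_FakePatient([4, 2]), 5, seed=3)


def test_no_tumor_slices_raises():
    with pytest.raises(pp.EmptyROIError):
        pp.select_tumor_slices(_FakePatient([0, 0]), 2)


def test_minority_multiplier_triples_extraction(tiny_cohort):
    _, patients = tiny_cohort
    wt = next(p for p in patients if p.class_index == 1)
    t1, fl = pp.extract_patient_crops(wt, k=3, out_size=16,
                                      minority_multiplier=3, minority_class=1)
    assert len(t1) == len(fl) == 9
    co = next(p for p in patients if p.class_index == 0)
    t1, _ = pp.extract_patient_crops(co, k=3, out_size=16,
                                     minority_multiplier=3, minority_class=1)
    assert len(t1) == 3


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

class _P:
    def __init__(self, pid, lab):
        self.patient_id = pid
        self.label_1p19q = lab


def _mkpatients(n0, n1):
    return [_P(f"p{i:03d}", "codeleted" if i < n0 else "non-codeleted")
            for i in range(n0 + n1)]


@pytest.mark.parametrize("n0,n1,sizes", [
    (5, 5, (6, 2, 2)),
    (77, 84, (97, 32, 32)),
])
def test_partition_sizes(n0, n1, sizes):
    pats = _mkpatients(n0, n1)
    assign = pp.partition_patients(pats, seed=4)
    counts = {s: sum(v == s for v in assign.values()) for s in ("train", "val", "test")}
    assert (counts["train"], counts["val"], counts["test"]) == sizes
    assert set(assign) == {p.patient_id for p in pats}


def test_partition_is_stratified_and_seed_sensitive():
    pats = _mkpatients(20, 20)
    a1 = pp.partition_patients(pats, seed=0)
    a2 = pp.partition_patients(pats, seed=1)
    assert a1 != a2
    for assign in (a1, a2):
        for lab in ("codeleted", "non-codeleted"):
            ids = [p.patient_id for p in pats if p.label_1p19q == lab]
            assert sum(assign[i] == "test" for i in ids) == 4
            assert sum(assign[i] == "val" for i in ids) == 4


def test_partition_small_class_falls_back_unstratified():
    pats = _mkpatients(8, 2)
    with pytest.warns(UserWarning):
        assign = pp.partition_patients(pats, seed=0)
    counts = {s: sum(v == s for v in assign.values()) for s in ("train", "val", "test")}
    assert counts == {"train": 6, "val": 2, "test": 2}


def test_partition_requires_five_patients():
    with pytest.raises(ValueError):
        pp.partition_patients(_mkpatients(2, 2), seed=0)


def test_patient_box_is_union_and_streams_aligned(tiny_cohort):
    _, patients = tiny_cohort
    p = patients[0]
    box = pp.patient_roi_box(p)
    for mask in p.masks:
        b = pp.tight_bbox(mask)
        assert box.row0 <= b.row0 and box.row1 >= b.row1
        assert box.col0 <= b.col0 and box.col1 >= b.col1


def test_otsu_roi_finds_bright_blob():
    img = np.zeros((64, 64), dtype=float)
    img[20:30, 35:50] = 1.0
    box = pp.otsu_roi_box(img)
    assert (box.row0, box.col0, box.row1, box.col1) == (20, 35, 30, 50)
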