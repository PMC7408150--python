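"""CycleGAN losses, schedule, architecture contracts, combination."""

import numpy as np
import pytest

from gliomap import domain_mapping as dm
from gliomap._nn import Sequential


class _Stub:
    """Generator stub applying a fixed elementwise function."""

    def __init__(self, fn):
        self.fn = fn

    def forward(self, x, train=True):
        return self.fn(np.asarray(x, dtype=np.float32))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_lsgan_discriminator_values():
    assert dm.lsgan_loss([1.0, 1.0], [0.0, 0.0]) == pytest.approx(0.0)
    assert dm.lsgan_loss([0.0], [1.0]) == pytest.approx(2.0)
    assert dm.lsgan_loss([0.5, 1.0], [0.5]) == pytest.approx(0.375)


def test_lsgan_generator_form():
    assert dm.lsgan_loss([1.0, 1.0], which="generator") == pytest.approx(0.0)
    assert dm.lsgan_loss([0.5], which="generator") == pytest.approx(0.25)


def test_lsgan_rejects_nonfinite():
    with pytest.raises(ValueError):
        dm.lsgan_loss([np.nan], [0.5])


def test_cycle_loss_identity_generators_is_zero(rng):
    a = rng.random((2, 4, 4)).astype(np.float32)
    b = rng.random((2, 4, 4)).astype(np.float32)
    ident = _Stub(lambda x: x)
    assert dm.cycle_loss(a, b, ident, ident) == pytest.approx(0.0)


def test_cycle_loss_offset_oracle():
    """One-direction constant offset of 0.1 contributes mean |0.1|."""
    a = np.zeros((1, 2, 2), dtype=np.float32)
    b = np.zeros((1, 2, 2), dtype=np.float32)
    g_b = _Stub(lambda x: x + 0.1)   # A -> B adds 0.1
    g_a = _Stub(lambda x: x)         # B -> A identity
    # G_A(G_B(a)) - a = 0.1 everywhere; G_B(G_A(b)) - b = 0.1 everywhere
    assert dm.cycle_loss(a, b, g_a, g_b) == pytest.approx(0.2)
    zero = _Stub(lambda x: np.zeros_like(x))
    assert dm.cycle_loss(a, b, zero, zero) == pytest.approx(0.0)


def test_total_objective_arithmetic():
    assert dm.total_objective(0.4, 0.6, 123.0, lambda_cyc=0.0) == pytest.approx(1.0)
    assert dm.total_objective(0.0, 0.0, 0.0) == pytest.approx(0.0)
    assert dm.total_objective(0.5, 0.3, 0.2, lambda_cyc=10.0) == pytest.approx(2.8)
    with pytest.raises(ValueError):
        dm.total_objective(0.1, 0.1, 0.1, lambda_cyc=-1.0)


def test_lr_schedule_linear_decay():
    spec = dm.CycleGANSpec(epochs=150, lr_decay_start=100, lr=2.0e-4)
    assert dm.lr_schedule(50, spec) == pytest.approx(2.0e-4)
    assert dm.lr_schedule(100, spec) == pytest.approx(2.0e-4)
    assert dm.lr_schedule(125, spec) == pytest.approx(1.0e-4)
    assert dm.lr_schedule(150, spec) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# architecture contracts
# ---------------------------------------------------------------------------

def test_tiny_generator_preserves_spatial_size(rng):
    spec = dm.CycleGANSpec.tiny(image_size=32)
    g = dm.build_generator(spec, np.random.default_rng(0))
    x = rng.normal(size=(2, 3, 32, 32)).astype(np.float32)
    y = g.forward(x, train=False)
    assert y.shape == x.shape
    assert y.min() >= -1.0 and y.max() <= 1.0  # Tanh output


def test_discriminator_patch_scores_in_unit_interval(rng):
    spec = dm.CycleGANSpec.tiny(image_size=32)
    d = dm.build_discriminator(spec, np.random.default_rng(0))
    s = d.forward(rng.normal(size=(2, 3, 32, 32)).astype(np.float32), train=False)
    assert s.ndim == 4 and s.shape[1] == 1
    assert np.all(s > 0.0) and np.all(s < 1.0)


def test_incompatible_image_size_raises():
    spec = dm.CycleGANSpec(image_size=30, gen_enc_filters=(8, 16, 32))
    with pytest.raises(ValueError):
        spec.validate()


# ---------------------------------------------------------------------------
# training / mapping plumbing
# ---------------------------------------------------------------------------

def test_one_epoch_smoke_run_records_finite_history(rng):
    a = rng.random((4, 16, 16)).astype(np.float32)
    b = rng.random((4, 16, 16)).astype(np.float32)
    spec = dm.CycleGANSpec.tiny(image_size=16, epochs=1)
    spec.batch_size = 2
    state = dm.train_cyclegan(a, b, spec)
    assert len(state.history) == 1
    for k, v in state.history[0].items():
        assert np.isfinite(v), k
        if k.startswith("loss"):
            assert v >= 0.0
    mapped = dm.map_domain(state, a)
    assert mapped.shape == a.shape
    assert mapped.min() >= 0.0 and mapped.max() <= 1.0


def test_map_domain_requires_trained_state():
    spec = dm.CycleGANSpec.tiny(image_size=16)
    rng0 = np.random.default_rng(0)
    state = dm.CycleGANState(spec=spec, G_A=Sequential([]), G_B=Sequential([]),
                             D_A=Sequential([]), D_B=Sequential([]))
    with pytest.raises(RuntimeError):
        dm.map_domain(state, np.zeros((1, 16, 16), np.float32))


class _Pat:
    def __init__(self, pid):
        self.patient_id = pid


def test_combine_domains_adds_cohorts_and_rejects_duplicates():
    a = [_Pat(f"fr{i}") for i in range(82)]
    b = [_Pat(f"us{i}") for i in range(79)]
    assert len(dm.combine_domains(a, b)) == 161
    assert dm.combine_domains([], b) == b
    with pytest.raises(ValueError):
        dm.combine_domains(a, a[:1] + b)
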