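"""Shape contracts, conditioning semantics and parameter counting of the
encoder–decoder pair."""

import numpy as np
import pytest

import statcell as sc
from statcell.architecture import (
    DownResidualBlock,
    UpResidualBlock,
    one_hot,
    full_scale_spec,
)
from statcell.nn.layers import Linear


def test_down_block_halves_and_up_block_doubles(rng):
    down = DownResidualBlock(np.random.default_rng(0), 2, 4).build(2)
    x = rng.standard_normal((3, 2, 64, 48)).astype(np.float32)
    assert down.forward(x).shape == (3, 4, 32, 24)
    up = UpResidualBlock(np.random.default_rng(0), 4, 2).build(2)
    h = rng.standard_normal((3, 4, 4, 3)).astype(np.float32)
    assert up.forward(h).shape == (3, 2, 8, 6)


def test_down_block_rejects_odd_spatial_input(rng):
    down = DownResidualBlock(np.random.default_rng(0), 2, 4).build(2)
    with pytest.raises(ValueError, match="odd"):
        down.forward(rng.standard_normal((1, 2, 7, 8)).astype(np.float32))


def test_conditional_pathway_is_additive_zero_ablation(rng):
    """Zeroing the conditional projections reduces the block to the
    unconditional computation."""
    r1, r2 = np.random.default_rng(7), np.random.default_rng(7)
    plain = DownResidualBlock(r1, 2, 4).build(2)
    cond = DownResidualBlock(r2, 2, 4, conditional=True, n_ref=2, n_classes=3).build(2)
    # same init stream for the shared layers; zero the conditional branch
    for name in ("conv4", "conv3", "bypass_conv"):
        getattr(cond, name).w.value[...] = getattr(plain, name).w.value
    for proj in (cond.cond.proj_ref, cond.cond.proj_label):
        proj.w.value[...] = 0.0
        proj.b.value[...] = 0.0
    x = rng.standard_normal((2, 2, 16, 16)).astype(np.float32)
    ref = rng.standard_normal((2, 2, 16, 16)).astype(np.float32)
    lbl = one_hot(np.array([0, 2]), 3)
    np.testing.assert_allclose(
        cond.forward(x, ref, lbl), plain.forward(x), rtol=1e-5, atol=1e-6
    )


def test_encode_decode_round_trip_shape(tiny_model, rng):
    x = rng.random((4, 2, 32, 32)).astype(np.float32)
    lat = tiny_model.encode(x)
    assert lat.mu.shape == (4, 6) and np.all(lat.sigma > 0)
    out = tiny_model.decode(lat.mu)
    assert out.shape == (4, 2, 32, 32)


def test_encoder_is_deterministic(tiny_model, rng):
    x = rng.random((2, 2, 32, 32)).astype(np.float32)
    a = tiny_model.encode(x)
    b = tiny_model.encode(x)
    np.testing.assert_array_equal(a.mu, b.mu)
    np.testing.assert_array_equal(a.sigma, b.sigma)
    # identical rows embed identically
    xx = np.repeat(x[:1], 2, axis=0)
    lat = tiny_model.encode(xx)
    np.testing.assert_array_equal(lat.mu[0], lat.mu[1])


def test_sigma_strictly_positive_across_random_inputs(tiny_model, rng):
    for _ in range(25):
        x = (rng.random((2, 2, 32, 32)) * 2 - 0.5).astype(np.float32)
        assert np.all(tiny_model.encode(x).sigma > 0)


def test_conditional_model_requires_reference_and_label(rng):
    spec = sc.NetworkSpec(
        dimensionality=2, input_shape=(32, 32), input_channels=1,
        channels=(3, 4), latent_dim=5, n_classes=3, conditional=True, seed=0,
    )
    mt = sc.build_target_model(spec)
    x = rng.random((1, 1, 32, 32)).astype(np.float32)
    with pytest.raises(TypeError, match="label"):
        mt.encode(x)
    ref = rng.random((1, 2, 32, 32)).astype(np.float32)
    lbl = one_hot(np.array([1]), 3)
    assert mt.encode(x, ref, lbl).mu.shape == (1, 5)


def test_input_shape_divisibility_is_enforced():
    with pytest.raises(ValueError, match="divisible"):
        sc.NetworkSpec(
            dimensionality=2, input_shape=(30, 32), channels=(3, 4), latent_dim=5
        )


def test_sampling_reproducible_and_diverse(tiny_model):
    a = tiny_model.sample(3, seed=5)
    b = tiny_model.sample(3, seed=5)
    np.testing.assert_array_equal(a, b)
    c = tiny_model.sample(3, seed=6)
    assert np.abs(a - c).max() > 0
    assert tiny_model.sample(0, seed=1).shape[0] == 0
    with pytest.raises(ValueError):
        tiny_model.sample(-1, seed=1)


def test_decode_rejects_wrong_latent_length(tiny_model):
    with pytest.raises(ValueError, match="latent"):
        tiny_model.decode(np.zeros((1, 7), dtype=np.float32))


def test_count_parameters_single_linear_layer():
    """A 512->512 fully connected layer with bias holds 512*512+512 weights."""
    lin = Linear(np.random.default_rng(0), 512, 512)
    assert sum(p.size for p in lin.params()) == 262_656


def test_tiny_spec_builds_and_runs_quickly(rng):
    import time

    spec = sc.NetworkSpec(
        dimensionality=2, input_shape=(32, 32), input_channels=2,
        channels=(4, 8), latent_dim=8, seed=2,
    )
    t0 = time.time()
    m = sc.build_reference_model(spec)
    x = rng.random((1, 2, 32, 32)).astype(np.float32)
    m.decode(m.encode(x).mu)
    assert time.time() - t0 < 1.0


def test_final_stride1_reading_builds_and_preserves_shape(rng):
    spec = sc.NetworkSpec(
        dimensionality=2, input_shape=(32, 32), input_channels=2,
        channels=(3, 4), latent_dim=5, final_stride1=True, seed=0,
    )
    m = sc.build_reference_model(spec)
    out = m.decode(np.zeros((1, 5), dtype=np.float32))
    # one fewer upsampling stage: output spatial is half the input
    assert out.shape == (1, 2, 16, 16)


def test_structure_label_bijection():
    lab = sc.StructureLabel(13)
    assert lab.name == "Nuclear envelope"
    assert sc.StructureLabel.from_name("Nuclear envelope").index == 13
    assert len(sc.STRUCTURE_CLASSES) == 24
    with pytest.raises(ValueError):
        sc.StructureLabel(24)


def test_full_scale_parameter_counts_exact():
    """Full-scale builds reproduce the published totals exactly:
    122,627,829 trainable parameters for the 3D reference+target pair and
    22,279,054 for the 2D reference model."""
    mr2 = sc.build_reference_model(full_scale_spec(2, False))
    assert sc.count_parameters(mr2) == 22_279_054
    del mr2
    mt2 = sc.build_target_model(full_scale_spec(2, True))
    c2t = sc.count_parameters(mt2)
    del mt2
    mr3 = sc.build_reference_model(full_scale_spec(3, False))
    c3r = sc.count_parameters(mr3)
    del mr3
    mt3 = sc.build_target_model(full_scale_spec(3, True))
    assert c3r + sc.count_parameters(mt3) == 122_627_829
    assert c2t > 0
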