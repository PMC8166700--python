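"""Architecture algebra and built-network structure."""

import itertools

import numpy as np
import pytest

import fundusnet.nn as nn
from fundusnet.model_family import (
    DEFAULT_SPEC,
    ArchitectureSpec,
    UnsupportedCountingError,
    build_network,
    build_variant_block,
    kernel_weight_count,
    predict_image,
)


@pytest.mark.parametrize("changes,expected", [
    ({}, 108_976),
    ({"activation": "linear"}, 108_976),
    ({"block_variant": "dilated_bottleneck"}, 108_976),
    ({"block_variant": "side_output"}, 109_072),
    ({"skip_connections": False}, 97_456),
    ({"convs_per_block": 1}, 49_072),
    ({"init_filters": 8}, 27_352),
    ({"init_filters": 4}, 6_892),
    ({"init_filters": 2}, 1_750),
    ({"init_filters": 1}, 451),
    ({"levels": 2}, 23_984),
])
def test_published_kernel_counts(changes, expected):
    """The counting algebra reproduces every published family count."""
    spec = DEFAULT_SPEC.with_(**changes)
    assert kernel_weight_count(spec) == expected
    assert build_network(spec, seed=0).kernel_weight_count == expected


def test_single_block_chain_count():
    """L=1, F0=1, C=1: one 3x3 conv (9) plus the 2-channel head (18)."""
    spec = ArchitectureSpec(levels=1, init_filters=1, convs_per_block=1)
    assert kernel_weight_count(spec) == 27
    assert kernel_weight_count(spec.with_(skip_connections=False)) == 27


def test_side_output_extra_weights():
    """Side taps add out_classes * f_l per decoder level: 2*32 + 2*16 = 96."""
    base = kernel_weight_count(DEFAULT_SPEC)
    side = kernel_weight_count(DEFAULT_SPEC.with_(block_variant="side_output"))
    assert side - base == 2 * 32 + 2 * 16 == 96


def test_skip_removal_delta():
    """Dropping concatenation halves the first decoder conv's input:
    delta = 9 * (f2^2 + f1^2)."""
    with_skip = kernel_weight_count(DEFAULT_SPEC)
    without = kernel_weight_count(DEFAULT_SPEC.with_(skip_connections=False))
    assert with_skip - without == 9 * (32 ** 2 + 16 ** 2)


def test_count_lattice_matches_built_networks():
    """Closed form == brute-force enumeration of built kernels across the
    full spec lattice."""
    for L, F0, C, s in itertools.product((1, 2, 3), (1, 2, 4, 8, 16),
                                         (1, 2), (False, True)):
        spec = ArchitectureSpec(levels=L, init_filters=F0, convs_per_block=C,
                                skip_connections=s)
        model = build_network(spec, seed=0)
        assert model.net.introspected_kernel_count() == kernel_weight_count(spec), spec


def test_quadratic_law_in_initial_filters():
    """count = A*F0^2 + B*F0 exactly; fitting at F0 in {1,2} for the default
    family gives A=424, B=27 and predicts the published larger counts."""
    c1 = kernel_weight_count(DEFAULT_SPEC.with_(init_filters=1))
    c2 = kernel_weight_count(DEFAULT_SPEC.with_(init_filters=2))
    # solve A + B = c1, 4A + 2B = c2
    A = (c2 - 2 * c1) // 2
    B = c1 - A
    assert (A, B) == (424, 27)
    for f0, expected in ((4, 6_892), (8, 27_352), (16, 108_976)):
        assert A * f0 ** 2 + B * f0 == expected
        assert kernel_weight_count(DEFAULT_SPEC.with_(init_filters=f0)) == expected


def test_count_monotonicity():
    base = kernel_weight_count(DEFAULT_SPEC)
    assert kernel_weight_count(DEFAULT_SPEC.with_(init_filters=17 * 2)) > base
    for f0 in (1, 2, 4, 8):
        assert kernel_weight_count(DEFAULT_SPEC.with_(init_filters=f0)) < \
            kernel_weight_count(DEFAULT_SPEC.with_(init_filters=f0 + 1))
    assert kernel_weight_count(DEFAULT_SPEC.with_(levels=2)) < base < \
        kernel_weight_count(DEFAULT_SPEC.with_(levels=4))
    assert kernel_weight_count(DEFAULT_SPEC.with_(convs_per_block=3)) > base
    assert kernel_weight_count(DEFAULT_SPEC.with_(skip_connections=False)) < base


def test_count_validation_errors():
    with pytest.raises(ValueError):
        ArchitectureSpec(levels=0)
    with pytest.raises(ValueError):
        ArchitectureSpec(init_filters=0)
    with pytest.raises(ValueError):
        ArchitectureSpec(convs_per_block=0)
    for variant in ("residual", "dense_encoder"):
        with pytest.raises(UnsupportedCountingError):
            kernel_weight_count(DEFAULT_SPEC.with_(block_variant=variant))


def test_forward_softmax_contract():
    """Two output channels, values in [0,1], summing to one per pixel."""
    spec = DEFAULT_SPEC.with_(init_filters=2)
    model = build_network(spec, seed=0)
    x = np.zeros((1, 1, 64, 64), dtype=np.float32)
    out = model.net.forward(x, train=False)
    assert out.shape == (1, 2, 64, 64)
    assert out.min() >= 0 and out.max() <= 1
    np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)


def test_seeded_build_reproducibility():
    a = build_network(DEFAULT_SPEC.with_(init_filters=2), seed=42)
    b = build_network(DEFAULT_SPEC.with_(init_filters=2), seed=42)
    c = build_network(DEFAULT_SPEC.with_(init_filters=2), seed=43)
    for pa, pb in zip(a.net.parameters(), b.net.parameters()):
        np.testing.assert_array_equal(pa.value, pb.value)
    assert any(not np.array_equal(pa.value, pc.value)
               for pa, pc in zip(a.net.parameters(), c.net.parameters()))


def test_forward_rejects_indivisible_shapes():
    model = build_network(DEFAULT_SPEC.with_(init_filters=1), seed=0)
    with pytest.raises(ValueError, match="divisible"):
        model.net.forward(np.zeros((1, 1, 63, 64), dtype=np.float32))
    with pytest.raises(ValueError, match="channels"):
        model.net.forward(np.zeros((1, 2, 64, 64), dtype=np.float32))


def test_predict_image_pads_and_crops():
    """A 565x584 input at L=3 is padded to a pooling-divisible grid and the
    output is cropped back to the input shape."""
    model = build_network(DEFAULT_SPEC.with_(init_filters=1), seed=0)
    img = np.random.default_rng(0).uniform(-1, 1, (565, 584)).astype(np.float32)
    prob = predict_image(model, img)
    assert prob.shape == (565, 584)
    assert prob.min() >= 0 and prob.max() <= 1


def test_predict_image_level_one_any_shape():
    model = build_network(ArchitectureSpec(levels=1, init_filters=2), seed=0)
    prob = predict_image(model, np.zeros((37, 41), dtype=np.float32))
    assert prob.shape == (37, 41)


def test_predict_image_channel_mismatch():
    model = build_network(DEFAULT_SPEC.with_(init_filters=1), seed=0)
    with pytest.raises(ValueError, match="channels"):
        predict_image(model, np.zeros((3, 32, 32), dtype=np.float32))


def test_dilation_rate_one_equals_vanilla():
    """A dilated bottleneck with rate 1 is the vanilla network."""
    spec_v = DEFAULT_SPEC.with_(init_filters=2)
    spec_d = spec_v.with_(block_variant="dilated_bottleneck", dilation_rate=1)
    x = np.random.default_rng(3).standard_normal((1, 1, 32, 32)).astype(np.float32)
    out_v = build_network(spec_v, seed=7).net.forward(x, train=False)
    out_d = build_network(spec_d, seed=7).net.forward(x, train=False)
    np.testing.assert_allclose(out_v, out_d, atol=1e-6)


def test_dilated_count_and_receptive_field():
    """Dilation adds no weights but widens the bottleneck's receptive field."""
    spec_d = DEFAULT_SPEC.with_(init_filters=2, block_variant="dilated_bottleneck",
                                dilation_rate=2)
    assert kernel_weight_count(spec_d) == kernel_weight_count(
        DEFAULT_SPEC.with_(init_filters=2))
    x = np.random.default_rng(3).standard_normal((1, 1, 32, 32)).astype(np.float32)
    out1 = build_network(spec_d.with_(dilation_rate=1), seed=7).net.forward(x, False)
    out2 = build_network(spec_d, seed=7).net.forward(x, False)
    assert not np.allclose(out1, out2)


def test_variant_block_placement_rules():
    with pytest.raises(ValueError, match="encoder-only"):
        build_variant_block("dense", 8, placement="decoder")
    with pytest.raises(ValueError, match="bottleneck"):
        build_variant_block("dilated", 8, placement="encoder")
    with pytest.raises(ValueError):
        build_variant_block("dilated", 8, dilation_rate=0)
    # legal placements build and run forward
    x = np.random.default_rng(0).standard_normal((1, 8, 16, 16)).astype(np.float32)
    for kind in ("residual", "dense", "dilated"):
        blk = build_variant_block(kind, 8, seed=1)
        assert blk.forward(x).shape == (1, 8, 16, 16)
    tap = build_variant_block("side_output", 8, input_shape=(32, 32), seed=1)
    assert tap.forward(x).shape == (1, 2, 32, 32)


def test_backprop_matches_finite_differences():
    """Analytic gradients agree with float64 central differences for every
    block variant (weights and input)."""
    old = nn.DTYPE
    nn.DTYPE = np.float64
    try:
        specs = [
            ArchitectureSpec(levels=2, init_filters=3),
            ArchitectureSpec(levels=2, init_filters=3, skip_connections=False),
            ArchitectureSpec(levels=1, init_filters=4),
            ArchitectureSpec(levels=2, init_filters=3, activation="linear"),
            ArchitectureSpec(levels=2, init_filters=3, batch_norm=False),
            ArchitectureSpec(levels=2, init_filters=3, block_variant="residual"),
            ArchitectureSpec(levels=2, init_filters=3, block_variant="dense_encoder"),
            ArchitectureSpec(levels=2, init_filters=3, block_variant="side_output"),
        ]
        for spec in specs:
            _gradcheck(spec)
    finally:
        nn.DTYPE = old


def _gradcheck(spec, eps=1e-6, tol=1e-5):
    rng = np.random.default_rng(0)
    model = build_network(spec, seed=3)
    x = rng.standard_normal((2, 1, 8, 8))
    t = rng.standard_normal((2, spec.out_classes, 8, 8))

    def loss(xv):
        out = model.net.forward(xv, train=True)
        if isinstance(out, tuple):
            p, sides = out
            return float((p * t).sum() + 0.1 * sum((s ** 2).sum() for s in sides))
        return float((out * t).sum())

    out = model.net.forward(x, train=True)
    model.net.zero_grad()
    if isinstance(out, tuple):
        gx = model.net.backward(t, [0.2 * s for s in out[1]])
    else:
        gx = model.net.backward(t)
    rs = np.random.default_rng(1)
    params = model.net.parameters()
    for p in params[::max(1, len(params) // 6)]:
        flat = p.value.reshape(-1)
        for _ in range(2):
            i = rs.integers(flat.size)
            old = flat[i]
            flat[i] = old + eps
            lp = loss(x)
            flat[i] = old - eps
            lm = loss(x)
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = p.grad.reshape(-1)[i]
            assert abs(num - ana) <= tol * max(1.0, abs(num)), (spec, p.name)
    flat = x.reshape(-1)
    for _ in range(3):
        i = rs.integers(flat.size)
        old = flat[i]
        flat[i] = old + eps
        lp = loss(x)
        flat[i] = old - eps
        lm = loss(x)
        flat[i] = old
        num = (lp - lm) / (2 * eps)
        assert abs(num - gx.reshape(-1)[i]) <= tol * max(1.0, abs(num)), spec
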