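"""Architecture contracts of the four denoising networks."""

import numpy as np
import pytest

from renodenoise.models import (AttnUNet, CBAM, DnCNN, DUDnCNN, NetworkConfig,
                                PixelDiscriminator, UDnCNN, build_discriminator,
                                build_model, conv_output_size, denoise,
                                dilation_for_layer, dilation_schedule,
                                load_checkpoint, save_checkpoint)
from renodenoise.nn.autograd import Tensor


def _image(*shape, seed=0):
    return Tensor(np.random.default_rng(seed).random(shape).astype(np.float32))


# ---------------------------------------------------------------- DnCNN ----

def test_dncnn_has_exactly_eight_conv_layers():
    model = build_model(NetworkConfig(family="dncnn"))
    assert model.n_conv_layers == 8


@pytest.mark.parametrize("height,width", [(8, 8), (17, 23), (128, 128)])
def test_dncnn_preserves_spatial_size(height, width):
    model = build_model(NetworkConfig(family="dncnn"))
    model.eval()
    out = model(_image(1, height, width, 1))
    assert out.shape == (1, height, width, 1)


def test_dncnn_parameter_count_matches_closed_form():
    config = NetworkConfig(family="dncnn", depth=8, filters=64, kernel=3)
    model = build_model(config)
    f, k = 64, 3
    convs = (1 * f * k * k + f) + 6 * (f * f * k * k + f) + (f * 1 * k * k + 1)
    bns = 6 * 2 * f
    assert model.n_parameters() == convs + bns


# ------------------------------------------------------- UDnCNN/DUDnCNN ----

def test_three_backbones_share_parameter_count():
    counts = {family: build_model(NetworkConfig(family=family)).n_parameters()
              for family in ("dncnn", "udncnn", "dudncnn")}
    assert len(set(counts.values())) == 1


def test_udncnn_restores_resolution():
    model = build_model(NetworkConfig(family="udncnn"))
    model.eval()
    assert model(_image(1, 128, 128, 1)).shape == (1, 128, 128, 1)


def test_udncnn_rejects_indivisible_input():
    model = build_model(NetworkConfig(family="udncnn"))
    model.eval()
    with pytest.raises(ValueError, match="divisible"):
        model(_image(1, 30, 30, 1))


def test_skip_merge_of_identical_tensors_is_identity():
    x = _image(1, 8, 8, 4)
    merged = (x + x) / 2.0
    np.testing.assert_array_equal(merged.numpy(), x.numpy())


def test_builders_are_pure():
    config = NetworkConfig(family="udncnn", seed=3)
    a, b = build_model(config), build_model(config)
    for (name_a, pa), (name_b, pb) in zip(a.named_parameters(),
                                          b.named_parameters()):
        assert name_a == name_b
        np.testing.assert_array_equal(pa.data, pb.data)


# ------------------------------------------------------------- dilation ----

def test_dilation_formula():
    assert dilation_for_layer(0, 0) == 1
    assert dilation_for_layer(1, 0) == 2
    assert dilation_for_layer(2, 1) == 2
    assert dilation_for_layer(2, 2) == 1
    with pytest.raises(ValueError):
        dilation_for_layer(0, 1)


def test_dilation_schedule_is_symmetric():
    schedule = dilation_schedule(NetworkConfig(family="dudncnn"))
    assert schedule == (1, 1, 2, 4, 4, 2, 1, 1)
    assert schedule == schedule[::-1]


@pytest.mark.parametrize("dilation,footprint", [(2, 5), (3, 7)])
def test_dilated_kernel_footprint(dilation, footprint):
    """A 3x3 kernel at dilation d spans d*(3-1)+1 pixels per side: impulse
    response support verifies the 5x5 / 7x7 footprints."""
    from renodenoise.nn import Conv2d

    conv = Conv2d(1, 1, 3, padding=0, dilation=dilation, bias=False)
    conv.weight.data = np.ones_like(conv.weight.data)
    size = 4 * footprint + 1
    impulse = np.zeros((1, size, size, 1), dtype=np.float32)
    impulse[0, size // 2, size // 2, 0] = 1.0
    # cross-correlate a delta: support of the response = kernel footprint
    out = conv(Tensor(impulse)).numpy()[0, :, :, 0]
    rows = np.argwhere(out > 0)
    span = rows.max(axis=0) - rows.min(axis=0) + 1
    assert tuple(span) == (footprint, footprint)
    assert dilation * (3 - 1) + 1 == footprint


def test_dudncnn_keeps_spatial_size_at_every_layer():
    """Forward-shape trace oracle: with pad = dilation*(k-1)/2 every layer
    preserves the input side exactly."""
    config = NetworkConfig(family="dudncnn")
    for side, dil in zip([32] * 8, dilation_schedule(config)):
        pad = dil * (config.kernel - 1) // 2
        assert conv_output_size(side, config.kernel, 1, pad, dil) == side
    model = build_model(config)
    model.eval()
    assert model(_image(1, 32, 32, 1)).shape == (1, 32, 32, 1)


def test_dudncnn_receptive_field_matches_pooled_equivalent():
    """Receptive-field oracle: one 2x2 pooling step doubles the stride of
    everything behind it, so a post-pool 3x3 conv sees a 6x6 input patch;
    the dilation-2 replacement sees 5x5 on the un-pooled grid (the same
    centers, no resolution loss).  Checked by impulse-support arithmetic."""
    # conv(3x3) after one pooling: receptive field on the original grid
    pooled_rf = 2 * (3 - 1) + 2          # stride-2 spacing + 2x2 pool window
    dilated_rf = 2 * (3 - 1) + 1         # dilation-2 footprint
    assert dilated_rf == pooled_rf - 1   # identical tap spacing, no pool blur


# ----------------------------------------------------------------- CBAM ----

def test_cbam_gates_bounded_and_zero_preserving():
    cbam = CBAM(8, rng=np.random.default_rng(0))
    cbam.eval()
    x = _image(2, 8, 8, 8)
    out = cbam(x).numpy()
    assert np.all(np.abs(out) <= np.abs(x.numpy()) + 1e-6), \
        "multiplicative gates in (0,1) can only shrink activations"
    zeros = cbam(Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32))).numpy()
    np.testing.assert_array_equal(zeros, 0.0)


# -------------------------------------------------------------- AttnGAN ----

def test_generator_restores_shape():
    model = build_model(NetworkConfig(family="attngan"))
    model.eval()
    out = model(_image(2, 64, 64, 1))
    assert out.shape == (2, 64, 64, 1)


def test_generator_feature_depth_doubles_per_stage():
    model = build_model(NetworkConfig(family="attngan"))
    depths = [stage.conv.weight.shape[-1] for stage in model.downs]
    assert depths == [128, 256, 512, 1024]


def test_generator_rejects_indivisible_input():
    model = build_model(NetworkConfig(family="attngan"))
    model.eval()
    with pytest.raises(ValueError, match="divisible"):
        model(_image(1, 40, 40, 1))


def test_discriminator_patch_map_from_256_input():
    disc = build_discriminator(NetworkConfig(family="attngan"))
    disc.eval()
    out = disc(_image(1, 256, 256, 1)).numpy()
    assert out.shape == (1, 30, 30, 1)
    assert np.isfinite(out).all()


@pytest.mark.parametrize("side", [64, 128, 256])
def test_discriminator_shape_matches_stride_arithmetic(side):
    """Shape-arithmetic oracle: chained floor((s + 2p - k)/stride) + 1."""
    expected = side
    for stride in (2, 2, 2, 1, 1):
        expected = conv_output_size(expected, 4, stride, 1)
    disc = build_discriminator(NetworkConfig(family="attngan"))
    disc.eval()
    out = disc(_image(1, side, side, 1))
    assert out.shape[1] == out.shape[2] == expected
    assert PixelDiscriminator.score_map_size(side) == expected


def test_discriminator_rejects_tiny_input():
    disc = build_discriminator(NetworkConfig(family="attngan"))
    with pytest.raises(ValueError, match="too small"):
        disc(_image(1, 2, 2, 1))


# ------------------------------------------------------------- plumbing ----

def test_checkpoint_roundtrip(tmp_path):
    model = build_model(NetworkConfig(family="dudncnn", seed=5))
    model.eval()
    x = _image(1, 32, 32, 1)
    before = model(x).numpy().copy()
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    restored = load_checkpoint(path)
    restored.eval()
    np.testing.assert_array_equal(restored(x).numpy(), before)


def test_config_yaml_roundtrip():
    config = NetworkConfig(family="udncnn", depth=8, filters=32, seed=9)
    assert NetworkConfig.from_yaml(config.to_yaml()) == config


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        NetworkConfig(family="resnet")
    with pytest.raises(ValueError):
        NetworkConfig(kernel=4)
    with pytest.raises(ValueError):
        NetworkConfig(depth=2)
    with pytest.raises(ValueError):
        NetworkConfig(pool_positions=(4,))   # no room for a mirrored unpool


def test_denoise_clips_and_batches():
    model = build_model(NetworkConfig(family="dncnn"))
    model.eval()
    images = np.random.default_rng(1).random((5, 32, 32)).astype(np.float32)
    out = denoise(model, images, batch_size=2)
    assert out.shape == images.shape
    assert out.min() >= 0.0
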