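import numpy as np
import pytest

from sctgen.networks import (
    AttentionGenerator,
    GeneratorConfig,
    MaskStack,
    PatchDiscriminator,
    channel_softmax,
    compose_output,
    discriminator_forward,
    generator_forward,
    patch_mean,
)
from sctgen.nn import Tensor

SMALL = GeneratorConfig(n_masks=10, base_channels=4, n_residual=1)


def random_mask_stack(rng, n=10, size=4):
    content = rng.uniform(-1, 1, size=(n - 1, size, size))
    attention = channel_softmax(rng.normal(size=(n, size, size)))
    return MaskStack(content=content, attention=attention)


class TestChannelSoftmax:
    def test_uniform_logits_give_equal_shares(self):
        out = channel_softmax(np.zeros((10, 3, 3)))
        np.testing.assert_allclose(out, 0.1, atol=1e-12)

    def test_closed_form_example(self):
        logits = np.log(np.array([2.0, 1.0, 1.0]))[:, None, None]
        out = channel_softmax(logits)
        np.testing.assert_allclose(out[:, 0, 0], [0.5, 0.25, 0.25], atol=1e-12)

    def test_normalization_and_overflow_safety(self, rng):
        logits = rng.normal(scale=300.0, size=(10, 100, 100))  # would overflow naively
        out = channel_softmax(logits)
        assert np.isfinite(out).all()
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-9)


class TestComposeOutput:
    def test_background_only_reproduces_input_bitexact(self, rng):
        n, size = 10, 8
        attention = np.zeros((n, size, size))
        attention[-1] = 1.0
        masks = MaskStack(content=np.zeros((n - 1, size, size)), attention=attention)
        image = rng.uniform(-1, 1, size=(size, size))
        np.testing.assert_array_equal(compose_output(masks, image), image)

    def test_uniform_attention_algebra(self):
        n, size, c = 10, 4, 0.3
        masks = MaskStack(
            content=np.full((n - 1, size, size), c),
            attention=np.full((n, size, size), 1.0 / n),
        )
        image = np.full((size, size), -0.5)
        expected = ((n - 1) * c + (-0.5)) / n
        np.testing.assert_allclose(compose_output(masks, image), expected, atol=1e-12)

    def test_matches_per_pixel_brute_force(self, rng):
        for _ in range(25):
            masks = random_mask_stack(rng)
            image = rng.uniform(-1, 1, size=(4, 4))
            out = compose_output(masks, image)
            for i in range(4):
                for j in range(4):
                    acc = image[i, j] * masks.attention[-1, i, j]
                    for f in range(9):
                        acc += masks.content[f, i, j] * masks.attention[f, i, j]
                    assert abs(out[i, j] - acc) < 1e-6

    def test_shape_mismatch_rejected(self, rng):
        masks = random_mask_stack(rng)
        with pytest.raises(ValueError):
            compose_output(masks, np.zeros((5, 5)))


class TestMaskStackInvariants:
    def test_attention_must_be_simplex(self, rng):
        bad = np.abs(rng.normal(size=(10, 4, 4)))  # not normalized
        with pytest.raises(ValueError, match="sum to 1"):
            MaskStack(content=np.zeros((9, 4, 4)), attention=bad)

    def test_content_must_be_bounded(self, rng):
        att = channel_softmax(rng.normal(size=(10, 4, 4)))
        with pytest.raises(ValueError, match="content"):
            MaskStack(content=np.full((9, 4, 4), 2.0), attention=att)


class TestGenerator:
    def test_output_shapes_and_channel_counts(self):
        gen = AttentionGenerator(SMALL, rng=np.random.default_rng(0))
        image = np.random.default_rng(1).uniform(-1, 1, (32, 32)).astype(np.float32)
        out, masks = generator_forward(image, gen)
        assert out.shape == (32, 32)
        assert masks.attention.shape == (10, 32, 32)
        assert masks.content.shape == (9, 32, 32)

    def test_output_bounded_for_random_weights(self, rng):
        for seed in range(5):
            gen = AttentionGenerator(SMALL, rng=np.random.default_rng(seed))
            image = rng.uniform(-1, 1, (16, 16)).astype(np.float32)
            out, masks = gen.synthesize(image)
            assert out.min() >= -1 - 1e-5 and out.max() <= 1 + 1e-5
            np.testing.assert_allclose(masks.attention.sum(axis=0), 1.0, atol=1e-5)

    def test_forward_is_deterministic(self):
        gen = AttentionGenerator(SMALL, rng=np.random.default_rng(3))
        image = np.random.default_rng(4).uniform(-1, 1, (16, 16)).astype(np.float32)
        a, _ = gen.synthesize(image)
        b, _ = gen.synthesize(image)
        np.testing.assert_array_equal(a, b)

    def test_no_attention_mode_single_channel(self):
        cfg = GeneratorConfig(n_masks=10, base_channels=4, n_residual=1, use_attention=False)
        gen = AttentionGenerator(cfg, rng=np.random.default_rng(0))
        out, masks = gen.synthesize(np.zeros((16, 16), dtype=np.float32))
        assert out.shape == (16, 16) and masks is None


class TestDiscriminator:
    def test_score_map_size_matches_receptive_field_arithmetic(self):
        disc = PatchDiscriminator(4, rng=np.random.default_rng(0))
        image = np.zeros((64, 64), dtype=np.float32)
        scores = discriminator_forward(image, disc)
        assert scores.shape == PatchDiscriminator.output_shape((64, 64))
        # independent arithmetic: three stride-2 and two stride-1 4x4 convs, pad 1
        h = 64
        for s in (2, 2, 2, 1, 1):
            h = (h + 2 - 4) // s + 1
        assert scores.shape == (h, h)

    def test_translation_equivariance_on_interior_patches(self):
        # toy network: instance norms removed so scores depend only on
        # each patch's receptive field, making the shift exact away from
        # the image border and the roll seam
        from sctgen.nn import Identity, InstanceNorm2d

        disc = PatchDiscriminator(4, rng=np.random.default_rng(5))
        disc.net.mods = [Identity() if isinstance(m, InstanceNorm2d) else m
                         for m in disc.net.mods]
        rng = np.random.default_rng(6)
        image = rng.uniform(-1, 1, (128, 128)).astype(np.float32)
        shifted = np.roll(image, 8, axis=1)  # one patch stride (2*2*2)
        s0 = discriminator_forward(image, disc)
        s1 = discriminator_forward(shifted, disc)
        np.testing.assert_allclose(s1[4:-4, 4:8], s0[4:-4, 3:7], atol=1e-4)

    def test_zero_weights_give_constant_map(self):
        disc = PatchDiscriminator(4, rng=np.random.default_rng(0))
        for p in disc.parameters():
            p.data = np.zeros_like(p.data)
        scores = discriminator_forward(np.ones((32, 32), dtype=np.float32), disc)
        assert np.ptp(scores) == 0


class TestPatchMean:
    def test_constant_and_simple_maps(self):
        assert patch_mean(np.full((3, 3), 0.7)) == pytest.approx(0.7)
        assert patch_mean(np.array([[0.0, 1.0]])) == pytest.approx(0.5)

    def test_matches_direct_summation(self, rng):
        m = rng.normal(size=(7, 5))
        assert patch_mean(m) == pytest.approx(m.sum() / m.size, abs=1e-12)

    def test_tensor_path_and_empty_map(self):
        t = Tensor(np.arange(4.0).reshape(2, 2))
        assert patch_mean(t).item() == pytest.approx(1.5)
        with pytest.raises(ValueError):
            patch_mean(np.zeros((0, 3)))
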