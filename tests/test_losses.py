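"""The four generator loss terms, their weighted combination, and the
discriminator loss."""

import numpy as np
import pytest

from csmri import (LossWeights, RandomFeatureExtractor, Tensor,
                   adversarial_gen_loss, combined_loss, discriminator_loss,
                   freq_mse_loss, image_mse_loss, perceptual_loss)


class TestImageMSE:
    def test_identical_inputs_give_zero(self, rng):
        x = rng.random((16, 16))
        assert float(image_mse_loss(x, x)) == 0.0

    def test_unit_difference_gives_half(self):
        assert float(image_mse_loss(np.ones((8, 8)), np.zeros((8, 8)))) == 0.5

    def test_symmetric_and_flip_invariant(self, rng):
        a, b = rng.random((12, 12)), rng.random((12, 12))
        assert float(image_mse_loss(a, b)) == pytest.approx(
            float(image_mse_loss(b, a)))
        assert float(image_mse_loss(a[::-1], b[::-1])) == pytest.approx(
            float(image_mse_loss(a, b)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            image_mse_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestFreqMSE:
    def test_equals_image_mse_by_parseval(self, rng):
        # unitary FFT: the frequency-domain term is identical to the
        # image-domain term for real inputs
        for _ in range(5):
            a, b = rng.random((16, 16)), rng.random((16, 16))
            assert abs(float(freq_mse_loss(a, b))
                       - float(image_mse_loss(a, b))) <= 1e-9

    def test_quadratic_homogeneity(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        base = float(freq_mse_loss(a, b))
        assert float(freq_mse_loss(3 * a, 3 * b)) == pytest.approx(9 * base)

    def test_gradient_matches_image_domain(self, rng):
        a = Tensor(rng.random((8, 8)), requires_grad=True)
        b = Tensor(rng.random((8, 8)), requires_grad=True)
        freq_mse_loss(a, b).backward()
        ga = a.grad.copy()
        a.grad = b.grad = None
        image_mse_loss(a, b).backward()
        np.testing.assert_allclose(ga, a.grad, atol=1e-12)


class TestPerceptual:
    def test_identical_inputs_give_zero(self, rng):
        x = rng.random((1, 1, 16, 16))
        ext = RandomFeatureExtractor(seed=0)
        assert float(perceptual_loss(x, x, ext)) == 0.0

    def test_identity_extractor_reduces_to_image_mse(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert float(perceptual_loss(a, b, lambda t: t)) == pytest.approx(
            float(image_mse_loss(a, b)))

    def test_invariant_under_matched_feature_permutation(self, rng):
        a, b = rng.random((1, 1, 16, 16)), rng.random((1, 1, 16, 16))
        ext = RandomFeatureExtractor(seed=1)
        perm = np.random.default_rng(0).permutation(16)

        def permuted(t):
            f = ext(t)
            return Tensor(f.data[:, perm]) if not f.requires_grad else f

        base = float(perceptual_loss(a, b, ext))
        assert float(perceptual_loss(a, b, permuted)) == pytest.approx(base)

    def test_extractor_is_frozen_and_deterministic(self, rng):
        ext1 = RandomFeatureExtractor(seed=5)
        ext2 = RandomFeatureExtractor(seed=5)
        x = rng.random((2, 1, 16, 16))
        np.testing.assert_array_equal(ext1(Tensor(x)).data, ext2(Tensor(x)).data)
        assert all(not p.requires_grad for p in ext1.parameters())


class TestAdversarial:
    def test_perfect_fool_gives_zero(self):
        assert float(adversarial_gen_loss(np.array([1.0]))) == pytest.approx(
            0.0, abs=1e-6)

    def test_half_probability_gives_ln2(self):
        assert float(adversarial_gen_loss(np.array([0.5]))) == pytest.approx(
            np.log(2))

    def test_strictly_decreasing_in_probability(self):
        grid = np.linspace(0.01, 0.99, 100)
        values = [float(adversarial_gen_loss(np.array([p]))) for p in grid]
        assert np.all(np.diff(values) < 0)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            adversarial_gen_loss(np.array([1.5]))


class TestDiscriminatorLoss:
    def test_uninformative_discriminator_gives_two_ln2(self):
        val = float(discriminator_loss(np.array([0.5]), np.array([0.5])))
        assert val == pytest.approx(2 * np.log(2))

    def test_perfect_discriminator_approaches_zero(self):
        val = float(discriminator_loss(np.array([1.0]), np.array([0.0])))
        assert val == pytest.approx(0.0, abs=1e-5)

    def test_increasing_in_fake_probability(self):
        grid = np.linspace(0.01, 0.99, 50)
        values = [float(discriminator_loss(np.array([0.8]), np.array([p])))
                  for p in grid]
        assert np.all(np.diff(values) > 0)


class TestCombinedLoss:
    def test_default_weights_match_printed_values(self):
        w = LossWeights()
        assert (w.alpha, w.beta, w.delta) == (15.0, 0.1, 0.0025)

    def test_unit_image_term_weights_to_alpha(self):
        assert float(LossWeights().combine(1.0, 0.0, 0.0, 0.0)) == 15.0

    def test_unit_perceptual_term_weights_to_delta(self):
        assert float(LossWeights().combine(0.0, 0.0, 1.0, 0.0)) == 0.0025

    def test_bundle_combination_identity(self, rng):
        xt = rng.random((1, 1, 16, 16))
        xu = rng.random((1, 1, 16, 16))
        w = LossWeights()
        bundle = combined_loss(xt, xu, np.array([0.7]), w,
                               RandomFeatureExtractor(seed=2))
        expected = (w.alpha * float(bundle.l_imse)
                    + w.beta * float(bundle.l_fmse)
                    + w.delta * float(bundle.l_vgg) + float(bundle.l_gen))
        assert float(bundle.l_combine) == pytest.approx(expected, rel=1e-9)

    def test_identical_images_and_fooled_discriminator_give_zero(self, rng):
        x = rng.random((1, 1, 16, 16))
        bundle = combined_loss(x, x, np.array([1.0]), LossWeights(),
                               RandomFeatureExtractor(seed=0))
        assert float(bundle.l_combine) == pytest.approx(0.0, abs=1e-6)

    def test_alpha_scaling_is_linear(self, rng):
        xt, xu = rng.random((8, 8)), rng.random((8, 8))
        d = np.array([0.5])
        w1 = LossWeights(alpha=15.0)
        w2 = LossWeights(alpha=30.0)
        diff = (float(combined_loss(xt, xu, d, w2).l_combine)
                - float(combined_loss(xt, xu, d, w1).l_combine))
        assert diff == pytest.approx(15.0 * float(image_mse_loss(xt, xu)),
                                     rel=1e-9)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-1.0)

    def test_all_terms_nonnegative(self, rng):
        bundle = combined_loss(rng.random((8, 8)), rng.random((8, 8)),
                               np.array([0.4]), LossWeights(),
                               RandomFeatureExtractor(seed=0))
        for value in bundle.to_dict().values():
            assert value >= 0
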