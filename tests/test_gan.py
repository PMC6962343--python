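import numpy as np
import pytest

from advdta.encoding import Vocabulary, encode_sequence, one_hot, one_hot_batch
from advdta.gan import (AdversarialState, Discriminator, DiscriminatorConfig,
                        GanDivergenceError, Generator, GeneratorConfig,
                        adversarial_train, discriminate, extract_features,
                        generate_fake, load_extractor, optimal_discriminator,
                        save_extractor)
from advdta.nnet import sigmoid


@pytest.fixture
def small_gen():
    return Generator(GeneratorConfig(noise_dim=8, hidden_dims=(16, 16, 16),
                                     output_shape=(5, 4)), seed=0)


@pytest.fixture
def small_disc():
    return Discriminator(DiscriminatorConfig(input_shape=(5, 4), hidden_dim=12,
                                             feature_dim=6), seed=1)


class TestGenerator:
    def test_fake_samples_are_row_stochastic(self, small_gen):
        fake = generate_fake(small_gen, 2, seed=3)
        assert fake.shape == (2, 5, 4)
        assert np.allclose(fake.sum(axis=2), 1.0, atol=1e-6)
        assert np.all(fake >= 0)

    def test_same_seed_bitwise_identical(self, small_gen):
        a = generate_fake(small_gen, 4, seed=7)
        b = generate_fake(small_gen, 4, seed=7)
        assert np.array_equal(a, b)

    def test_four_affine_layers(self, small_gen):
        assert len(small_gen.net.parameter_layers()) == 4

    def test_hidden_dims_must_be_three(self):
        with pytest.raises(ValueError):
            GeneratorConfig(hidden_dims=(16, 16))


class TestDiscriminator:
    def test_output_strictly_in_unit_interval(self, small_disc, rng):
        x = rng.random((5, 4)).astype(np.float32)
        p = discriminate(small_disc, x)
        assert 0.0 < p < 1.0

    def test_zero_head_outputs_half(self, small_disc, rng):
        small_disc.head.params["W"][...] = 0.0
        for _ in range(5):
            assert discriminate(small_disc, rng.random((5, 4))) == 0.5

    def test_decomposition_exact(self, small_disc, rng):
        # D(s) == sigmoid(phi_l . F(s; phi_f)), same float32 contraction
        x = rng.random((5, 4)).astype(np.float32)
        f = extract_features(small_disc, x)
        manual = float(sigmoid(f[None].astype(np.float32)
                               @ small_disc.head.params["W"])[0, 0])
        assert discriminate(small_disc, x) == pytest.approx(manual, abs=1e-12)

    def test_head_scaling_saturates_output(self, small_disc, rng):
        x = rng.random((5, 4)).astype(np.float32)
        base = discriminate(small_disc, x)
        small_disc.head.params["W"][...] *= 1e6
        saturated = discriminate(small_disc, x)
        assert saturated < 1e-6 or saturated > 1 - 1e-6
        assert (saturated > 0.5) == (base > 0.5)

    def test_three_affine_layers(self, small_disc):
        assert len(small_disc.parameter_layers()) == 3

    def test_shape_mismatch_rejected(self, small_disc, rng):
        with pytest.raises(ValueError, match="shape"):
            discriminate(small_disc, rng.random((3, 4)))

    def test_identity_extractor_passes_input_through(self):
        # body sized input == hidden == feature; identity weights and
        # non-negative inputs make F the identity map
        disc = Discriminator(DiscriminatorConfig(input_shape=(2, 3),
                                                 hidden_dim=6, feature_dim=6), seed=0)
        for layer in disc.body.parameter_layers():
            layer.params["W"][...] = np.eye(6)
            layer.params["b"][...] = 0.0
        x = np.array([[0, 1, 0], [1, 0, 0]], dtype=np.float32)
        assert np.array_equal(extract_features(disc, x), x.ravel())

    def test_features_deterministic_and_pad_sensitive(self, small_disc, rng):
        vocab = Vocabulary("smiles", {"A": 1, "B": 2})
        enc = encode_sequence("ABAB", vocab, max_len=5)
        x = one_hot(enc, vocab)
        assert np.array_equal(extract_features(small_disc, x),
                              extract_features(small_disc, x))
        masked = one_hot(encode_sequence("AB", vocab, max_len=5), vocab)
        assert not np.array_equal(extract_features(small_disc, x),
                                  extract_features(small_disc, masked))


class TestOptimalDiscriminator:
    def test_equal_distributions_give_half(self):
        p = np.array([0.25, 0.75])
        assert np.allclose(optimal_discriminator(p, p), 0.5)

    def test_data_only_mass_gives_one(self):
        assert optimal_discriminator(np.array([1.0]), np.array([0.0]))[0] == 1.0

    def test_printed_formula_example(self):
        d = optimal_discriminator(np.array([0.8, 0.2]), np.array([0.2, 0.8]))
        assert np.allclose(d, [0.8, 0.2])

    def test_zero_total_mass_yields_nan(self):
        d = optimal_discriminator(np.array([0.5, 0.0]), np.array([0.5, 0.0]))
        assert np.isnan(d[1])


def _real_pool(n, seq, vocab, max_len):
    return one_hot_batch([encode_sequence(seq, vocab, max_len)] * n, vocab)


class TestAdversarialTraining:
    def test_losses_finite_every_step(self, small_gen, small_disc):
        vocab = Vocabulary("smiles", {"A": 1, "B": 2})
        real = _real_pool(64, "ABABA", vocab, 5)[:, :, :4]
        state = AdversarialState(generator=small_gen, discriminator=small_disc)
        adversarial_train(state, real, epochs=10, batch_size=16, lr=1e-3, seed=0)
        assert state.history
        assert all(np.isfinite(d) and np.isfinite(g) for _, d, g in state.history)

    def test_fixed_seed_reproduces_final_parameters(self):
        vocab = Vocabulary("smiles", {"A": 1, "B": 2})
        real = _real_pool(32, "ABBA", vocab, 4)
        finals = []
        for _ in range(2):
            gen = Generator(GeneratorConfig(noise_dim=8, hidden_dims=(8, 8, 8),
                                            output_shape=(4, 4)), seed=5)
            disc = Discriminator(DiscriminatorConfig(input_shape=(4, 4),
                                                     hidden_dim=8, feature_dim=4), seed=6)
            state = adversarial_train(AdversarialState(gen, disc), real,
                                      epochs=5, batch_size=8, lr=1e-3, seed=9)
            finals.append((gen.net.state_dict(), disc.body.state_dict(),
                           state.history))
        for a, b in zip(finals[0][0], finals[1][0]):
            for k in a:
                assert np.array_equal(a[k], b[k])
        assert finals[0][2] == finals[1][2]

    def test_single_token_universe_becomes_indistinguishable(self):
        # degenerate vocabulary: every real sequence is the same token string,
        # so the generator can match P_data and D(real)-D(fake) shrinks
        vocab = Vocabulary("smiles", {"A": 1})
        real = _real_pool(64, "AAAA", vocab, 4)
        gen = Generator(GeneratorConfig(noise_dim=4, hidden_dims=(8, 8, 8),
                                        output_shape=(4, 3)), seed=2)
        disc = Discriminator(DiscriminatorConfig(input_shape=(4, 3),
                                                 hidden_dim=8, feature_dim=4), seed=3)

        def gap():
            fake = generate_fake(gen, 64, seed=11)
            return float(np.mean(discriminate(disc, real)) -
                         np.mean(discriminate(disc, fake)))

        state = AdversarialState(gen, disc)
        adversarial_train(state, real, epochs=1, batch_size=32, lr=2e-3, seed=4)
        early = gap()
        adversarial_train(state, real, epochs=60, batch_size=32, lr=2e-3, seed=5)
        assert abs(gap()) < abs(early)

    def test_divergence_aborts_with_diagnostic(self, small_gen, small_disc):
        vocab = Vocabulary("smiles", {"A": 1, "B": 2})
        real = _real_pool(16, "AB", vocab, 5)[:, :, :4]
        small_disc.head.params["W"][...] = np.nan
        with pytest.raises(GanDivergenceError):
            adversarial_train(AdversarialState(small_gen, small_disc), real,
                              epochs=1, batch_size=8, lr=1e-3, seed=0)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, small_gen, small_disc, rng):
        vocab = Vocabulary("smiles", {"A": 1, "B": 2})
        state = AdversarialState(generator=small_gen, discriminator=small_disc)
        path = tmp_path / "extractor.npz"
        save_extractor(path, state, vocab, max_len=5)
        loaded, vocab2, max_len = load_extractor(path)
        assert vocab2.token_to_index == vocab.token_to_index
        assert max_len == 5
        x = rng.random((3, 5, 4)).astype(np.float32)
        assert np.array_equal(loaded.discriminator.features(x),
                              small_disc.features(x))
        assert np.array_equal(loaded.generator.sample(2, np.random.default_rng(1)),
                              small_gen.sample(2, np.random.default_rng(1)))
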