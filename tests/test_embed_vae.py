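"""VAE architecture, losses, Adam and training behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deardia import embed_vae as ev
from deardia._nn import Tensor
from deardia.embed_vae import (
    AdamState, TripletExample, VaeArch, adam_step, decode, embed_xics,
    encode, init_vae_params, normalize_xic, sample_latent, total_loss,
    train_vae, triplet_loss, vae_loss,
)

TINY = VaeArch(input_dim=6, latent_dim=2,
               enc_branches=((4,), (3, 4), (3, 4), (4,)),
               dec_branches=((4,), (4, 3), (4, 3), (4,)), dropout=0.0)


@pytest.fixture(scope="module")
def params():
    return init_vae_params(seed=7)


class TestArchitecture:
    def test_encoder_heads_are_16_dim(self, params):
        out = encode(np.random.default_rng(0).random(20), params)
        assert out.mu.shape == (16,) and out.log_var.shape == (16,)

    def test_decoder_concatenation_width_is_752(self):
        arch = VaeArch()
        assert arch.dec_concat == 384 + 192 + 48 + 128 == 752
        assert arch.enc_concat == 384 + 384 + 128 + 128 == 1024

    def test_decode_outputs_length_20(self, params):
        assert decode(np.zeros(16), params).shape == (20,)

    def test_zero_input_finite(self, params):
        out = encode(np.zeros(20), params)
        assert np.isfinite(out.mu).all() and np.isfinite(out.log_var).all()

    def test_inference_deterministic(self, params):
        x = np.random.default_rng(1).random(20)
        a, b = encode(x, params), encode(x, params)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.log_var, b.log_var)

    def test_wrong_length_raises(self, params):
        with pytest.raises(ValueError):
            encode(np.zeros(19), params)
        with pytest.raises(ValueError):
            decode(np.zeros(15), params)


class TestSampleLatent:
    def test_zero_epsilon_returns_mu(self):
        out = ev.EncoderOutput(mu=np.arange(16.0), log_var=np.ones(16))
        np.testing.assert_array_equal(
            sample_latent(out, np.zeros(16)), out.mu)

    def test_unit_variance_equal_in_both_modes(self):
        out = ev.EncoderOutput(mu=np.zeros(16), log_var=np.zeros(16))
        e = np.random.default_rng(0).standard_normal(16)
        np.testing.assert_allclose(sample_latent(out, e), e)
        np.testing.assert_allclose(sample_latent(out, e, literal=True), e)

    def test_variance_four_distinguishes_modes(self):
        out = ev.EncoderOutput(mu=np.zeros(1), log_var=np.log(4.0) * np.ones(1))
        assert sample_latent(out, np.ones(1))[0] == pytest.approx(2.0)
        assert sample_latent(out, np.ones(1), literal=True)[0] == pytest.approx(4.0)


class TestVaeLoss:
    def test_standard_normal_posterior_perfect_reconstruction(self):
        x = np.random.default_rng(0).random(20)
        kl, recon, total = vae_loss(x, x, np.zeros(16), np.zeros(16))
        assert kl == pytest.approx(0.0)
        assert recon == pytest.approx(0.0)
        assert total == pytest.approx(0.0)

    def test_unit_mean_single_dim_gives_half(self):
        kl, _, _ = vae_loss(np.zeros(1), np.zeros(1),
                            np.array([1.0]), np.array([0.0]))
        assert kl == pytest.approx(0.5)

    def test_unit_impulse_reconstruction_error(self):
        x = np.zeros(20)
        x[0] = 1.0
        _, recon, _ = vae_loss(x, np.zeros(20), np.zeros(16), np.zeros(16))
        assert recon == pytest.approx(0.05)

    def test_literal_mode_flips_kl_sign(self):
        x = np.zeros(20)
        kl, recon, total = vae_loss(x, x, np.ones(16), np.zeros(16),
                                    literal_eq2=True)
        assert total == pytest.approx(-kl + recon)

    def test_nonfinite_raises(self):
        with pytest.raises(FloatingPointError):
            vae_loss(np.full(20, np.nan), np.zeros(20),
                     np.zeros(16), np.zeros(16))

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=4),
           st.lists(st.floats(-3, 3), min_size=4, max_size=4))
    def test_kl_nonnegative(self, mu, log_var):
        kl, _, _ = vae_loss(np.zeros(4), np.zeros(4),
                            np.array(mu), np.array(log_var))
        assert kl >= -1e-12


class TestTripletLoss:
    def test_identical_embeddings_give_margin(self):
        mu = np.random.default_rng(0).random(16)
        assert triplet_loss(mu, mu, mu) == pytest.approx(1.0)

    def test_hinge_clamps_at_zero(self):
        mu_a = np.zeros(16)
        mu_n = np.zeros(16)
        mu_n[0] = np.sqrt(5.0)
        assert triplet_loss(mu_a, mu_a, mu_n) == 0.0

    def test_batch_mean_of_hinges(self):
        mu_a = np.zeros((2, 16))
        mu_p = np.zeros((2, 16))
        mu_n = np.zeros((2, 16))
        mu_n[1, 0] = np.sqrt(5.0)  # hinge terms: 1 and 0
        assert triplet_loss(mu_a, mu_p, mu_n) == pytest.approx(0.5)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            triplet_loss(np.zeros(16), np.zeros(16), np.zeros(8))


class TestTotalLoss:
    def test_decomposition_identity(self, params):
        rng = np.random.default_rng(3)
        trip = TripletExample(*(rng.random(20) * 100 for _ in range(3)))
        total = total_loss(trip, params)
        parts = []
        mus = []
        for x in (trip.anchor, trip.positive, trip.negative):
            xn = normalize_xic(x)
            out = encode(xn, params)
            xh = decode(sample_latent(out, np.zeros(16)), params)
            parts.append(vae_loss(xn, xh, out.mu, out.log_var)[2])
            mus.append(out.mu)
        expected = sum(parts) / 3 + triplet_loss(*mus)
        assert total == pytest.approx(expected, abs=1e-10)

    def test_finite_on_random_triplets(self, params):
        rng = np.random.default_rng(9)
        for _ in range(5):
            trip = TripletExample(*(rng.random(20) for _ in range(3)))
            assert np.isfinite(total_loss(trip, params))


class TestAdam:
    def test_zero_gradient_leaves_params(self):
        p = {"w": np.array([1.0, -2.0])}
        st_ = AdamState.init(p)
        adam_step(p, {"w": np.zeros(2)}, st_)
        np.testing.assert_array_equal(p["w"], [1.0, -2.0])

    def test_first_step_magnitude(self):
        p = {"w": np.array([0.0])}
        adam_step(p, {"w": np.array([1.0])}, AdamState.init(p))
        assert p["w"][0] == pytest.approx(-0.001 / (1 + 1e-8), rel=1e-9)

    def test_agrees_with_scalar_reference_over_100_steps(self):
        rng = np.random.default_rng(0)
        p = {"w": np.array([0.0])}
        st_ = AdamState.init(p)
        m = v = th = 0.0
        for t in range(1, 101):
            g = float(rng.standard_normal())
            adam_step(p, {"w": np.array([g])}, st_)
            m = 0.9 * m + 0.1 * g
            v = 0.999 * v + 0.001 * g * g
            m_hat = m / (1 - 0.9 ** t)
            v_hat = v / (1 - 0.999 ** t)
            th -= 0.001 * m_hat / (np.sqrt(v_hat) + 1e-8)
            assert p["w"][0] == pytest.approx(th, abs=1e-12)


class TestGradients:
    def test_analytic_matches_finite_difference_on_tiny_network(self):
        params = init_vae_params(TINY, seed=1)
        rng = np.random.default_rng(2)
        xa, xp, xn = (rng.random((2, 6)) for _ in range(3))

        def run(p):
            pt = {k: Tensor(v, requires_grad=True) for k, v in p.items()}
            loss = ev._triplet_batch_graph(
                xa, xp, xn, pt, TINY, np.random.default_rng(5), 1.0,
                False, False, training=False)
            return loss, pt

        loss, pt = run(params)
        loss.backward()
        eps = 1e-6
        for k in params:
            analytic = pt[k].grad
            numeric = np.zeros_like(params[k])
            it = np.nditer(params[k], flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                p2 = {kk: vv.copy() for kk, vv in params.items()}
                p2[k][i] += eps
                lp, _ = run(p2)
                p2[k][i] -= 2 * eps
                lm, _ = run(p2)
                numeric[i] = (lp.data - lm.data) / (2 * eps)
            rel = np.abs(numeric - analytic) / np.maximum(
                1e-6, np.abs(numeric) + np.abs(analytic))
            assert rel.max() < 1e-4, f"gradient mismatch in {k}"


class TestTraining:
    def _triplets(self, n=600, seed=0):
        from deardia import synthdia
        xics = synthdia.make_training_xics(n_peptides=40, seed=seed)
        return synthdia.make_triplets(xics, n=n, seed=seed + 1)

    def test_loss_decreases(self):
        _, hist = train_vae(self._triplets(), epochs=3, batch_size=128,
                            seed=0)
        assert hist[-1] < hist[0]

    def test_seeded_reproducibility(self):
        trips = self._triplets(n=300)
        _, h1 = train_vae(trips, epochs=2, batch_size=128, seed=5)
        _, h2 = train_vae(trips, epochs=2, batch_size=128, seed=5)
        assert h1 == h2

    def test_empty_stream_raises(self):
        with pytest.raises(ValueError):
            train_vae([], epochs=1)

    def test_heldout_separation(self, trained_vae):
        """After training, anchors sit closer to positives than negatives
        for >= 85% of held-out triplets."""
        from deardia import synthdia
        params = trained_vae["params"]
        xics = synthdia.make_training_xics(n_peptides=60, seed=100)
        held = synthdia.make_triplets(xics, n=1000, seed=101)
        mu_a = embed_xics([t.anchor for t in held], params)
        mu_p = embed_xics([t.positive for t in held], params)
        mu_n = embed_xics([t.negative for t in held], params)
        d_ap = ((mu_a - mu_p) ** 2).sum(1)
        d_an = ((mu_a - mu_n) ** 2).sum(1)
        assert (d_ap < d_an).mean() >= 0.85

    def test_training_separates_embedding_distances(self, trained_vae):
        """Mean intra-peptide embedding distance < mean inter-peptide."""
        from deardia import synthdia
        params = trained_vae["params"]
        xics = synthdia.make_training_xics(
            n_peptides=5, fragments_per_peptide=6, seed=77)
        labels = np.repeat(np.arange(5), 6)
        emb = embed_xics([x for p in range(5) for x in xics[p]], params)
        intra, inter = [], []
        for i in range(len(emb)):
            for j in range(i + 1, len(emb)):
                d = float(((emb[i] - emb[j]) ** 2).sum())
                (intra if labels[i] == labels[j] else inter).append(d)
        assert np.mean(intra) < np.mean(inter)


class TestEmbedding:
    def test_shapes_and_duplicates(self, params):
        rng = np.random.default_rng(0)
        x = rng.random((4, 20))
        x[3] = x[0]
        emb = embed_xics(x, params)
        assert emb.shape == (4, 16)
        np.testing.assert_array_equal(emb[0], emb[3])

    def test_scale_invariance_via_normalization(self, params):
        x = np.random.default_rng(1).random(20)
        e1 = embed_xics([x], params)
        e2 = embed_xics([10.0 * x], params)
        np.testing.assert_allclose(e1, e2, atol=1e-12)

    def test_normalize_xic_bounds(self):
        x = np.random.default_rng(2).random(20) * 1e5
        n = normalize_xic(x)
        assert n.min() == 0.0 and n.max() == 1.0
        assert not normalize_xic(np.full(20, 3.0)).any()
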