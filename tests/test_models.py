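import copy

import numpy as np
import pytest
from autograd.misc.flatten import flatten

from dsvae.io_windows import Window
from dsvae.models import (
    BaseSequenceVAE,
    DiagonalGaussian,
    ModelConfig,
    decode,
    elbo_loss,
    encode_context,
    encode_local,
    init_params,
    kl_diag_gaussian,
    local_prior,
    loss_batch,
    lvae_context,
    make_estimator,
)
from dsvae.nn import count_params

N, W = 5, 8  # tiny geometry for fast model tests


def tiny_config(variant="dsvae", **kw):
    defaults = dict(
        variant=variant, local_size=3, context_size=2, hidden_size=6,
        prior_hidden_size=6, conv_channels=6, seed=7,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


@pytest.fixture
def window(rng):
    return Window("s", 0, rng.standard_normal((N, W)))


def mc_kl(q, p, n=200_000, seed=0):
    """Monte-Carlo KL oracle: E_q[log q - log p]."""
    rng = np.random.default_rng(seed)
    sq = np.exp(0.5 * q.log_variance)
    x = q.mean + sq * rng.standard_normal((n, q.dim))

    def logpdf(x, mu, lv):
        return -0.5 * np.sum((x - mu) ** 2 / np.exp(lv) + lv + np.log(2 * np.pi), axis=1)

    return np.mean(logpdf(x, q.mean, q.log_variance) - logpdf(x, p.mean, p.log_variance))


class TestKl:
    def test_identical_distributions_give_exact_zero(self, rng):
        q = DiagonalGaussian(rng.standard_normal(4), rng.standard_normal(4))
        assert kl_diag_gaussian(q, q) == 0.0

    def test_unit_shift_closed_form(self):
        q = DiagonalGaussian([1.0], [0.0])
        p = DiagonalGaussian([0.0], [0.0])
        assert kl_diag_gaussian(q, p) == pytest.approx(0.5, abs=1e-12)

    def test_shrinking_variance_diverges_monotonically(self):
        p = DiagonalGaussian([0.0], [0.0])
        kls = [
            kl_diag_gaussian(DiagonalGaussian([0.0], [np.log(s**2)]), p)
            for s in (0.5, 0.1, 0.02, 0.004)
        ]
        assert all(a < b for a, b in zip(kls, kls[1:]))
        # closed form -log(s) + (s^2 - 1)/2 at s = 0.1
        assert kls[1] == pytest.approx(-np.log(0.1) + (0.01 - 1) / 2, abs=1e-12)

    def test_matches_monte_carlo(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            q = DiagonalGaussian(r.normal(size=3), r.normal(scale=0.5, size=3))
            p = DiagonalGaussian(r.normal(size=3), r.normal(scale=0.5, size=3))
            assert kl_diag_gaussian(q, p) == pytest.approx(
                mc_kl(q, p, seed=seed), abs=0.02
            )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            kl_diag_gaussian(DiagonalGaussian([0.0], [0.0]),
                             DiagonalGaussian([0.0, 0.0], [0.0, 0.0]))


class TestEncodeContext:
    @pytest.mark.parametrize("arch", ["rnn", "conv"])
    def test_posterior_dimension_and_determinism(self, window, arch):
        cfg = tiny_config(context_encoder_arch=arch)
        params = init_params(cfg, N, W)
        a = encode_context(window, cfg, params)
        b = encode_context(window, cfg, params)
        assert a.dim == cfg.context_size
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.log_variance, b.log_variance)

    def test_all_zero_window_gives_finite_clamped_logvar(self):
        cfg = tiny_config()
        params = init_params(cfg, N, W)
        post = encode_context(Window("s", 0, np.zeros((N, W))), cfg, params)
        assert np.all(np.isfinite(post.log_variance))
        assert np.all(np.abs(post.log_variance) <= 10.0)

    def test_lvae_has_no_context_encoder(self, window):
        cfg = tiny_config("lvae")
        with pytest.raises(ValueError, match="lvae_context"):
            encode_context(window, cfg, init_params(cfg, N, W))

    def test_width_mismatch_rejected(self, rng):
        cfg = tiny_config()
        params = init_params(cfg, N, W)
        bad = Window("s", 0, rng.standard_normal((N, W + 2)))
        with pytest.raises(ValueError, match="width"):
            encode_context(bad, cfg, params, width=W)


class TestEncodeLocal:
    def test_output_length_is_window_width(self, window, rng):
        cfg = tiny_config("idsvae")
        post = encode_local(window, None, cfg, init_params(cfg, N, W))
        assert len(post) == W and post[0].dim == cfg.local_size

    def test_dsvae_depends_on_context_sample(self, window, rng):
        cfg = tiny_config("dsvae")
        params = init_params(cfg, N, W)
        a = encode_local(window, np.zeros(2), cfg, params)
        b = encode_local(window, np.ones(2), cfg, params)
        assert not np.allclose(a[0].mean, b[0].mean)

    def test_idsvae_rejects_context_sample(self, window):
        # the factorization contrast: the independent model's local channel
        # must never see the context embedding
        cfg = tiny_config("idsvae")
        with pytest.raises(ValueError, match="dsvae-specific"):
            encode_local(window, np.zeros(2), cfg, init_params(cfg, N, W))

    def test_dsvae_requires_context_sample(self, window):
        cfg = tiny_config("dsvae")
        with pytest.raises(ValueError, match="context sample"):
            encode_local(window, None, cfg, init_params(cfg, N, W))


class TestLocalPrior:
    def test_zeroed_recurrence_gives_constant_prior(self, rng):
        # zero weights and zero conditioning make the state a fixed point,
        # so every step's prior depends on the conditioning alone
        cfg = tiny_config("idsvae")
        params = init_params(cfg, N, W)
        for k in ("Wx", "Wh", "b"):
            params["prior"]["gru"][k] = np.zeros_like(params["prior"]["gru"][k])
        params["prior"]["h0"] = np.zeros_like(params["prior"]["h0"])
        z = rng.standard_normal((W, cfg.local_size))
        pri = local_prior(cfg, params, z)
        for p in pri[1:]:
            np.testing.assert_allclose(p.mean, pri[0].mean, atol=1e-12)
            np.testing.assert_allclose(p.log_variance, pri[0].log_variance, atol=1e-12)

    def test_dsvae_context_changes_step_one_prior(self, rng):
        cfg = tiny_config("dsvae")
        params = init_params(cfg, N, W)
        z = rng.standard_normal((W, cfg.local_size))
        a = local_prior(cfg, params, z, context_sample=np.zeros(2))
        b = local_prior(cfg, params, z, context_sample=np.ones(2))
        assert not np.allclose(a[0].mean, b[0].mean)

    def test_idsvae_step_one_prior_shared_across_windows(self, rng):
        cfg = tiny_config("idsvae")
        params = init_params(cfg, N, W)
        pris = [
            local_prior(cfg, params, rng.standard_normal((W, cfg.local_size)))
            for _ in range(3)
        ]
        for p in pris[1:]:
            np.testing.assert_array_equal(p[0].mean, pris[0][0].mean)
            np.testing.assert_array_equal(p[0].log_variance, pris[0][0].log_variance)

    def test_prior_at_t_ignores_future_samples(self, rng):
        cfg = tiny_config("idsvae")
        params = init_params(cfg, N, W)
        z = rng.standard_normal((W, cfg.local_size))
        z2 = z.copy()
        z2[4:] += 10.0  # perturb the future only
        a = local_prior(cfg, params, z)
        b = local_prior(cfg, params, z2)
        for t in range(5):  # steps 0..4 depend on z[:4] only
            np.testing.assert_array_equal(a[t].mean, b[t].mean)
        assert not np.allclose(a[6].mean, b[6].mean)

    def test_wrong_length_rejected(self, rng):
        cfg = tiny_config("idsvae")
        with pytest.raises(ValueError, match="dimension"):
            local_prior(cfg, init_params(cfg, N, W),
                        rng.standard_normal((W, cfg.local_size + 1)))


class TestDecode:
    def test_deterministic_and_correct_dimension(self, rng):
        cfg = tiny_config()
        params = init_params(cfg, N, W)
        zc, zl = rng.standard_normal(2), rng.standard_normal(3)
        a = decode(cfg, params, zc, zl)
        np.testing.assert_array_equal(a, decode(cfg, params, zc, zl))
        assert a.shape == (N,)

    def test_cvae_decodes_full_window_from_context_only(self, rng):
        cfg = tiny_config("cvae")
        params = init_params(cfg, N, W)
        out = decode(cfg, params, rng.standard_normal(2), width=W)
        assert out.shape == (N, W)
        with pytest.raises(ValueError, match="context sample only"):
            decode(cfg, params, rng.standard_normal(2), rng.standard_normal(3), width=W)

    def test_dimension_mismatch_rejected(self, rng):
        cfg = tiny_config()
        with pytest.raises(ValueError, match="dimensions"):
            decode(cfg, init_params(cfg, N, W), np.zeros(3), np.zeros(3))


class TestElboLoss:
    def test_zero_weights_leave_reconstruction_only(self, window, rng):
        cfg = tiny_config(beta=0.0, gamma=0.0)
        params = init_params(cfg, N, W)
        bd = elbo_loss(window, cfg, params, np.random.default_rng(0))
        assert bd.total == bd.reconstruction

    def test_forced_standard_normal_posterior_zeroes_context_kl(self, window):
        cfg = tiny_config()
        params = init_params(cfg, N, W)
        for head in ("mu", "lv"):
            params["ctx"][head]["W"] = np.zeros_like(params["ctx"][head]["W"])
            params["ctx"][head]["b"] = np.zeros_like(params["ctx"][head]["b"])
        bd = elbo_loss(window, cfg, params, np.random.default_rng(0))
        assert bd.context_kl == 0.0

    def test_total_linear_in_gamma_at_frozen_samples(self, window):
        params = init_params(tiny_config(), N, W)
        bds = [
            elbo_loss(window, tiny_config(gamma=g), params, np.random.default_rng(3))
            for g in (0.0, 2.0)
        ]
        assert bds[1].context_kl == pytest.approx(bds[0].context_kl, abs=1e-12)
        assert bds[1].total - bds[0].total == pytest.approx(
            2.0 * bds[0].context_kl, abs=1e-10
        )

    def test_kl_terms_non_negative_for_all_variants(self, window):
        for variant in ("dsvae", "idsvae", "lvae", "cvae"):
            cfg = tiny_config(variant)
            bd = elbo_loss(window, cfg, init_params(cfg, N, W),
                           np.random.default_rng(1))
            assert bd.local_kl >= 0 and bd.context_kl >= 0
            assert bd.total == pytest.approx(
                bd.reconstruction + cfg.beta * bd.local_kl + cfg.gamma * bd.context_kl,
                rel=1e-12,
            )


class TestLvaeContext:
    def test_identical_timesteps_idempotent(self):
        g = DiagonalGaussian([1.0, -2.0], [0.0, 0.0])
        np.testing.assert_array_equal(lvae_context([g, g, g]), g.mean)

    def test_opposite_means_cancel(self):
        a = DiagonalGaussian([1.0, 2.0], [0.0, 0.0])
        b = DiagonalGaussian([-1.0, -2.0], [0.0, 0.0])
        np.testing.assert_allclose(lvae_context([a, b]), 0.0, atol=1e-15)

    def test_matches_brute_force_mean_over_32_steps(self, rng):
        posts = [
            DiagonalGaussian(rng.standard_normal(3), rng.standard_normal(3))
            for _ in range(32)
        ]
        expected = sum(p.mean for p in posts) / 32
        np.testing.assert_allclose(lvae_context(posts), expected, atol=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lvae_context([])


class TestStructuralSharing:
    def test_dsvae_idsvae_share_context_encoder_and_decoder(self):
        d = init_params(tiny_config("dsvae"), N, W)
        i = init_params(tiny_config("idsvae"), N, W)
        for head in ("mu", "lv"):
            np.testing.assert_array_equal(d["ctx"][head]["W"], i["ctx"][head]["W"])
        for cell in ("fw", "bw"):
            np.testing.assert_array_equal(
                d["ctx"]["rnn"][cell]["Wx"], i["ctx"]["rnn"][cell]["Wx"]
            )
        for layer in ("h", "out"):
            np.testing.assert_array_equal(d["dec"][layer]["W"], i["dec"][layer]["W"])
        np.testing.assert_array_equal(d["prior"]["gru"]["Wx"], i["prior"]["gru"]["Wx"])

    def test_param_count_difference_is_exactly_the_conditioning(self):
        cfg_d, cfg_i = tiny_config("dsvae"), tiny_config("idsvae")
        d = init_params(cfg_d, N, W)
        i = init_params(cfg_i, N, W)
        H, P, CS = cfg_d.hidden_size, cfg_d.prior_hidden_size, cfg_d.context_size
        # dsvae extras: CS more input rows per local-encoder direction, and a
        # CS->P init layer instead of a learnable P-vector
        expected = 2 * CS * H + (CS * P + P) - P
        assert count_params(d) - count_params(i) == expected


class TestSaveLoad:
    def test_embeddings_identical_after_reload(self, tmp_path, rng):
        X = rng.standard_normal((12, N, W))
        est = make_estimator(tiny_config(max_epochs=2, batch_size=6))
        est.fit(X[:8], X_val=X[8:])
        Z = est.transform(X)
        est.save(tmp_path / "model")
        back = BaseSequenceVAE.load(tmp_path / "model")
        np.testing.assert_array_equal(back.transform(X), Z)
        assert back.config_ == est.config_

    def test_unfitted_save_rejected(self, tmp_path):
        with pytest.raises(RuntimeError, match="not fitted"):
            make_estimator(tiny_config()).save(tmp_path / "m")


class TestGradientDescent:
    @pytest.mark.parametrize("variant", ["dsvae", "idsvae", "lvae", "cvae"])
    def test_one_adam_step_reduces_batch_loss(self, variant, rng):
        """End-to-end gradient sanity: a single optimizer step on a fixed
        batch with fixed reparameterization noise strictly reduces the
        training loss of every variant."""
        from autograd import value_and_grad
        from dsvae.nn import Adam

        cfg = tiny_config(variant)
        params = init_params(cfg, N, W)
        X = rng.standard_normal((16, W, N))
        ec = rng.standard_normal((16, cfg.context_size))
        el = rng.standard_normal((16, W, cfg.local_size))
        fn = lambda p: loss_batch(p, cfg, X, ec, el)["total"]
        before, grad = value_and_grad(fn)(params)
        flat, unflatten = flatten(params)
        stepped = unflatten(Adam(learning_rate=1e-3).step(flat, flatten(grad)[0]))
        assert fn(stepped) < before
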