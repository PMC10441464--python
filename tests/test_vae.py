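"""Masked VAE: forward correctness, loss closed forms, mask integrity."""

import numpy as np
import pytest

from autosurv._nn import l2_penalty, softplus
from autosurv.pathways import PathwayMask
from autosurv.vae import (
    KLPMVAE,
    LatentRepresentation,
    VAEConfig,
    gaussian_kl,
    reparameterize,
    vae_loss,
)


def _one_gene_model():
    mask = PathwayMask(["g"], ["p"], np.ones((1, 1)))
    cfg = VAEConfig(n_latent=1, trunk_hidden=2, batchnorm=False, epochs=1)
    return KLPMVAE(mask, 1, cfg, seed=0), mask


class TestEncode:
    def test_hand_forward_pass(self):
        model, _ = _one_gene_model()
        # set the whole affine chain by hand
        model.gene_stack.layers[0].W.value[:] = 0.5
        model.gene_stack.layers[0].b.value[:] = 0.1
        model.trunk.layers[0].W.value[:] = [[1.0, -1.0], [2.0, 0.5]]
        model.trunk.layers[0].b.value[:] = [0.0, 0.2]
        model.head_mu.W.value[:] = [[1.0], [3.0]]
        model.head_mu.b.value[:] = [0.25]
        xg, xm = np.array([[0.8]]), np.array([[0.4]])
        pa = max(0.5 * 0.8 + 0.1, 0.0)                       # 0.5
        h1 = max(1.0 * pa + 2.0 * 0.4 + 0.0, 0.0)            # 1.3
        h2 = max(-1.0 * pa + 0.5 * 0.4 + 0.2, 0.0)           # 0 (relu clips -0.1)
        expected = 1.0 * h1 + 3.0 * h2 + 0.25                # 1.55
        latent = model.encode(xg, xm)
        assert latent.mu[0, 0] == pytest.approx(expected)

    def test_zero_weights_give_constant_mu(self):
        model, _ = _one_gene_model()
        for p in model.params():
            if p.name.endswith(".W"):
                p.value[...] = 0.0
        model.head_mu.b.value[:] = [0.7]
        rng = np.random.default_rng(1)
        latent = model.encode(rng.random((5, 1)), rng.random((5, 1)))
        assert np.allclose(latent.mu, 0.7)

    def test_masked_gene_cannot_reach_pathway(self, toy_mask):
        cfg = VAEConfig(n_latent=2, trunk_hidden=4, batchnorm=False, epochs=1)
        model = KLPMVAE(toy_mask, 4, cfg, seed=2)
        rng = np.random.default_rng(3)
        xg = rng.random((6, toy_mask.n_genes))
        xm = rng.random((6, 4))
        base = model.gene_stack.forward(xg)
        i, j = next(
            (i, j) for i in range(toy_mask.n_genes) for j in range(toy_mask.n_pathways)
            if toy_mask.mask[i, j] == 0
        )
        bumped = xg.copy()
        bumped[:, i] += 10.0
        assert np.allclose(model.gene_stack.forward(bumped)[:, j], base[:, j])

    def test_misaligned_gene_columns_rejected(self, toy_mask):
        import pandas as pd

        cfg = VAEConfig(n_latent=2, trunk_hidden=4, epochs=1)
        model = KLPMVAE(toy_mask, 4, cfg, seed=2)
        df = pd.DataFrame(np.random.default_rng(0).random((3, toy_mask.n_genes)),
                          columns=list(reversed(toy_mask.gene_ids)))
        with pytest.raises(ValueError, match="misaligned"):
            model.encode(df, np.zeros((3, 4)))


class TestReparameterize:
    def test_vanishing_sigma_returns_mu(self):
        latent = LatentRepresentation(mu=np.full((4, 2), 1.5),
                                      logvar=np.full((4, 2), -60.0))
        z = reparameterize(latent, np.random.default_rng(0))
        assert np.allclose(z, 1.5)

    def test_standard_normal_moments(self):
        n = 10**5
        latent = LatentRepresentation(mu=np.zeros((n, 1)), logvar=np.zeros((n, 1)))
        z = reparameterize(latent, np.random.default_rng(1))
        se_mean = 1 / np.sqrt(n)
        assert abs(z.mean()) < 3 * se_mean
        assert abs(z.var() - 1.0) < 3 * np.sqrt(2 / n)

    def test_seeded_draws_identical(self):
        latent = LatentRepresentation(mu=np.zeros((3, 2)), logvar=np.zeros((3, 2)))
        a = reparameterize(latent, np.random.default_rng(5))
        b = reparameterize(latent, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestLoss:
    def test_kl_zero_iff_standard_normal(self):
        assert gaussian_kl(np.zeros((3, 4)), np.zeros((3, 4))) == 0.0
        # mu=1, sigma^2=1, one dim: KL = 0.5*(1 + 1 - 0 - 1) = 0.5
        assert gaussian_kl(np.ones((1, 1)), np.zeros((1, 1))) == pytest.approx(0.5)
        rng = np.random.default_rng(0)
        mu, lv = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert gaussian_kl(mu, lv) > 0.0

    def test_bce_at_half_is_k_ln2(self):
        k, n = 7, 3
        x = np.full((n, k), 0.5)
        latent = LatentRepresentation(mu=np.zeros((n, 2)), logvar=np.zeros((n, 2)))
        total, comps = vae_loss(x, None, x, None, latent, beta=1.0)
        assert comps["recon_gene"] == pytest.approx(k * np.log(2))
        assert total == pytest.approx(k * np.log(2))  # KL term is zero here

    def test_reconstruction_outside_unit_interval_rejected(self):
        x = np.full((2, 3), 0.5)
        latent = LatentRepresentation(mu=np.zeros((2, 1)), logvar=np.zeros((2, 1)))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            vae_loss(x, None, x + 1.0, None, latent, beta=1.0)

    def test_loss_invariant_to_sample_order(self):
        rng = np.random.default_rng(2)
        x = rng.random((10, 4))
        xhat = rng.random((10, 4))
        mu, lv = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
        perm = rng.permutation(10)
        a, _ = vae_loss(x, None, xhat, None,
                        LatentRepresentation(mu, lv), beta=0.6)
        b, _ = vae_loss(x[perm], None, xhat[perm], None,
                        LatentRepresentation(mu[perm], lv[perm]), beta=0.6)
        assert a == pytest.approx(b)

    def test_l2_term_counts_weights_not_biases(self):
        model, _ = _one_gene_model()
        params = model.params()
        expected = sum(np.sum(p.value**2) for p in params if p.name.endswith(".W"))
        assert l2_penalty(params, 1.0) == pytest.approx(expected)


class TestTrainingMechanics:
    def test_gradients_match_finite_differences(self, toy_mask):
        cfg = VAEConfig(n_latent=2, trunk_hidden=4, lambda1=0.01, epochs=1,
                        batch_size=6)
        model = KLPMVAE(toy_mask, 3, cfg, seed=4)
        rng = np.random.default_rng(5)
        xg, xm = rng.random((6, toy_mask.n_genes)), rng.random((6, 3))
        beta = 0.7

        def loss_at():
            eps_rng = np.random.default_rng(99)
            pa = model.gene_stack.forward(xg, training=True)
            t = model.trunk.forward(np.concatenate([pa, xm], 1), training=True)
            mu = model.head_mu.forward(t)
            lv = model.head_logvar.forward(t)
            z = mu + np.exp(0.5 * lv) * eps_rng.standard_normal(mu.shape)
            td = model.dec_trunk.forward(z, training=True)
            glog = model.dec_gene.forward(td, training=True)
            mlog = model.dec_mirna.forward(td, training=True)
            return (float((softplus(glog) - xg * glog).sum(1).mean())
                    + float((softplus(mlog) - xm * mlog).sum(1).mean())
                    + beta * gaussian_kl(mu, lv)
                    + l2_penalty(model.params(), cfg.lambda1))

        class FixedRng:
            def __init__(self):
                self._r = np.random.default_rng(99)

            def standard_normal(self, shape):
                return self._r.standard_normal(shape)

        for p in model.params():
            p.zero_grad()
        model._train_step(xg, xm, beta, FixedRng())
        masks = {"enc_gene.W": toy_mask.mask, "dec_gene_out.W": toy_mask.mask.T}
        h = 1e-6
        check_rng = np.random.default_rng(6)
        for p in model.params():
            for _ in range(min(p.value.size, 4)):
                idx = tuple(check_rng.integers(0, s) for s in p.value.shape)
                if p.name in masks and masks[p.name][idx] == 0:
                    continue
                old = p.value[idx]
                p.value[idx] = old + h
                up = loss_at()
                p.value[idx] = old - h
                down = loss_at()
                p.value[idx] = old
                numeric = (up - down) / (2 * h)
                assert p.grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7), p.name

    def test_masked_weights_and_gradients_stay_zero(self, toy_vae):
        model, _, _ = toy_vae
        enc_W = model.gene_stack.layers[0]
        dec_W = model.dec_gene.layers[-1]
        assert np.all(enc_W.W.value[enc_W.mask == 0] == 0.0)
        assert np.all(dec_W.W.value[dec_W.mask == 0] == 0.0)
        assert np.all(enc_W.W.grad[enc_W.mask == 0] == 0.0)
        assert np.all(dec_W.W.grad[dec_W.mask == 0] == 0.0)

    def test_pure_reconstruction_loss_decreases(self, toy_mask):
        cfg = VAEConfig(n_latent=2, trunk_hidden=6, lambda1=0.0, epochs=15,
                        batch_size=16, learning_rate=5e-3)
        model = KLPMVAE(toy_mask, 4, cfg, seed=10)
        rng = np.random.default_rng(11)
        xg, xm = rng.random((48, toy_mask.n_genes)), rng.random((48, 4))
        hist = model.fit(xg, xm, beta_schedule=lambda e: 0.0, seed=12)
        recon = hist["recon_gene"] + hist["recon_mirna"]
        assert recon.iloc[-1] < recon.iloc[0]

    def test_extract_latent_deterministic(self, toy_vae):
        model, xg, xm = toy_vae
        a = model.extract_latent(xg, xm)
        b = model.extract_latent(xg, xm)
        assert np.array_equal(a, b)

    def test_single_omics_output_arity(self, toy_mask):
        cfg = VAEConfig(n_latent=2, trunk_hidden=4, integration_mode="gene_only",
                        epochs=1)
        model = KLPMVAE(toy_mask, None, cfg, seed=0)
        out = model.decode(np.zeros((3, 2)))
        assert isinstance(out, np.ndarray) and out.shape == (3, toy_mask.n_genes)
        assert np.all((out > 0) & (out < 1))  # sigmoid range

    def test_checkpoint_round_trip(self, toy_vae, tmp_path):
        model, xg, xm = toy_vae
        model.save(tmp_path / "vae.npz")
        loaded = KLPMVAE.load(tmp_path / "vae.npz")
        assert np.allclose(model.extract_latent(xg, xm),
                           loaded.extract_latent(xg, xm))
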