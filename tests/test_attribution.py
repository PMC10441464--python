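"""DeepLIFT-rescale attribution: closed forms, summation-to-delta, key factors."""

import numpy as np
import pandas as pd
import pytest

from autosurv.attribution import (
    chain_forward,
    deep_shap,
    explain_latent,
    explain_pathway_node,
    explain_pi,
    fold_stack,
    identify_key_factors,
    overall_contributions,
    percent_contributions,
)
from autosurv.pathways import PathwayMask
from autosurv.survnet import LFSurv, SurvConfig
from autosurv.vae import KLPMVAE, VAEConfig


class TestLinearClosedForm:
    def test_linear_model_contributions_are_w_times_delta(self):
        rng = np.random.default_rng(0)
        w = np.array([[1.5], [-2.0], [0.5]])
        chain = [("affine", w, np.array([0.3]))]
        X = rng.random((6, 3))
        R = rng.random((4, 3))
        res = deep_shap(chain, X, R, feature_ids=["a", "b", "c"])
        expected = w[:, 0][None, :] * (X - R.mean(axis=0)[None, :])
        assert np.allclose(res.contributions, expected)
        assert np.allclose(res.overall.to_numpy(),
                           np.abs(expected).mean(axis=0))

    def test_identical_sample_and_reference_gives_zero(self):
        chain = [("affine", np.array([[2.0], [1.0]]), np.zeros(1)), ("act", "tanh")]
        x = np.array([[0.4, 0.6]])
        res = deep_shap(chain, x, x, feature_ids=["a", "b"])
        assert np.allclose(res.contributions, 0.0)
        assert res.output_values[0] == pytest.approx(res.reference_mean_output)


class TestRescaleRule:
    def test_hand_computed_tanh_toy_network(self):
        # two features -> one tanh hidden unit -> linear output
        net = LFSurv(2, SurvConfig(hidden_width=1, dropout_rate=0.0, epochs=1))
        wh = np.array([0.8, -0.4])
        net.net.layers[0].W.value[:] = wh[:, None]
        net.net.layers[0].b.value[:] = [0.1]
        net.net.layers[-1].W.value[:] = [[2.0]]
        x = np.array([[0.9, 0.2]])
        r = np.array([[0.1, 0.7]])
        ax = float((x @ wh)[0] + 0.1)
        ar = float((r @ wh)[0] + 0.1)
        shared = (np.tanh(ax) - np.tanh(ar)) / (ax - ar)  # rescale multiplier
        expected = 2.0 * shared * wh * (x - r)[0]
        res = explain_pi(net, x, r)
        assert np.allclose(res.contributions[0], expected)
        delta = 2.0 * (np.tanh(ax) - np.tanh(ar))
        assert res.contributions.sum() == pytest.approx(delta)

    def test_vanishing_delta_falls_back_to_derivative(self):
        chain = [("act", "tanh"), ("affine", np.array([[1.0]]), np.zeros(1))]
        x = np.array([[0.5]])
        res = deep_shap(chain, x, x + 1e-12, feature_ids=["a"])
        assert res.contributions[0, 0] == pytest.approx(
            (1 - np.tanh(0.5) ** 2) * -1e-12, rel=1e-3)

    def test_batchnorm_folding_matches_eval_forward(self, toy_vae):
        model, xg, _ = toy_vae
        chain = fold_stack(model.gene_stack)
        folded = chain_forward(chain, xg)[-1]
        direct = model.gene_stack.forward(xg, training=False)
        assert np.allclose(folded, direct)


class TestSummationToDelta:
    def test_holds_for_trained_pi_and_all_latents(self, toy_vae):
        model, xg, xm = toy_vae
        mu = model.extract_latent(xg, xm)
        net = LFSurv(mu.shape[1], SurvConfig(hidden_width=4, dropout_rate=0.1,
                                             epochs=20), seed=1)
        rng = np.random.default_rng(2)
        net.fit(mu, rng.exponential(size=len(mu)), np.ones(len(mu), int), seed=3)
        res = explain_pi(net, mu[:10], mu[10:])
        assert res.summation_to_delta_error() < 1e-4
        for l in range(model.config.n_latent):
            attr = explain_latent(model, l, xg[:10], xm[:10], xg[10:], xm[10:])
            assert attr.summation_to_delta_error() < 1e-4

    def test_deterministic_given_seed(self, toy_vae):
        model, xg, xm = toy_vae
        a = explain_latent(model, 0, xg[:5], xm[:5], xg[5:], xm[5:], seed=4)
        b = explain_latent(model, 0, xg[:5], xm[:5], xg[5:], xm[5:], seed=4)
        assert np.array_equal(a.contributions, b.contributions)
        assert a.reference_ids == b.reference_ids


class TestPathwayNodeAttribution:
    def test_unconnected_genes_get_exactly_zero(self, toy_vae):
        model, xg, _ = toy_vae
        mask = model.mask
        pw = mask.pathway_ids[1]
        res = explain_pathway_node(model, pw, xg[:6], xg[6:])
        outside = [i for i, g in enumerate(mask.gene_ids)
                   if mask.mask[i, 1] == 0]
        assert np.all(res.contributions[:, outside] == 0.0)
        assert res.summation_to_delta_error() < 1e-4

    def test_single_gene_pathway_takes_entire_delta(self):
        mask = PathwayMask(["g0", "g1"], ["solo", "pair"],
                           np.array([[1.0, 1.0], [0.0, 1.0]]))
        cfg = VAEConfig(n_latent=1, trunk_hidden=2, epochs=3, batch_size=8)
        model = KLPMVAE(mask, 2, cfg, seed=5)
        rng = np.random.default_rng(6)
        model.fit(rng.random((16, 2)), rng.random((16, 2)), seed=7)
        res = explain_pathway_node(model, "solo", rng.random((4, 2)),
                                   rng.random((5, 2)))
        delta = res.output_values - res.reference_mean_output
        assert np.allclose(res.contributions[:, 0], delta)
        assert np.all(res.contributions[:, 1] == 0.0)

    def test_unknown_pathway_rejected(self, toy_vae):
        model, xg, _ = toy_vae
        with pytest.raises(ValueError, match="unknown"):
            explain_pathway_node(model, "nope", xg[:2], xg[2:])


class TestScores:
    def test_overall_is_mean_absolute(self):
        res = _fake_attr(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        assert overall_contributions(res).tolist() == [1.0, 1.0]

    def test_single_sample_overall_is_absolute_value(self):
        res = _fake_attr(np.array([[-2.0, 0.5]]))
        assert overall_contributions(res).tolist() == [2.0, 0.5]

    def test_percent_contributions(self):
        pct = percent_contributions(pd.Series([2.0, 3.0, 5.0], index=list("abc")))
        assert pct.tolist() == [20.0, 30.0, 50.0]
        assert pct.sum() == pytest.approx(100.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            percent_contributions(pd.Series([0.0, 0.0]))


def _fake_attr(contribs):
    from autosurv.attribution import AttributionResult

    n, k = contribs.shape
    return AttributionResult(
        target="t", feature_ids=[f"f{i}" for i in range(k)],
        contributions=contribs, output_values=contribs.sum(axis=1),
        reference_mean_output=0.0,
        explained_ids=[str(i) for i in range(n)], reference_ids=["r"],
    )


class TestKeyFactors:
    @staticmethod
    def _scores(ranking):
        """Series where listed features get descending scores."""
        return pd.Series({f: float(len(ranking) - i)
                          for i, f in enumerate(ranking)})

    def test_frequencies_match_bruteforce_counting(self):
        rng = np.random.default_rng(8)
        factors = [f"f{i}" for i in range(30)]
        per_latent = {}
        for l in range(6):
            scores = pd.Series(rng.random(30), index=factors)
            per_latent[f"mu_{l}"] = scores
        report = identify_key_factors(per_latent, top_k=10, min_frequency=2)
        # independent counting oracle
        expected = {}
        for scores in per_latent.values():
            for f in scores.nlargest(10).index:
                expected[f] = expected.get(f, 0) + 1
        got = dict(zip(report.table["factor"], report.table["frequency"]))
        assert got == expected

    def test_frequency_three_is_key(self):
        per_latent = {
            "mu_0": self._scores(["a", "b", "c"]),
            "mu_1": self._scores(["a", "c", "b"]),
            "mu_2": self._scores(["a", "d", "e"]),
        }
        report = identify_key_factors(per_latent, top_k=2, min_frequency=2)
        table = report.table.set_index("factor")
        assert table.loc["a", "frequency"] == 3
        assert bool(table.loc["a", "key"])

    def test_frequency_one_is_not_key(self):
        per_latent = {
            "mu_0": self._scores(["a", "b"]),
            "mu_1": self._scores(["c", "d"]),
        }
        report = identify_key_factors(per_latent, top_k=2, min_frequency=2)
        assert report.key_factors() == []

    def test_rank_boundary_tie_flagged_and_lexicographic(self):
        scores = pd.Series({"a": 3.0, "c": 2.0, "b": 2.0, "d": 1.0})
        report = identify_key_factors({"mu_0": scores, "mu_1": scores},
                                      top_k=2, min_frequency=2)
        # tie at rank 2 between b and c -> lexicographic picks b, run flagged
        assert set(report.key_factors()) == {"a", "b"}
        assert report.ties_flagged == ["mu_0", "mu_1"]

    def test_fewer_factors_than_topk_warns(self):
        with pytest.warns(UserWarning, match="top-10"):
            identify_key_factors({"mu_0": self._scores(["a", "b"])})
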