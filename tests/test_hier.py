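import numpy as np
import pytest
from scipy import stats
from scipy.special import logit

from conftest import make_items
from focusrsa import hier
from focusrsa.calibration import binomial_size_probs
from focusrsa.hier import (
    McmcConfig,
    PriorHyperParams,
    alpha_gamma_params,
    clip_unit,
    fit_prior_model,
    posterior_predictive_hdi,
    posterior_predictive_pvalues,
    prior_model_logdensity,
    rsa_bridge,
    slider_link,
)


class TestLink:
    def test_midpoint_maps_to_zero(self):
        assert slider_link(0.5, 3.7) == 0.0

    def test_kappa_scales_the_logit(self):
        assert slider_link(0.9, 1.0) == pytest.approx(logit(0.9))
        assert slider_link(0.9, 2.0) == pytest.approx(2 * logit(0.9))

    def test_requires_interior_values(self):
        with pytest.raises(ValueError):
            slider_link(0.0, 1.0)
        assert clip_unit(0.0) == pytest.approx(hier.CLIP_EPS)
        with pytest.raises(ValueError):
            clip_unit(1.2)

    def test_alpha_gamma_moments(self):
        shape, rate = alpha_gamma_params(3.0, 1.5)
        x = np.random.default_rng(0).gamma(shape, 1 / rate, size=100_000)
        assert x.mean() == pytest.approx(3.0, rel=0.02)
        assert x.var() == pytest.approx(1.5, rel=0.05)


class TestBridge:
    def test_symmetric_prior_anchor(self):
        assert np.allclose(rsa_bridge([0.5, 0.5], 3.0, 2), [0.9, 0.1])

    def test_point_masses_are_preserved(self):
        assert np.allclose(rsa_bridge([1.0, 0.0], 3.0, 2), [1.0, 0.0])
        assert np.allclose(rsa_bridge([0.0, 1.0], 3.0, 2), [0.0, 1.0])

    def test_matches_brute_force_speaker(self):
        # independent oracle: explicit loops over the focus lexicon on the
        # compatible subspace of k=3
        rng = np.random.default_rng(5)
        k = 3
        compat = [1, 3, 5, 7]
        masks = list(range(1, 8)) + [0]  # focus expressions + null
        for _ in range(10):
            q = rng.dirichlet(np.ones(4))
            alpha = rng.uniform(0, 5)
            s1_foc = []
            for s in compat:
                weights = []
                for m in masks:
                    true = (s & m) == m
                    if not true:
                        weights.append(0.0)
                        continue
                    mass = sum(qq for ss, qq in zip(compat, q) if (ss & m) == m)
                    l0 = q[compat.index(s)] / mass
                    weights.append(l0**alpha)
                s1_foc.append(weights[masks.index(1)] / sum(weights))
            expected = np.array(s1_foc) * q
            expected /= expected.sum()
            assert np.allclose(rsa_bridge(q, alpha, k), expected, atol=1e-12)

    def test_broadcasts_over_participants(self):
        q = np.tile([0.5, 0.5], (4, 1))
        alphas = np.array([0.0, 1.0, 3.0, 10.0])
        post = rsa_bridge(q, alphas, 2)
        assert post.shape == (4, 2)
        assert np.all(np.diff(post[:, 0]) > 0)  # sharper speakers, more exhaustive

    def test_rejects_negative_alpha_and_bad_length(self):
        with pytest.raises(ValueError):
            rsa_bridge([0.5, 0.5], -1.0, 2)
        with pytest.raises(ValueError):
            rsa_bridge([0.5, 0.3, 0.2], 1.0, 2)


class TestLogDensity:
    def _toy(self):
        hyper = PriorHyperParams(
            kappa=1.2, w=15.0, sigma2=0.3, mu={2: np.array([0.3, 0.5, 0.2])}
        )
        records = []
        raws = {"p1": [0.2, 0.5, 0.4, 0.1], "p2": [0.3, 0.3, 0.3, 0.3]}
        for pid, vals in raws.items():
            for s, v in enumerate(vals):
                records.append((pid, 2, "vacation_camping", s, v, 40.0))
        data = make_items(records)
        beliefs = {("p1", 2): np.array([0.25, 0.5, 0.25]), ("p2", 2): np.array([0.4, 0.4, 0.2])}
        return data, hyper, beliefs

    def test_matches_independent_oracle(self):
        data, hyper, beliefs = self._toy()
        got = prior_model_logdensity(data, hyper, beliefs)
        # brute force with scipy.stats, written independently of the package
        expected = (
            stats.gamma.logpdf(hyper.kappa, 5, scale=1 / 5)
            + stats.gamma.logpdf(hyper.w, 2, scale=1 / 0.1)
            + stats.invgamma.logpdf(hyper.sigma2, 1, scale=1)
            + stats.dirichlet.logpdf(hyper.mu[2], [1, 1, 1])
        )
        for pid in ("p1", "p2"):
            p = beliefs[(pid, 2)]
            expected += stats.dirichlet.logpdf(p, hyper.w * hyper.mu[2])
            Q = np.array([p[0], p[1] / 2, p[1] / 2, p[2]])
            sub = data[data["participant_id"] == pid].sort_values("state_index")
            y = logit(np.clip(sub["raw_value"].to_numpy(), hier.CLIP_EPS, 1 - hier.CLIP_EPS))
            mu = hyper.kappa * logit(np.clip(Q, hier.CLIP_EPS, 1 - hier.CLIP_EPS))
            expected += stats.norm.logpdf(y, mu, np.sqrt(hyper.sigma2)).sum()
        assert got == pytest.approx(expected, abs=1e-8)

    def test_empty_data_returns_hyperprior_terms(self):
        data, hyper, _ = self._toy()
        got = prior_model_logdensity(data.iloc[0:0], hyper, {})
        expected = (
            stats.gamma.logpdf(hyper.kappa, 5, scale=1 / 5)
            + stats.gamma.logpdf(hyper.w, 2, scale=1 / 0.1)
            + stats.invgamma.logpdf(hyper.sigma2, 1, scale=1)
            + stats.dirichlet.logpdf(hyper.mu[2], [1, 1, 1])
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_vanishing_noise_kills_the_density(self):
        data, hyper, beliefs = self._toy()
        tight = PriorHyperParams(kappa=hyper.kappa, w=hyper.w, sigma2=1e-5, mu=hyper.mu)
        assert prior_model_logdensity(data, tight, beliefs) < prior_model_logdensity(
            data, hyper, beliefs
        )

    def test_rejects_out_of_range_responses(self):
        data, hyper, beliefs = self._toy()
        bad = data.copy()
        bad.loc[bad.index[0], "raw_value"] = 1.2
        with pytest.raises(ValueError):
            prior_model_logdensity(bad, hyper, beliefs)


class TestFits:
    def test_prior_fit_shapes_and_diagnostics(self, tiny_prior_fit):
        fit = tiny_prior_fit
        C, D = fit.config.chains, fit.config.kept
        assert fit.draws["kappa"].shape == (C, D)
        assert fit.draws["mu_2"].shape == (C, D, 3)
        assert fit.draws["mu_3"].shape == (C, D, 4)  # length k+1
        assert fit.draws["p_2"].shape == (C, D, 10, 3)
        assert set(fit.rhat) >= {"kappa", "w", "sigma2", "mu_2", "mu_3"}

    def test_same_seed_reproduces_draws(self, tiny_prior_data):
        import warnings

        cfg = McmcConfig(iterations=300, seed=123)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_prior_model(tiny_prior_data, cfg)
            b = fit_prior_model(tiny_prior_data, cfg)
        for name in a.draws:
            assert np.array_equal(a.draws[name], b.draws[name])

    def test_zero_participants_is_an_error(self, tiny_prior_data):
        with pytest.raises(ValueError):
            fit_prior_model(tiny_prior_data.iloc[0:0])

    def test_posterior_fit_requires_matching_fixed_mu(self, tiny_posterior_data):
        fixed = PriorHyperParams(mu={2: np.array([0.3, 0.5, 0.2])})
        with pytest.raises(ValueError, match="mu for k=3"):
            hier.fit_posterior_model(tiny_posterior_data, fixed, McmcConfig(iterations=100))

    def test_posterior_fit_alpha_tracks_exhaustive_responses(self, tiny_posterior_data):
        """Participants with consistently high exhaustive-state sliders get
        larger posterior-mean rationality than consistently low ones."""
        import warnings

        data = tiny_posterior_data.copy()
        pids = sorted(data["participant_id"].unique())
        hi, lo = pids[0], pids[1]
        exh = data["state_index"].eq(1).fillna(False)
        for pid, e_val, o_val in ((hi, 0.95, 0.05), (lo, 0.4, 0.6)):
            mine = data["participant_id"] == pid
            data.loc[mine & exh, "raw_value"] = e_val
            data.loc[mine & ~exh, "raw_value"] = o_val
        fixed = PriorHyperParams(
            kappa=1.0, w=20.0, sigma2=0.25,
            mu={k: binomial_size_probs(k, 0.4) for k in (2, 3)},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = hier.fit_posterior_model(data, fixed, McmcConfig(iterations=600, seed=17))
        alpha_means = fit.stacked("alpha").mean(axis=0)
        i_hi, i_lo = fit.participants.index(hi), fit.participants.index(lo)
        assert alpha_means[i_hi] > alpha_means[i_lo]

    def test_hyper_means_round_trip(self, tiny_prior_fit):
        hm = tiny_prior_fit.hyper_means()
        assert set(hm.mu) == {2, 3}
        assert hm.kappa > 0 and hm.w > 0

    def test_draws_frame_is_long_format(self, tiny_prior_fit):
        df = tiny_prior_fit.draws_frame()
        assert {"parameter", "chain", "draw", "value"} == set(df.columns)
        assert (df["parameter"] == "kappa").sum() == (
            tiny_prior_fit.config.chains * tiny_prior_fit.config.kept
        )


class TestPosteriorPredictive:
    def test_hdi_bounds_are_ordered(self, tiny_prior_fit):
        hdis = posterior_predictive_hdi(tiny_prior_fit, n_draws=400, seed=3)
        assert (hdis["lower"] <= hdis["upper"]).all()
        assert set(hdis["domain_size"]) == {2, 3}
        assert len(hdis[hdis["domain_size"] == 2]) == 4

    def test_hdi_rejects_tiny_draw_counts(self, tiny_prior_fit):
        with pytest.raises(ValueError):
            posterior_predictive_hdi(tiny_prior_fit, n_draws=10)

    def test_pvalues_are_probabilities_and_mostly_unflagged(
        self, tiny_prior_fit, tiny_prior_data
    ):
        rep = posterior_predictive_pvalues(tiny_prior_fit, tiny_prior_data, seed=4)
        assert ((rep.table["p_value"] >= 0) & (rep.table["p_value"] <= 1)).all()
        assert len(rep.table) == 20  # 10 participants x 2 items
        # data generated from the model itself should rarely be flagged
        assert rep.fraction_below_05 <= 0.2

    def test_posterior_model_pvalues(self, tiny_posterior_fit, tiny_posterior_data):
        rep = posterior_predictive_pvalues(tiny_posterior_fit, tiny_posterior_data, seed=5)
        assert ((rep.table["p_value"] >= 0) & (rep.table["p_value"] <= 1)).all()
        assert rep.fraction_below_05 <= 0.3
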