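"""Hierarchical model internals: likelihood, priors, summaries, group test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, truncnorm, halfcauchy, norm

from tauspread.dynamics import ConcentrationState, SubjectParams, integrate
from tauspread.errors import DataError
from tauspread.inference import (
    HierarchicalModel,
    HyperParams,
    ModelSpec,
    PriorConfig,
    SamplerConfig,
    build_model,
    compare_groups,
    sample_posterior,
    sample_prior,
    summarize_posterior,
)
from tauspread.preprocess import ScanSeries
from tauspread.synthetic import CohortConfig, simulate_cohort

from conftest import make_random_network

HYPER = HyperParams(1.0, 0.3, 0.08, 0.08, -0.08, 0.08, 0.05)


def tiny_cohort(net, n_pos=2, n_neg=2, seed=0, followups=(2, 2)):
    cfg = CohortConfig(
        n_positive=n_pos, n_negative=n_neg, true_hyperparams=HYPER,
        followup_range=followups, seed_regions=tuple(range(net.n)),
        seed_level=(0.1, 0.5), background_level=(0.0, 0.0), rng_seed=seed,
    )
    return simulate_cohort(cfg, net)


class TestBuildModel:
    def test_log_likelihood_matches_direct_summation_oracle(self):
        """At fixed parameters the likelihood equals the hand-computed sum of
        Gaussian log densities of follow-up observations around the ODE
        solution."""
        net = make_random_network(6, seed=2)
        co = tiny_cohort(net, seed=3)
        model = build_model(ModelSpec(network=net, cohort=co.scan_series))
        kappas = np.array([p.kappa for p in co.true_subject_params])
        alphas = np.array([p.alpha for p in co.true_subject_params])
        theta = model.pack_natural(HYPER, kappas, alphas)
        got = model.log_likelihood(theta[None])[0]

        expected = 0.0
        for s, series in enumerate(co.scan_series):
            traj = integrate(
                ConcentrationState(series.normalized[0]),
                SubjectParams(kappas[s], alphas[s]), net, series.scan_times,
                rtol=1e-10, atol=1e-12,
            )
            for m in range(1, series.n_scans):
                for r in model.obs_regions:
                    expected += norm.logpdf(
                        series.normalized[m, r], traj.states[m, r], HYPER.sigma_err
                    )
        assert got == pytest.approx(expected, abs=1e-3)

    def test_no_observed_regions_makes_posterior_equal_prior(self):
        net = make_random_network(5, seed=4)
        co = tiny_cohort(net, seed=1)
        model = build_model(ModelSpec(network=net, cohort=co.scan_series,
                                      observed_region_indices=np.array([], dtype=int)))
        theta = model.pack_natural(
            HYPER,
            np.full(model.n_subjects, 1.0),
            np.zeros(model.n_subjects),
        )[None]
        assert model.log_likelihood(theta)[0] == 0.0
        assert model.log_posterior(theta)[0] == model.log_prior(theta)[0]

    def test_subject_without_followup_excluded(self, caplog):
        net = make_random_network(4, seed=5)
        co = tiny_cohort(net, seed=2)
        lonely = ScanSeries("only-baseline", True, np.array([0.0]),
                            co.scan_series[0].raw_suvr[:1],
                            normalized=co.scan_series[0].normalized[:1])
        with caplog.at_level("WARNING"):
            model = build_model(
                ModelSpec(network=net, cohort=co.scan_series + [lonely])
            )
        assert "only-baseline" not in model.subject_ids
        assert model.n_subjects == 4

    def test_empty_cohort_rejected(self):
        net = make_random_network(4, seed=5)
        with pytest.raises(DataError, match="empty cohort"):
            build_model(ModelSpec(network=net, cohort=[]))

    def test_extreme_parameters_get_minus_infinity_not_nan(self):
        net = make_random_network(5, seed=6)
        co = tiny_cohort(net, seed=4)
        model = build_model(ModelSpec(network=net, cohort=co.scan_series))
        theta = np.zeros((3, model.ndim))
        theta[0, 7] = -500.0  # kappa_s forced negative
        theta[1, 0] = 800.0  # exp overflow in mu_kappa
        theta[2, 7 + model.n_subjects] = 1e6  # absurd alpha -> blow-up
        out = model.log_posterior(theta)
        assert np.all(np.isneginf(out) | np.isfinite(out))
        assert np.isneginf(out[0])


class TestPriors:
    def test_prior_marginals_match_reference_families(self):
        """Direct hyperprior draws follow BoundNormal(>0,1,20), HalfCauchy(1)
        and Normal(0,2)."""
        rng = np.random.default_rng(0)
        draws = sample_prior(PriorConfig(), 10_000, rng)
        a = (0 - 1.0) / 20.0
        assert kstest(draws["mu_kappa"],
                      lambda x: truncnorm.cdf(x, a, np.inf, 1.0, 20.0)).statistic < 0.02
        assert kstest(draws["sigma_err"],
                      lambda x: halfcauchy.cdf(x, scale=1.0)).statistic < 0.02
        assert kstest(draws["mu_alpha_pos"],
                      lambda x: norm.cdf(x, 0.0, 2.0)).statistic < 0.02
        assert (draws["mu_kappa"] > 0).all()

    def test_log_prior_consistent_with_monte_carlo_moments(self):
        """The packed log-prior density is maximal near typical prior mass,
        and respects the positivity constraint on kappa."""
        net = make_random_network(4, seed=7)
        co = tiny_cohort(net, seed=5)
        model = build_model(ModelSpec(network=net, cohort=co.scan_series))
        ok = model.pack_natural(HYPER, np.full(4, 1.0), np.zeros(4))
        bad = ok.copy()
        bad[7] = -100.0  # z_kappa far below the truncation boundary
        lp = model.log_prior(np.stack([ok, bad]))
        assert np.isfinite(lp[0]) and np.isneginf(lp[1])


class TestSummaries:
    def make_samples(self, subject_ids, amyloid, kappa, alpha):
        import arviz as az
        from tauspread.inference import PosteriorSamples

        post = {
            "mu_kappa": kappa.mean(-1), "sigma_kappa": kappa.std(-1) + 0.1,
            "mu_alpha_pos": alpha.mean(-1), "sigma_alpha_pos": alpha.std(-1) + 0.1,
            "mu_alpha_neg": alpha.mean(-1), "sigma_alpha_neg": alpha.std(-1) + 0.1,
            "sigma_err": np.full(kappa.shape[:2], 0.05),
            "kappa": kappa, "alpha": alpha,
        }
        idata = az.from_dict(posterior=post,
                             dims={"kappa": ["subject"], "alpha": ["subject"]},
                             coords={"subject": list(subject_ids)})
        return PosteriorSamples(
            idata=idata, subject_ids=tuple(subject_ids),
            amyloid_positive=np.asarray(amyloid, bool),
            diagnostics=pd.DataFrame({"parameter": [], "rhat": [], "ess_bulk": []}),
        )

    def test_constant_draws_give_exact_summary(self):
        kappa = np.broadcast_to(np.array([0.5, 1.5]), (2, 10, 2)).copy()
        alpha = np.broadcast_to(np.array([0.2, 0.4]), (2, 10, 2)).copy()
        samples = self.make_samples(["a", "b"], [True, True], kappa, alpha)
        summary = summarize_posterior(samples)
        assert summary.table.loc["Mean", "kappa"] == pytest.approx(1.0)
        assert summary.table.loc["Mean", "alpha_pos"] == pytest.approx(0.3)
        assert summary.table.loc["Min", "alpha_pos"] == pytest.approx(0.2)
        assert summary.table.loc["Max", "alpha_pos"] == pytest.approx(0.4)
        assert summary.subjects["kappa_mean"].tolist() == [0.5, 1.5]
        # degenerate draws: zero-width intervals
        assert (summary.subjects["kappa_lo95"] == summary.subjects["kappa_hi95"]).all()

    def test_group_table_splits_alpha_by_amyloid_status(self):
        rng = np.random.default_rng(0)
        kappa = rng.uniform(0.5, 1.5, (2, 50, 4))
        alpha = rng.normal(0, 0.1, (2, 50, 4)) + np.array([0.3, 0.3, -0.3, -0.3])
        samples = self.make_samples(list("abcd"), [True, True, False, False],
                                    kappa, alpha)
        summary = summarize_posterior(samples)
        assert summary.table.loc["Mean", "alpha_pos"] > 0.2
        assert summary.table.loc["Mean", "alpha_neg"] < -0.2


class TestCompareGroups:
    def frame(self, pos, neg):
        return pd.DataFrame({
            "amyloid_positive": [1] * len(pos) + [0] * len(neg),
            "alpha_mean": list(pos) + list(neg),
        })

    def test_identical_groups_give_t_zero_p_one(self):
        res = compare_groups(self.frame([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]))
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_strongly_significant(self):
        res = compare_groups(self.frame([1.0, 1.001, 0.999], [0.0, 0.001, -0.001]))
        assert res.p_value < 1e-6 and res.t_statistic > 0

    def test_direction_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(0)
        pos = [0.25, 0.1, 0.31, 0.05]
        neg = [-0.1, 0.02, -0.2, -0.05]
        res = compare_groups(self.frame(pos, neg))
        pooled = np.array(pos + neg)
        observed = np.mean(pos) - np.mean(neg)
        perm = np.array([
            (lambda idx: pooled[idx[:4]].mean() - pooled[idx[4:]].mean())(
                rng.permutation(8))
            for _ in range(20000)
        ])
        p_perm = np.mean(np.abs(perm) >= abs(observed))
        assert (res.p_value < 0.05) == (p_perm < 0.05)
        assert res.t_statistic > 0

    def test_too_small_group_rejected(self):
        with pytest.raises(DataError, match="at least 2"):
            compare_groups(self.frame([0.1], [0.2, 0.3]))


class TestSamplingSmoke:
    """Short-chain runs: shapes, determinism and persistence round-trip."""

    @pytest.fixture(scope="class")
    def fitted(self):
        net = make_random_network(5, seed=8)
        co = tiny_cohort(net, n_pos=2, n_neg=2, seed=6)
        spec = ModelSpec(
            network=net, cohort=co.scan_series,
            sampler_config=SamplerConfig(chains=2, tune=120, draws=80,
                                         walkers=32, seed=1),
        )
        model = build_model(spec)
        return model, sample_posterior(model, spec.sampler_config)

    def test_posterior_shapes_and_support(self, fitted):
        model, samples = fitted
        assert samples.n_chains == 2 * 32
        assert samples.n_draws == 80
        assert (samples.subject_draws("kappa") > 0).all()
        assert (samples.hyper_draws("sigma_err") > 0).all()
        assert samples.divergences == 0
        assert set(samples.diagnostics.columns) == {"parameter", "rhat", "ess_bulk"}

    def test_same_seed_reproduces_draws(self, fitted):
        model, samples = fitted
        again = sample_posterior(model, SamplerConfig(chains=2, tune=120, draws=80,
                                                      walkers=32, seed=1))
        np.testing.assert_array_equal(
            samples.idata.posterior["kappa"].to_numpy(),
            again.idata.posterior["kappa"].to_numpy(),
        )

    def test_save_load_round_trip(self, fitted, tmp_path):
        _, samples = fitted
        samples.save(tmp_path, thin=4)
        from tauspread.inference import PosteriorSamples

        back = PosteriorSamples.load(tmp_path)
        assert back.subject_ids == samples.subject_ids
        np.testing.assert_allclose(
            back.idata.posterior["alpha"].to_numpy(),
            samples.idata.posterior["alpha"].to_numpy()[:, ::4],
        )
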