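"""Priors, training sets, posterior backends, summaries and effect sizes."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from sfcpitch.inference import (
    MixtureDensityPosterior,
    PosteriorSamples,
    PriorSpec,
    RejectionABC,
    evaluate_hypotheses,
    fit_posterior,
    generate_training_set,
    glass_delta,
    pool_repetitions,
    rmse,
    sample_prior,
    summarize_posterior,
)
from sfcpitch.params import PARAM_NAMES


def make_samples(values: np.ndarray, rep=0, obs_id="x") -> PosteriorSamples:
    df = pd.DataFrame(values, columns=list(PARAM_NAMES))
    df["repetition"] = rep
    return PosteriorSamples(samples=df, observation_id=obs_id)


class TestPrior:
    def test_draws_respect_bounds(self):
        prior = PriorSpec()
        draws = sample_prior(prior, 10_000, seed=0)
        assert np.all(draws >= prior.lower) and np.all(draws <= prior.upper)

    def test_degenerate_prior_constant(self):
        prior = PriorSpec().fix(g_c=3.0)
        draws = sample_prior(prior, 50, seed=0)
        assert np.all(draws[:, 4] == 3.0)
        assert prior.fixed_names == ("g_c",)

    def test_marginals_are_uniform(self):
        """KS distance of each marginal against its uniform CDF is < 0.02 at n=1e4."""
        prior = PriorSpec()
        draws = sample_prior(prior, 10_000, seed=1)
        for j in range(5):
            u = (draws[:, j] - prior.lower[j]) / prior.width[j]
            ks = scipy.stats.kstest(u, "uniform").statistic
            assert ks < 0.02

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="r"):
            PriorSpec(bounds={**PriorSpec().bounds, "r": (6.0, 0.1)})


class TestTrainingSet:
    def test_training_noise_bounded_and_scaled(self):
        prior = PriorSpec()
        clean = generate_training_set(prior, 200, training_noise_halfwidth=0.0, seed=3)
        noisy = generate_training_set(prior, 200, training_noise_halfwidth=3.5, seed=3)
        added = noisy.trajectories - clean.trajectories
        assert np.max(np.abs(added)) <= 3.5
        # variance of U(−a, a) is a²/3
        assert np.var(added) == pytest.approx(3.5**2 / 3.0, rel=0.05)

    def test_zero_halfwidth_returns_raw_output(self):
        prior = PriorSpec()
        a = generate_training_set(prior, 50, training_noise_halfwidth=0.0, seed=4)
        b = generate_training_set(prior, 50, training_noise_halfwidth=0.0, seed=4)
        np.testing.assert_array_equal(a.trajectories, b.trajectories)

    def test_all_draws_stable(self):
        ts = generate_training_set(PriorSpec(), 500, seed=5)
        assert np.all(np.abs(ts.trajectories) < 1e4 + 3.5)


@pytest.fixture(scope="module")
def training():
    return generate_training_set(PriorSpec(), 3000, seed=6)


class TestBackends:
    def test_abc_nearest_theta_in_degenerate_limit(self, training):
        est = RejectionABC(accept_quantile=1e-9).fit(training.trajectories, training.thetas)
        obs = training.trajectories[17]
        accepted = est.sample(obs, n_samples=None)
        assert accepted.shape[0] == 1
        np.testing.assert_array_equal(accepted[0], training.thetas[17])

    def test_flat_observation_pulls_gain_down(self, training):
        """A zero perturbation response implies a weak controller: the
        posterior median of g_c drops below the prior median."""
        prior = PriorSpec()
        flat = np.zeros(training.trajectories.shape[1])
        est = RejectionABC(accept_quantile=0.02).fit(training.trajectories, training.thetas)
        post = est.sample(flat, n_samples=2000, random_state=0)
        prior_median_gc = (prior.bounds["g_c"][0] + prior.bounds["g_c"][1]) / 2
        assert np.median(post[:, 4]) < prior_median_gc

    def test_density_backend_samples_in_prior_support(self, training):
        prior = PriorSpec()
        est = MixtureDensityPosterior(prior=prior, random_state=0)
        est.fit(training.trajectories, training.thetas)
        post = est.sample(training.trajectories[3], n_samples=500, random_state=1)
        assert np.all(prior.contains(post))

    def test_backends_deterministic_given_seed(self, training):
        obs = training.trajectories[5]
        for backend in ("abc", "density"):
            a = fit_posterior(training, obs, 500, seed=9, backend=backend, prior=PriorSpec())
            b = fit_posterior(training, obs, 500, seed=9, backend=backend, prior=PriorSpec())
            pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_loclinear_adjustment_respects_prior_box(self, training):
        prior = PriorSpec()
        est = RejectionABC(accept_quantile=0.01, adjust="loclinear", prior=prior)
        est.fit(training.trajectories, training.thetas)
        post = est.sample(training.trajectories[7], n_samples=1000, random_state=0)
        assert np.all(prior.contains(post))

    def test_loclinear_adjustment_keeps_pinned_parameters_pinned(self, training):
        prior = PriorSpec().fix(g_c=2.5)
        thetas = training.thetas.copy()
        thetas[:, 4] = 2.5
        est = RejectionABC(accept_quantile=0.01, adjust="loclinear", prior=prior)
        est.fit(training.trajectories, thetas)
        post = est.sample(training.trajectories[7], n_samples=200, random_state=0)
        assert np.all(post[:, 4] == 2.5)

    def test_loclinear_sharpens_toward_truth_on_clean_observation(self):
        """On a noiseless self-generated observation the regression correction
        moves the posterior median of the well-identified parameters (r, g_c)
        at least as close to the truth as plain rejection."""
        prior = PriorSpec()
        ts = generate_training_set(prior, 8000, seed=42)
        from sfcpitch.params import ParameterSet
        from sfcpitch.simulate import simulate_mean_response

        truth = ParameterSet(91.5, 15.5, -5.6, 1.0, 3.1)
        obs, _ = simulate_mean_response(truth, n_runs=20, seed=43)
        plain = RejectionABC(accept_quantile=0.01).fit(ts.trajectories, ts.thetas)
        adj = RejectionABC(accept_quantile=0.01, adjust="loclinear", prior=prior).fit(
            ts.trajectories, ts.thetas
        )
        m_plain = np.median(plain.sample(obs.f_o, 2000, random_state=0), axis=0)
        m_adj = np.median(adj.sample(obs.f_o, 2000, random_state=0), axis=0)
        t = truth.to_array()
        for j in (3, 4):  # r, g_c
            assert abs(m_adj[j] - t[j]) <= abs(m_plain[j] - t[j]) + 0.05

    def test_too_small_training_set_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            RejectionABC().fit(np.zeros((1, 300)), np.zeros((1, 5)))
        with pytest.raises(ValueError, match="too small"):
            MixtureDensityPosterior(n_components=8).fit(np.zeros((20, 300)), np.zeros((20, 5)))


class TestPooling:
    def test_pooled_counts_and_provenance(self, rng):
        reps = [make_samples(rng.random((100, 5)), rep=i) for i in range(10)]
        pooled = pool_repetitions(reps)
        assert pooled.n == 1000
        assert set(pooled.samples["repetition"]) == set(range(10))

    def test_single_repetition_identity(self, rng):
        s = make_samples(rng.random((100, 5)))
        pooled = pool_repetitions([s])
        pd.testing.assert_frame_equal(pooled.samples, s.samples)

    def test_mismatched_observations_rejected(self, rng):
        a = make_samples(rng.random((10, 5)), obs_id="a")
        b = make_samples(rng.random((10, 5)), obs_id="b")
        with pytest.raises(ValueError, match="different observations"):
            pool_repetitions([a, b])

    def test_pooled_median_bracketed_by_repetition_medians(self, rng):
        reps = [make_samples(rng.random((200, 5)) + i * 0.1, rep=i) for i in range(3)]
        pooled = pool_repetitions(reps)
        med = pooled.samples[list(PARAM_NAMES)].median()
        per_rep = np.array([r.samples[list(PARAM_NAMES)].median() for r in reps])
        assert np.all(med >= per_rep.min(axis=0) - 1e-12)
        assert np.all(med <= per_rep.max(axis=0) + 1e-12)


class TestSummaries:
    def test_quantiles_match_hand_calculation(self):
        base = np.tile(np.linspace(0, 1, 100)[:, None], (1, 5))
        s = summarize_posterior(make_samples(base))
        v = base[:, 0]
        for name in PARAM_NAMES:
            assert s.median(name) == pytest.approx(np.median(v))
            lo, hi = s.ci(name)
            assert lo == pytest.approx(np.quantile(v, 0.025))
            assert hi == pytest.approx(np.quantile(v, 0.975))
            assert lo <= s.median(name) <= hi

    def test_ci_widens_with_spread(self, rng):
        base = rng.standard_normal((5000, 5))
        s1 = summarize_posterior(make_samples(base + 5.0))
        s2 = summarize_posterior(make_samples(base * 3.0 + 5.0))
        for name in PARAM_NAMES:
            lo1, hi1 = s1.ci(name)
            lo2, hi2 = s2.ci(name)
            assert (hi2 - lo2) > (hi1 - lo1)

    def test_minimum_sample_count_enforced(self, rng):
        with pytest.raises(ValueError, match="100"):
            summarize_posterior(make_samples(rng.random((50, 5))))


class TestGlassDelta:
    def test_unit_separation_standard_normals(self, rng):
        A = rng.standard_normal((20_000, 5)) + 1.0
        B = rng.standard_normal((20_000, 5))
        report = glass_delta(A, B, seed=0)
        for name in PARAM_NAMES:
            assert report.table.loc[name, "delta_mean"] == pytest.approx(1.0, abs=0.15)

    def test_identical_distributions_near_zero(self, rng):
        A = rng.standard_normal((5000, 5))
        report = glass_delta(A, A, seed=1)
        for name in PARAM_NAMES:
            row = report.table.loc[name]
            assert abs(row["delta_mean"]) < 3 * row["delta_se"] + 1e-9

    def test_scale_invariance(self, rng):
        A = rng.standard_normal((5000, 5)) + 0.5
        B = rng.standard_normal((5000, 5))
        r1 = glass_delta(A, B, seed=2)
        r2 = glass_delta(A * 7.0, B * 7.0, seed=2)
        np.testing.assert_allclose(
            r1.table["delta_mean"], r2.table["delta_mean"], rtol=1e-9
        )

    def test_zero_variance_comparison_group_rejected(self, rng):
        A = rng.standard_normal((100, 5))
        B = np.ones((100, 5))
        with pytest.raises(ValueError, match="zero standard deviation"):
            glass_delta(A, B)


class TestRmse:
    def test_identity_and_offset(self):
        x = np.arange(10.0)
        assert rmse(x, x) == 0.0
        assert rmse(x, x + 2.5) == pytest.approx(2.5)

    def test_hand_computed_toy_vectors(self):
        assert rmse(np.zeros(3), np.array([1.0, 2.0, 2.0])) == pytest.approx(1.7321, abs=1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse(np.zeros(3), np.zeros(4))


class TestHypotheses:
    def _summary(self, r, sigma):
        values = {"delta_a_ms": 90.0, "delta_s_ms": 20.0, "sigma_log10": sigma, "r": r, "g_c": 2.0}
        rows = {
            n: {"median": v, "ci_low": v - 1.0, "ci_high": v + 1.0, "sd": 1.0}
            for n, v in values.items()
        }
        from sfcpitch.inference import PosteriorSummary

        return PosteriorSummary(table=pd.DataFrame(rows).T)

    def test_published_medians_give_h1_not_h2(self):
        ca = self._summary(r=1.0, sigma=-5.6)
        ctrl = self._summary(r=2.0, sigma=-5.8)
        report = evaluate_hypotheses(ca, ctrl)
        assert report["H1_r_ca_lt_control"] is True
        assert report["H2_sigma_ca_lt_control"] is False

    def test_identical_summaries_reject_both(self):
        s = self._summary(r=1.0, sigma=-5.6)
        report = evaluate_hypotheses(s, s)
        assert not report["H1_r_ca_lt_control"] and not report["H2_sigma_ca_lt_control"]

    def test_swapping_groups_flips_h1(self):
        ca = self._summary(r=1.0, sigma=-5.6)
        ctrl = self._summary(r=2.0, sigma=-5.8)
        assert evaluate_hypotheses(ctrl, ca)["H1_r_ca_lt_control"] is False
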