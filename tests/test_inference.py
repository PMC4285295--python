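"""Rejection, model choice, regression adjustment, HPD intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from triadmix.inference import (
    BF_CAP,
    ModelPosterior,
    NNSettings,
    abc_reject,
    bayes_factor_min,
    estimate_parameters_nn,
    hpd_interval,
    model_posterior_mnlogistic,
    model_posterior_rejection,
    weighted_median,
)
from triadmix.models import ModelSpec, simulation_priors
from triadmix.simulate import ReferenceTable
from triadmix.sumstats import StatConfig

SC13 = StatConfig("means_only")


def _table(stats, models, params=None):
    df = pd.DataFrame(np.asarray(stats, dtype=float), columns=SC13.names)
    df.insert(0, "model", models)
    pnames = ()
    if params is not None:
        for k, v in params.items():
            df[k] = v
        pnames = tuple(params)
    return ReferenceTable(df, SC13, pnames, {})


def _noise_table(rng, n, models):
    per = n // len(models)
    stats = rng.normal(size=(per * len(models), 13))
    return _table(stats, np.repeat(models, per))


class TestRejection:
    @pytest.mark.parametrize(
        "n,tol,expect",
        [
            (1_400_000, 0.001, 1400),
            (200_000, 0.005, 1000),
            (2_000_000, 0.001, 2000),
            (999, 1.0, 999),
        ],
    )
    def test_retention_counts_exact(self, rng, n, tol, expect):
        table = _noise_table(rng, n, ["ISO"])
        acc = abc_reject(np.zeros(13), table, tol)
        assert len(acc) == expect

    def test_full_tolerance_orders_by_distance(self, rng):
        table = _noise_table(rng, 200, ["ISO"])
        acc = abc_reject(np.zeros(13), table, 1.0)
        assert (np.diff(acc.distances) >= 0).all()

    def test_scale_invariance(self, rng):
        """Multiplying a statistic column (table + observed) by a
        positive constant changes nothing downstream."""
        table = _noise_table(rng, 2000, ["A", "B"])
        obs = rng.normal(size=13)
        acc1 = abc_reject(obs, table, 0.05)
        scaled = table.df.copy()
        scaled[SC13.names[0]] *= 1000.0
        table2 = ReferenceTable(scaled, SC13, (), {})
        obs2 = obs.copy()
        obs2[0] *= 1000.0
        acc2 = abc_reject(obs2, table2, 0.05)
        np.testing.assert_array_equal(acc1.indices, acc2.indices)
        np.testing.assert_allclose(acc1.weights, acc2.weights)
        p1 = model_posterior_rejection(acc1, table)
        p2 = model_posterior_rejection(acc2, table2)
        assert p1.probs == p2.probs

    def test_weights_nonnegative_and_bounded(self, rng):
        acc = abc_reject(np.zeros(13), _noise_table(rng, 1000, ["ISO"]), 0.1)
        assert (acc.weights >= 0).all() and (acc.weights <= 1).all()

    def test_bad_inputs(self, rng):
        table = _noise_table(rng, 100, ["ISO"])
        with pytest.raises(ValueError):
            abc_reject(np.zeros(13), table, 0.0)
        with pytest.raises(ValueError):
            abc_reject(np.zeros(12), table, 0.5)


class TestModelPosteriors:
    def test_rejection_frequency_definition(self, rng):
        table = _noise_table(rng, 700, list("ABCDEF") + ["ISO"])
        acc = abc_reject(np.zeros(13), table, 1.0)
        post = model_posterior_rejection(acc, table)
        assert sum(post.probs.values()) == pytest.approx(1.0)
        np.testing.assert_allclose(list(post.probs.values()), 1 / 7, atol=1e-12)

    def test_separated_model_dominates(self, rng):
        """A model whose statistics sit far from the rest receives
        nearly all posterior mass at its own centroid."""
        per = 300
        stats = rng.normal(size=(7 * per, 13))
        stats[:per] += 50.0
        models = np.repeat(list("ABCDEF") + ["ISO"], per)
        table = _table(stats, models)
        centroid = np.zeros(13) + 50.0
        acc = abc_reject(centroid, table, 0.05)
        post = model_posterior_rejection(acc, table)
        assert post.probs["A"] > 0.95
        post_mn = model_posterior_mnlogistic(centroid, table, 0.3)
        assert post_mn.probs["A"] > 0.95
        assert post_mn.best() == "A"

    def test_mnlogistic_separable_two_model_toy(self, rng):
        stats = rng.normal(size=(1000, 13))
        stats[:500, 0] += 8.0
        table = _table(stats, np.repeat(["A", "B"], 500))
        obs = np.zeros(13)
        obs[0] = 8.0
        post = model_posterior_mnlogistic(obs, table, 0.5)
        assert post.probs["A"] > 0.99

    def test_mnlogistic_noise_is_uninformative(self, rng):
        """Statistics independent of the label: averaged over 100
        observed draws, each model's probability is within 0.05 of
        1/7."""
        table = _noise_table(rng, 7000, list("ABCDEF") + ["ISO"])
        probs = np.zeros(7)
        for _ in range(100):
            obs = rng.normal(size=13)
            post = model_posterior_mnlogistic(obs, table, 0.1)
            probs += np.array([post.probs[m] for m in table.models])
        probs /= 100
        np.testing.assert_allclose(probs, 1 / 7, atol=0.05)

    def test_mnlogistic_agrees_with_rejection_when_separated(self, rng):
        """On a well-separated toy problem the two model-choice routes
        agree within 0.1 per model."""
        per = 400
        stats = rng.normal(size=(3 * per, 13))
        stats[per : 2 * per, 1] += 12.0
        stats[2 * per :, 2] += 12.0
        table = _table(stats, np.repeat(["A", "B", "C"], per))
        obs = np.zeros(13)
        obs[1] = 12.0
        rej = model_posterior_rejection(abc_reject(obs, table, 0.02), table)
        # wider tolerance so competing models appear in the regression
        mn = model_posterior_mnlogistic(obs, table, 0.6)
        for m in table.models:
            assert abs(rej.probs[m] - mn.probs[m]) < 0.1

    def test_single_model_accepted_rejected(self, rng):
        stats = rng.normal(size=(200, 13))
        stats[:100] += 100
        table = _table(stats, np.repeat(["A", "B"], 100))
        with pytest.raises(ValueError, match="fewer than two"):
            model_posterior_mnlogistic(np.full(13, 100.0), table, 0.05)


class TestBayesFactor:
    def test_examples(self):
        post = ModelPosterior(
            {"A": 0.8, "B": 0.1, "C": 0.1}, "rejection", 0.1
        )
        assert bayes_factor_min(post, "A") == pytest.approx(8.0)
        uniform = ModelPosterior(
            {m: 1 / 7 for m in "ABCDEFG"}, "rejection", 0.1
        )
        assert bayes_factor_min(uniform, "A") == pytest.approx(1.0)

    def test_strong_support_threshold(self):
        post = ModelPosterior(
            {"A": 11 / 12, "B": 1 / 12, "C": 0.0}, "rejection", 0.1
        )
        assert bayes_factor_min(post, "A") == pytest.approx(11.0)
        assert bayes_factor_min(post, "A") > 10

    def test_zero_competitor_capped(self):
        post = ModelPosterior({"A": 1.0, "B": 0.0}, "rejection", 0.1)
        assert bayes_factor_min(post, "A") == BF_CAP

    def test_unknown_model(self):
        post = ModelPosterior({"A": 0.5, "B": 0.5}, "rejection", 0.1)
        with pytest.raises(KeyError):
            bayes_factor_min(post, "Z")


class TestHPD:
    def test_uniform_closed_form(self, rng):
        x = rng.uniform(0, 1, 100_000)
        lo, hi = hpd_interval(x, mass=0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_normal_closed_form(self, rng):
        x = rng.normal(size=100_000)
        lo, hi = hpd_interval(x, mass=0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_point_mass(self):
        lo, hi = hpd_interval(np.full(10, 3.2))
        assert (lo, hi) == (3.2, 3.2)

    def test_weighted_mass_respected(self, rng):
        """Weights proportional to a density concentrate the interval:
        uniform draws weighted by a normal density recover the normal's
        interval."""
        x = rng.uniform(-5, 5, 200_000)
        w = sps.norm.pdf(x)
        lo, hi = hpd_interval(x, w, mass=0.95)
        assert lo == pytest.approx(-1.96, abs=0.08)
        assert hi == pytest.approx(1.96, abs=0.08)

    def test_shortest_interval_asymmetric(self, rng):
        """For a right-skewed distribution the HPD is shorter than the
        equal-tailed interval."""
        x = rng.exponential(size=100_000)
        lo, hi = hpd_interval(x, mass=0.95)
        eq = np.quantile(x, [0.025, 0.975])
        assert hi - lo < eq[1] - eq[0]
        assert lo == pytest.approx(0.0, abs=0.01)

    def test_weighted_median(self):
        assert weighted_median(np.array([1.0, 2.0, 10.0]), np.array([1, 1, 4.0])) == 10.0
        assert weighted_median(np.array([1.0, 2.0, 3.0])) == 2.0


class TestNNEstimation:
    def _theta_table(self, rng, n=5000, noise=1e-3):
        theta = rng.uniform(0.007, 0.35, n)
        stats = rng.normal(size=(n, 13))
        stats[:, 0] = theta + rng.normal(0, noise, n)
        return _table(
            stats,
            ["ISO"] * n,
            params={
                "theta_S": theta,
                "T1": rng.uniform(0.4, 1.0, n),
                "T2": rng.uniform(1.0, 4.0, n),
            },
        )

    def test_identity_map_recovered(self, rng):
        """When statistic 1 equals theta (plus tiny noise) the adjusted
        posterior median lands within 2% of the observed statistic."""
        table = self._theta_table(rng)
        pri = simulation_priors()
        obs = rng.normal(size=13)
        obs[0] = 0.2
        post = estimate_parameters_nn(
            obs, table, 0.2, pri, model=ModelSpec("ISO"), seed=5
        )
        assert post.point["theta_S"] == pytest.approx(0.2, rel=0.02)

    def test_adjusted_samples_inside_prior_support(self, rng):
        table = self._theta_table(rng, n=2000)
        pri = simulation_priors()
        obs = rng.normal(size=13)
        obs[0] = 0.34  # near the upper prior bound
        post = estimate_parameters_nn(
            obs, table, 0.25, pri, model=ModelSpec("ISO"), seed=2
        )
        assert post.samples["theta_S"].between(0.007, 0.35).all()
        assert post.samples["T1"].between(0.4, 1.0).all()
        assert post.samples["T2"].between(1.0, 4.0).all()

    def test_noise_statistics_return_the_prior(self, rng):
        """Pure-noise statistics: the adjusted posterior matches the
        prior (two-sample KS at alpha=0.01; at most 2 rejections in 20
        seeded repeats across all parameters)."""
        pri = simulation_priors()
        rejections = 0
        tests = 0
        for rep in range(20):
            r = np.random.default_rng(100 + rep)
            n = 3000
            table = _table(
                r.normal(size=(n, 13)),
                ["ISO"] * n,
                params={
                    "theta_S": r.uniform(0.007, 0.35, n),
                    "T1": r.uniform(0.4, 1.0, n),
                    "T2": r.uniform(1.0, 4.0, n),
                },
            )
            obs = r.normal(size=13)
            post = estimate_parameters_nn(
                obs, table, 1000 / n, pri, model=ModelSpec("ISO"), seed=rep
            )
            for name, (a, b) in (
                ("theta_S", (0.007, 0.35)),
                ("T1", (0.4, 1.0)),
                ("T2", (1.0, 4.0)),
            ):
                prior_sample = r.uniform(a, b, 2000)
                pv = sps.ks_2samp(post.samples[name], prior_sample).pvalue
                tests += 1
                rejections += pv < 0.01
        assert tests == 60
        assert rejections <= 2

    def test_reproducible_given_seed(self, rng):
        table = self._theta_table(rng, n=1500)
        pri = simulation_priors()
        obs = rng.normal(size=13)
        obs[0] = 0.1
        a = estimate_parameters_nn(obs, table, 0.2, pri, model=ModelSpec("ISO"), seed=3)
        b = estimate_parameters_nn(obs, table, 0.2, pri, model=ModelSpec("ISO"), seed=3)
        assert a.samples.equals(b.samples)
        assert a.point == b.point

    def test_accepted_floor_enforced(self, rng):
        table = self._theta_table(rng, n=1000)
        pri = simulation_priors()
        with pytest.raises(ValueError, match="floor"):
            estimate_parameters_nn(
                np.zeros(13), table, 0.01, pri, model=ModelSpec("ISO"), seed=1
            )
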