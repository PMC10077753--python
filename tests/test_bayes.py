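"""Posterior machinery: priors, MCMC, Rhat, summaries, return rates."""

import numpy as np
import pandas as pd
import pytest

from reprorsf.bayes import (
    Posterior,
    PriorSpec,
    adjusted_return,
    coefficient_trajectory,
    fit_mortality_model,
    log_posterior,
    overlap_with_pre,
    rhat,
    run_mcmc,
    summarize,
    summary_table,
)
from reprorsf.model import ModelSpec, fit_ml, neg_log_likelihood


def logistic_table(rng, n=3000, beta=(0.8, -0.5), beta0=-1.0):
    X = rng.normal(size=(n, 2))
    eta = beta0 + X @ np.array(beta)
    case = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame({"a": X[:, 0], "b": X[:, 1], "case": case, "lamb": 0,
                         "part": 0.0})


class TestPriorSpec:
    def test_precision_reading_gives_variance_ten(self):
        assert PriorSpec().beta_var == pytest.approx(10.0)

    def test_variance_and_sd_readings(self):
        assert PriorSpec(beta_spread=0.1, beta_spread_kind="variance").beta_var == 0.1
        assert PriorSpec(beta_spread=2.0, beta_spread_kind="sd").beta_var == 4.0

    def test_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(beta_spread=-1)
        with pytest.raises(ValueError):
            PriorSpec(sigma_lower=60, sigma_upper=1)


class TestLogPosterior:
    spec = ModelSpec(("a",), ("a",))
    priors = PriorSpec()

    def table(self, rng):
        t = logistic_table(rng, n=50)
        t["lamb"] = 1
        t["part"] = 10.0
        return t

    def test_sigma_outside_support_is_minus_inf(self, rng):
        t = self.table(rng)
        # order: beta0, beta_a, gamma_a, sigma_a
        assert log_posterior([0, 0, 0, 0.5], t, self.spec, self.priors) == -np.inf
        assert log_posterior([0, 0, 0, 61.0], t, self.spec, self.priors) == -np.inf

    def test_flat_prior_limit_tracks_likelihood(self, rng):
        t = self.table(rng)
        vague = PriorSpec(beta_spread=1e-8, beta_spread_kind="precision")
        t1 = [0.1, 0.2, 0.3, 20.0]
        t2 = [-0.4, 0.8, -0.2, 35.0]
        names = ["beta0", "beta_a", "gamma_a", "sigma_a"]
        d1 = log_posterior(t1, t, self.spec, vague) - log_posterior(t2, t, self.spec, vague)
        n1 = -neg_log_likelihood(dict(zip(names, t1)), t, self.spec) + neg_log_likelihood(
            dict(zip(names, t2)), t, self.spec
        )
        assert d1 == pytest.approx(n1, abs=1e-6)

    def test_matches_hand_summed_density_terms(self, rng):
        t = self.table(rng)
        theta = [0.3, -0.2, 0.5, 12.0]
        names = ["beta0", "beta_a", "gamma_a", "sigma_a"]
        var = self.priors.beta_var
        want = -neg_log_likelihood(dict(zip(names, theta)), t, self.spec)
        for v in theta[:3]:
            want += -0.5 * v**2 / var - 0.5 * np.log(2 * np.pi * var)
        want += -np.log(60.0 - 1.0)
        assert log_posterior(theta, t, self.spec, self.priors) == pytest.approx(want, abs=1e-9)


class TestRhat:
    def test_identical_chains_score_one(self, rng):
        x = rng.normal(size=2000)
        chains = np.stack([x, x, x])
        assert rhat(chains) == pytest.approx(1.0, abs=1e-3)

    def test_shifted_chain_diverges(self, rng):
        a = rng.normal(size=(1, 500))
        chains = np.concatenate([a, a + 10.0])
        assert rhat(chains) > 1.1

    def test_matches_direct_between_within_formula(self, rng):
        x = rng.normal(size=(4, 300))
        m, n = x.shape
        means = x.mean(axis=1)
        W = np.mean([np.var(x[i], ddof=1) for i in range(m)])
        B = n * np.var(means, ddof=1)
        want = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert rhat(x) == pytest.approx(want, abs=1e-12)

    def test_constant_chains_flagged(self):
        assert rhat(np.ones((3, 100))) == np.inf

    def test_requires_two_chains(self, rng):
        with pytest.raises(ValueError):
            rhat(rng.normal(size=(1, 100)))


class TestSummarize:
    def test_symmetric_draws_split_fifty_fifty(self):
        s = np.tile([-1.0, 1.0], 200)
        row = summarize(s, "x", "Pre")
        assert row.prob_gt0 == 50.0 and row.prob_lt0 == 50.0

    def test_all_positive_draws(self):
        row = summarize(np.abs(np.random.default_rng(0).normal(size=500)) + 0.01, "x")
        assert row.prob_gt0 == 100.0 and row.prob_lt0 == 0.0

    def test_sign_probabilities_always_total_hundred(self, rng):
        s = np.r_[rng.normal(size=300), np.zeros(10)]
        row = summarize(s, "x")
        assert row.prob_gt0 + row.prob_lt0 == pytest.approx(100.0)

    def test_quantiles_match_sorted_array_oracle(self, rng):
        s = rng.normal(size=4001)
        row = summarize(s, "x")
        srt = np.sort(s)

        def q(p):  # linear-interpolation quantile on the sorted array
            h = (len(srt) - 1) * p
            lo = int(np.floor(h))
            return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])

        assert row.q025 == pytest.approx(q(0.025), abs=1e-12)
        assert row.q975 == pytest.approx(q(0.975), abs=1e-12)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize(np.arange(50.0), "x")


class TestOverlap:
    def test_identical_samples_give_full_overlap(self, rng):
        s = rng.normal(size=4000)
        assert overlap_with_pre(s, s) == pytest.approx(100.0, abs=1.5)

    def test_disjoint_supports_give_zero(self, rng):
        a = rng.uniform(0, 1, 2000)
        b = rng.uniform(100, 101, 2000)
        assert overlap_with_pre(a, b) == pytest.approx(0.0, abs=0.5)

    def test_half_shifted_uniforms_match_analytic_ovl(self, rng):
        # U(0,2) vs U(1,3): overlapping coefficient is exactly 50%
        a = rng.uniform(0, 2, 20000)
        b = rng.uniform(1, 3, 20000)
        assert overlap_with_pre(a, b) == pytest.approx(50.0, abs=5.0)

    def test_symmetry_of_ovl(self, rng):
        a = rng.normal(0, 1, 3000)
        b = rng.normal(1, 1.5, 3000)
        assert overlap_with_pre(a, b) == pytest.approx(overlap_with_pre(b, a), abs=1e-9)

    def test_cri_method_and_validation(self, rng):
        a = rng.normal(size=2000)
        assert overlap_with_pre(a, a, method="cri") == pytest.approx(95.0, abs=2.0)
        with pytest.raises(ValueError):
            overlap_with_pre(np.ones(100), a)
        with pytest.raises(ValueError):
            overlap_with_pre(a, a, method="nope")


class TestAdjustedReturn:
    # printed posterior-mean scales and the tabulated doubled return times
    @pytest.mark.parametrize(
        "mean,doubled",
        [(54.092, 108.184), (5.720, 11.440), (2.246, 4.492), (26.460, 52.921)],
    )
    def test_doubling_reproduces_tabulated_rows(self, mean, doubled):
        assert adjusted_return(mean) == pytest.approx(doubled, abs=1e-3)

    def test_exact_linearity_and_zero(self):
        assert adjusted_return(0.0) == 0.0
        a, s = 3.7, 12.3
        assert adjusted_return(a * s) == pytest.approx(a * adjusted_return(s))

    def test_mapping_input_and_negative_rejected(self):
        out = adjusted_return({"mean": 10.0, "q025": 5.0})
        assert out == {"mean": 20.0, "q025": 10.0}
        with pytest.raises(ValueError):
            adjusted_return(-1.0)


@pytest.fixture(scope="module")
def small_posterior():
    """Well-mixed posterior on a small simulated logistic dataset."""
    rng = np.random.default_rng(31)
    t = logistic_table(rng, n=2500)
    spec = ModelSpec(("a", "b"))
    ml = fit_ml(t, spec)
    post = run_mcmc(t, spec, iters=1500, burnin=400, chains=3, seed=5, ml_init=ml)
    return t, spec, ml, post


class TestRunMcmc:
    def test_posterior_means_agree_with_ml(self, small_posterior):
        _, spec, ml, post = small_posterior
        for name in spec.param_names:
            draws = post.samples(name)
            assert abs(draws.mean() - ml.params[name]) < 2 * draws.std()

    def test_well_mixed_chains_converge(self, small_posterior):
        *_, post = small_posterior
        assert max(post.rhat().values()) < 1.05

    def test_same_master_seed_reproduces_chains(self, small_posterior):
        t, spec, ml, post = small_posterior
        again = run_mcmc(t, spec, iters=1500, burnin=400, chains=3, seed=5, ml_init=ml)
        np.testing.assert_array_equal(post.draws, again.draws)

    def test_draws_shape_and_burnin(self, small_posterior):
        *_, post = small_posterior
        assert post.draws.shape == (3, 1500, 3)
        assert post.kept.shape == (3, 1100, 3)

    def test_long_format_export_round_trips(self, small_posterior):
        *_, post = small_posterior
        df = post.to_dataframe()
        assert len(df) == 3 * 1500 * 3
        v = df[(df["chain"] == 1) & (df["parameter"] == "beta_a")]["value"].to_numpy()
        np.testing.assert_array_equal(v, post.draws[1, :, 1])


class TestTrajectory:
    @pytest.fixture()
    def tv_posterior(self):
        spec = ModelSpec(("a",), ("a",))
        rng = np.random.default_rng(8)
        n = 600
        draws = np.stack(
            [
                np.column_stack(
                    [
                        rng.normal(-2, 0.05, n),
                        rng.normal(0.5, 0.05, n),
                        rng.normal(1.0, 0.1, n),
                        rng.uniform(15, 25, n),
                    ]
                )
                for _ in range(2)
            ]
        )
        return Posterior(draws, list(spec.param_names), 100, 0, spec)

    def test_day_zero_median_is_base_plus_gamma(self, tv_posterior):
        traj = coefficient_trajectory(tv_posterior)
        day0 = traj[(traj["day"] == 0)].iloc[0]
        b = tv_posterior.samples("beta_a")
        g = tv_posterior.samples("gamma_a")
        assert day0["median"] == pytest.approx(float(np.median(b + g)), abs=1e-12)

    def test_baseline_column_and_long_time_limit(self, tv_posterior):
        traj = coefficient_trajectory(tv_posterior)
        base = traj[traj["day"] == -1].iloc[0]["median"]
        last = traj[traj["day"] == 120].iloc[0]["median"]
        assert base == pytest.approx(0.5, abs=0.02)
        assert last == pytest.approx(base, abs=0.02)

    def test_monotone_approach_per_day(self, tv_posterior):
        traj = coefficient_trajectory(tv_posterior)
        med = traj[traj["day"] >= 0].sort_values("day")["median"].to_numpy()
        dev = np.abs(med - med[-1])
        assert (np.diff(dev) <= 1e-6).all()


class TestSummaryTable:
    def test_pre_and_pp_rows_with_overlap(self, small_posterior):
        *_, post = small_posterior
        spec_tv = ModelSpec(("a",), ("a",))
        rng = np.random.default_rng(9)
        n = 500
        draws = np.stack(
            [
                np.column_stack(
                    [rng.normal(0, .05, n), rng.normal(0.5, .05, n),
                     rng.normal(1.0, .05, n), rng.uniform(10, 30, n)]
                )
                for _ in range(2)
            ]
        )
        p = Posterior(draws, list(spec_tv.param_names), 50, 0, spec_tv)
        t1 = summary_table(p)
        assert list(t1["Parameter"]) == ["Pre a", "PP a"]
        pp = t1.iloc[1]
        assert pp["Mean"] == pytest.approx(1.5, abs=0.05)
        assert pp["Overlap with Pre"] < 5.0  # distributions ~10 SDs apart


class TestMortalityModel:
    def build_table(self, rng, shift, n=2500):
        """Pre rows select with beta 0.6; AD rows with beta 0.6 + shift."""
        rows = []
        for state, beta in (("pre", 0.6), ("ad", 0.6 + shift)):
            x = rng.normal(size=n)
            eta = -1.5 + beta * x
            case = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            rows.append(pd.DataFrame({"elev": x, "case": case, "state": state}))
        return pd.concat(rows, ignore_index=True)

    def test_null_shift_gives_high_overlap(self, rng):
        t = self.build_table(rng, 0.0)
        res = fit_mortality_model(t, ["elev"], iters=1200, burnin=300, chains=2, seed=3)
        ad = res["summary"].iloc[1]
        assert ad["Overlap with Pre"] > 30.0
        pre = res["summary"].iloc[0]
        assert not (ad["Lower 95% CI"] > pre["Upper 95% CI"]
                    or ad["Upper 95% CI"] < pre["Lower 95% CI"])

    def test_unit_shift_detected(self, rng):
        t = self.build_table(rng, 1.0)
        res = fit_mortality_model(t, ["elev"], iters=1200, burnin=300, chains=2, seed=4)
        post = res["posterior"]
        contrast = post.samples("beta_elev__ad") - post.samples("beta_elev__pre")
        assert 100.0 * np.mean(contrast > 0) > 99.0

    def test_model_is_time_constant(self, rng):
        t = self.build_table(rng, 0.5)
        res = fit_mortality_model(t, ["elev"], iters=400, burnin=100, chains=2, seed=5)
        names = res["posterior"].param_names
        assert not any(n.startswith(("gamma", "sigma")) for n in names)
        assert names[0] == "beta0"  # shared intercept

    def test_too_few_mortality_rows_aborts(self, rng):
        t = self.build_table(rng, 0.0, n=50)
        with pytest.raises(ValueError, match="too few"):
            fit_mortality_model(t, ["elev"], min_rows=200)
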