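import math

import numpy as np
import pytest
from scipy import stats

from datediag import (
    ClockModel,
    LineageCountCurve,
    alpha_posterior_sample,
    apply_clock,
    attach_dates,
    branch_logprob,
    clock_loglik,
    coalescent_loglik,
    conjugate_toy,
    dic,
    mcmc_date,
    ml_date,
    mle_alpha,
    mle_mu,
    parse_newick,
    posterior_residual_pvalues,
    pseudo_posterior,
    tree_residuals,
    uniform_residual,
)
from datediag.posterior import PosteriorSample
from datediag.simulate import sim_coalescent_constant, simulate_dataset, uniform_dates


def _two_tip_tree(delta=1.0):
    t = parse_newick(f"(A:{delta},B:{delta});", unit="years")
    return attach_dates(t, {"A": 2000.0, "B": 2000.0})


class TestCoalescentLoglik:
    def test_two_tips_unit_ne(self):
        assert coalescent_loglik(_two_tip_tree(1.0), 1.0) == pytest.approx(-1.0)

    def test_two_tips_ne_two(self):
        assert coalescent_loglik(_two_tip_tree(1.0), 2.0) == pytest.approx(
            -0.5 - math.log(2)
        )

    def test_against_interval_oracle(self, rng):
        """Matches a direct interval-by-interval recomputation."""
        D = sim_coalescent_constant(uniform_dates(50, 2000, 2020, rng), 2.0, rng)
        ne = 1.7
        events = sorted(
            [(float(D.dates[v]), v < D.n_tips) for v in range(D.n_nodes)],
            reverse=True,
        )
        k, ll = 0, 0.0
        for j, (t, is_tip) in enumerate(events):
            if j > 0:
                dt = events[j - 1][0] - t
                ll -= k * (k - 1) / 2.0 * dt / ne
            k += 1 if is_tip else -1
            if not is_tip:
                ll -= math.log(ne)
        assert coalescent_loglik(D, ne) == pytest.approx(ll, abs=1e-10)

    def test_lineage_curve_counts(self):
        D = _two_tip_tree(1.0)
        curve = LineageCountCurve.from_tree(D)
        assert curve.n_tips == 2
        assert curve.pair_time == pytest.approx(2.0)


class TestClockLoglik:
    def test_doubling_mu_decreases_at_mode(self, rng):
        D = sim_coalescent_constant(uniform_dates(30, 2010, 2020, rng), 1.0, rng)
        L = apply_clock(D, ClockModel("poisson", 10.0), rng)
        mu_hat = mle_mu(L, D)
        base = clock_loglik(D, L, ClockModel("poisson", mu_hat))
        assert clock_loglik(D, L, ClockModel("poisson", 2 * mu_hat)) < base
        assert clock_loglik(D, L, ClockModel("poisson", 0.5 * mu_hat)) < base

    def test_two_tip_reduces_to_branch_terms(self):
        D = _two_tip_tree(1.0)
        L = parse_newick("(A:7,B:13);")
        m = ClockModel("gamma", 10.0)
        # root split of l_x=20 over equal durations gives 10 and 10
        expected = 2 * branch_logprob(m, 10.0, 1.0)
        assert clock_loglik(D, L, m) == pytest.approx(expected)


class TestEstimators:
    def test_mle_mu_arithmetic(self):
        D = attach_dates(
            parse_newick("(A:1,B:2);", unit="years"), {"A": 2011.0, "B": 2012.0}
        )
        L = parse_newick("(A:10,B:20);")
        assert mle_mu(L, D) == pytest.approx(10.0)

    def test_mle_mu_zero_substitutions(self):
        D = attach_dates(
            parse_newick("(A:1,B:2);", unit="years"), {"A": 2011.0, "B": 2012.0}
        )
        L = parse_newick("(A:0,B:0);")
        assert mle_mu(L, D) == 0.0

    def test_mle_mu_matches_grid_argmax(self, rng):
        D = sim_coalescent_constant(uniform_dates(20, 2010, 2020, rng), 1.0, rng)
        L = apply_clock(D, ClockModel("poisson", 10.0), rng)
        mu_hat = mle_mu(L, D)
        grid = np.linspace(0.5 * mu_hat, 2 * mu_hat, 401)
        lls = [clock_loglik(D, L, ClockModel("poisson", g)) for g in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(mu_hat, rel=0.01)

    @pytest.mark.parametrize("delta,expected", [(1.0, 1.0), (3.0, 3.0)])
    def test_mle_alpha_two_tips(self, delta, expected):
        assert mle_alpha(_two_tip_tree(delta)) == pytest.approx(expected)

    def test_mle_alpha_matches_grid_argmax(self, rng):
        for _ in range(10):
            D = sim_coalescent_constant(uniform_dates(15, 2010, 2020, rng), 1.0, rng)
            a_hat = mle_alpha(D)
            grid = np.linspace(0.5 * a_hat, 2 * a_hat, 301)
            lls = [coalescent_loglik(D, g) for g in grid]
            assert grid[int(np.argmax(lls))] == pytest.approx(a_hat, rel=0.01)


class TestAlphaPosterior:
    def test_two_tip_median_closed_form(self, rng):
        """alpha ~ InvGamma(1, 1): the median is 1/ln 2."""
        D = _two_tip_tree(1.0)
        draws = alpha_posterior_sample(D, rng, size=200_000)
        assert np.median(draws) == pytest.approx(1 / math.log(2), rel=0.02)

    def test_concentrates_with_more_tips(self, rng):
        def rel_iqr(n):
            vals = []
            for _ in range(10):
                D = sim_coalescent_constant(uniform_dates(n, 2010, 2020, rng), 1.0, rng)
                d = alpha_posterior_sample(D, rng, size=2_000)
                vals.append((np.quantile(d, 0.75) - np.quantile(d, 0.25)) / np.median(d))
            return np.mean(vals)

        assert rel_iqr(80) < rel_iqr(10)

    def test_deterministic_under_seed(self):
        D = _two_tip_tree(1.0)
        a = alpha_posterior_sample(D, np.random.default_rng(5), size=10)
        b = alpha_posterior_sample(D, np.random.default_rng(5), size=10)
        np.testing.assert_array_equal(a, b)


class TestConjugateToy:
    def test_worked_example(self):
        assert conjugate_toy(2, 2, 1, 3) == pytest.approx((5, 2 / 3))

    def test_zero_count(self):
        assert conjugate_toy(2, 2, 1, 0) == pytest.approx((2, 2 / 3))

    def test_posterior_resampling_restores_calibration(self, rng):
        """Residuals against posterior-resampled durations are Uniform(0,1);
        residuals against the ML durations d = l/mu are underdispersed."""
        k, theta, mu, n = 2.0, 2.0, 1.0, 100_000
        d = rng.gamma(shape=k, scale=theta, size=n)
        l = rng.poisson(d * mu)
        shape = k + l
        scale = theta / (1 + theta * mu)
        d_post = rng.gamma(shape=shape, scale=scale)
        m = ClockModel("poisson", mu)
        u_post = uniform_residual(m, l, d_post, rng)
        assert stats.kstest(u_post, "uniform").pvalue > 1e-3
        # ML plug-in: underdispersed normal residuals
        d_ml = np.maximum(l / mu, 1e-9)
        u_ml = uniform_residual(m, l, d_ml, rng)
        from scipy.special import ndtri

        assert np.var(ndtri(u_ml)) < 0.8


class TestMCMC:
    def test_deterministic_under_seed(self):
        data = simulate_dataset("constant", np.random.default_rng(70), n=20)
        kw = dict(iters=4_000, thin_to=20)
        a = mcmc_date(data["undated"], data["dates"], ClockModel("poisson", 10.0),
                      rng=np.random.default_rng(8), **kw)
        b = mcmc_date(data["undated"], data["dates"], ClockModel("poisson", 10.0),
                      rng=np.random.default_rng(8), **kw)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.trees[-1].dates, b.trees[-1].dates)

    def test_fixed_parameters_still_mixes(self):
        data = simulate_dataset("constant", np.random.default_rng(71), n=40)
        truth = data["truth"]
        post = mcmc_date(
            data["undated"], data["dates"], ClockModel("poisson", truth["mu"]),
            iters=30_000, thin_to=200, rng=np.random.default_rng(9),
            fixed={"mu": truth["mu"], "ne": truth["ne"],
                   "root_date": truth["root_date"] - 0.5},
        )
        assert np.all(post.mu == truth["mu"])
        internal_dates = np.array([t.dates[t.n_tips] for t in post.trees])
        assert internal_dates.std() > 0  # internal dates explored
        pv = posterior_residual_pvalues(post, data["undated"],
                                        np.random.default_rng(10), max_draws=100)
        assert pv.median > 0.05

    def test_mu_recovery(self):
        data = simulate_dataset("constant", np.random.default_rng(72), n=100)
        post = mcmc_date(data["undated"], data["dates"], ClockModel("poisson", 10.0),
                         iters=60_000, thin_to=300, rng=np.random.default_rng(11))
        assert post.mu.mean() == pytest.approx(10.0, rel=0.2)
        lo, hi = np.quantile(post.mu, [0.025, 0.975])
        assert lo < 12 and hi > 8

    def test_three_tip_grid_posterior(self):
        """Root-date posterior matches a fine-grid numerical posterior
        (total variation < 0.05) on a fixed-parameter 3-tip problem."""
        L = parse_newick("((A:6,B:4):5,C:12);")
        dates = {"A": 2010.0, "B": 2010.0, "C": 2010.0}
        mu, ne = 10.0, 1.0
        post = mcmc_date(L, dates, ClockModel("poisson", mu), iters=200_000,
                         thin_to=2_000, rng=np.random.default_rng(12),
                         fixed={"mu": mu, "ne": ne})
        roots = np.array([t.dates[t.root] for t in post.trees])
        # numerical posterior over (t_root, t_ab)
        t0 = np.linspace(2004, 2010 - 1e-6, 220)  # root date
        t1 = np.linspace(2004, 2010 - 1e-6, 221)  # (A,B) ancestor date
        T0, T1 = np.meshgrid(t0, t1, indexing="ij")
        valid = T1 >= T0
        d_ab = np.maximum(T1 - T0, 1e-12)
        d_c = np.maximum(2010.0 - T0, 1e-12)
        d_tip = np.maximum(2010.0 - T1, 1e-12)
        # tip branches: Poisson counts; root pair: l_x = 5 + 12 = 17 split
        # proportionally over (d_ab, d_c) and scored by the same-moment Gamma
        split_ab = 17.0 * d_ab / (d_ab + d_c)
        split_c = 17.0 - split_ab
        logp = (
            stats.poisson.logpmf(6, d_tip * mu)
            + stats.poisson.logpmf(4, d_tip * mu)
            + stats.gamma.logpdf(split_ab, a=d_ab * mu)
            + stats.gamma.logpdf(split_c, a=d_c * mu)
        )
        # coalescent: k=3 on (t1, 2010), k=2 on (t0, t1), two 1/Ne factors
        logp = logp + (
            -(3 * 2 / 2) * (2010.0 - T1) / ne - (2 * 1 / 2) * (T1 - T0) / ne
            - 2 * math.log(ne)
        )
        w = np.where(valid, np.exp(logp - logp[valid].max()), 0.0)
        marg = w.sum(axis=1)
        marg /= marg.sum()
        hist, edges = np.histogram(roots, bins=np.linspace(2004, 2010, 31),
                                   density=False)
        hist = hist / hist.sum()
        grid_bins = np.zeros(30)
        idx = np.clip(np.searchsorted(edges, t0) - 1, 0, 29)
        for i, b in enumerate(idx):
            grid_bins[b] += marg[i]
        tv = 0.5 * np.abs(hist - grid_bins).sum()
        assert tv < 0.05

    def test_split_root_substitutions_used(self):
        """The two root branches are scored on the duration-proportional split,
        so the sampler is invariant to how L's root branch lengths divide."""
        data = simulate_dataset("constant", np.random.default_rng(73), n=15)
        L = data["undated"]
        L2 = L.copy()
        a, b = L.children[L.root]
        tot = L.lengths[a] + L.lengths[b]
        L2.lengths[a], L2.lengths[b] = tot, 0.0
        kw = dict(iters=5_000, thin_to=20, fixed={"ne": 1.0, "mu": 10.0},
                  init_dates=data["dated"].dates)
        post1 = mcmc_date(L, data["dates"], ClockModel("poisson", 10.0),
                          rng=np.random.default_rng(13), **kw)
        post2 = mcmc_date(L2, data["dates"], ClockModel("poisson", 10.0),
                          rng=np.random.default_rng(13), **kw)
        np.testing.assert_allclose(
            [t.dates[t.root] for t in post1.trees],
            [t.dates[t.root] for t in post2.trees],
        )


class TestDIC:
    def test_degenerate_posterior(self):
        D = _two_tip_tree(1.0)
        post = PosteriorSample(
            trees=[D] * 60, mu=np.full(60, 1.0), ne=np.ones(60),
            loglik=np.full(60, -12.0), family="poisson",
        )
        assert dic(post) == pytest.approx(24.0)

    def test_too_few_draws_rejected(self):
        from datediag import ValidationError

        D = _two_tip_tree(1.0)
        post = PosteriorSample(trees=[D], mu=[1.0], ne=[1.0], loglik=[-1.0])
        with pytest.raises(ValidationError):
            dic(post)

    def test_relaxed_data_prefers_relaxed_model(self, relaxed_dataset):
        data = relaxed_dataset
        strict = mcmc_date(data["undated"], data["dates"], ClockModel("poisson", 10.0),
                           iters=40_000, thin_to=200, rng=np.random.default_rng(14))
        relaxed = mcmc_date(data["undated"], data["dates"],
                            ClockModel("negbin", 10.0, 5.0),
                            iters=40_000, thin_to=200, rng=np.random.default_rng(15))
        assert dic(relaxed) < dic(strict)


class TestPseudoPosterior:
    def test_centering_on_point_estimate(self, strict_dataset):
        data = strict_dataset
        Dhat, mfit = ml_date(data["undated"], data["dates"], ClockModel("poisson", 10.0))
        pp = pseudo_posterior(Dhat, data["undated"], model=mfit, iters=40_000,
                              thin_to=200, rng=np.random.default_rng(16))
        mean_dates = np.mean([t.dates for t in pp.trees], axis=0)
        height = max(data["dates"].values()) - Dhat.dates[Dhat.root]
        mad = np.abs(mean_dates - Dhat.dates).mean()
        assert mad < 0.05 * height

    def test_ml_tree_overfits_and_pseudo_restores(self, strict_dataset):
        data = strict_dataset
        L = data["undated"]
        Dhat, mfit = ml_date(L, data["dates"], ClockModel("poisson", 10.0))
        res = tree_residuals(Dhat, L, mfit, np.random.default_rng(17))
        pp = pseudo_posterior(Dhat, L, model=mfit, iters=60_000, thin_to=300,
                              rng=np.random.default_rng(18))
        pv = posterior_residual_pvalues(pp, L, np.random.default_rng(19), max_draws=300)
        # direct ML residuals fit worse than typical pseudo-posterior draws
        assert res.pvalue < pv.median
        assert pv.median > 0.05
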