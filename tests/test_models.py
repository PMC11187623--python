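"""Dose-response model fitting, BMD, profile limits, selection — vs oracles."""

import numpy as np
import pytest
from scipy import stats

from metabmd import models as M
from metabmd.design import DEFAULT_DESIGN
from metabmd.models import mean_function
from metabmd.synthetic import solve_params_for_bmd

DOSES = np.array(DEFAULT_DESIGN.sample_doses())


class TestFitModel:
    def test_exact_linear_data_interpolated(self):
        y = 10.0 + 0.02 * DOSES
        f = M.fit_model(y, DOSES, "linear")
        assert f.params["b0"] == pytest.approx(10.0, abs=1e-9)
        assert f.params["b1"] == pytest.approx(0.02, abs=1e-12)
        assert f.sigma == pytest.approx(0.0, abs=1e-9)

    def test_constant_data_gives_flat_fit(self):
        y = np.full_like(DOSES, 42.0)
        f = M.fit_model(y, DOSES, "linear")
        assert f.params["b1"] == pytest.approx(0.0, abs=1e-12)
        assert f.params["b0"] == pytest.approx(42.0)
        assert f.sigma == pytest.approx(0.0, abs=1e-10)
        # with noise around a constant, the linear fit can only improve on
        # the intercept-only likelihood
        rng = np.random.default_rng(20)
        y2 = 42.0 + rng.normal(0, 3, DOSES.size)
        f2 = M.fit_model(y2, DOSES, "linear")
        n = len(y2)
        rss0 = float(((y2 - y2.mean()) ** 2).sum())
        ll0 = -0.5 * n * (np.log(2 * np.pi * rss0 / n) + 1.0)
        assert f2.loglik >= ll0 - 1e-9

    def test_exp4_estimates_match_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        params = {"a": 100.0, "b": 0.01, "c": 0.4}
        design6 = DEFAULT_DESIGN.__class__(DEFAULT_DESIGN.doses, (6,) * 6)
        d = np.array(design6.sample_doses())
        mu = mean_function("exp4", params, d)
        y = mu * rng.lognormal(0, 0.1, d.size)
        f = M.fit_model(y, d, "exp4")
        # dense independent grid over the 3-parameter box
        best = (np.inf, None)
        for a in np.linspace(80, 120, 41):
            for b in np.geomspace(1e-3, 0.1, 41):
                for c in np.linspace(0.1, 0.9, 41):
                    m = a * (c - (c - 1) * np.exp(-b * d))
                    rss = float(((y - m) ** 2).sum())
                    if rss < best[0]:
                        best = (rss, (a, b, c))
        rss_fit = float(((y - f.mu(d)) ** 2).sum())
        assert rss_fit <= best[0] + 1e-6  # fit at least as good as the grid
        a, b, c = best[1]
        assert f.params["a"] == pytest.approx(a, rel=0.05)
        assert f.params["b"] == pytest.approx(b, rel=0.15)
        assert f.params["c"] == pytest.approx(c, rel=0.1)

    def test_aic_counts_mean_parameters_plus_sigma(self):
        rng = np.random.default_rng(0)
        y = 50 + 0.05 * DOSES + rng.normal(0, 3, DOSES.size)
        for fam in M.FAMILIES:
            f = M.fit_model(y, DOSES, fam)
            assert f.aic == pytest.approx(
                2 * (M.N_MEAN_PARAMS[fam] + 1) - 2 * f.loglik)

    def test_too_few_distinct_doses_refused(self):
        d = np.array([0.0, 0, 55, 55, 110, 110])
        with pytest.raises(ValueError, match="distinct doses"):
            M.fit_model(np.ones(6), d, "linear")


class TestComputeBmd:
    def test_linear_closed_form(self):
        f = M.ModelFit(family="linear", params={"b0": 1.0, "b1": 0.05},
                       sigma=2.5, loglik=0, aic=0, converged=True, n_obs=17,
                       n_mean_params=2)
        M.compute_bmd(f, 1.0, 881.0)
        assert f.bmd == pytest.approx(2.5 / 0.05)  # = 50.0

    def test_root_found_linear_bmd_matches_closed_form_to_1e10(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = 50 + rng.uniform(-0.1, 0.1) * DOSES + rng.normal(0, 4, DOSES.size)
            f = M.fit_model(y, DOSES, "linear")
            M.compute_bmd(f, 1.0, DOSES.max())
            closed = f.sigma / abs(f.params["b1"])
            # independent bracketed bisection on the fitted curve
            mu0 = f.params["b0"]
            g = lambda d: abs(f.params["b0"] + f.params["b1"] * d - mu0) - f.sigma
            lo, hi = 0.0, 10 * DOSES.max()
            if g(hi) < 0:
                assert f.bmd is None or f.bmd > DOSES.max()
                continue
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                lo, hi = (mid, hi) if g(mid) < 0 else (lo, mid)
            assert f.bmd == pytest.approx(closed, rel=1e-10)
            assert f.bmd == pytest.approx(0.5 * (lo + hi), rel=1e-9)

    def test_bmd_increases_with_bmr_for_monotone_curve(self):
        params = solve_params_for_bmd("exp4", 100.0, 5.0, 100.0, 8.0, 1)
        b1 = M.bmd_from_params("exp4", params, 5.0, 1.0, 881.0)
        b3 = M.bmd_from_params("exp4", params, 5.0, 3.0, 881.0)
        assert b3 > b1

    def test_exp2_bmd_matches_bisection_oracle(self):
        params = {"a": 100.0, "b": 0.001, "s": 1.0}
        got = M.bmd_from_params("exp2", params, 5.0, 1.0, 881.0)
        # 100*(e^{0.001 d} - 1) = 5
        lo, hi = 0.0, 8810.0
        f = lambda d: 100.0 * (np.exp(0.001 * d) - 1.0) - 5.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if f(mid) < 0 else (lo, mid)
        assert got == pytest.approx(0.5 * (lo + hi), rel=1e-8)

    def test_flat_curve_has_no_bmd(self):
        f = M.ModelFit(family="linear", params={"b0": 5.0, "b1": 0.0},
                       sigma=1.0, loglik=0, aic=0, converged=True, n_obs=17,
                       n_mean_params=2)
        M.compute_bmd(f, 1.0, 881.0)
        assert f.bmd is None

    def test_saturating_curve_below_bmr_undefined(self):
        # plateau departure 2*sigma can never reach a 3-SD benchmark
        params = solve_params_for_bmd("exp4", 100.0, 5.0, 100.0, 2.0, 1)
        assert M.bmd_from_params("exp4", params, 5.0, 3.0, 881.0) is None


class TestProfileLimits:
    def test_interval_collapses_in_low_noise_limit(self):
        rng = np.random.default_rng(1)
        y = 100 + 0.1 * DOSES + rng.normal(0, 1e-4, DOSES.size)
        f = M.fit_model(y, DOSES, "linear")
        M.compute_bmd(f, 1.0, DOSES.max())
        M.profile_bmdl_bmdu(f, y, DOSES)
        assert f.bmdl == pytest.approx(f.bmd, rel=0.35)
        assert f.bmdu == pytest.approx(f.bmd, rel=0.45)
        assert f.bmdl <= f.bmd <= f.bmdu

    def test_linear_profile_matches_grid_oracle(self):
        rng = np.random.default_rng(7)
        sigma, b1 = 4.0, 0.04
        y = 50 + b1 * DOSES + rng.normal(0, sigma, DOSES.size)
        f = M.fit_model(y, DOSES, "linear")
        M.compute_bmd(f, 1.0, DOSES.max())
        M.profile_bmdl_bmdu(f, y, DOSES)

        # independent dense-grid profile: for pinned BMD b, sigma = |b1|*b,
        # maximize the normal log-likelihood over (b0, b1) on a fine grid
        n = len(y)

        def profile_ll(bmd):
            best = -np.inf
            for b0 in np.linspace(40, 60, 120):
                for b1g in np.concatenate([np.linspace(-0.1, -1e-4, 150),
                                           np.linspace(1e-4, 0.1, 150)]):
                    s = abs(b1g) * bmd
                    rss = float(((y - b0 - b1g * DOSES) ** 2).sum())
                    ll = -0.5 * n * np.log(2 * np.pi * s * s) - rss / (2 * s * s)
                    best = max(best, ll)
            return best

        cut = stats.chi2.ppf(0.90, 1)
        for bound in (f.bmdl, f.bmdu):
            # at the reported bound the profile deviance equals the cutoff
            dev = 2.0 * (f.loglik - profile_ll(bound))
            assert dev == pytest.approx(cut, abs=0.12)

    def test_bmdl_monotone_in_confidence(self):
        rng = np.random.default_rng(9)
        y = 50 + 0.05 * DOSES + rng.normal(0, 4, DOSES.size)
        f = M.fit_model(y, DOSES, "linear")
        M.compute_bmd(f, 1.0, DOSES.max())
        bounds = []
        for conf in (0.90, 0.95, 0.99):
            g = M.fit_model(y, DOSES, "linear")
            M.compute_bmd(g, 1.0, DOSES.max())
            M.profile_bmdl_bmdu(g, y, DOSES, confidence=conf, sides=("lower",))
            bounds.append(g.bmdl)
        assert bounds[0] >= bounds[1] >= bounds[2]


class TestFitPValue:
    def test_perfect_fit_gives_p_one(self):
        group_means = {0: 10.0, 55: 12, 110: 14, 220: 18, 441: 26, 881: 40}
        rng = np.random.default_rng(2)
        y = np.array([group_means[d] for d in DOSES]) + rng.normal(0, 2, DOSES.size)
        sat = M.ModelFit(family="hill", params={}, sigma=1, loglik=0, aic=0,
                         converged=True, n_obs=17, n_mean_params=4)
        # a fit whose mean function reproduces the group means exactly
        means = {d: y[DOSES == d].mean() for d in np.unique(DOSES)}
        sat.mu = lambda d: np.array([means[x] for x in np.asarray(d)])
        M.fit_p_value(sat, y, DOSES)
        assert sat.fit_p_value == pytest.approx(1.0)

    def test_nonmonotone_means_reject_linear_at_small_variance(self):
        pattern = {0: 10.0, 55: 30, 110: 5, 220: 40, 441: 8, 881: 35}
        rng = np.random.default_rng(4)
        y = np.array([pattern[d] for d in DOSES]) + rng.normal(0, 0.05, DOSES.size)
        f = M.fit_model(y, DOSES, "linear")
        M.fit_p_value(f, y, DOSES)
        assert f.fit_p_value < 1e-10

    def test_df_zero_or_negative_leaves_p_undefined(self):
        rng = np.random.default_rng(5)
        y = 10 + rng.normal(0, 1, DOSES.size)
        f = M.fit_model(y, DOSES, "hill")  # 4 mean params
        f.n_mean_params = 6  # more than the number of dose groups
        M.fit_p_value(f, y, DOSES)
        assert f.fit_p_value is None

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(300):
            y = 100 + rng.normal(0, 5, DOSES.size)
            f = M.fit_model(y, DOSES, "linear")
            M.fit_p_value(f, y, DOSES)
            ps.append(f.fit_p_value)
        ps = np.array(ps)
        # coarse uniformity: quartile occupancy within sampling error
        for q in (0.25, 0.5, 0.75):
            assert abs((ps < q).mean() - q) < 0.09


class TestSelectBestModel:
    def _fit(self, family, aic, bmd=100.0, p=0.5, k=None):
        params = {"k": k} if k is not None else {}
        f = M.ModelFit(family=family, params=params, sigma=1.0, loglik=0,
                       aic=aic, converged=True, n_obs=17,
                       n_mean_params=M.N_MEAN_PARAMS[family])
        f.bmd = bmd
        f.fit_p_value = p
        f.bmr_factor = 1.0
        return f

    def test_lowest_aic_wins(self):
        fits = [self._fit("linear", 105.0), self._fit("exp2", 100.0)]
        assert M.select_best_model(fits, 55.0).family == "exp2"

    def test_flagged_hill_sole_survivor_gives_none(self):
        # k = 17 < 55/3: flagged and excluded even when it is the only fit
        fits = [self._fit("hill", 90.0, k=17.0)]
        assert M.select_best_model(fits, 55.0) is None
        # k above the threshold is kept
        fits = [self._fit("hill", 90.0, k=20.0)]
        assert M.select_best_model(fits, 55.0).family == "hill"

    def test_screens_remove_unconverged_undefined_and_poor_fits(self):
        good = self._fit("linear", 120.0)
        bad_p = self._fit("exp2", 90.0, p=0.01)
        no_bmd = self._fit("power", 80.0)
        no_bmd.bmd = None
        unconv = self._fit("exp3", 70.0)
        unconv.converged = False
        assert M.select_best_model([good, bad_p, no_bmd, unconv], 55.0) is good

    def test_matches_exhaustive_ranking_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            fits = []
            for fam in M.FAMILIES:
                f = self._fit(fam, rng.uniform(50, 150),
                              bmd=rng.uniform(10, 2000) if rng.random() > 0.2 else None,
                              p=rng.uniform(0, 1),
                              k=rng.uniform(5, 200) if fam == "hill" else None)
                f.converged = rng.random() > 0.15
                fits.append(f)
            got = M.select_best_model(fits, 55.0)
            # independent loop re-applying every rule
            viable = [f for f in fits
                      if f.converged and f.bmd is not None and f.bmd > 0
                      and f.fit_p_value is not None and f.fit_p_value > 0.05
                      and not (f.family == "hill" and f.params["k"] < 55.0 / 3)]
            expect = min(viable, key=lambda f: f.aic) if viable else None
            assert got is expect


class TestScalingInvariances:
    def test_dose_scaling_equivariance(self):
        rng = np.random.default_rng(13)
        y = 100 * np.exp(0.0008 * DOSES) + rng.normal(0, 4, DOSES.size)
        c = 3.0
        for fam in ("linear", "power", "exp2", "exp4"):
            f1 = M.fit_model(y, DOSES, fam)
            M.compute_bmd(f1, 1.0, DOSES.max())
            f2 = M.fit_model(y, c * DOSES, fam)
            M.compute_bmd(f2, 1.0, c * DOSES.max())
            if f1.bmd is not None:
                assert f2.bmd == pytest.approx(c * f1.bmd, rel=1e-4)

    def test_response_scaling_leaves_bmd_unchanged(self):
        rng = np.random.default_rng(14)
        y = 100 + 0.07 * DOSES + rng.normal(0, 5, DOSES.size)
        for fam in ("linear", "power", "exp2", "exp4"):
            f1 = M.fit_model(y, DOSES, fam)
            M.compute_bmd(f1, 1.0, DOSES.max())
            f2 = M.fit_model(10.0 * y, DOSES, fam)
            M.compute_bmd(f2, 1.0, DOSES.max())
            if f1.bmd is not None:
                assert f2.bmd == pytest.approx(f1.bmd, rel=1e-4)
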