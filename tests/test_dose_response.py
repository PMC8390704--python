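"""Probit fitting, LC estimation and fiducial limits.

The oracle for the maximum-likelihood fit is an independent brute-force
grid search over (intercept, slope) written here from scratch; a
statsmodels probit GLM provides a second, library-level cross-check.
"""

import math

import numpy as np
import pytest
from scipy import stats

from epfassay.dose_response import (
    DoseMortalityTable,
    control_mortality_percent,
    fiducial_limits,
    fit_probit,
    goodness_of_fit,
    lc,
)


def _table(doses, deaths, n, iso="X"):
    return DoseMortalityTable(
        isolate_id=iso,
        doses=np.asarray(doses, dtype=float),
        deaths=np.asarray(deaths, dtype=float),
        n=np.asarray(n, dtype=float),
    )


def oracle_grid_mle(x, deaths, n, a_lo=-6.0, a_hi=6.0, b_lo=0.01, b_hi=3.0):
    """Exhaustive likelihood grid, zoomed twice; independent of the package."""
    prop = deaths / n
    best = None
    npts = 161
    for _ in range(5):
        a_vals = np.linspace(a_lo, a_hi, npts)
        b_vals = np.linspace(b_lo, b_hi, npts)
        ll_best = -np.inf
        for a in a_vals:
            mu = stats.norm.cdf(a + np.outer(b_vals, x))
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            ll = (n * (prop * np.log(mu) + (1 - prop) * np.log(1 - mu))).sum(axis=1)
            j = int(np.argmax(ll))
            if ll[j] > ll_best:
                ll_best, best = ll[j], (a, b_vals[j])
        da = (a_hi - a_lo) / (npts - 1)
        db = (b_hi - b_lo) / (npts - 1)
        # wide zoom window: the (alpha, beta) likelihood ridge is strongly
        # correlated, so the refined optimum can sit several cells away
        a_lo, a_hi = best[0] - 8 * da, best[0] + 8 * da
        b_lo, b_hi = best[1] - 8 * db, best[1] + 8 * db
    return best


class TestFitProbit:
    def test_two_point_saturated_fit(self):
        # exact proportions 0.5 and Phi(1) at log10 doses 2 and 4 pin the line
        n = 100000
        doses = [1e2, 1e4]
        deaths = [0.5 * n, stats.norm.cdf(1.0) * n]
        fit = fit_probit(_table(doses, deaths, [n, n]))
        assert fit.alpha == pytest.approx(-1.0, abs=1e-4)
        assert fit.beta == pytest.approx(0.5, abs=1e-4)

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        doses = 10.0 ** np.arange(4, 9)
        x = np.log10(doses)
        n = np.full(5, 60)
        deaths = rng.binomial(n, stats.norm.cdf(-3.0 + 0.5 * x))
        fit = fit_probit(_table(doses, deaths, n))
        glm = sm.GLM(
            np.column_stack([deaths, n - deaths]), sm.add_constant(x),
            family=sm.families.Binomial(sm.families.links.Probit()),
        ).fit()
        assert fit.alpha == pytest.approx(glm.params[0], abs=1e-6)
        assert fit.beta == pytest.approx(glm.params[1], abs=1e-6)
        assert fit.se_beta == pytest.approx(glm.bse[1], rel=1e-4)

    def test_newton_equals_grid_oracle_on_random_instances(self):
        matched = 0
        for s in range(20):
            r = np.random.default_rng(500 + s)
            k = int(r.integers(3, 6))
            doses = 10.0 ** np.sort(r.uniform(2, 8, size=k))
            x = np.log10(doses)
            a_true = r.uniform(-4, 0)
            b_true = r.uniform(0.2, 1.2)
            n = np.full(k, int(r.integers(40, 120)))
            deaths = r.binomial(n, stats.norm.cdf(a_true + b_true * x))
            # the MLE is only point-identified with >= 2 interior proportions;
            # degenerate patterns put the optimum on a flat likelihood ridge
            if np.count_nonzero((deaths > 0) & (deaths < n)) < 2:
                continue
            fit = fit_probit(_table(doses, deaths, n))
            a_o, b_o = oracle_grid_mle(x, deaths.astype(float), n.astype(float))
            assert fit.alpha == pytest.approx(a_o, abs=1e-3)
            assert fit.beta == pytest.approx(b_o, abs=1e-3)
            matched += 1
        assert matched >= 15

    def test_abbott_precorrection_shifts_fit(self):
        doses = 10.0 ** np.arange(4, 9)
        n = np.full(5, 60)
        deaths = np.array([20, 30, 40, 50, 58], dtype=float)
        raw = fit_probit(_table(doses, deaths, n), natural_response="none")
        corr = fit_probit(_table(doses, deaths, n), control_mortality_pct=10.0)
        assert corr.natural_mortality == pytest.approx(0.10)
        assert corr.alpha != raw.alpha  # correction actually applied

    def test_joint_natural_response_estimation(self):
        doses = 10.0 ** np.arange(4, 9)
        x = np.log10(doses)
        n = np.full(5, 2000)
        c = 0.08
        p = c + (1 - c) * stats.norm.cdf(-3.0 + 0.5 * x)
        deaths = np.round(p * n)
        fit = fit_probit(_table(doses, deaths, n), natural_response="joint")
        assert fit.natural_mortality == pytest.approx(c, abs=0.03)
        assert fit.beta == pytest.approx(0.5, abs=0.05)

    def test_uniform_total_response_is_error(self):
        with pytest.raises(ValueError, match="no gradient information"):
            fit_probit(_table([1e4, 1e6], [20, 20], [20, 20]))

    def test_flat_response_flagged_non_informative(self):
        fit = fit_probit(_table([1e4, 1e6, 1e8], [10, 10, 10], [20, 20, 20]))
        assert not fit.informative
        assert fit.beta == pytest.approx(0.0, abs=1e-6)

    def test_perfect_separation_flagged_not_raised(self):
        fit = fit_probit(_table([1e4, 1e6, 1e8], [0, 20, 20], [20, 20, 20]))
        assert fit.separation
        assert np.isfinite(fit.alpha) and np.isfinite(fit.beta)
        assert fit.vcov[1, 1] > 1.0  # deliberately inflated

    def test_single_dose_rejected(self):
        with pytest.raises(ValueError, match=">= 2 distinct doses"):
            fit_probit(_table([1e6], [10], [20]))

    def test_control_mortality_percent(self):
        from epfassay.data_model import MortalityAssay

        ctrl = [MortalityAssay(isolate_id="X", host="tuta", dose=0.0, replicate=r,
                               n_exposed=20, deaths_by_day=(0, 0, 1), window_days=3)
                for r in (1, 2)]
        assert control_mortality_percent(ctrl) == pytest.approx(5.0)


class TestLC:
    def _fit(self, alpha=-1.0, beta=0.5, v=None):
        from epfassay.dose_response import ProbitFit

        return ProbitFit(isolate_id="X", alpha=alpha, beta=beta,
                         vcov=np.asarray(v if v is not None else np.eye(2) * 1e-12),
                         natural_mortality=0.0, chi2=0.0, df=3, heterogeneity=1.0,
                         converged=True, n_doses=5, n_total=300)

    def test_lc50_closed_form(self):
        assert lc(self._fit(), 0.5) == pytest.approx(100.0)

    def test_lc90_closed_form(self):
        expected = 10 ** ((1.281552 + 1.0) / 0.5)
        assert lc(self._fit(), 0.9) == pytest.approx(expected, rel=1e-5)

    def test_lc_ratio_depends_only_on_slope(self):
        for beta in (0.35, 0.5, 0.9):
            fit = self._fit(alpha=-2.2, beta=beta)
            gap = math.log10(lc(fit, 0.9)) - math.log10(lc(fit, 0.5))
            assert gap == pytest.approx(1.281552 / beta, rel=1e-6)

    def test_monotone_in_p(self):
        fit = self._fit()
        lcs = [lc(fit, p) for p in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a < b for a, b in zip(lcs, lcs[1:]))

    def test_dose_unit_equivariance(self, rng):
        doses = 10.0 ** np.arange(4, 9)
        n = np.full(5, 60)
        deaths = rng.binomial(n, stats.norm.cdf(-3.0 + 0.5 * np.log10(doses)))
        f1 = fit_probit(_table(doses, deaths, n))
        k = 37.0
        f2 = fit_probit(_table(doses * k, deaths, n))
        assert f2.beta == pytest.approx(f1.beta, rel=1e-6)
        assert f2.alpha == pytest.approx(f1.alpha - f1.beta * math.log10(k), abs=1e-6)
        assert lc(f2, 0.5) == pytest.approx(k * lc(f1, 0.5), rel=1e-6)


class TestFiducialLimits:
    def _fitted(self, n_per_dose=200, seed=5, alpha=-1.5, beta=0.5):
        r = np.random.default_rng(seed)
        doses = 10.0 ** np.arange(1, 6)
        x = np.log10(doses)
        n = np.full(5, n_per_dose)
        deaths = r.binomial(n, stats.norm.cdf(alpha + beta * x))
        return fit_probit(_table(doses, deaths, n))

    def test_degenerate_interval_as_variance_vanishes(self):
        fit = self._fitted(n_per_dose=200)
        fit.vcov = fit.vcov * 1e-12
        est = fiducial_limits(fit, 0.5)
        assert est.lower == pytest.approx(est.lc, rel=1e-4)
        assert est.upper == pytest.approx(est.lc, rel=1e-4)

    def test_matches_delta_method_when_g_small(self):
        fit = self._fitted(n_per_dose=5000)
        est = fiducial_limits(fit, 0.5)
        assert est.g < 0.01
        m = math.log10(est.lc)
        v = (fit.vcov[0, 0] + 2 * m * fit.vcov[0, 1] + m**2 * fit.vcov[1, 1]) / fit.beta**2
        z = stats.norm.ppf(0.975)
        lo, hi = 10 ** (m - z * math.sqrt(v)), 10 ** (m + z * math.sqrt(v))
        assert est.lower == pytest.approx(lo, rel=0.02)
        assert est.upper == pytest.approx(hi, rel=0.02)

    def test_wide_variance_gives_unbounded_interval(self):
        fit = self._fitted()
        fit.vcov = np.array([[10.0, 0.0], [0.0, 10.0]])
        est = fiducial_limits(fit, 0.5)
        assert est.unbounded and est.upper == math.inf

    def test_point_inside_interval(self):
        est = fiducial_limits(self._fitted(), 0.5)
        assert est.lower <= est.lc <= est.upper


class TestGoodnessOfFit:
    def test_two_doses_give_zero_df_unit_h(self):
        fit = fit_probit(_table([1e4, 1e6], [5, 15], [20, 20]))
        with pytest.warns(UserWarning, match="df = 0"):
            chi2, df, h = goodness_of_fit(fit)
        assert (df, h) == (0, 1.0)

    def test_well_specified_model_has_h_near_one(self):
        doses = 10.0 ** np.arange(1, 6)
        x = np.log10(doses)
        hs = []
        for s in range(40):
            r = np.random.default_rng(900 + s)
            n = np.full(5, 500)
            deaths = r.binomial(n, stats.norm.cdf(-1.5 + 0.5 * x))
            hs.append(fit_probit(_table(doses, deaths, n)).heterogeneity)
        # h = max(1, chi2/df), so its mean under a correct model is ~1.2, not 10
        assert np.mean(hs) < 1.8

    def test_overdispersion_widens_limits(self):
        doses = 10.0 ** np.arange(1, 6)
        x = np.log10(doses)
        n = np.full(5, 400)
        r = np.random.default_rng(77)
        p = stats.norm.cdf(-1.5 + 0.5 * x)
        # beta-binomial: replicate-level probability jitter inflates dispersion
        deaths = np.array([
            r.binomial(n[i] // 4, np.clip(r.normal(p[i], 0.12, 4), 0.01, 0.99)).sum()
            for i in range(5)
        ])
        fit = fit_probit(_table(doses, deaths, n))
        assert fit.heterogeneity > 1.0
        est = fiducial_limits(fit, 0.5)
        plain = fit_probit(_table(doses, np.round(p * n), n))
        base = fiducial_limits(plain, 0.5)
        width = math.log10(est.upper) - math.log10(est.lower)
        base_width = math.log10(base.upper) - math.log10(base.lower)
        assert width > base_width
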