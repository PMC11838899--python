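import numpy as np
import pytest
from scipy import stats

import mitofibre as mf
from mitofibre.posterior import (hdi, posterior_predictive_band, summarize_pi)


class TestHdi:
    def test_uniform_sample_width(self):
        x = np.linspace(0, 1, 100_001)
        lo, hi = hdi(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=1e-4)

    def test_skewed_sample_hugs_zero(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(size=100_000)
        lo, hi = hdi(x, 0.95)
        assert lo < 0.01
        # unlike the equal-tailed interval, whose lower bound is ~q(0.025)
        assert np.quantile(x, 0.025) > lo
        assert hi < np.quantile(x, 0.975) + 0.5

    def test_contains_mode_and_matches_arviz(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            import arviz as az

        rng = np.random.default_rng(1)
        x = rng.normal(3.0, 1.0, size=50_000)
        lo, hi = hdi(x, 0.9)
        assert lo < 3.0 < hi
        # arviz includes floor(level*n) samples where we take ceil, so the
        # endpoints may sit one order statistic apart
        ref = np.asarray(az.hdi(x, hdi_prob=0.9)).ravel()
        assert lo == pytest.approx(float(ref[0]), abs=2e-3)
        assert hi == pytest.approx(float(ref[1]), abs=2e-3)

    def test_level_one_spans_range_and_width_monotone(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        lo, hi = hdi(x, 1.0)
        assert (lo, hi) == (x.min(), x.max())
        widths = []
        for lv in (0.5, 0.8, 0.9, 0.99):
            a, b = hdi(x, lv)
            widths.append(b - a)
        assert all(a <= b + 1e-12 for a, b in zip(widths, widths[1:]))

    def test_boundary_support_snapping(self):
        rng = np.random.default_rng(3)
        x = rng.beta(1, 200, size=5000)  # piles up at 0
        lo, _ = hdi(x, 0.99)
        assert lo > 0  # pure sample method cannot reach the boundary
        lo_s, _ = hdi(x, 0.99, support=(0.0, 0.5))
        assert lo_s == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.arange(5), 0.95)


class TestClassifyBayes:
    def test_constant_memberships_and_threshold_boundary(self, fitted):
        import copy

        res = copy.copy(fitted)
        # expected probability exactly at 0.5 maps to not-like-control
        for const, expected in [(0.0, 0), (1.0, 1), (0.499, 0), (0.5, 1)]:
            chain = fitted.chain
            chain_mod = copy.copy(chain)
            chain_mod.membership = np.full_like(chain.membership, const)
            draws = copy.copy(fitted.draws)
            draws.chains = list(fitted.draws.chains)
            draws.chains[fitted.selected_chain] = chain_mod
            res.draws = draws
            cls = mf.classify_bayes(res)
            assert (cls.label == expected).all()
            assert cls.probability == pytest.approx(const)

    def test_mean_oracle_and_threshold_monotonicity(self, fitted):
        cls = fitted.classification()
        # independent summation oracle for the posterior-mean probability
        expected = np.add.reduce(fitted.membership, axis=0) / fitted.membership.shape[0]
        np.testing.assert_allclose(cls.probability, expected, rtol=1e-12)
        stricter = fitted.classification(threshold=0.9)
        assert not np.any((cls.label == 0) & (stricter.label == 1))


class TestPredictiveBand:
    def test_point_mass_posterior_closed_form(self):
        m, c, tau = 1.2, -0.3, 25.0
        n = 50
        lo, fit, hi = posterior_predictive_band(
            np.full(n, m), np.full(n, c), np.full(n, tau),
            x_grid=[0.0, 1.0, 2.5], level=0.95)
        z = stats.norm.ppf(0.975)
        for i, x0 in enumerate([0.0, 1.0, 2.5]):
            mu = m * x0 + c
            assert fit[i] == pytest.approx(mu, abs=1e-12)
            assert lo[i] == pytest.approx(mu - z / np.sqrt(tau), abs=1e-8)
            assert hi[i] == pytest.approx(mu + z / np.sqrt(tau), abs=1e-8)

    def test_band_contains_fitted_line(self, fitted):
        pat = fitted.model.dataset.patient
        grid = np.linspace(pat.x.min(), pat.x.max(), 15)
        lo, fit, hi = fitted.predictive_band(grid)
        assert (lo < fit).all() and (fit < hi).all()

    def test_coverage_on_like_control_patient(self, healthy_patient_fit):
        _, data, res = healthy_patient_fit
        pat = data.patient
        lo, _, hi = res.predictive_band(pat.x, level=0.95)
        inside = ((pat.y >= lo) & (pat.y <= hi)).mean()
        assert 0.92 <= inside <= 0.98


class TestSummarizePi:
    def test_reference_at_median_gives_zero_difference(self):
        rng = np.random.default_rng(4)
        pi = rng.beta(5, 20, size=4001) / 2
        ref = float(np.median(pi))
        comp = summarize_pi(pi, ref)
        assert comp.difference_median == 0.0

    def test_resolution_floor_with_extreme_reference(self):
        rng = np.random.default_rng(5)
        pi = rng.uniform(0.05, 0.2, size=5000)
        comp = summarize_pi(pi, 0.45)
        assert comp.tail_is_upper_bound
        assert comp.tail_probability == pytest.approx(2.0e-4)

    def test_tail_probability_counting_oracle(self):
        rng = np.random.default_rng(6)
        pi = rng.uniform(0, 0.5, size=2000)
        for ref in (0.1, 0.3, 0.49):
            comp = summarize_pi(pi, ref)
            if ref >= np.median(pi):
                expected = int(sum(1 for v in pi if v >= ref)) / len(pi)
            else:
                expected = int(sum(1 for v in pi if v <= ref)) / len(pi)
            assert comp.tail_probability == pytest.approx(expected)
            assert not comp.tail_is_upper_bound

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            summarize_pi(np.linspace(0, 0.5, 100), 1.5)
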