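"""Gamma-prior BEST fits and the highest-density interval."""

import numpy as np
import pytest

from psynet.best import BestConfig, compare_all_metrics, fit_best, hdi
from psynet.network import MetricDistribution

FAST = BestConfig(burn_in=500, iterations=2000, rng_seed=11)


class TestHdi:
    def test_point_mass(self):
        assert hdi([3.0] * 10) == (3.0, 3.0)

    def test_uniform_width(self):
        x = np.random.default_rng(0).uniform(0, 1, 100_000)
        lo, hi = hdi(x, 0.9)
        assert hi - lo == pytest.approx(0.9, abs=0.01)

    def test_normal_matches_central_interval(self):
        x = np.random.default_rng(1).normal(0, 1, 100_000)
        lo, hi = hdi(x, 0.9)
        assert lo == pytest.approx(-1.645, abs=0.05)
        assert hi == pytest.approx(1.645, abs=0.05)

    def test_width_monotone_in_mass(self):
        x = np.random.default_rng(2).normal(0, 1, 5_000)
        widths = [np.diff(hdi(x, m))[0] for m in (0.5, 0.7, 0.9, 0.99)]
        assert widths == sorted(widths)

    def test_cross_check_against_arviz(self):
        import arviz as az

        x = np.random.default_rng(3).gamma(2.0, 3.0, 20_000)
        lo, hi = hdi(x, 0.9)
        ref = az.hdi(x, hdi_prob=0.9)
        assert lo == pytest.approx(float(ref[0]), abs=0.05)
        assert hi == pytest.approx(float(ref[1]), abs=0.05)


class TestFitBest:
    def test_identical_samples_hdi_spans_zero(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(3.0, 2.0, 80)
        res = fit_best(x, x, FAST)
        assert res.hdi_low < 0 < res.hdi_high
        assert 0.4 <= res.probability_direction <= 0.6

    def test_separated_gamma_groups(self):
        rng = np.random.default_rng(5)
        a = rng.gamma(2.0, 2.5, 100)  # mean 5
        b = rng.gamma(2.0, 5.0, 100)  # mean 10
        res = fit_best(a, b, FAST)
        diff = res.mean_impv - res.mean_mc
        assert -6.0 < diff < -4.0 or abs(diff + 5) < 1.5
        assert res.hdi_high < 0  # difference credibly negative

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(6)
        a = rng.gamma(2.0, 2.0, 40)
        b = rng.gamma(2.0, 3.0, 40)
        r1 = fit_best(a, b, FAST)
        r2 = fit_best(a, b, FAST)
        assert np.array_equal(r1.diff_samples, r2.diff_samples)
        assert (r1.hdi_low, r1.hdi_high) == (r2.hdi_low, r2.hdi_high)

    def test_degenerate_equal_constants(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = fit_best([2.0, 2.0, 2.0], [2.0, 2.0], FAST)
        assert res.degenerate
        assert (res.hdi_low, res.hdi_high) == (0.0, 0.0)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit_best([-1.0, 2.0], [1.0, 2.0], FAST)

    def test_location_tracks_sample_mean_for_symmetric_data(self):
        """With near-normal data and n=200, the posterior location sits
        within 2 standard errors of the sample mean."""
        rng = np.random.default_rng(7)
        a = rng.normal(10.0, 1.0, 200)
        b = rng.normal(10.0, 1.0, 200)
        res = fit_best(a, b, FAST)
        se = 1.0 / np.sqrt(200)
        assert abs(res.mean_impv - a.mean()) < 2 * se
        assert abs(res.mean_mc - b.mean()) < 2 * se

    def test_scale_equivariance_of_difference(self):
        """Scaling both samples by c scales the difference posterior by c
        (within Monte-Carlo error)."""
        rng = np.random.default_rng(8)
        a = rng.gamma(2.0, 2.0, 80)
        b = rng.gamma(2.0, 3.5, 80)
        r1 = fit_best(a, b, FAST)
        r2 = fit_best(10 * a, 10 * b, FAST)
        d1 = float(np.mean(r1.diff_samples))
        d2 = float(np.mean(r2.diff_samples))
        assert d2 == pytest.approx(10 * d1, rel=0.15)

    def test_convergence_diagnostic_at_default_schedule(self):
        """The shipped 1000/10000 schedule mixes well (split R-hat < 1.05)."""
        rng = np.random.default_rng(9)
        res = fit_best(rng.gamma(2, 2, 60), rng.gamma(2, 2.5, 60),
                       BestConfig(rng_seed=9))
        assert res.rhat < 1.05
        assert res.ess > 500


class TestCompareAllMetrics:
    @staticmethod
    def _pairs(n_metrics, rng):
        pairs = []
        for i in range(n_metrics):
            a = {f"n{k}": float(v) for k, v in enumerate(rng.gamma(2, 2, 40))}
            b = {f"n{k}": float(v) for k, v in enumerate(rng.gamma(2, 2, 40))}
            name = f"metric_{i}"
            pairs.append(
                (MetricDistribution(name, "IMPV", a, "node"),
                 MetricDistribution(name, "MC", b, "node"))
            )
        return pairs

    def test_one_row_per_metric(self):
        rng = np.random.default_rng(10)
        results, report = compare_all_metrics(self._pairs(3, rng), FAST)
        assert len(results) == 3
        assert list(report["metric"]) == ["metric_0", "metric_1", "metric_2"]
        assert {"mean_impv", "mean_mc", "hdi_5", "hdi_95"} <= set(report.columns)

    def test_identical_distributions_span_zero(self):
        rng = np.random.default_rng(11)
        vals = {f"n{k}": float(v) for k, v in enumerate(rng.gamma(3, 2, 50))}
        pair = (
            MetricDistribution("m", "IMPV", vals, "node"),
            MetricDistribution("m", "MC", dict(vals), "node"),
        )
        results, _ = compare_all_metrics([pair], FAST)
        assert results[0].hdi_low < 0 < results[0].hdi_high

    def test_mismatched_names_rejected(self):
        rng = np.random.default_rng(12)
        (a, _), (_, b) = self._pairs(2, rng)
        with pytest.raises(ValueError, match="mismatch"):
            compare_all_metrics([(a, b)], FAST)

    def test_negative_metric_values_shifted(self):
        rng = np.random.default_rng(13)
        a = {f"n{k}": float(v) for k, v in enumerate(rng.normal(5, 1, 40))}
        b = {f"n{k}": float(v) - 6.0 for k, v in enumerate(rng.normal(5, 1, 40))}
        assert min(b.values()) < 0
        pair = (
            MetricDistribution("m", "IMPV", a, "node"),
            MetricDistribution("m", "MC", b, "node"),
        )
        results, _ = compare_all_metrics([pair], FAST)
        assert results[0].shift_applied > 0
        # difference is shift-invariant: roughly +6
        assert float(np.mean(results[0].diff_samples)) == pytest.approx(6.0, abs=1.0)
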