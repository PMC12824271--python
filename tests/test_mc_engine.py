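import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from proxypower.mc_engine import RateEstimate, estimate_rate, read_rates, run_sweep
from proxypower.model_core import ReducedParams


def mc_tol(rate, reps):
    return 3 * np.sqrt(max(rate * (1 - rate), 1e-12) / reps)


class TestEstimateRate:
    def test_null_calibration(self, rng):
        """With no effect and no bias, FPR = alpha for any parameters."""
        for _ in range(5):
            p = ReducedParams(
                rho=rng.uniform(0, 1), VR=rng.uniform(0.5, 2),
                R_sigma=rng.uniform(0.5, 2), n_a=int(rng.integers(5, 40)),
                n_b=int(rng.integers(5, 40)), alpha=0.05,
            )
            est = estimate_rate(p, reps=20_000, seed=int(rng.integers(2**31)))
            assert est.rate_type == "FPR"
            assert abs(est.rate - 0.05) < max(3 * est.mc_se, mc_tol(0.05, est.reps))

    def test_regime_labels_and_mixing_guard(self):
        fpr = estimate_rate(ReducedParams(rho=0.5, delta=1.0), reps=100, seed=0)
        assert fpr.rate_type == "FPR"
        fnr = estimate_rate(ReducedParams(rho=0.5, Delta=1.0), reps=100, seed=0)
        assert fnr.rate_type == "FNR"
        mixed = ReducedParams(rho=0.5, Delta=1.0, delta=1.0)
        with pytest.raises(ValueError, match="regime"):
            estimate_rate(mixed, reps=100, seed=0)
        est = estimate_rate(mixed, reps=100, seed=0, allow_mixed=True)
        assert est.rate_type == "FNR"

    def test_deterministic_and_batch_invariant(self):
        p = ReducedParams(rho=0.7, Delta=0.5)
        a = estimate_rate(p, reps=5_000, seed=11)
        b = estimate_rate(p, reps=5_000, seed=11)
        assert a.rate == b.rate

    def test_rule_of_three(self):
        p = ReducedParams(rho=1.0, Delta=10.0)  # power ~ 1: FNR = 0
        est = estimate_rate(p, reps=1_000, seed=0)
        assert est.rate == 0.0
        assert est.rule_of_three == pytest.approx(3 / 1_000)
        assert estimate_rate(ReducedParams(rho=0.5, Delta=0.3),
                             reps=5_000, seed=0).rule_of_three is None


class TestExactInvariances:
    """Rejection decisions are bit-identical under reparameterizations
    that leave the standardized test statistic unchanged."""

    base = dict(rho=0.6, R_sigma=1.0, delta=0.8, n_a=20, n_b=20)
    reps = 2_000

    def rate(self, **kw):
        p = ReducedParams(**{**self.base, **kw})
        return estimate_rate(p, reps=self.reps, seed=99).rate

    def test_mean_invariance(self):
        assert self.rate() == self.rate(mu_bio=5.0, mu_contam=-3.0)

    def test_vr_invariance_at_fixed_sigma_bio(self):
        assert self.rate(VR=1.0) == self.rate(VR=2.5)

    def test_r_sigma_invariance_when_delta_zero(self):
        assert (self.rate(delta=0.0, R_sigma=0.5)
                == self.rate(delta=0.0, R_sigma=2.0))

    def test_r_sigma_matters_when_delta_nonzero(self):
        assert self.rate(R_sigma=0.5) != self.rate(R_sigma=2.0)


class TestDirectionalClaims:
    """Qualitative behavior of the error rates under the proxy model."""

    def test_fpr_increases_with_sample_size(self):
        rates = []
        for n in (10, 25, 100):
            p = ReducedParams(rho=0.6, delta=1.0, n_a=n, n_b=n)
            rates.append(estimate_rate(p, reps=20_000, seed=n))
        for lo, hi in zip(rates, rates[1:]):
            assert hi.rate > lo.rate - 3 * (lo.mc_se + hi.mc_se)
        assert rates[-1].rate > rates[0].rate

    def test_fpr_decreases_with_r_sigma(self):
        rates = []
        for i, r_sigma in enumerate((0.5, 1.0, 2.0)):
            p = ReducedParams(rho=0.6, R_sigma=r_sigma, delta=1.0)
            rates.append(estimate_rate(p, reps=20_000, seed=i))
        for hi, lo in zip(rates, rates[1:]):
            assert lo.rate < hi.rate + 3 * (lo.mc_se + hi.mc_se)
        assert rates[-1].rate < rates[0].rate

    def test_fnr_decreases_with_sample_size(self):
        rates = []
        for n in (10, 25, 100):
            p = ReducedParams(rho=0.7, Delta=1.0, n_a=n, n_b=n)
            rates.append(estimate_rate(p, reps=20_000, seed=n))
        assert rates[0].rate > rates[1].rate > rates[2].rate


class TestRunSweep:
    def test_row_count_and_order(self):
        base = ReducedParams(rho=0.5)
        res = run_sweep({"rho": [0.0, 0.5, 1.0], "delta": [0.0, 1.0]},
                        base, reps=200, seed=0)
        assert len(res.rows) == 6
        # axes sorted lexicographically: delta varies slower than rho
        coords = [(r.params.delta, r.params.rho) for r in res.rows]
        assert coords == sorted(coords)

    def test_per_point_seeds(self):
        base = ReducedParams(rho=0.5)
        res = run_sweep({"rho": [0.2, 0.8]}, base, reps=200, seed=100)
        assert [r.seed for r in res.rows] == [100, 101]
        # each point individually reproducible
        single = estimate_rate(dataclasses.replace(base, rho=0.8),
                               reps=200, seed=101)
        assert res.rows[1].rate == single.rate

    def test_invalid_grid_point_names_coordinates(self):
        base = ReducedParams(rho=0.5)
        with pytest.raises(ValueError, match="rho"):
            run_sweep({"rho": [0.5, 1.5]}, base, reps=100, seed=0)

    def test_fpr_monotone_in_delta(self):
        """FPR is non-decreasing in the differential bias at fixed rho < 1."""
        base = ReducedParams(rho=0.7)
        res = run_sweep({"delta": [0.2, 1.0, 2.2]}, base, reps=20_000, seed=0)
        rates = [r.rate for r in res.rows]
        ses = [r.mc_se for r in res.rows]
        for i in range(len(rates) - 1):
            assert rates[i + 1] > rates[i] - 3 * (ses[i] + ses[i + 1])
        assert rates[-1] > rates[0]

    def test_alpha_sweep_directions(self):
        """Raising the nominal level trades false negatives for positives."""
        alphas = [0.01, 0.05, 0.2]
        fpr = run_sweep({"alpha": alphas}, ReducedParams(rho=0.7, delta=1.0),
                        reps=20_000, seed=0)
        fnr = run_sweep({"alpha": alphas}, ReducedParams(rho=0.7, Delta=1.0),
                        reps=20_000, seed=0)
        fpr_rates = [r.rate for r in fpr.rows]
        fnr_rates = [r.rate for r in fnr.rows]
        assert fpr_rates == sorted(fpr_rates)
        assert fnr_rates == sorted(fnr_rates, reverse=True)

    def test_csv_round_trip(self, tmp_path):
        base = ReducedParams(rho=0.5, delta=0.4)
        res = run_sweep({"rho": [0.3, 0.6]}, base, reps=500, seed=7)
        path = tmp_path / "sweep.csv"
        res.to_csv(path)
        back = read_rates(path)
        assert list(back["rate"]) == [r.rate for r in res.rows]
        assert list(back["mc_se"]) == [r.mc_se for r in res.rows]
        assert list(back["seed"]) == [r.seed for r in res.rows]


class TestRateEstimate:
    def test_validation(self):
        p = ReducedParams(rho=0.5)
        with pytest.raises(ValueError):
            RateEstimate("FPR", 1.5, 0.0, 100, p, 0)
        with pytest.raises(ValueError):
            RateEstimate("FPR", 0.5, 0.01, 0, p, 0)
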