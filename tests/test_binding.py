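import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from calpain_ppi.binding import (
    FlatResponseError,
    TitrationDataset,
    competitive_complex,
    estimate_kd,
    fit_4pl,
    fit_ec50,
    fit_ic50,
    fold_change,
    occupancy_hyperbolic,
    occupancy_quadratic,
    slope_zero_test,
    z_factor,
)
from calpain_ppi.synth import SimulationConfig, simulate_assay


def _four_pl(x, bottom, top, m, h):
    return bottom + (top - bottom) / (1 + 10 ** ((np.log10(m) - np.log10(x)) * h))


class TestOccupancyModels:
    def test_hyperbolic_half_saturation(self):
        assert occupancy_hyperbolic(50.0, 50.0) == pytest.approx(0.5)
        assert occupancy_hyperbolic(0.0, 50.0) == 0.0
        assert occupancy_hyperbolic(9 * 50.0, 50.0) == pytest.approx(0.9)

    def test_hyperbolic_rejects_bad_kd(self):
        with pytest.raises(ValueError):
            occupancy_hyperbolic(1.0, 0.0)

    def test_quadratic_closed_form_symmetric_point(self):
        # a0 = b0 = kd: [AB] = kd*(3 - sqrt(5))/2
        kd = 123.0
        expected = kd * (3 - np.sqrt(5)) / 2
        assert occupancy_quadratic(kd, kd, kd) == pytest.approx(expected, rel=1e-12)

    def test_quadratic_stoichiometric_limit(self):
        assert occupancy_quadratic(30.0, 70.0, 0.0) == pytest.approx(30.0)
        assert occupancy_quadratic(70.0, 30.0, 0.0) == pytest.approx(30.0)

    def test_quadratic_matches_mass_balance_root(self):
        # cross-check against numeric bisection on the mass balance
        from scipy.optimize import brentq

        for a0, b0, kd in [(10, 100, 50), (500, 100, 508.6), (1, 1, 1e-3)]:
            ab = occupancy_quadratic(a0, b0, kd)
            f = lambda c: (a0 - c) * (b0 - c) - kd * c
            assert ab == pytest.approx(brentq(f, 0, min(a0, b0)), rel=1e-9)

    @given(
        st.floats(0.0, 1e6), st.floats(0.0, 1e6), st.floats(1e-6, 1e6)
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_quadratic_bounds(self, a0, b0, kd):
        ab = occupancy_quadratic(a0, b0, kd)
        assert 0.0 <= ab <= min(a0, b0) + 1e-9

    @pytest.mark.parametrize("ratio", [1e-6, 1e-4, 1e-3])
    def test_depletion_free_limit_recovers_hyperbola(self, ratio):
        kd, a0 = 200.0, 500.0
        b0 = kd * ratio
        frac = occupancy_quadratic(a0, b0, kd) / b0
        assert frac == pytest.approx(occupancy_hyperbolic(a0, kd), abs=2 * b0 / kd)


class TestCompetitiveComplex:
    def test_no_inhibitor_equals_quadratic(self):
        ab = competitive_complex(100, 50, 0.0, 30.0, 10.0)
        assert ab == pytest.approx(occupancy_quadratic(100, 50, 30.0), rel=1e-9)

    def test_non_binding_inhibitor_is_transparent(self):
        ab = competitive_complex(100, 50, 1000.0, 30.0, 1e12)
        assert ab == pytest.approx(occupancy_quadratic(100, 50, 30.0), rel=1e-6)

    def test_exchange_symmetry_and_mass_balance(self):
        # swapping the roles of reporter and competitor yields the partner
        # complex of the same system; together they close the mass balance
        a0, b0, i0, kab, kai = 100.0, 80.0, 60.0, 50.0, 70.0
        ab = competitive_complex(a0, b0, i0, kab, kai)
        ai = competitive_complex(a0, i0, b0, kai, kab)
        a_free = kab * ab / (b0 - ab)
        assert a_free + ab + ai == pytest.approx(a0, rel=1e-9)
        # equal totals and affinities: the two complexes are equal
        assert competitive_complex(100, 100, 100, 50.0, 50.0) == pytest.approx(
            competitive_complex(100, 100, 100, 50.0, 50.0), rel=1e-12
        )

    def test_monotone_in_inhibitor(self):
        vals = [competitive_complex(100, 50, i0, 30.0, 20.0) for i0 in np.linspace(0, 2000, 30)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestFit4PL:
    def test_exact_recovery_on_noiseless_data(self):
        x = np.geomspace(1, 1e5, 12)
        y = _four_pl(x, 100.0, 5e4, 750.0, 1.3)
        fit = fit_4pl(x, y)
        assert fit.midpoint == pytest.approx(750.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.3, rel=1e-6)
        assert fit.bottom == pytest.approx(100.0, abs=1e-3)
        assert fit.top == pytest.approx(5e4, rel=1e-6)
        assert fit.converged

    def test_hyperbola_is_4pl_with_unit_hill(self):
        kd = 42.0
        x = np.geomspace(0.01 * kd, 100 * kd, 15)
        y = occupancy_hyperbolic(x, kd)
        fit = fit_4pl(x, y, hill_fixed=1.0)
        assert fit.midpoint == pytest.approx(kd, rel=1e-6)

    def test_constant_response_is_error(self):
        x = np.geomspace(1, 1e4, 8)
        with pytest.raises(FlatResponseError):
            fit_4pl(x, np.full_like(x, 100.0))

    def test_descending_data_normalised(self):
        x = np.geomspace(1, 1e5, 12)
        y = _four_pl(x, 100.0, 5e4, 400.0, -1.0)
        fit = fit_4pl(x, y)
        assert fit.direction == "descending"
        assert fit.top >= fit.bottom
        assert fit.midpoint == pytest.approx(400.0, rel=1e-6)

    def test_ci_brackets_midpoint(self):
        ds = simulate_assay(SimulationConfig(
            kind="dose_response", truth={"midpoint_nM": 500.0, "hill": 1.0}, seed=5,
        ))
        fit = fit_ec50(ds)
        assert fit.ci95_low <= fit.midpoint <= fit.ci95_high


class TestEstimateKd:
    def _titration(self, kd, fixed, noise=0.0, seed=1, grid=(1.0, 1e5, 12)):
        return simulate_assay(SimulationConfig(
            kind="titration",
            truth={"kd_nM": kd, "fixed_nM": fixed},
            grid_min_nM=grid[0], grid_max_nM=grid[1], grid_points=grid[2],
            noise_cv=noise, seed=seed,
        ))

    def test_both_methods_agree_without_depletion(self):
        # fixed component far below kd: free ~ total, methods coincide
        ds = self._titration(kd=5000.0, fixed=1.0)
        infl = estimate_kd(ds, method="inflection").midpoint
        quad = estimate_kd(ds, method="quadratic").midpoint
        assert infl == pytest.approx(5000.0, rel=1e-3)
        assert quad == pytest.approx(5000.0, rel=1e-4)

    def test_quadratic_exact_and_inflection_biased_under_depletion(self):
        kd = 508.6
        ds = self._titration(kd=kd, fixed=100.0)
        quad = estimate_kd(ds, method="quadratic").midpoint
        infl = estimate_kd(ds, method="inflection").midpoint
        assert quad == pytest.approx(kd, rel=1e-6)
        assert infl > kd  # total > free titrant at the midpoint

    def test_inflection_bias_shrinks_with_fixed_concentration(self):
        kd = 508.6
        biases = []
        for fixed in (400.0, 100.0, 25.0, 5.0):
            ds = self._titration(kd=kd, fixed=fixed)
            biases.append(estimate_kd(ds, method="inflection").midpoint - kd)
        assert all(b > 0 for b in biases)
        assert biases == sorted(biases, reverse=True)

    def test_noisy_median_recovery(self):
        kd = 300.0
        recovered = [
            estimate_kd(self._titration(kd, 100.0, noise=0.05, seed=s), "quadratic").midpoint
            for s in range(1, 51)
        ]
        assert np.median(recovered) == pytest.approx(kd, rel=0.05)


class TestEc50Ic50:
    def test_ec50_noiseless_recovery(self):
        ds = simulate_assay(SimulationConfig(
            kind="dose_response", truth={"midpoint_nM": 59.9e3, "hill": 1.5},
            grid_min_nM=1e2, grid_max_nM=1e7, grid_points=10,
            noise_cv=0.0, seed=1,
        ))
        fit = fit_ec50(ds)
        assert fit.midpoint == pytest.approx(59.9e3, rel=1e-6)
        assert fit.direction == "ascending"

    def test_ic50_noiseless_recovery(self):
        ds = simulate_assay(SimulationConfig(
            kind="inhibition", truth={"midpoint_nM": 463.3, "hill": 1.0},
            grid_min_nM=1.0, grid_max_nM=1e5, grid_points=11,
            noise_cv=0.0, seed=1,
        ))
        fit = fit_ic50(ds)
        assert fit.midpoint == pytest.approx(463.3, rel=1e-6)
        assert fit.direction == "descending"

    def test_direction_mismatch_warns_and_fits_observed(self):
        ds = simulate_assay(SimulationConfig(
            kind="inhibition", truth={"midpoint_nM": 500.0}, noise_cv=0.0, seed=1,
        ))
        with pytest.warns(UserWarning, match="descending"):
            fit = fit_ec50(ds)
        assert fit.direction == "descending"
        assert fit.notes


class TestAssayStats:
    def test_z_factor_arithmetic(self):
        pos = [95.0, 100.0, 105.0]  # mean 100, sd 5
        neg = [5.0, 10.0, 15.0]     # mean 10, sd 5
        q = z_factor(pos, neg)
        assert q.z_factor == pytest.approx(1 - 30.0 / 90.0)

    def test_z_factor_perfect_separation(self):
        assert z_factor([10.0] * 4, [1.0] * 4).z_factor == 1.0

    def test_z_factor_equal_means_error(self):
        with pytest.raises(ValueError, match="undefined"):
            z_factor([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])

    @given(st.floats(0.1, 100), st.floats(-50, 50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_z_factor_affine_invariance(self, gain, offset):
        pos = np.array([90.0, 100.0, 110.0, 95.0])
        neg = np.array([8.0, 10.0, 12.0, 9.0])
        z0 = z_factor(pos, neg).z_factor
        z1 = z_factor(gain * pos + offset, gain * neg + offset).z_factor
        assert z1 == pytest.approx(z0, rel=1e-9)

    def test_fold_change(self):
        assert fold_change(4000.0, 10.0) == pytest.approx(400.0)
        assert fold_change([5.0, 15.0], [10.0]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            fold_change(10.0, 0.0)


class TestSlopeZeroTest:
    def test_constant_signal(self):
        res = slope_zero_test([1.0, 2.0, 3.0, 4.0], [7.0, 7.0, 7.0, 7.0])
        assert res.slope == 0.0
        assert res.f_statistic == 0.0

    def test_perfect_line_has_tiny_p(self):
        x = np.arange(1.0, 6.0)
        res = slope_zero_test(x, 2.0 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.p_value < 1e-10

    def test_needs_three_distinct_x(self):
        with pytest.raises(ValueError):
            slope_zero_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_p_values_are_uniform(self):
        """Under the null (no slope), p-values are ~Uniform(0,1)."""
        rng = np.random.default_rng(42)
        x = np.linspace(0, 3, 10)
        pvals = [
            slope_zero_test(x, 5.0 + rng.normal(0, 1, x.size)).p_value
            for _ in range(500)
        ]
        assert kstest(pvals, "uniform").pvalue > 1e-3
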