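"""Size grid construction, vital-rate fitting, and kernel assembly."""

import numpy as np
import pandas as pd
import pytest

import reefscape as rs
from reefscape.demography import MIN_COLONY_AREA_CM2
from reefscape.kernel import EGG, LARVA, N_DISCRETE, SETTLER

from conftest import scalar_type_spec, tiny_grid, toy_kernel


class TestSizeGrid:
    def test_default_class_count_and_bounds(self):
        g = rs.build_size_grid(1000.0, n_classes=100)
        assert g.n_classes == 100
        assert g.bounds[0] == pytest.approx(np.pi * 0.25, abs=1e-12)  # 1 cm diameter
        assert g.bounds[0] == pytest.approx(0.7854, abs=1e-4)
        assert g.bounds[-1] == pytest.approx(900.0)  # 90% of the largest colony

    def test_areas_are_log_midpoints_inside_classes(self):
        g = rs.build_size_grid(500.0, n_classes=10)
        assert np.all(np.diff(g.bounds) > 0)
        assert np.all(g.areas > g.bounds[:-1]) and np.all(g.areas < g.bounds[1:])
        np.testing.assert_allclose(g.areas, np.sqrt(g.bounds[:-1] * g.bounds[1:]))

    @pytest.mark.parametrize("bad", [0.0, -5.0, np.nan, MIN_COLONY_AREA_CM2])
    def test_invalid_max_area_rejected(self, bad):
        with pytest.raises(ValueError):
            rs.build_size_grid(bad)


class TestFitGrowth:
    def test_recovers_known_log_linear_growth(self):
        rng = np.random.default_rng(42)
        la = rng.uniform(0, 3, size=500)
        la1 = 1.0 + 0.9 * la + rng.normal(0, 0.3, size=500)
        rec = pd.DataFrame({"area_t_cm2": 10**la, "area_t1_cm2": 10**la1})
        m = rs.fit_growth(rec)
        assert m.slope == pytest.approx(0.9, abs=0.05)
        assert m.intercept == pytest.approx(1.0, abs=0.1)
        assert m.sd == pytest.approx(0.3, abs=0.05)

    def test_identity_growth_gives_unit_slope_zero_spread(self):
        areas = np.logspace(0, 3, 50)
        rec = pd.DataFrame({"area_t_cm2": areas, "area_t1_cm2": areas})
        m = rs.fit_growth(rec)
        assert m.slope == pytest.approx(1.0, abs=1e-10)
        assert m.sd == pytest.approx(0.0, abs=1e-8)

    def test_exact_doubling_predicts_double(self):
        areas = np.logspace(0, 2, 40)
        rec = pd.DataFrame({"area_t_cm2": areas, "area_t1_cm2": 2 * areas})
        m = rs.fit_growth(rec)
        assert m.predict_mean_area(10.0) == pytest.approx(20.0, rel=1e-9)

    def test_single_size_is_singular(self):
        rec = pd.DataFrame({"area_t_cm2": [10.0] * 40, "area_t1_cm2": [12.0] * 40})
        with pytest.raises(ValueError):
            rs.fit_growth(rec)


class TestFitSurvival:
    def test_all_alive_clamps_high(self):
        rec = pd.DataFrame({"area_t_cm2": np.logspace(0, 3, 60), "survived": 1})
        m = rs.fit_survival(rec)
        p = m.prob(np.array([1.0, 50.0, 900.0]))
        assert np.all(p >= 0.999 - 1e-12)

    def test_recovers_logistic_parameters(self):
        rng = np.random.default_rng(7)
        la = rng.uniform(-1, 4, size=1000)
        p = 1 / (1 + np.exp(-(-1.0 + 0.5 * la)))
        y = (rng.random(1000) < p).astype(int)
        rec = pd.DataFrame({"area_t_cm2": 10**la, "survived": y})
        m = rs.fit_survival(rec)
        assert m.intercept == pytest.approx(-1.0, abs=0.15)
        assert m.slope == pytest.approx(0.5, abs=0.15)

    def test_size_independent_coinflip(self):
        rng = np.random.default_rng(3)
        la = rng.uniform(0, 3, size=2000)
        y = (rng.random(2000) < 0.5).astype(int)
        rec = pd.DataFrame({"area_t_cm2": 10**la, "survived": y})
        m = rs.fit_survival(rec)
        assert m.slope == pytest.approx(0.0, abs=0.1)
        assert float(np.mean(m.prob(10 ** la))) == pytest.approx(0.5, abs=0.05)


class TestFitFecundity:
    def test_constant_rates_multiply(self):
        rec = pd.DataFrame(
            {"area_t_cm2": np.logspace(0, 2, 50), "eggs_per_polyp": 6, "polyps_per_cm2": 10}
        )
        m = rs.fit_fecundity(rec)
        assert m.eggs(100.0) == pytest.approx(6 * 10 * 100.0, rel=1e-6)

    def test_zero_eggs_everywhere(self):
        rec = pd.DataFrame(
            {"area_t_cm2": np.logspace(0, 2, 50), "eggs_per_polyp": 0, "polyps_per_cm2": 10}
        )
        m = rs.fit_fecundity(rec)
        assert np.all(m.eggs(np.logspace(0, 3, 7)) == 0.0)

    def test_negative_counts_rejected(self):
        rec = pd.DataFrame(
            {"area_t_cm2": [1.0, 10.0], "eggs_per_polyp": [-1, 2], "polyps_per_cm2": [5, 5]}
        )
        with pytest.raises(ValueError):
            rs.fit_fecundity(rec)

    def test_poisson_rates_recovered_within_bootstrap_ci(self):
        rng = np.random.default_rng(19)
        la = rng.uniform(0, 3, size=1500)
        epp = rng.poisson(np.exp(1.0 + 0.3 * la))
        ppc = rng.poisson(np.exp(2.5 - 0.2 * la))
        rec = pd.DataFrame(
            {"area_t_cm2": 10**la, "area_t1_cm2": 10**la, "survived": 1,
             "eggs_per_polyp": epp, "polyps_per_cm2": ppc}
        )
        fits = rs.bootstrap_vital_rates(rec, n_boot=60, rng=np.random.default_rng(1))
        from reefscape.demography import bootstrap_se

        se = bootstrap_se(fits)
        point = rs.fit_fecundity(rec)
        for got, truth, key in [
            (point.epp_intercept, 1.0, "epp_intercept"),
            (point.epp_slope, 0.3, "epp_slope"),
            (point.ppc_intercept, 2.5, "ppc_intercept"),
            (point.ppc_slope, -0.2, "ppc_slope"),
        ]:
            assert abs(got - truth) <= 2 * se[key]


class TestKernelAssembly:
    def test_zero_survival_zeroes_growth_block(self, vital_rates, grid):
        from dataclasses import replace
        from reefscape.demography import SurvivalModel

        dead = replace(vital_rates, survival=SurvivalModel(0, 0, constant=0.0))
        k = rs.assemble_kernel(dead, scalar_type_spec(), grid)
        assert np.all(k.P_part == 0.0)

    def test_stay_in_place_limit_is_diagonal(self):
        """Spread -> 0 with identity growth concentrates each column on its
        own class with the survival probability."""
        from reefscape.demography import (FecundityModel, GrowthModel,
                                          SurvivalModel, VitalRates)

        g = tiny_grid(8)
        vit = rs.VitalRates(
            growth=GrowthModel(0.0, 1.0, 0.0),
            survival=SurvivalModel(0, 0, constant=0.8),
            fecundity=FecundityModel(-np.inf, 0, -np.inf, 0),
        )
        k = rs.assemble_kernel(vit, scalar_type_spec(), g)
        np.testing.assert_allclose(k.P_part, 0.8 * np.eye(8), atol=1e-12)
        np.testing.assert_allclose(k.survival_column_sums(), 0.8, atol=1e-12)

    def test_toy_kernel_matches_bruteforce_midpoint_sums(self):
        """3-class kernel equals an independently coded normal-CDF/eviction
        computation and the discrete chain lands in the right entries."""
        from scipy.stats import norm
        from reefscape.demography import (FecundityModel, GrowthModel,
                                          SurvivalModel, VitalRates)

        g = tiny_grid(3)
        growth = GrowthModel(intercept=0.2, slope=0.85, sd=0.3)
        surv = SurvivalModel(intercept=0.5, slope=0.4)
        fec = FecundityModel(0.5, 0.1, 1.0, 0.0)
        vit = rs.VitalRates(growth=growth, survival=surv, fecundity=fec)
        spec = scalar_type_spec(fertilisation_prob=0.6, first_year_survival=0.1)
        k = rs.assemble_kernel(vit, spec, g)

        # independent brute-force oracle
        expected = np.zeros((6, 6))
        lb = np.log10(g.bounds)
        for x in range(3):
            a = g.areas[x]
            s = 1 / (1 + np.exp(-(0.5 + 0.4 * np.log10(a))))
            mu = 0.2 + 0.85 * np.log10(a)
            masses = [norm.cdf(lb[y + 1], mu, 0.3) - norm.cdf(lb[y], mu, 0.3) for y in range(3)]
            masses[0] += norm.cdf(lb[0], mu, 0.3)
            masses[-1] += 1 - norm.cdf(lb[-1], mu, 0.3)
            for y in range(3):
                expected[3 + y, 3 + x] = s * masses[y]
            expected[0, 3 + x] = (
                np.exp(0.5 + 0.1 * np.log10(a)) * np.exp(1.0) * a
            )
        expected[1, 0] = 0.6  # eggs -> larvae
        expected[3, 2] = 0.1  # settlers -> smallest class
        np.testing.assert_allclose(k.matrix, expected, rtol=1e-10)

    def test_column_sums_equal_survival_probability(self, vital_rates, grid):
        """Eviction conserved: each continuous column sums to s(a_x)."""
        k = rs.assemble_kernel(vital_rates, scalar_type_spec(), grid)
        expected = vital_rates.survival.prob(grid.areas)
        np.testing.assert_allclose(k.survival_column_sums(), expected, atol=1e-10)


class TestIntrinsicGrowth:
    def test_identity_kernel_gives_zero_operator(self):
        r = rs.intrinsic_growth(np.eye(7))
        assert np.all(r == 0.0)

    def test_scalar_kernel(self):
        r = rs.intrinsic_growth(np.array([[1.3]]))
        assert r[0, 0] == pytest.approx(0.3)

    def test_elementwise_subtraction_oracle(self):
        rng = np.random.default_rng(5)
        M = rng.uniform(0, 1, size=(4, 4))
        np.testing.assert_array_equal(rs.intrinsic_growth(M), M - np.eye(4))


class TestReplicateKernels:
    def test_replicate_count_and_determinism(self, colony_records, type_specs):
        spec = type_specs["corymbose_acropora"]
        ks = rs.replicate_kernels(colony_records, spec, 5, seed=3, n_classes=20)
        assert len(ks) == 5
        ks2 = rs.replicate_kernels(colony_records, spec, 5, seed=3, n_classes=20)
        for a, b in zip(ks, ks2):
            np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_eigenvalue_spread_shrinks_with_more_records(self, true_params, type_specs):
        spec = type_specs["corymbose_acropora"]
        small = rs.gen_colony_data(true_params, n_colonies=60, n_years=1, seed=2)
        large = rs.gen_colony_data(true_params, n_colonies=600, n_years=1, seed=2)
        lam_small = [
            k.dominant_eigenvalue()
            for k in rs.replicate_kernels(small, spec, 25, seed=9, n_classes=20)
        ]
        lam_large = [
            k.dominant_eigenvalue()
            for k in rs.replicate_kernels(large, spec, 25, seed=9, n_classes=20)
        ]
        assert np.std(lam_large) < np.std(lam_small)


class TestKernelIterationProperties:
    def test_iteration_with_full_density_equals_matrix_power(self):
        """With D fixed at 1 the logistic update degenerates to plain
        multiplication by the kernel."""
        rng = np.random.default_rng(8)
        g = tiny_grid(4)
        P = rng.uniform(0, 0.2, size=(4, 4))
        k = toy_kernel(P, g, eggs=rng.uniform(0, 5, 4), fertilisation=0.5,
                       first_year_survival=0.1)
        r = rs.intrinsic_growth(k)
        N = rng.uniform(0, 10, size=7)
        iterated = N.copy()
        for _ in range(6):
            iterated = iterated + 1.0 * (r @ iterated)
        np.testing.assert_allclose(iterated, np.linalg.matrix_power(k.matrix, 6) @ N,
                                   atol=1e-12)

    def test_asymptotic_growth_factor_is_dominant_eigenvalue(self):
        rng = np.random.default_rng(21)
        g = tiny_grid(5)
        P = rng.uniform(0.05, 0.3, size=(5, 5))
        k = toy_kernel(P, g)
        lam = np.max(np.abs(np.linalg.eigvals(k.matrix)))
        N = np.ones(8)
        for _ in range(300):
            N = k.matrix @ N
            N /= N.sum()
        growth = (k.matrix @ N).sum() / N.sum()
        assert growth == pytest.approx(lam, rel=1e-8)
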