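"""Monte-Carlo GLV communities: sampling, equilibria, feasibility estimation."""

import math
import warnings

import numpy as np
import pytest

from thermorich import (
    CommunityThermalParams,
    EnsembleTPC,
    LogNormalTraitDist,
    ThermalContext,
    estimate_pfeas,
    feasibility_probability,
    relative_growth_distribution,
    sample_community,
    simulated_max_richness,
)
from thermorich.glv import (
    default_size_sweep,
    is_feasible,
    mean_field_diagnostics,
    realize_at_temperature,
    simulated_richness_curve,
    solve_equilibrium,
)


def weak_params(var_r=0.25, mu_a=math.log(0.01), var_a=0.0):
    """Community with unit intraspecific strength and tunable variation."""
    return CommunityThermalParams(
        growth=EnsembleTPC(0.0, 0.0, var_r, 0.0),
        inter=EnsembleTPC(mu_a, 0.0, var_a, 0.0),
    )


class TestSampleCommunity:
    def test_zero_variance_gives_identical_species(self, rng):
        params = CommunityThermalParams(
            growth=EnsembleTPC(0.2, 0.6, 0.0, 0.0),
            inter=EnsembleTPC(-4.0, 0.6, 0.0, 0.0),
        )
        c = sample_community(params, 5, rng)
        assert np.allclose(c.growth, c.growth[0])
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(c.inter[off], [-4.0, 0.6])

    def test_seed_reproducibility(self, experimental_ens):
        params = CommunityThermalParams(growth=experimental_ens, inter=experimental_ens)
        c1 = sample_community(params, 8, np.random.default_rng(9))
        c2 = sample_community(params, 8, np.random.default_rng(9))
        assert np.array_equal(c1.growth, c2.growth)
        assert np.array_equal(c1.inter, c2.inter)

    def test_pair_sensitivity_moments(self, experimental_ens, rng):
        params = CommunityThermalParams(growth=experimental_ens, inter=experimental_ens)
        c = sample_community(params, 100, rng)
        off = ~np.eye(100, dtype=bool)
        e_vals = c.inter[off][:, 1]
        se = math.sqrt(experimental_ens.var_e / len(e_vals))
        assert abs(e_vals.mean() - experimental_ens.mu_e) < 3 * se


class TestRealizeAtTemperature:
    def test_reference_temperature_recovers_normalisation(self, ctx13, rng):
        params = weak_params(var_r=0.3, var_a=0.2)
        c = sample_community(params, 6, rng)
        r, a = realize_at_temperature(c, ctx13.t_ref, ctx13)
        assert np.allclose(r, np.exp(c.growth[:, 0]))
        assert np.allclose(np.diag(a), 1.0)  # constant-1 intraspecific mode

    def test_common_sensitivity_scales_matrix_uniformly(self, ctx13, rng):
        params = CommunityThermalParams(
            growth=EnsembleTPC(0.0, 0.6, 0.2, 0.0),
            inter=EnsembleTPC(-4.0, 0.6, 0.2, 0.0),
        )
        c = sample_community(params, 5, rng)
        _, a_ref = realize_at_temperature(c, ctx13.t_ref, ctx13)
        _, a_hot = realize_at_temperature(c, 300.0, ctx13)
        off = ~np.eye(5, dtype=bool)
        ratios = a_hot[off] / a_ref[off]
        assert np.allclose(ratios, ratios[0])

    def test_single_entity_closed_form(self, ctx13):
        # offset -1 eV^-1, log_b0 = -5, e = 1 -> exp(-4)
        t = 1.0 / (ctx13.k * (1.0 / (ctx13.k * ctx13.t_ref) - 1.0))
        params = weak_params(mu_a=-5.0)
        c = sample_community(
            CommunityThermalParams(
                growth=EnsembleTPC(-5.0, 1.0, 0.0, 0.0),
                inter=EnsembleTPC(-5.0, 1.0, 0.0, 0.0),
            ),
            2,
            np.random.default_rng(0),
        )
        r, _ = realize_at_temperature(c, t, ctx13)
        assert r[0] == pytest.approx(math.exp(-4.0), rel=1e-9)


class TestSolveEquilibrium:
    def test_symmetric_two_species(self):
        x, resid = solve_equilibrium(np.ones(2), np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert np.allclose(x, 2.0 / 3.0)
        assert resid < 1e-12

    def test_identity_matrix(self):
        r = np.array([0.3, 1.2, 0.7])
        x, _ = solve_equilibrium(r, np.eye(3))
        assert np.allclose(x, r)

    def test_infeasible_component(self):
        a = np.full((3, 3), 0.6)
        np.fill_diagonal(a, 1.0)
        x, _ = solve_equilibrium(np.array([1.0, 0.2, 1.0]), a)
        assert x[1] < 0  # direct solve gives (1, -1, 1)
        assert not is_feasible(x)

    def test_singular_matrix_flagged(self):
        x, resid = solve_equilibrium(np.ones(2), np.ones((2, 2)))
        assert x is None or not np.all(np.isfinite(x)) or resid > 1e-8


class TestIsFeasible:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (np.array([0.1, 2.0]), True),
            (np.array([0.1, 0.0]), False),
            (np.array([0.1, -0.2]), False),
            (None, False),
        ],
    )
    def test_strict_positivity(self, x, expected):
        assert is_feasible(x) is expected

    def test_nonfinite_is_infeasible(self):
        with pytest.warns(UserWarning):
            assert not is_feasible(np.array([1.0, np.inf]))


class TestEstimatePfeas:
    def test_identical_weakly_competing_species_always_feasible(self, ctx13, rng):
        params = weak_params(var_r=0.0, var_a=0.0)
        est = estimate_pfeas(params, 10, ctx13.t_ref, ctx13, replicates=20, rng=rng)
        assert est.pfeas_hat == 1.0

    def test_seed_determinism(self, ctx13):
        params = weak_params()
        kwargs = dict(replicates=30)
        e1 = estimate_pfeas(params, 20, 290.0, ctx13,
                            rng=np.random.default_rng(4), **kwargs)
        e2 = estimate_pfeas(params, 20, 290.0, ctx13,
                            rng=np.random.default_rng(4), **kwargs)
        assert e1.n_feasible == e2.n_feasible

    def test_matches_analytic_probability(self, ctx13):
        # regime where the analytic Pfeas ~ 0.91: N=30, <a>=0.01, var_r=0.25
        params = weak_params()
        r_prime = relative_growth_distribution(LogNormalTraitDist(0.0, 0.25))
        p_analytic = feasibility_probability(30, 0.01, r_prime)
        est = estimate_pfeas(
            params, 30, ctx13.t_ref, ctx13, replicates=400,
            rng=np.random.default_rng(12),
        )
        se = math.sqrt(p_analytic * (1 - p_analytic) / est.n_replicates)
        assert abs(est.pfeas_hat - p_analytic) < 3 * se


class TestSimulatedRichness:
    def test_no_competition_hits_sweep_cap(self, ctx13):
        params = weak_params(mu_a=-30.0)  # vanishing interaction strength
        from thermorich.feasibility import RichnessCapWarning

        with pytest.warns(RichnessCapWarning):
            n = simulated_max_richness(
                params, ctx13.t_ref, ctx13, replicates=10,
                n_sweep=np.array([2, 4, 8]), rng=np.random.default_rng(1),
            )
        assert n == 8

    def test_nonincreasing_in_threshold(self, ctx13):
        params = weak_params()
        sweep = np.arange(2, 80, 4)
        lo = simulated_max_richness(
            params, ctx13.t_ref, ctx13, threshold=0.5, replicates=60,
            n_sweep=sweep, rng=np.random.default_rng(7),
        )
        hi = simulated_max_richness(
            params, ctx13.t_ref, ctx13, threshold=1.0, replicates=60,
            n_sweep=sweep, rng=np.random.default_rng(7),
        )
        assert hi <= lo

    def test_curve_seed_determinism(self, ctx13):
        params = weak_params(var_a=0.1)
        grid = np.array([280.0, 290.0, 300.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = simulated_richness_curve(
                params, grid, ctx13, replicates=15, rng=np.random.default_rng(5)
            )
            s2 = simulated_richness_curve(
                params, grid, ctx13, replicates=15, rng=np.random.default_rng(5)
            )
        assert np.array_equal(s1, s2)

    def test_default_sweep_brackets_predictions(self):
        sweep = default_size_sweep(np.array([10, 40]))
        assert sweep.min() == 2
        assert sweep.max() >= 64
        assert np.all(np.diff(sweep) > 0)


class TestMeanFieldDiagnostics:
    def test_zero_interaction_variance_gives_zero_covariance(self, ctx13, rng):
        params = weak_params(var_r=0.1, var_a=0.0)
        c = sample_community(params, 8, rng)
        d = mean_field_diagnostics(c, ctx13.t_ref, ctx13)
        assert d.cov_a_x == pytest.approx(0.0, abs=1e-15)
        assert d.var_a == pytest.approx(0.0, abs=1e-15)

    def test_neglected_covariance_shrinks_with_interaction_variance(self, ctx13):
        # the mean-field closure drops cov(a_ij, x_j); its magnitude scales
        # with the interaction spread and the community-mean correlation
        # stays small in this weak-interaction regime
        cov_mag = {}
        for var_a in (0.3, 0.005):
            vals, corrs = [], []
            rng = np.random.default_rng(77)
            params = weak_params(
                var_r=0.02, mu_a=math.log(0.08) - var_a / 2, var_a=var_a
            )
            tries = 0
            while len(vals) < 30 and tries < 300:
                tries += 1
                c = sample_community(params, 25, rng)
                try:
                    d = mean_field_diagnostics(c, ctx13.t_ref, ctx13)
                except ValueError:
                    continue
                vals.append(abs(d.cov_a_x))
                corrs.append(abs(d.corr_a_x))
            cov_mag[var_a] = np.mean(vals)
            assert np.mean(corrs) < 0.2
        assert cov_mag[0.005] < cov_mag[0.3]
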