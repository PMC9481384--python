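"""Unit and property tests for the rate equations and their composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from midsim.core_model import (CommunitySpec, DimensionError, NoiseSample,
                               derivatives, growth_rates,
                               interspecific_rates, intraspecific_rates,
                               metabolism_rates, rate_components,
                               substrate_consumption_rates,
                               substrate_production_rates)
from midsim.community_gen import sample_community

from conftest import single_species_community


def uniform_community(M, m, beta=0.5, **kw):
    base = dict(mu=np.full(M, 0.8), alpha=np.full(M, 0.3),
                beta=np.full((M, M), beta), K=np.full((M, m), 100.0),
                d=np.full(M, 0.1), c=np.full(M, 200.0),
                gamma=np.full(M, 5.0), Z=np.full(M, 100.0),
                r=np.full(m, 1.0 / m), h=np.full(m, 1.0 / m),
                x0=np.ones(M), S0=np.full(m, 100.0))
    base.update(kw)
    np.fill_diagonal(base["beta"], 0.0)
    return CommunitySpec(**base)


class TestGrowthRates:
    def test_no_substrate_means_no_growth(self):
        comm = uniform_community(3, 2)
        v = growth_rates(np.ones(3), np.zeros(2), comm, NoiseSample.zeros(3))
        assert np.all(v == 0.0)

    def test_half_saturation_halves_the_rate(self):
        comm = single_species_community(mu=0.24, K=50.0)
        v = growth_rates([1.0], [50.0], comm, NoiseSample.zeros(1))
        assert v[0] == pytest.approx(0.12)

    def test_saturation_limit_reaches_mu_times_x(self):
        K = 3.0
        comm = single_species_community(mu=0.5, K=K)
        v = growth_rates([2.0], [1e9 * K], comm, NoiseSample.zeros(1))
        assert v[0] == pytest.approx(0.5 * 2.0, abs=1e-6)

    def test_zero_abundance_contributes_zero(self):
        comm = uniform_community(4, 3)
        x = np.array([1.0, 0.0, 2.0, 0.0])
        v = growth_rates(x, np.full(3, 50.0), comm, NoiseSample.zeros(4))
        assert v[1] == 0.0 and v[3] == 0.0

    def test_dimension_mismatch_raises(self):
        comm = uniform_community(3, 2)
        with pytest.raises(DimensionError):
            growth_rates(np.ones(4), np.ones(2), comm, NoiseSample.zeros(3))


class TestCompetitionAndMetabolism:
    def test_intraspecific_direct_formula(self):
        comm = single_species_community(alpha=0.05)
        v = intraspecific_rates([2.0], comm, NoiseSample.zeros(1))
        assert v[0] == pytest.approx(0.2)

    def test_intraspecific_zero_at_zero_abundance(self):
        comm = single_species_community(alpha=0.7)
        assert intraspecific_rates([0.0], comm, NoiseSample.zeros(1))[0] == 0.0

    def test_negative_effective_alpha_clamps_to_zero_rate(self):
        comm = single_species_community(alpha=1.0)
        noise = NoiseSample.zeros(1)
        noise.eps2 = np.array([-1.0])
        v = intraspecific_rates([3.0], comm, noise, clamp="all")
        assert v[0] == 0.0

    def test_single_species_has_no_interspecific_loss(self):
        comm = single_species_community()
        v = interspecific_rates([5.0], comm, NoiseSample.zeros(1))
        assert v[0] == 0.0

    def test_two_species_direct_formula(self):
        comm = uniform_community(2, 1, beta=0.16)
        v = interspecific_rates(np.array([1.0, 1.0]), comm,
                                NoiseSample.zeros(2))
        assert v[0] == pytest.approx(0.16)

    def test_three_species_brute_force_sum(self):
        # independent brute force over j != i
        comm = uniform_community(3, 1, beta=0.5)
        x = np.array([1.0, 2.0, 3.0])
        v = interspecific_rates(x, comm, NoiseSample.zeros(3))
        brute = [sum(comm.beta[i, j] * x[i] * x[j]
                     for j in range(3) if j != i) for i in range(3)]
        assert v == pytest.approx(brute)
        assert v[0] == pytest.approx(0.5 * 1.0 * (2.0 + 3.0))

    @pytest.mark.parametrize("d,x,expected", [(0.03, 10.0, 0.3),
                                              (0.58, 2.0, 1.16),
                                              (0.3, 0.0, 0.0)])
    def test_metabolism_is_linear(self, d, x, expected):
        comm = single_species_community(d=d)
        assert metabolism_rates([x], comm)[0] == pytest.approx(expected)


class TestSubstrateRates:
    def test_production_single_species_half_saturated(self):
        # r_k = 0.5, c = 100, Z = 50, x = 50 -> 0.5 * 100 * (50/100) = 25
        comm = CommunitySpec(mu=[0.5], alpha=[0.1], beta=[[0.0]],
                             K=[[100.0]], d=[0.1], c=[100.0], gamma=[1.0],
                             Z=[50.0], r=[0.5], h=[1.0],
                             x0=[1.0], S0=[100.0])
        v = substrate_production_rates([50.0], comm, NoiseSample.zeros(1))
        assert v[0] == pytest.approx(25.0)

    def test_production_zero_at_zero_abundance(self):
        comm = uniform_community(3, 2)
        v = substrate_production_rates(np.zeros(3), comm, NoiseSample.zeros(3))
        assert np.all(v == 0.0)

    def test_production_two_species_brute_force(self):
        comm = uniform_community(2, 1, c=np.array([200.0, 300.0]),
                                 Z=np.array([100.0, 100.0]))
        v = substrate_production_rates(np.array([100.0, 300.0]), comm,
                                       NoiseSample.zeros(2))
        assert v[0] == pytest.approx(200 * 0.5 + 300 * 0.75)

    def test_production_shares_conserve_total(self):
        rng = np.random.default_rng(3)
        comm = sample_community(6, 4, rng=rng)
        x = rng.uniform(0, 5, 6)
        v = substrate_production_rates(x, comm, NoiseSample.zeros(6))
        total = np.sum(comm.c * x / (comm.Z + x))
        assert v.sum() == pytest.approx(total, rel=1e-12)

    def test_consumption_single_species(self):
        comm = single_species_community(mu=0.5, gamma=3.32, K=100.0, S0=100.0)
        v_b = growth_rates([1.0], [100.0], comm, NoiseSample.zeros(1))
        v_c = substrate_consumption_rates([1.0], [100.0], comm,
                                          NoiseSample.zeros(1))
        assert v_c[0] == pytest.approx(3.32 * v_b[0])

    def test_consumption_vanishes_without_substrate(self):
        comm = uniform_community(3, 2)
        v = substrate_consumption_rates(np.ones(3), np.zeros(2), comm,
                                        NoiseSample.zeros(3))
        assert np.all(v == 0.0)

    def test_consumption_split_follows_h_shares(self):
        comm = uniform_community(2, 2, h=np.array([0.3, 0.7]))
        v = substrate_consumption_rates(np.ones(2), np.full(2, 80.0), comm,
                                        NoiseSample.zeros(2))
        assert v[0] / v.sum() == pytest.approx(0.3, rel=1e-12)

    def test_consumption_shares_eps1_with_growth(self):
        # the growth disturbance must propagate into consumption
        comm = single_species_community(mu=0.5, gamma=2.0, K=100.0, S0=100.0)
        noise = NoiseSample.zeros(1)
        noise.eps1 = np.array([0.3])
        v_b = growth_rates([1.0], [100.0], comm, noise)
        v_c = substrate_consumption_rates([1.0], [100.0], comm, noise)
        assert v_c[0] == pytest.approx(2.0 * v_b[0], rel=1e-12)


class TestDerivatives:
    def test_zero_abundance_is_a_fixed_point(self):
        comm = uniform_community(4, 3)
        d = derivatives(np.zeros(4), np.full(3, 50.0), comm,
                        NoiseSample.zeros(4))
        assert np.all(d.dx == 0.0) and np.all(d.dS == 0.0)

    def test_single_species_reduces_to_logistic(self):
        comm = single_species_community(mu=0.5, alpha=0.05, d=0.1)
        x = 3.0
        d = derivatives([x], [1e12], comm, NoiseSample.zeros(1))
        assert d.dx[0] == pytest.approx((0.5 - 0.1) * x - 0.05 * x**2,
                                        rel=1e-6)

    def test_composition_matches_individual_rate_ops(self, medium_community):
        comm = medium_community
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.uniform(0, 3, comm.M)
            S = rng.uniform(0, 5e4, comm.m)
            noise = NoiseSample.zeros(comm.M)
            d = derivatives(x, S, comm, noise)
            expected_dx = (growth_rates(x, S, comm, noise)
                           - intraspecific_rates(x, comm, noise)
                           - interspecific_rates(x, comm, noise)
                           - metabolism_rates(x, comm))
            expected_dS = (substrate_production_rates(x, comm, noise)
                           - substrate_consumption_rates(x, S, comm, noise))
            np.testing.assert_allclose(d.dx, expected_dx, rtol=1e-12)
            np.testing.assert_allclose(d.dS, expected_dS, rtol=1e-12)

    def test_rate_components_consistent_with_derivatives(self, small_community):
        comm = small_community
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 2, comm.M)
        S = rng.uniform(0, 2e4, comm.m)
        noise = NoiseSample.zeros(comm.M)
        g, l, vp, vc = rate_components(x, S, comm, noise)
        d = derivatives(x, S, comm, noise)
        np.testing.assert_allclose((g - l) * x, d.dx, rtol=1e-12)
        np.testing.assert_allclose(vp - vc, d.dS, rtol=1e-12)

    def test_pure_function_with_zero_noise(self, small_community):
        comm = small_community
        x = np.linspace(0.1, 1.0, comm.M)
        S = np.full(comm.m, 1e4)
        a = derivatives(x, S, comm, NoiseSample.zeros(comm.M))
        b = derivatives(x, S, comm, NoiseSample.zeros(comm.M))
        assert np.array_equal(a.dx, b.dx) and np.array_equal(a.dS, b.dS)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=6),
       st.integers(min_value=1, max_value=4),
       st.integers(min_value=0, max_value=2**31 - 1))
def test_every_rate_vanishes_where_abundance_is_zero(M, m, seed):
    rng = np.random.default_rng(seed)
    comm = sample_community(M, m, rng=rng)
    x = rng.uniform(0, 2, M)
    x[rng.integers(0, M)] = 0.0
    S = rng.uniform(0, 1e5, m)
    noise = NoiseSample.zeros(M)
    zeros = x == 0.0
    assert np.all(growth_rates(x, S, comm, noise)[zeros] == 0.0)
    assert np.all(intraspecific_rates(x, comm, noise)[zeros] == 0.0)
    assert np.all(interspecific_rates(x, comm, noise)[zeros] == 0.0)
    assert np.all(metabolism_rates(x, comm)[zeros] == 0.0)
    assert np.all(derivatives(x, S, comm, noise).dx[zeros] == 0.0)


def test_species_params_round_trip(small_community):
    comm = small_community
    rebuilt = type(comm).from_params(comm.species, comm.substrates,
                                     comm.x0, comm.S0)
    for name in ("mu", "alpha", "beta", "K", "d", "c", "gamma", "Z", "r", "h"):
        np.testing.assert_array_equal(getattr(comm, name),
                                      getattr(rebuilt, name))


def test_nonnegativity_contracts():
    with pytest.raises(ValueError):
        single_species_community(mu=-0.1)
    comm = uniform_community(2, 1)
    with pytest.raises(ValueError):
        growth_rates(np.array([-1.0, 1.0]), np.ones(1), comm,
                     NoiseSample.zeros(2))
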