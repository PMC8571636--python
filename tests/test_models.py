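import numpy as np
import pytest
from scipy.integrate import solve_ivp

from stresscomm import models
from stresscomm.models import (
    CommunityState,
    LVParams,
    MacArthurParams,
    ResourceLogistic,
    StompParams,
    absorbed_light_profile,
    carrying_capacity,
    per_capita_growth,
    resource_dynamics,
)


def make_macarthur(n=2, r=2, seed=0):
    rng = np.random.default_rng(seed)
    c = rng.uniform(0.0, 0.15, size=(n, r))
    c[np.arange(n), np.arange(min(n, r))] = rng.uniform(0.6, 1.0, size=min(n, r))
    w = rng.lognormal(0, 0.25, size=n)
    growth = ResourceLogistic(rate=np.ones(r), capacity=np.ones(r))
    m = 0.3 * w * (c @ growth.capacity)
    return MacArthurParams(w=w, c=c, m=m, resource_growth=growth)


def make_stomp(n=2, seed=0, n_wl=31, n_depth=51, flat_peak=None):
    rng = np.random.default_rng(seed)
    wl = np.linspace(400.0, 700.0, n_wl)
    peaks = np.linspace(450.0, 650.0, n)
    spectra = 0.1 * np.exp(-((wl[None] - peaks[:, None]) ** 2) / (2 * 40.0**2))
    if flat_peak is not None:
        spectra = np.full((n, n_wl), flat_peak)
    return StompParams(
        phi=rng.lognormal(0, 0.25, size=n), loss=np.full(n, 0.3), depth=10.0,
        wavelengths=wl, absorption_spectra=spectra,
        incident_spectrum=np.ones(n_wl),
        background_attenuation=np.full(n_wl, 0.05), n_depth=n_depth)


class TestPerCapitaGrowth:
    def test_lv_zero_at_symmetric_equilibrium(self, symmetric_lv_pair):
        state = CommunityState(np.array([2 / 3, 2 / 3]))
        g = per_capita_growth(symmetric_lv_pair, state)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_lv_empty_community_grows_at_mu(self):
        p = LVParams(mu=[0.7, 1.3, 2.0], alpha=np.eye(3))
        g = per_capita_growth(p, CommunityState(np.zeros(3)))
        np.testing.assert_allclose(g, p.mu)

    def test_macarthur_starves_without_resources(self):
        p = make_macarthur()
        state = CommunityState(np.ones(2), np.zeros(2))
        np.testing.assert_allclose(per_capita_growth(p, state), -p.m)

    def test_dimension_mismatch_raises(self, symmetric_lv_pair):
        with pytest.raises(ValueError):
            per_capita_growth(symmetric_lv_pair, CommunityState(np.ones(3)))

    def test_negative_abundance_raises(self, symmetric_lv_pair):
        with pytest.raises(ValueError):
            per_capita_growth(symmetric_lv_pair, CommunityState(np.array([-0.1, 1.0])))

    def test_stomp_growth_monotone_in_phi(self):
        base = make_stomp()
        state = CommunityState(np.array([5.0, 5.0]))
        g_lo = per_capita_growth(base, state)
        boosted = models.with_focal_traits(base, base.phi * 1.5)
        g_hi = per_capita_growth(boosted, state)
        assert np.all(g_hi > g_lo)


class TestResourceDynamics:
    def test_zero_at_capacity_without_consumers(self):
        p = make_macarthur()
        state = CommunityState(np.zeros(2), p.resource_growth.capacity.copy())
        np.testing.assert_allclose(resource_dynamics(p, state), 0.0, atol=1e-14)

    def test_positive_below_capacity_without_consumers(self):
        p = make_macarthur()
        state = CommunityState(np.zeros(2), 0.4 * p.resource_growth.capacity)
        assert np.all(resource_dynamics(p, state) > 0)

    def test_euler_relaxation_reaches_closed_form(self):
        # one consumer held at fixed N: each resource relaxes to
        # R* = K (1 - c N / r) (logistic supply minus mass-action uptake)
        p = make_macarthur(n=1, r=2, seed=3)
        N = np.array([0.5])
        R = np.full(2, 0.9)
        dt = 1e-3
        for _ in range(40000):
            R = R + dt * resource_dynamics(p, CommunityState(N, R))
        g = p.resource_growth
        expected = g.capacity * (1.0 - p.c[0] * N[0] / g.rate)
        np.testing.assert_allclose(R, expected, rtol=1e-5)

    def test_rejects_non_macarthur(self, symmetric_lv_pair):
        with pytest.raises(TypeError):
            resource_dynamics(symmetric_lv_pair, CommunityState(np.ones(2)))


class TestAbsorbedLight:
    def test_unattenuated_at_zero_abundance(self):
        p = make_stomp()
        p = StompParams(phi=p.phi, loss=p.loss, depth=p.depth,
                        wavelengths=p.wavelengths,
                        absorption_spectra=p.absorption_spectra,
                        incident_spectrum=p.incident_spectrum,
                        background_attenuation=np.zeros_like(p.wavelengths))
        gamma = absorbed_light_profile(p, np.zeros(2), depth_point=7.0)
        expected = np.trapezoid(p.absorption_spectra * p.incident_spectrum,
                                p.wavelengths, axis=1)
        np.testing.assert_allclose(gamma, expected)

    def test_zero_incident_means_zero_absorption(self):
        p = make_stomp()
        p = StompParams(phi=p.phi, loss=p.loss, depth=p.depth,
                        wavelengths=p.wavelengths,
                        absorption_spectra=p.absorption_spectra,
                        incident_spectrum=np.zeros_like(p.wavelengths),
                        background_attenuation=p.background_attenuation)
        gamma = absorbed_light_profile(p, np.array([3.0, 1.0]), depth_point=2.0)
        np.testing.assert_allclose(gamma, 0.0)

    def test_flat_spectrum_matches_analytic_beer_lambert(self):
        # wavelength-flat absorption k: gamma(z) = W k I exp(-(kN+a) z)
        k, a, N = 0.02, 0.05, 4.0
        p = make_stomp(n=1, flat_peak=k)
        z = 3.7
        gamma = absorbed_light_profile(p, np.array([N]), depth_point=z)
        width = p.wavelengths[-1] - p.wavelengths[0]
        expected = width * k * np.exp(-(k * N + a) * z)
        np.testing.assert_allclose(gamma, [expected], rtol=1e-12)

    def test_depth_outside_column_raises(self):
        p = make_stomp()
        with pytest.raises(ValueError):
            absorbed_light_profile(p, np.zeros(2), depth_point=11.0)


class TestCarryingCapacity:
    def test_lv_closed_form(self):
        p = LVParams(mu=[1.0], alpha=[[2.0]])
        assert carrying_capacity(p, 0) == pytest.approx(0.5)

    def test_lv_scales_linearly_with_stressed_trait(self):
        p = LVParams(mu=[1.0], alpha=[[2.0]])
        stressed = models.with_focal_traits(p, np.array([0.5]))
        assert carrying_capacity(stressed, 0) == pytest.approx(0.25)

    def test_macarthur_single_species_single_resource_closed_form(self):
        # coupled linear system: R* from w c R = m, N* from r(1-R/K) = c N
        p = make_macarthur(n=1, r=1, seed=5)
        K = carrying_capacity(p, 0)
        g = p.resource_growth
        R_star = p.m[0] / (p.w[0] * p.c[0, 0])
        N_star = g.rate[0] * (1 - R_star / g.capacity[0]) / p.c[0, 0]
        assert K == pytest.approx(N_star, rel=1e-10)

    def test_stomp_monoculture_agrees_with_time_integration(self):
        p = make_stomp(n=1, seed=9)
        K = carrying_capacity(p, 0)
        assert K > 0

        def dyn(_, N):
            N = np.clip(N, 1e-12, None)
            return N * per_capita_growth(p, CommunityState(N))

        sol = solve_ivp(dyn, (0, 5000.0), [1.0], method="LSODA",
                        rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(K, rel=1e-6)

    def test_growth_vanishes_at_monoculture_equilibrium(self):
        for p in (make_macarthur(n=1, r=3, seed=2), make_stomp(n=1, seed=4)):
            K = carrying_capacity(p, 0)
            if isinstance(p, MacArthurParams):
                g = p.resource_growth
                R = g.capacity * np.clip(1 - p.c[0] * K / g.rate, 0, None)
                state = CommunityState(np.array([K]), R)
            else:
                state = CommunityState(np.array([K]))
            assert abs(per_capita_growth(p, state)[0]) < 1e-9


class TestNumericalIntegration:
    def test_stomp_grids_are_converged_by_doubling(self):
        coarse = make_stomp(n=2, n_wl=31, n_depth=51)
        fine = make_stomp(n=2, n_wl=61, n_depth=101)
        state_c = CommunityState(np.array([8.0, 3.0]))
        g_coarse = per_capita_growth(coarse, state_c)
        g_fine = per_capita_growth(fine, state_c)
        np.testing.assert_allclose(g_coarse, g_fine, rtol=2e-3)


class TestParameterSurface:
    def test_subset_keeps_selected_species(self):
        p = LVParams(mu=[1.0, 2.0, 3.0], alpha=np.eye(3) + 0.1)
        sub = models.subset(p, np.array([True, False, True]))
        np.testing.assert_allclose(sub.mu, [1.0, 3.0])
        assert sub.alpha.shape == (2, 2)

    def test_with_focal_traits_rejects_nonpositive(self, symmetric_lv_pair):
        with pytest.raises(ValueError):
            models.with_focal_traits(symmetric_lv_pair, np.array([1.0, 0.0]))

    def test_stomp_caps_at_four_species(self):
        with pytest.raises(ValueError):
            make_stomp(n=5)
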