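import itertools

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from stresscomm import models
from stresscomm.communities import CommunitySpec, sample_community
from stresscomm.equilibrium import prune_extinctions, solve_equilibrium
from stresscomm.models import CommunityState, LVParams, ResourceLogistic, MacArthurParams


class TestSolveEquilibrium:
    def test_lv_symmetric_pair_from_generic_start(self, symmetric_lv_pair):
        rep = solve_equilibrium(symmetric_lv_pair, np.array([0.5, 0.5]))
        assert rep.converged
        np.testing.assert_allclose(rep.state.abundances, [2 / 3, 2 / 3],
                                   atol=1e-8)

    def test_start_at_exact_equilibrium_is_immediate(self, symmetric_lv_pair):
        rep = solve_equilibrium(symmetric_lv_pair, np.array([2 / 3, 2 / 3]))
        assert rep.converged
        assert rep.iterations <= 1
        assert rep.residual_norm < 1e-12

    def test_residual_below_tolerance_at_reported_equilibrium(self):
        spec = CommunitySpec("macarthur", 4)
        p = sample_community(spec, np.random.default_rng(3))
        rep = solve_equilibrium(p)
        assert rep.converged
        g = models.per_capita_growth(p, rep.state)
        assert np.max(np.abs(g)) < 1e-10

    def test_macarthur_matches_stiff_time_integration(self):
        spec = CommunitySpec("macarthur", 2)
        p = sample_community(spec, np.random.default_rng(8))
        rep = solve_equilibrium(p)
        assert rep.converged
        n, r = p.n, p.r

        def dyn(_, x):
            N, R = np.clip(x[:n], 0, None), np.clip(x[n:], 0, None)
            state = CommunityState(N, R)
            dN = N * models.per_capita_growth(p, state)
            dR = models.resource_dynamics(p, state)
            return np.concatenate([dN, dR])

        x0 = np.concatenate([np.full(n, 0.05), p.resource_growth.capacity])
        sol = solve_ivp(dyn, (0, 5000.0), x0, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(
            sol.y[:, -1],
            np.concatenate([rep.state.abundances, rep.state.resources]),
            rtol=1e-6)

    def test_nonconvergence_is_reported_not_raised(self):
        # structurally singular interaction matrix: no interior root exists
        p = LVParams(mu=[1.0, 2.0], alpha=[[1.0, 1.0], [1.0, 1.0]])
        rep = solve_equilibrium(p, np.array([1.0, 1.0]))
        assert not rep.converged
        assert np.isfinite(rep.residual_norm)


class TestPruneExtinctions:
    def test_no_pruning_when_all_above_threshold(self, symmetric_lv_pair):
        rep = prune_extinctions(symmetric_lv_pair)
        assert rep.converged and rep.pruned_species == []
        np.testing.assert_allclose(rep.state.abundances, [2 / 3, 2 / 3],
                                   atol=1e-8)

    def test_competitive_exclusion_leaves_one_survivor(self, symmetric_lv_pair):
        # stressor ratio rho = 0.4 < alpha = 0.5 violates the coexistence
        # band, so species 2 is excluded and species 1 sits at its
        # stressed monoculture equilibrium
        e = np.array([1.0, 0.4])
        theta = symmetric_lv_pair.mu * e
        rep = prune_extinctions(symmetric_lv_pair, theta)
        assert rep.converged
        assert rep.pruned_species == [1]
        np.testing.assert_allclose(rep.state.abundances, [1.0, 0.0], atol=1e-8)

    def test_idempotent_on_own_output(self, symmetric_lv_pair):
        theta = symmetric_lv_pair.mu * np.array([1.0, 0.45])
        first = prune_extinctions(symmetric_lv_pair, theta)
        again = prune_extinctions(
            models.with_focal_traits(symmetric_lv_pair, theta),
            carrying_capacities=models.carrying_capacities(symmetric_lv_pair),
            initial_state=first.state)
        np.testing.assert_allclose(again.state.abundances,
                                   first.state.abundances, atol=1e-9)
        assert again.pruned_species == first.pruned_species

    def test_survivors_meet_threshold(self, rng):
        spec = CommunitySpec("lotka_volterra", 4)
        for seed in range(5):
            p = sample_community(spec, np.random.default_rng(seed))
            K = models.carrying_capacities(p)
            theta = p.mu * rng.beta(6.5, 0.25, size=4) ** 5
            rep = prune_extinctions(p, theta, carrying_capacities=K)
            if not rep.converged:
                continue
            alive = rep.state.survivors
            assert np.all(rep.state.abundances >= 0)
            assert np.all(rep.state.abundances[alive] >= 0.01 * K[alive] - 1e-12)
            assert np.all(rep.state.abundances[~alive] == 0)

    def test_invariant_under_species_relabeling(self):
        p = sample_community(CommunitySpec("lotka_volterra", 4),
                             np.random.default_rng(17))
        theta = p.mu * np.array([0.9, 0.3, 0.95, 0.5])
        rep = prune_extinctions(p, theta)
        perm = np.array([2, 0, 3, 1])
        p_perm = LVParams(mu=p.mu[perm], alpha=p.alpha[np.ix_(perm, perm)])
        rep_perm = prune_extinctions(p_perm, theta[perm])
        np.testing.assert_allclose(rep_perm.state.abundances,
                                   rep.state.abundances[perm], atol=1e-8)

    def test_all_species_can_go_extinct(self):
        p = LVParams(mu=[1.0, 1.0], alpha=[[1.0, 0.5], [0.5, 1.0]])
        # traits crushed to 0.1% of carrying capacity: nothing survives the
        # 1% threshold
        theta = p.mu * 1e-5
        rep = prune_extinctions(p, theta, carrying_capacities=np.array([1.0, 1.0]))
        assert rep.converged
        assert rep.state.abundances.sum() == 0
        assert sorted(rep.pruned_species) == [0, 1]


class TestBruteForceOracle:
    """Pruned LV equilibria agree with long-time integration, itself checked
    against exhaustive survivor-subset enumeration at n <= 4."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 4, 5, 7, 8, 9])
    def test_lv_pruning_matches_time_integration(self, seed, lv_time_integrator):
        rng = np.random.default_rng(seed)
        p = sample_community(CommunitySpec("lotka_volterra", 4), rng)
        from stresscomm.communities import screen_coexistence
        res = screen_coexistence(p)
        assert res.accept
        e = rng.beta(6.5, 0.25, size=(4, 8)).prod(axis=1)
        theta = p.mu * e
        K = models.carrying_capacities(p)
        rep = prune_extinctions(p, theta, carrying_capacities=K)
        assert rep.converged

        stressed = models.with_focal_traits(p, theta)
        final = lv_time_integrator(stressed, res.state.abundances)
        survivors_ode = final >= 0.01 * K
        np.testing.assert_array_equal(rep.state.survivors, survivors_ode)
        np.testing.assert_allclose(rep.state.abundances[survivors_ode],
                                   final[survivors_ode], rtol=1e-5)

    def test_integration_endpoint_is_a_feasible_subset_equilibrium(
            self, lv_time_integrator):
        rng = np.random.default_rng(42)
        p = sample_community(CommunitySpec("lotka_volterra", 4), rng)
        theta = p.mu * rng.beta(6.5, 0.25, size=(4, 10)).prod(axis=1)
        stressed = models.with_focal_traits(p, theta)
        final = lv_time_integrator(stressed, np.full(4, 0.2))
        alive = final > 1e-6
        # the reached endpoint must solve the subset linear system
        sub = models.subset(stressed, alive)
        np.testing.assert_allclose(
            sub.alpha @ final[alive], sub.mu, rtol=1e-6)
        # and be one of the 2^n enumerated feasible subsets
        feasible = []
        for r in range(1, 5):
            for combo in itertools.combinations(range(4), r):
                mask = np.zeros(4, bool)
                mask[list(combo)] = True
                sub_c = models.subset(stressed, mask)
                try:
                    N = np.linalg.solve(sub_c.alpha, sub_c.mu)
                except np.linalg.LinAlgError:
                    continue
                if np.all(N > 0):
                    feasible.append(frozenset(combo))
        assert frozenset(np.where(alive)[0]) in feasible
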