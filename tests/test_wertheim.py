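"""Bond integrals, mass balance, free energies, and coexistence."""

import numpy as np
import pytest
from scipy import integrate

from azeopatch import design_rules as dr
from azeopatch import wertheim as w
from azeopatch.fixtures import generate_rule_matrix
from azeopatch.interactions import (
    InteractionMatrix,
    KernFrenkelParams,
    MixtureSpec,
    SpeciesSpec,
    TETRAHEDRAL_VECTORS,
    bonding_volume,
)


class TestBondIntegral:
    def test_high_temperature_vanishes(self, n2c8s2):
        assert w.bond_integral(n2c8s2.kf, 1e6, 0.3) < 1e-9

    def test_zero_density_reference(self, n2c8s2):
        kf = n2c8s2.kf
        expected = bonding_volume(kf) * np.expm1(kf.epsilon / 0.1)
        assert np.isclose(w.bond_integral(kf, 0.1, 0.0), expected, rtol=1e-12)

    def test_quadrature_oracle(self, n2c8s2):
        """Direct numerical quadrature of the shell integral with the same
        contact expansion of g_HS."""
        kf = n2c8s2.kf
        T, rho = 0.08, 0.3
        phi = rho * np.pi / 6
        g0 = w.contact_value(phi)
        g1 = w.contact_slope(phi) / kf.sigma
        p = 0.5 * (1 - kf.cos_theta_max)

        def integrand(r):
            return (g0 + g1 * (r - kf.sigma)) * 4 * np.pi * r**2

        shell, _ = integrate.quad(integrand, kf.sigma, kf.well_range)
        expected = np.expm1(kf.epsilon / T) * p * p * shell
        assert np.isclose(w.bond_integral(kf, T, rho), expected, rtol=1e-10)

    def test_order_zero_uses_contact_value_only(self, n2c8s2):
        kf = n2c8s2.kf
        d0 = w.bond_integral(kf, 0.08, 0.3, order=0)
        phi = 0.3 * np.pi / 6
        expected = bonding_volume(kf) * np.expm1(kf.epsilon / 0.08) * w.contact_value(phi)
        assert np.isclose(d0, expected, rtol=1e-12)


class TestMassBalance:
    def test_zero_delta_all_unbonded(self, n2c8s2):
        state = w.ThermoState(0.08, 0.3, [0.5, 0.5])
        sol = w.solve_mass_balance(n2c8s2, state, 0.0)
        assert np.allclose(sol.values, 1.0)

    @pytest.mark.parametrize("T,rho", [(0.07, 0.1), (0.08, 0.3), (0.1, 0.5)])
    def test_equimolar_azeotropic_solution(self, n2c8s2, T, rho):
        state = w.ThermoState(T, rho, [0.5, 0.5])
        delta = w.bond_integral(n2c8s2.kf, T, rho)
        sol = w.solve_mass_balance(n2c8s2, state, delta)
        assert sol.spread < 1e-12
        rep = dr.check_bond_exclusivity(n2c8s2)
        xs = dr.solve_azeotropic_x(rep, state.packing_fraction, delta)
        assert abs(sol.values[0, 0] - xs) < 1e-10

    def test_multistart_uniqueness_small_system(self, rng):
        """Damped fixed-point iteration from 50 random starts converges to
        the same point as the production solver."""
        sp0 = SpeciesSpec(TETRAHEDRAL_VECTORS[:2], [0, 1])
        sp1 = SpeciesSpec(TETRAHEDRAL_VECTORS[:2], [1, 0])
        m = InteractionMatrix(np.array([[0, 1], [1, 0]]))
        mix = MixtureSpec((sp0, sp1), [0.3, 0.7], KernFrenkelParams(), m)
        state = w.ThermoState(0.09, 0.35, [0.3, 0.7])
        delta = w.bond_integral(mix.kf, 0.09, 0.35)
        ref = w.solve_mass_balance(mix, state, delta).values.reshape(-1)
        wm = w._coupling_matrix(mix, 0.35, [0.3, 0.7], delta)
        for _ in range(50):
            x = rng.random(4)
            for _ in range(20000):
                step = 1.0 / (1.0 + wm @ x) - x
                x += 0.3 * step
                if np.max(np.abs(step)) < 1e-14:
                    break
            assert np.max(np.abs(x - ref)) < 1e-9

    def test_color_permutation_invariance(self, n2c8s2, rng):
        perm = rng.permutation(8)
        inv = np.argsort(perm)
        m2 = n2c8s2.matrix.entries[np.ix_(inv, inv)]
        species = tuple(
            SpeciesSpec(s.patch_vectors, perm[s.patch_colors]) for s in n2c8s2.species
        )
        mix2 = MixtureSpec(species, [0.5, 0.5], n2c8s2.kf, InteractionMatrix(m2))
        state = w.ThermoState(0.08, 0.3, [0.5, 0.5])
        delta = w.bond_integral(n2c8s2.kf, 0.08, 0.3)
        a = w.solve_mass_balance(n2c8s2, state, delta).values
        b = w.solve_mass_balance(mix2, state, delta).values
        assert np.allclose(np.sort(a.ravel()), np.sort(b.ravel()), atol=1e-13)


class TestHelmholtz:
    def test_zero_delta_reduces_to_reference(self, n2c8s2):
        state = w.ThermoState(0.08, 0.3, [0.5, 0.5])
        fb = w.helmholtz_free_energy(n2c8s2, state, delta_bond=0.0)
        assert fb.f_bond == 0.0
        phi = state.packing_fraction
        assert np.isclose(fb.f_hs, phi * (4 - 3 * phi) / (1 - phi) ** 2)

    def test_fully_connected_bond_energy_composition_independent(self, rng):
        mix = generate_rule_matrix("fully_connected", 2, 4, rng)
        T, rho = 0.09, 0.3
        vals = []
        for x1 in np.linspace(0.05, 0.95, 7):
            state = w.ThermoState(T, rho, [x1, 1 - x1])
            vals.append(w.helmholtz_free_energy(mix, state).f_bond)
        assert max(vals) - min(vals) < 1e-12

    def test_equimolar_reduces_to_one_component(self, n2c8s2):
        """At the azeotrope the bonding free energy equals that of a
        one-component four-patch fluid whose single-bond strength carries the
        equimolar factor x = 1/2."""
        T, rho = 0.08, 0.3
        state = w.ThermoState(T, rho, [0.5, 0.5])
        delta = w.bond_integral(n2c8s2.kf, T, rho)
        f_mix = w.helmholtz_free_energy(n2c8s2, state, delta).f_bond
        # one-component reference: 4 patches, every patch exactly one partner
        sp = SpeciesSpec(TETRAHEDRAL_VECTORS, [0, 1, 2, 3])
        m = np.zeros((4, 4), dtype=int)
        m[0, 1] = m[1, 0] = m[2, 3] = m[3, 2] = 1
        ref = MixtureSpec((sp,), [1.0], n2c8s2.kf, InteractionMatrix(m))
        ref_state = w.ThermoState(T, rho, [1.0])
        f_one = w.helmholtz_free_energy(ref, ref_state, delta_bond=0.5 * delta).f_bond
        assert abs(f_mix - f_one) < 1e-12

    def test_composition_mirror_symmetry(self, n2c8s2):
        T, rho = 0.08, 0.3
        for x1 in (0.1, 0.27, 0.42):
            fa = w.free_energy_kT(n2c8s2, T, rho, [x1, 1 - x1])
            fb = w.free_energy_kT(n2c8s2, T, rho, [1 - x1, x1])
            assert abs(fa - fb) < 1e-12

    def test_close_packing_rejected(self, n2c8s2):
        with pytest.raises(ValueError):
            w.ThermoState(0.08, 1.5, [0.5, 0.5])


class TestGibbsAndCoexistence:
    def test_ideal_gas_equation_of_state(self, n2c8s2):
        dead = MixtureSpec(n2c8s2.species, [0.5, 0.5], n2c8s2.kf,
                           InteractionMatrix(np.zeros((8, 8), dtype=int)))
        T, P = 0.1, 1e-6
        res = w.gibbs_free_energy(dead, T, P, [0.5, 0.5])
        assert abs(P - res.rho * T) < 1e-8

    def test_pressure_self_consistency(self, n2c8s2):
        T, P = 0.08, 5e-5
        res = w.gibbs_free_energy(n2c8s2, T, P, [0.3, 0.7])
        assert abs(w.pressure(n2c8s2, T, res.rho, [0.3, 0.7]) - P) < 1e-8

    def test_smooth_density_derivative(self, n2c8s2):
        """The analytic pressure agrees with a plain finite difference of the
        total free energy (smoothness of f in rho)."""
        T, rho, x = 0.08, 0.25, [0.4, 0.6]
        h = 1e-5
        dfdr = (w.free_energy_kT(n2c8s2, T, rho + h, x)
                - w.free_energy_kT(n2c8s2, T, rho - h, x)) / (2 * h)
        p_fd = T * rho * rho * dfdr
        assert abs(p_fd - w.pressure(n2c8s2, T, rho, x)) < 1e-6

    def test_high_temperature_single_phase(self, n2c8s2):
        assert w.common_tangent(n2c8s2, 0.2, 1e-3) is None

    def test_coexistence_pair_and_mirror(self, n2c8s2):
        """Inside the lens the left-side tangent pair has a mirror pair on
        the right side (the species-relabeling symmetry of the design)."""
        T = 0.07
        P = 1.2e-5
        left = w.common_tangent(n2c8s2, T, P, x_window=(0.0, 0.55))
        assert left is not None
        x1, x2, r1, r2 = left
        assert x1 < 0.5 and x1 < x2
        right = w.common_tangent(n2c8s2, T, P, x_window=(0.45, 1.0))
        assert right is not None
        assert abs(right[0] - (1 - x2)) < 5e-4
        assert abs(right[1] - (1 - x1)) < 5e-4

    def test_equal_depth_construction_brackets_coexistence(self, n2c8s2):
        """The effective one-component construction at x = 0.5 finds a gas
        and a liquid minimum of equal depth at a single pressure."""
        co = w.fixed_x_coexistence(n2c8s2, 0.08, [0.5, 0.5])
        assert co is not None
        p_eq, rho_g, rho_l = co
        assert rho_g < 0.05 < rho_l
        ga = w.gibbs_free_energy(n2c8s2, 0.08, p_eq, [0.5, 0.5])
        assert len(ga.minima) >= 2
        assert abs(ga.minima[0][1] - ga.minima[-1][1]) < 1e-8
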