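"""Monte Carlo engine: energies, AVB detailed balance, NVT/Gibbs sampling,
and the crystal detector."""

import numpy as np
import pytest

from azeopatch import fixtures, mcsim
from azeopatch import wertheim as w
from azeopatch.geometry import matrix_to_quat, quat_identity, rotation_matrix_from_to
from azeopatch.interactions import (
    InteractionMatrix,
    KernFrenkelParams,
    MixtureSpec,
    SpeciesSpec,
    bonding_volume,
)
from azeopatch.mcsim import Configuration, GibbsState, MoveMix


@pytest.fixture(scope="module")
def single_patch_mixture():
    """One species with a single self-complementary patch."""
    sp = SpeciesSpec(np.array([[0.0, 0.0, 1.0]]), [0])
    return MixtureSpec((sp,), [1.0], KernFrenkelParams(),
                       InteractionMatrix(np.array([[1]])))


def _dimer(mixture, r):
    """Two particles bonded through their first compatible patch pair."""
    s0 = mixture.species[0]
    s1 = mixture.species[-1]
    from azeopatch.design_rules import partner_count_table

    # find a compatible patch pair between the two species
    colors0, colors1 = s0.patch_colors, s1.patch_colors
    pair = None
    for a, ca in enumerate(colors0):
        for g, cg in enumerate(colors1):
            if mixture.matrix.compatible(int(ca), int(cg)):
                pair = (a, g)
        if pair:
            break
    a, g = pair
    q0 = matrix_to_quat(rotation_matrix_from_to(s0.patch_vectors[a], [1.0, 0, 0]))
    q1 = matrix_to_quat(rotation_matrix_from_to(s1.patch_vectors[g], [-1.0, 0, 0]))
    pos = np.array([[5.0, 5.0, 5.0], [5.0 + r, 5.0, 5.0]])
    species = np.array([0, mixture.n_species - 1])
    _ = partner_count_table
    return Configuration(pos, np.array([q0, q1]), species, 12.0)


class TestTotalEnergy:
    def test_distant_particles_no_bond(self, n2c8s2):
        cfg = _dimer(n2c8s2, 3.0)
        e, graph = mcsim.total_energy(cfg, n2c8s2)
        assert e == 0.0 and len(graph.edges) == 0

    def test_constructed_dimer(self, n2c8s2):
        cfg = _dimer(n2c8s2, 1.1)
        e, graph = mcsim.total_energy(cfg, n2c8s2)
        assert e == -n2c8s2.kf.epsilon
        assert len(graph.edges) == 1

    def test_overlap_flagged(self, n2c8s2):
        cfg = _dimer(n2c8s2, 3.0)
        cfg.positions[1] = cfg.positions[0] + [0.5, 0, 0]
        e, graph = mcsim.total_energy(cfg, n2c8s2)
        assert np.isinf(e) and graph is None

    def test_diamond_cell_fully_bonded(self, n2c8s2):
        cfg = fixtures.build_diamond_seed(2, "cubic", n2c8s2)
        e, graph = mcsim.total_energy(cfg, n2c8s2)
        assert np.all(graph.degrees == 4)
        # half a bond of energy -eps per bond, 4 bonds per particle
        assert np.isclose(e / cfg.n_particles, -2.0 * n2c8s2.kf.epsilon)


class TestAVB:
    def test_detailed_balance_arithmetic(self, n2c8s2):
        """For a fixed microstate pair the forward/backward acceptance ratio
        equals the Boltzmann factor times the proposal-density ratio."""
        beta = 1.0 / 0.08
        vb = bonding_volume(n2c8s2.kf)
        volume = 12.0**3
        n_total, n_in, n_pair, du = 16, 2, 3, -1.0
        acc_b = mcsim.avb_acceptance("B", du, beta, n_in, n_total, n_pair, vb, volume)
        # reverse move from the bonded state: one more partner, opposite dU
        acc_u = mcsim.avb_acceptance("U", -du, beta, n_in + 1, n_total, n_pair,
                                     vb, volume)
        n_out = n_total - 1 - n_in
        v_in = n_pair * vb
        expected = np.exp(-beta * du) * (n_out / (n_in + 1)) * (v_in / (volume - v_in))
        assert abs(acc_b / acc_u - expected) < 1e-12 * expected

    def test_two_particle_bonded_fraction(self, single_patch_mixture):
        """Long-run bonded fraction of an isolated pair against the exact
        two-state partition function."""
        mix = single_patch_mixture
        L = 8.0
        vb = bonding_volume(mix.kf)
        T = 0.07
        pred = vb * np.exp(1 / T) / (L**3 - vb + vb * np.exp(1 / T))
        cfg = Configuration(np.array([[2.0, 2, 2], [5.0, 5, 5]]),
                            np.array([quat_identity(), quat_identity()]),
                            np.array([0, 0]), L)
        mm = MoveMix(p_rototranslation=0.3, p_avb_bond=0.35)
        mcsim.run_nvt(cfg, mix, T, 100, seed=17, sample_every=100, move_mix=mm)
        bonded = 0
        n_samples = 1500
        for k in range(n_samples):
            r = mcsim.run_nvt(cfg, mix, T, 25, seed=1000 + k, sample_every=25,
                              move_mix=mm)
            bonded += int(r.n_bonds[-1])
        f = bonded / n_samples
        # effective error accounting for sample correlation (tau ~ few samples)
        se = np.sqrt(pred * (1 - pred) / n_samples) * 2.0
        assert abs(f - pred) < 3 * se

    def test_noninteracting_sampling_stays_uniform(self, rng):
        """With eps -> 0 well depth the AVB machinery must leave the uniform
        distribution invariant: positions stay uniform in the box."""
        sp = SpeciesSpec(np.array([[0.0, 0.0, 1.0]]), [0])
        mix = MixtureSpec((sp,), [1.0], KernFrenkelParams(epsilon=1e-12),
                          InteractionMatrix(np.array([[1]])))
        mm = MoveMix(p_rototranslation=0.4, p_avb_bond=0.3)
        samples = []
        for k in range(30):  # independent replicas, one snapshot each
            cfg = fixtures.random_gas(32, 0.05, [1.0], mix,
                                      np.random.default_rng(1000 + k))
            r = mcsim.run_nvt(cfg, mix, 0.07, 150, seed=k, sample_every=150,
                              move_mix=mm)
            samples.append(r.config.positions.copy() / cfg.box_length)
        coords = np.concatenate(samples)[:, 0]
        # coarse uniformity: chi-square over 8 bins
        counts, _ = np.histogram(coords, bins=8, range=(0, 1))
        expected = len(coords) / 8
        chi2 = np.sum((counts - expected) ** 2 / expected)
        assert chi2 < 30  # 7 dof, p ~ 1e-4 cut


class TestRunNVT:
    def test_seeded_runs_bit_reproducible(self, n2c8s2, rng):
        cfg1 = fixtures.random_gas(48, 0.2, [0.5, 0.5], n2c8s2, rng)
        cfg2 = Configuration(cfg1.positions.copy(), cfg1.orientations.copy(),
                             cfg1.species_labels.copy(), cfg1.box_length)
        r1 = mcsim.run_nvt(cfg1, n2c8s2, 0.1, 300, seed=5, sample_every=300)
        r2 = mcsim.run_nvt(cfg2, n2c8s2, 0.1, 300, seed=5, sample_every=300)
        assert np.array_equal(r1.config.positions, r2.config.positions)
        assert np.array_equal(r1.config.orientations, r2.config.orientations)

    def test_quench_binds_monotonically(self, n2c8s2, rng):
        """Deep quench from a random gas: the energy trend is downward."""
        cfg = fixtures.random_gas(96, 0.3, [0.5, 0.5], n2c8s2, rng)
        res = mcsim.run_nvt(cfg, n2c8s2, 0.09, 4000, seed=8, sample_every=500)
        e = res.energies
        assert e[-1] < e[0]
        # no sustained uphill drift: each quarter no higher than the last
        quarters = [e[: len(e) // 4], e[len(e) // 4: len(e) // 2],
                    e[len(e) // 2: 3 * len(e) // 4], e[3 * len(e) // 4:]]
        means = [q.mean() for q in quarters if len(q)]
        assert means[-1] <= means[0]

    def test_pure_species_chains_only(self, n2c8s2, rng):
        """A single-species system can bond through at most two patches:
        the bond network is a set of chains (max degree 2)."""
        for x in ([1.0, 0.0], [0.0, 1.0]):
            cfg = fixtures.random_gas(64, 0.3, x, n2c8s2, rng)
            res = mcsim.run_nvt(cfg, n2c8s2, 0.08, 3000, seed=21, sample_every=1000)
            graph = mcsim.bond_graph(res.config, n2c8s2)
            assert len(graph.edges) > 0  # chains did form
            assert graph.degrees.max() <= 2


class TestGibbs:
    def test_conservation_and_reproducibility(self, n2c8s2, rng):
        box_a = fixtures.random_gas(16, 0.05, [0.5, 0.5], n2c8s2, rng)
        box_b = fixtures.random_gas(48, 0.3, [0.5, 0.5], n2c8s2, rng)
        state = GibbsState(box_a, box_b)
        v0 = state.total_volume
        n0 = state.total_per_species()
        res = mcsim.run_gibbs(state, n2c8s2, 0.1, 2000, seed=3, sample_every=500)
        assert abs(state.total_volume - v0) < 1e-9 * v0
        assert np.array_equal(state.total_per_species(), n0)
        assert len(res.rho_a) == 4

    def test_hard_sphere_boxes_equalize(self, n2c8s2, rng):
        """Without attractions there is no phase separation: box densities
        converge toward each other."""
        dead = MixtureSpec(n2c8s2.species, [0.5, 0.5], n2c8s2.kf,
                           InteractionMatrix(np.zeros((8, 8), dtype=int)))
        box_a = fixtures.random_gas(16, 0.02, [0.5, 0.5], dead, rng)
        box_b = fixtures.random_gas(48, 0.15, [0.5, 0.5], dead, rng)
        state = GibbsState(box_a, box_b)
        res = mcsim.run_gibbs(state, dead, 0.1, 6000, seed=4, sample_every=500)
        gap0 = abs(res.rho_a[0] - res.rho_b[0])
        gap1 = abs(np.mean(res.rho_a[-4:]) - np.mean(res.rho_b[-4:]))
        assert gap1 < max(0.5 * gap0, 0.05)


class TestCrystalDetector:
    def test_ideal_gas_fraction_zero(self, n2c8s2, rng):
        cfg = fixtures.random_gas(64, 0.05, [0.5, 0.5], n2c8s2, rng)
        frac, _ = mcsim.crystal_fraction(cfg, n2c8s2)
        assert frac == 0.0

    def test_cubic_seed_interior_fraction_one(self, n2c8s2):
        cfg = fixtures.build_diamond_seed(2, "cubic", n2c8s2)
        frac, largest = mcsim.crystal_fraction(cfg, n2c8s2)
        assert frac == 1.0
        assert largest == cfg.n_particles

    def test_hexagonal_seed_rejected_by_cubic_criterion(self, n2c8s2):
        cfg = fixtures.build_diamond_seed(3, "hexagonal", n2c8s2)
        frac, _ = mcsim.crystal_fraction(cfg, n2c8s2)
        assert frac == 0.0
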