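"""Pair potential, bonding volume, and the N2c8s2 design object."""

import numpy as np
import pytest

from azeopatch.geometry import quat_identity, random_quat
from azeopatch.interactions import (
    HARD_CORE_ENERGY,
    InteractionMatrix,
    KernFrenkelParams,
    MixtureSpec,
    SpeciesSpec,
    TETRAHEDRAL_VECTORS,
    bonding_volume,
    build_n2c8s2,
    pair_energy,
)


def _pose(x, q=None):
    return (np.array([x, 0.0, 0.0]) * 1.0 if np.isscalar(x) else np.asarray(x),
            quat_identity() if q is None else q)


def _facing_pair(mixture, r):
    """Two particles along x with a compatible patch pair exactly facing."""
    s0, s1 = mixture.species
    # patch 2 of species 0 has color 3 which binds color 7 = patch 2 of species 1
    v0 = s0.patch_vectors[1]  # color 2, partner color 6 on species 1 (slot 1)
    v1 = s1.patch_vectors[1]
    # rotate each particle so the chosen patch points along +/- x
    from azeopatch.geometry import matrix_to_quat, rotation_matrix_from_to

    q0 = matrix_to_quat(rotation_matrix_from_to(v0, np.array([1.0, 0, 0])))
    q1 = matrix_to_quat(rotation_matrix_from_to(v1, np.array([-1.0, 0, 0])))
    p0 = (np.zeros(3), q0)
    p1 = (np.array([r, 0.0, 0.0]), q1)
    return p0, p1


class TestPairEnergy:
    def test_hard_core_overlap(self, n2c8s2):
        p0 = (np.zeros(3), quat_identity())
        p1 = (np.array([0.5, 0, 0]), quat_identity())
        e, bond = pair_energy(p0, p1, *n2c8s2.species, n2c8s2.kf, n2c8s2.matrix)
        assert e == HARD_CORE_ENERGY and bond is None

    def test_beyond_well_no_interaction(self, n2c8s2):
        r = n2c8s2.kf.well_range + 1e-6
        p0 = (np.zeros(3), quat_identity())
        p1 = (np.array([r, 0, 0]), quat_identity())
        e, bond = pair_energy(p0, p1, *n2c8s2.species, n2c8s2.kf, n2c8s2.matrix)
        assert e == 0.0 and bond is None

    def test_facing_compatible_patches_bond(self, n2c8s2):
        r = n2c8s2.kf.sigma + 0.5 * n2c8s2.kf.delta
        p0, p1 = _facing_pair(n2c8s2, r)
        e, bond = pair_energy(p0, p1, *n2c8s2.species, n2c8s2.kf, n2c8s2.matrix)
        assert e == -n2c8s2.kf.epsilon
        assert bond == (1, 1)

    def test_exchange_symmetry_random_poses(self, n2c8s2, rng):
        s0, s1 = n2c8s2.species
        for _ in range(200):
            p0 = (rng.random(3) * 3, random_quat(rng))
            p1 = (rng.random(3) * 3, random_quat(rng))
            e01, _ = pair_energy(p0, p1, s0, s1, n2c8s2.kf, n2c8s2.matrix)
            e10, _ = pair_energy(p1, p0, s1, s0, n2c8s2.kf, n2c8s2.matrix)
            assert e01 == e10

    def test_zero_matrix_never_bonds(self, n2c8s2, rng):
        dead = InteractionMatrix(np.zeros((8, 8), dtype=int))
        s0, s1 = n2c8s2.species
        r = n2c8s2.kf.sigma + 0.5 * n2c8s2.kf.delta
        p0, p1 = _facing_pair(n2c8s2, r)
        e, bond = pair_energy(p0, p1, s0, s1, n2c8s2.kf, dead)
        assert e == 0.0 and bond is None
        for _ in range(100):
            p0 = (rng.random(3) * 2.5, random_quat(rng))
            p1 = (rng.random(3) * 2.5, random_quat(rng))
            e, _ = pair_energy(p0, p1, s0, s1, n2c8s2.kf, dead)
            assert e >= 0.0

    def test_non_unit_quaternion_rejected(self, n2c8s2):
        p0 = (np.zeros(3), np.array([1.0, 0.2, 0, 0]))
        p1 = (np.array([1.1, 0, 0]), quat_identity())
        with pytest.raises(ValueError, match="unit quaternion"):
            pair_energy(p0, p1, *n2c8s2.species, n2c8s2.kf, n2c8s2.matrix)

    def test_small_periodic_box_rejected(self, n2c8s2):
        p0 = (np.zeros(3), quat_identity())
        p1 = (np.array([1.1, 0, 0]), quat_identity())
        with pytest.raises(ValueError, match="minimum image"):
            pair_energy(p0, p1, *n2c8s2.species, n2c8s2.kf, n2c8s2.matrix,
                        box_length=2.0)


class TestN2c8s2:
    def test_matrix_structure(self, n2c8s2):
        m = n2c8s2.matrix.entries
        assert np.array_equal(m, m.T)
        assert (m.sum(axis=1) == 1).all()  # bond exclusivity
        assert n2c8s2.matrix.trace == 2  # two self-interacting colors

    def test_species_and_colors(self, n2c8s2):
        assert n2c8s2.n_species == 2
        assert n2c8s2.matrix.n_colors == 8
        all_colors = np.sort(np.concatenate([s.patch_colors for s in n2c8s2.species]))
        assert np.array_equal(all_colors, np.arange(8))
        assert np.allclose(n2c8s2.composition, [0.5, 0.5])
        for s in n2c8s2.species:
            assert np.allclose(np.linalg.norm(s.patch_vectors, axis=1), 1.0)

    def test_pure_species_effective_valence_two(self, n2c8s2):
        # within one species only two patch slots can find partners: chains
        for i, s in enumerate(n2c8s2.species):
            own = set(s.patch_colors.tolist())
            bondable = sum(
                1 for c in s.patch_colors
                if set(np.flatnonzero(n2c8s2.matrix.entries[c]).tolist()) & own
            )
            assert bondable == 2


class TestBondingVolume:
    def test_degenerate_limits(self):
        assert bonding_volume(KernFrenkelParams(delta=1e-300)) < 1e-299
        assert bonding_volume(KernFrenkelParams(cos_theta_max=1.0)) == 0.0

    def test_monte_carlo_oracle_default_params(self, rng):
        kf = KernFrenkelParams(delta=0.2, cos_theta_max=0.98)
        vb = bonding_volume(kf)
        est, err = _mc_bonding_volume(kf, rng, n=10_000_000)
        assert abs(est - vb) < max(3 * err, 1e-3 * vb)

    def test_factorized_oracle_three_significant_figures(self, rng):
        """The patch alignment factors are independent of the bond direction
        by rotational symmetry, so sampling each acceptance factor separately
        gives the bonding volume to sub-percent precision."""
        kf = KernFrenkelParams(delta=0.2, cos_theta_max=0.98)
        vb = bonding_volume(kf)
        shell_vol = 4 * np.pi / 3 * (kf.well_range**3 - kf.sigma**3)
        hits = np.zeros(2)
        n_chunk, n_chunks = 10_000_000, 12
        for _ in range(n_chunks):
            for k in range(2):
                c = 1.0 - 2.0 * rng.random(n_chunk)  # cos(angle) of a uniform axis
                hits[k] += np.count_nonzero(c >= kf.cos_theta_max)
        p1, p2 = hits / (n_chunk * n_chunks)
        est = shell_vol * p1 * p2
        assert abs(est - vb) / vb < 5e-3

    @pytest.mark.parametrize("delta,cosmax", [(0.1, 0.95), (0.3, 0.9), (0.05, 0.99)])
    def test_monte_carlo_oracle_grid(self, delta, cosmax, rng):
        kf = KernFrenkelParams(delta=delta, cos_theta_max=cosmax)
        vb = bonding_volume(kf)
        est, err = _mc_bonding_volume(kf, rng, n=2_000_000)
        assert abs(est - vb) < 4 * err


def _mc_bonding_volume(kf, rng, n):
    """Brute-force pose sampling: relative position uniform in the shell,
    both patch orientations uniform on the sphere; bonded fraction times the
    shell volume times the two orientation acceptance factors is estimated
    jointly by sampling patch directions."""
    lo, hi = kf.sigma, kf.well_range
    shell_vol = 4 * np.pi / 3 * (hi**3 - lo**3)
    r = (lo**3 + rng.random(n) * (hi**3 - lo**3)) ** (1 / 3)
    rhat = rng.normal(size=(n, 3))
    rhat /= np.linalg.norm(rhat, axis=1)[:, None]
    v1 = rng.normal(size=(n, 3))
    v1 /= np.linalg.norm(v1, axis=1)[:, None]
    v2 = rng.normal(size=(n, 3))
    v2 /= np.linalg.norm(v2, axis=1)[:, None]
    c1 = np.sum(v1 * rhat, axis=1)
    c2 = -np.sum(v2 * rhat, axis=1)
    hit = (c1 >= kf.cos_theta_max) & (c2 >= kf.cos_theta_max)
    _ = r
    p = hit.mean()
    est = p * shell_vol
    err = shell_vol * np.sqrt(max(p * (1 - p), 1e-12) / n)
    return est, err


class TestSerialization:
    def test_matrix_csv_json_roundtrip(self, n2c8s2, tmp_path):
        m = n2c8s2.matrix
        m.to_csv(tmp_path / "m.csv")
        m.to_json(tmp_path / "m.json")
        assert np.array_equal(InteractionMatrix.from_csv(tmp_path / "m.csv").entries,
                              m.entries)
        assert np.array_equal(InteractionMatrix.from_json(tmp_path / "m.json").entries,
                              m.entries)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            InteractionMatrix(np.array([[0, 1], [0, 0]]))
        with pytest.raises(ValueError, match="0 or 1"):
            InteractionMatrix(np.array([[2, 0], [0, 0]]))

    def test_invalid_mixture_rejected(self, n2c8s2):
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureSpec(n2c8s2.species, [0.6, 0.6], n2c8s2.kf, n2c8s2.matrix)
        with pytest.raises(ValueError, match="unit norm"):
            SpeciesSpec(TETRAHEDRAL_VECTORS * 1.01, [0, 1, 2, 3])
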