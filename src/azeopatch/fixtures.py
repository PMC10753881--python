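"""Generators for test fixtures: rule-satisfying mixtures, diamond seed
lattices, and random gas configurations.

Every fixture is validated by the corresponding checker or energy routine
before it is returned, so fixtures cannot silently drift from the model.
"""

from __future__ import annotations

import numpy as np

from . import design_rules as rules
from .geometry import matrix_to_quat, quat_to_matrix
from .interactions import (
    TETRAHEDRAL_VECTORS,
    InteractionMatrix,
    KernFrenkelParams,
    MixtureSpec,
    SpeciesSpec,
)
from .mcsim import Configuration, total_energy

__all__ = [
    "generate_rule_matrix",
    "build_diamond_seed",
    "random_gas",
    "largest_remainder_counts",
]


class InfeasibleDesignError(ValueError):
    """No interaction matrix satisfies the requested rule at these sizes."""


def _random_kf() -> KernFrenkelParams:
    return KernFrenkelParams()


def generate_rule_matrix(
    rule: str, n_species: int, n_patches: int, rng: np.random.Generator, n: int = 1
) -> MixtureSpec:
    """Random mixture whose matrix provably satisfies the requested rule.

    ``rule`` is one of ``exclusivity``, ``multiplicity`` (binary, requires
    multiplicity ``n``) or ``fully_connected``.  The returned mixture is at
    the rule's azeotropic composition (uniform for fully connected) and is
    checker-verified before being returned.
    """
    if n_patches < 1 or n_species < 1:
        raise ValueError("need at least one species and one patch")
    vectors = _patch_vectors(n_patches)
    if rule == "exclusivity":
        mixture = _exclusivity_mixture(n_species, n_patches, vectors, rng)
        report = rules.check_bond_exclusivity(mixture)
    elif rule == "multiplicity":
        if n_species != 2:
            raise InfeasibleDesignError("multiplicity designs are binary")
        if n_patches % n != 0:
            raise InfeasibleDesignError(
                f"no design with {n_patches} patches satisfies the bonding rules "
                f"for the ratio 1:{n} (patch count not divisible by n)"
            )
        mixture = _multiplicity_mixture(n_patches, n, vectors, rng)
        report = rules.check_bond_multiplicity(mixture, n)
    elif rule == "fully_connected":
        mixture = _fully_connected_mixture(n_species, n_patches, vectors, rng)
        report = rules.check_fully_connected(mixture)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if not report.satisfied:
        raise RuntimeError("generator produced a matrix the checker rejects")
    if report.predicted_azeotrope is not None:
        mixture = mixture.with_composition(report.predicted_azeotrope)
    return mixture


def _patch_vectors(n_patches: int) -> np.ndarray:
    if n_patches <= 4:
        return TETRAHEDRAL_VECTORS[:n_patches]
    # evenly spread unit vectors (Fibonacci sphere) for larger valences
    k = np.arange(n_patches)
    z = 1.0 - 2.0 * (k + 0.5) / n_patches
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _exclusivity_mixture(n_species, n_patches, vectors, rng):
    n_colors = n_species * n_patches
    # random involution on colors (fixed points = self-complementary colors)
    order = rng.permutation(n_colors)
    partner = np.empty(n_colors, dtype=int)
    pool = list(order)
    while pool:
        a = pool.pop()
        if pool and rng.random() < 0.7:
            b = pool.pop(int(rng.integers(len(pool))))
            partner[a], partner[b] = b, a
        else:
            partner[a] = a
    m = np.zeros((n_colors, n_colors), dtype=int)
    for a, b in enumerate(partner):
        m[a, b] = 1
    colors = rng.permutation(n_colors).reshape(n_species, n_patches)
    species = tuple(SpeciesSpec(vectors, colors[i]) for i in range(n_species))
    x = np.full(n_species, 1.0 / n_species)
    return MixtureSpec(species, x, _random_kf(), InteractionMatrix(m))


def _multiplicity_mixture(n_patches, n, vectors, rng):
    """Binary 1:n design: species-2 colors bond either to one species-2
    color, or to a species-1 color that is repeated n times."""
    n_cross = int(rng.integers(1, n_patches // n + 1))  # cross-bonded sp1 colors
    n_a = n_patches // n - n_cross  # intra-sp1 colors (each repeated n times)
    # species 1 slots: n_a intra colors + n_cross cross colors, each n times
    sp1_colors = []
    color = 0
    intra1 = []
    cross1 = []
    for _ in range(n_a):
        intra1.append(color)
        sp1_colors += [color] * n
        color += 1
    for _ in range(n_cross):
        cross1.append(color)
        sp1_colors += [color] * n
        color += 1
    # species 2 slots: n_cross single partners + the rest intra-sp2 colors
    cross2 = []
    for _ in range(n_cross):
        cross2.append(color)
        color += 1
    intra2 = list(range(color, color + (n_patches - n_cross)))
    color += len(intra2)
    sp2_colors = cross2 + intra2
    m = np.zeros((color, color), dtype=int)
    for c in intra1:
        m[c, c] = 1  # sp1 self-pair: n partners on species 1
    for c1, c2 in zip(cross1, cross2):
        m[c1, c2] = m[c2, c1] = 1
    # pair up intra-sp2 colors (odd one left self-complementary)
    pool = list(rng.permutation(intra2))
    while len(pool) >= 2:
        a, b = pool.pop(), pool.pop()
        m[a, b] = m[b, a] = 1
    if pool:
        m[pool[0], pool[0]] = 1
    sp1 = SpeciesSpec(vectors, rng.permutation(sp1_colors))
    sp2 = SpeciesSpec(vectors, rng.permutation(sp2_colors))
    x = np.array([1.0 / (n + 1), n / (n + 1.0)])
    return MixtureSpec((sp1, sp2), x, _random_kf(), InteractionMatrix(m))


def _fully_connected_mixture(n_species, n_patches, vectors, rng):
    """Each patch index forms a clique of colors across all species."""
    n_colors = n_species * n_patches
    m = np.zeros((n_colors, n_colors), dtype=int)
    colors = np.arange(n_colors).reshape(n_species, n_patches)
    for p in range(n_patches):
        group = colors[:, p]
        for a in group:
            for b in group:
                m[a, b] = 1
    perm = rng.permutation(n_colors)
    m = m[np.ix_(perm, perm)]
    inv = np.argsort(perm)
    species = tuple(SpeciesSpec(vectors, inv[colors[i]]) for i in range(n_species))
    x = np.full(n_species, 1.0 / n_species)
    return MixtureSpec(species, x, _random_kf(), InteractionMatrix(m))


# -- diamond seeds ---------------------------------------------------------

# proper rotations of the cube (order 24): candidates for orienting a
# tetrahedral particle so its patches point along lattice bond directions
def _cube_rotations():
    mats = []
    from itertools import permutations, product

    for perm in permutations(range(3)):
        for signs in product((1, -1), repeat=3):
            m = np.zeros((3, 3))
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if np.isclose(np.linalg.det(m), 1.0):
                mats.append(m)
    return mats


_CUBE_ROTS = _cube_rotations()


def build_diamond_seed(
    n_cells: int, flavor: str, mixture: MixtureSpec, bond_length: float | None = None
) -> Configuration:
    """Periodic cubic-diamond or free-standing hexagonal-diamond seed.

    For the cubic flavor, species and orientations are solved against the
    mixture's interaction matrix by constraint propagation so that every
    nearest-neighbor pair forms a color-compatible bond; the builder verifies
    full interior valence with the energy routine before returning.  The
    hexagonal flavor (the competing polytype, which an azeotropic
    exclusivity design is built to avoid) is produced as a geometric
    cluster with patches along the bond directions, used as ground truth
    for the crystal detector.
    """
    if mixture.n_patches != 4:
        raise ValueError("diamond seeds require tetravalent (4-patch) species")
    kf = mixture.kf
    if bond_length is None:
        bond_length = kf.sigma * (1.0 + 0.5 * kf.delta)
    if flavor == "cubic":
        return _cubic_seed(n_cells, mixture, bond_length)
    if flavor == "hexagonal":
        return _hexagonal_seed(n_cells, mixture, bond_length)
    raise ValueError("flavor must be 'cubic' or 'hexagonal'")


def _cubic_seed(n_cells, mixture, bond_length):
    if n_cells % 2:
        raise ValueError(
            "periodic two-species diamond seeds need an even number of cells: "
            "the species pattern alternates with period two cells along [1-10]"
        )
    a = 4.0 * bond_length / np.sqrt(3.0)  # conventional cell edge
    cell = a / 4.0
    basis_a = [(0, 0, 0), (0, 2, 2), (2, 0, 2), (2, 2, 0)]
    sites = []
    for cx in range(n_cells):
        for cy in range(n_cells):
            for cz in range(n_cells):
                for bx, by, bz in basis_a:
                    x, y, z = 4 * cx + bx, 4 * cy + by, 4 * cz + bz
                    sites.append((x, y, z, 0))  # sublattice A
                    sites.append((x + 1, y + 1, z + 1, 1))  # sublattice B
    n = len(sites)
    coords = np.array([s[:3] for s in sites], dtype=float)
    sub = np.array([s[3] for s in sites])
    box = n_cells * 4
    pos = coords * cell
    box_length = box * cell
    # species from the chain decomposition: chains run along [110] and
    # alternate species between neighboring chains
    u = coords[:, 0] - coords[:, 1]
    species = ((np.round(u / 2).astype(int) % 2)).astype(np.int64)
    # neighbor map via integer arithmetic
    index = {tuple(c): i for i, c in enumerate(np.mod(coords, box).astype(int))}
    dirs_a = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)])
    neighbors = np.full((n, 4), -1, dtype=int)
    bond_dirs = np.empty((n, 4, 3))
    for i in range(n):
        dirs = dirs_a if sub[i] == 0 else -dirs_a
        for k, d in enumerate(dirs):
            key = tuple((np.asarray(sites[i][:3]) + d) % box)
            neighbors[i, k] = index[key]
            bond_dirs[i, k] = d / np.sqrt(3.0)
    orientations = _solve_orientations(mixture, species, neighbors, bond_dirs)
    quats = np.array([matrix_to_quat(R) for R in orientations])
    cfg = Configuration(pos, quats, species, box_length)
    # verify: fully bonded lattice (valence 4 everywhere, periodic)
    e, graph = total_energy(cfg, mixture)
    deg = graph.degrees if graph is not None else np.zeros(n)
    if graph is None or not np.all(deg == 4):
        raise RuntimeError("cubic seed failed bond verification")
    return cfg


def _solve_orientations(mixture, species, neighbors, bond_dirs):
    """Backtracking search for per-particle orientations under which every
    lattice bond pairs interaction-compatible patch colors."""
    n = len(species)
    body = [np.asarray(s.patch_vectors) for s in mixture.species]
    colors = [np.asarray(s.patch_colors) for s in mixture.species]
    compat = mixture.matrix.entries
    # per particle: candidate rotations aligning the body patches with the
    # four bond directions, and the color each bond direction receives
    cand_colors = []
    cand_rots = []
    for i in range(n):
        sp = int(species[i])
        opts_c, opts_r = [], []
        for rot in _CUBE_ROTS:
            rotated = body[sp] @ rot.T  # (4, 3)
            match = rotated @ bond_dirs[i].T  # alignment matrix
            assign = np.argmax(match, axis=0)  # patch index per bond slot
            if np.any(match[assign, np.arange(4)] < 0.999):
                continue
            opts_c.append(colors[sp][assign])
            opts_r.append(rot)
        cand_colors.append(opts_c)
        cand_rots.append(opts_r)
        if not opts_c:
            raise RuntimeError("no orientation aligns patches with the lattice")
    # back-pointing bond slot for each directed bond (i, k) -> (j, back)
    back_slot = np.empty((n, 4), dtype=int)
    for i in range(n):
        for k in range(4):
            j = neighbors[i, k]
            back_slot[i, k] = int(np.argmax(-(bond_dirs[j] @ bond_dirs[i, k])))

    def edge_ok(i, ci, j, cj):
        cols_i = cand_colors[i][ci]
        cols_j = cand_colors[j][cj]
        for k in range(4):
            if neighbors[i, k] == j:
                if compat[cols_i[k], cols_j[back_slot[i, k]]] == 0:
                    return False
        return True

    # constraint search with unit propagation and minimum-remaining-values:
    # parity constraints travel along bond chains, so propagating singleton
    # domains makes the search collapse onto a few global binary choices
    def propagate(domains, queue):
        while queue:
            i = queue.pop()
            ci = next(iter(domains[i]))
            for k in range(4):
                j = neighbors[i, k]
                allowed = {cj for cj in domains[j] if edge_ok(i, ci, j, cj)}
                if not allowed:
                    return False
                if len(allowed) < len(domains[j]):
                    domains[j] = allowed
                    if len(allowed) == 1:
                        queue.append(j)
        return True

    def search(domains):
        unresolved = [i for i in range(n) if len(domains[i]) > 1]
        if not unresolved:
            return domains
        i = min(unresolved, key=lambda p: len(domains[p]))
        for ci in sorted(domains[i]):
            trial = [set(dom) for dom in domains]
            trial[i] = {ci}
            if propagate(trial, [i]):
                result = search(trial)
                if result is not None:
                    return result
        return None

    import sys

    sys.setrecursionlimit(max(10_000, 4 * n))
    domains = [set(range(len(cand_colors[i]))) for i in range(n)]
    # seed: fix particle 0 arbitrarily (global gauge) and propagate
    solution = None
    for c0 in range(len(cand_colors[0])):
        trial = [set(dom) for dom in domains]
        trial[0] = {c0}
        if propagate(trial, [0]):
            solution = search(trial)
            if solution is not None:
                break
    if solution is None:
        raise RuntimeError("mixture incompatible with the cubic-diamond lattice")
    chosen = [next(iter(dom)) for dom in solution]
    return [cand_rots[i][chosen[i]] for i in range(n)]


def _hexagonal_seed(n_cells, mixture, bond_length):
    """Free-standing lonsdaleite cluster in a large box (ideal c/a)."""
    a = bond_length * np.sqrt(8.0 / 3.0)
    c = a * np.sqrt(8.0 / 3.0)
    a1 = np.array([a, 0, 0])
    a2 = np.array([-0.5 * a, 0.5 * np.sqrt(3) * a, 0])
    a3 = np.array([0, 0, c])
    frac = [
        (1 / 3, 2 / 3, 0.0),
        (2 / 3, 1 / 3, 0.5),
        (1 / 3, 2 / 3, 3 / 8),
        (2 / 3, 1 / 3, 7 / 8),
    ]
    pts = []
    for i in range(n_cells):
        for j in range(n_cells):
            for k in range(n_cells):
                for fa, fb, fc in frac:
                    pts.append((i + fa) * a1 + (j + fb) * a2 + (k + fc) * a3)
    pos = np.array(pts)
    pos -= pos.mean(axis=0)
    span = np.max(np.linalg.norm(pos, axis=1))
    box_length = 4.0 * span + 10.0
    pos += 0.5 * box_length
    n = len(pos)
    # orient patches along the local bond directions (any proper rotation)
    rc = mixture.kf.well_range
    d = pos[None, :, :] - pos[:, None, :]
    r2 = np.sum(d * d, axis=2)
    np.fill_diagonal(r2, np.inf)
    quats = np.empty((n, 4))
    body = np.asarray(mixture.species[0].patch_vectors)
    for i in range(n):
        nbr = np.flatnonzero(r2[i] < rc * rc)
        if len(nbr) >= 4:
            targets = d[i, nbr[:4]]
            targets = targets / np.linalg.norm(targets, axis=1)[:, None]
        else:
            targets = body.copy()
            k = len(nbr)
            if k:
                t = d[i, nbr] / np.linalg.norm(d[i, nbr], axis=1)[:, None]
                targets[:k] = t
        rot = _kabsch_proper(body, targets)
        quats[i] = matrix_to_quat(rot)
    species = (np.arange(n) % mixture.n_species).astype(np.int64)
    return Configuration(pos, quats, species, box_length)


def _kabsch_proper(src, dst):
    """Proper rotation best aligning src (4,3) onto dst (4,3)."""
    h = src.T @ dst
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


# -- random gas ------------------------------------------------------------


def largest_remainder_counts(n: int, x) -> np.ndarray:
    """Integer species counts summing to n, proportional to x (largest
    remainder / Hare allocation)."""
    x = np.asarray(x, dtype=float)
    raw = x * n
    base = np.floor(raw).astype(int)
    rem = raw - base
    short = n - base.sum()
    order = np.argsort(-rem)
    base[order[:short]] += 1
    return base


def random_gas(
    n: int,
    rho: float,
    x,
    mixture: MixtureSpec,
    rng: np.random.Generator,
    max_retries: int = 10_000,
) -> Configuration:
    """Overlap-free random configuration at density rho and composition x.

    Sequential insertion with rejection; fails loudly when the packing
    fraction is too high to place particles this way.
    """
    box_length = (n / rho) ** (1.0 / 3.0)
    sigma2 = mixture.kf.sigma**2
    counts = largest_remainder_counts(n, x)
    species = np.repeat(np.arange(len(counts)), counts).astype(np.int64)
    rng.shuffle(species)
    pos = np.empty((n, 3))
    for i in range(n):
        for attempt in range(max_retries):
            trial = rng.random(3) * box_length
            d = pos[:i] - trial
            d -= box_length * np.round(d / box_length)
            if i == 0 or np.all(np.sum(d * d, axis=1) >= sigma2):
                pos[i] = trial
                break
        else:
            raise RuntimeError(f"could not place particle {i} after {max_retries} tries")
    quats = np.array([_random_quat(rng) for _ in range(n)])
    cfg = Configuration(pos, quats, species, box_length)
    cfg.validate(mixture)
    return cfg


def _random_quat(rng):
    u1, u2, u3 = rng.random(3)
    a, b = np.sqrt(1 - u1), np.sqrt(u1)
    return np.array([a * np.sin(2 * np.pi * u2), a * np.cos(2 * np.pi * u2),
                     b * np.sin(2 * np.pi * u3), b * np.cos(2 * np.pi * u3)])
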