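"""Monte Carlo engine for Kern-Frenkel patchy mixtures.

NVT sampling with rototranslation and aggregation-volume-bias (AVB) moves,
Gibbs-ensemble coexistence between two coupled boxes, and bond / cluster /
crystal analysis.  The inner loops are numba kernels (``_kernels``); this
module owns the state objects, move bookkeeping that must be exact
(conserved totals in the Gibbs ensemble), and observables.

AVB moves (bias toward forming/breaking bonds, essential at low T where
bonds are many k_B T deep):

* AVB-B picks a target ``i`` and a particle ``j`` not bonded to it and
  re-poses ``j`` uniformly inside the bonding volume of a free compatible
  patch pair; accepted with
  ``min[1, e^{-beta dU} (N_out / (N_in + 1)) (n_pair V_b / V_out)]``.
* AVB-U re-poses a bonded neighbor uniformly in the complementary volume
  ``V_out = V - n_pair V_b``; accepted with
  ``min[1, e^{-beta dU} (N_in / (N - N_in)) (V_out / n_pair V_b)]``.

Here ``N_in`` is the number of particles bonded to the target, ``n_pair``
the number of free compatible patch pairs between target and candidate, and
``V_b`` the single-pair bonding volume.  The pair is detailed-balanced
against the Boltzmann distribution (see :func:`avb_acceptance`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .geometry import quat_to_matrix
from .interactions import MixtureSpec, bonding_volume

__all__ = [
    "Configuration",
    "GibbsState",
    "BondGraph",
    "MoveMix",
    "total_energy",
    "bond_graph",
    "avb_acceptance",
    "run_nvt",
    "run_gibbs",
    "crystal_fraction",
    "largest_cluster",
]


@dataclass
class Configuration:
    """Particle state in a cubic periodic box."""

    positions: np.ndarray  # (N, 3)
    orientations: np.ndarray  # (N, 4) unit quaternions
    species_labels: np.ndarray  # (N,)
    box_length: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.species_labels = np.asarray(self.species_labels, dtype=np.int64)
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("orientations must be unit quaternions")

    @property
    def n_particles(self) -> int:
        return len(self.species_labels)

    def lab_patches(self, mixture: MixtureSpec) -> np.ndarray:
        """(N, Np, 3) lab-frame patch vectors."""
        n, npatch = self.n_particles, mixture.n_patches
        out = np.empty((n, npatch, 3))
        for i in range(n):
            rot = quat_to_matrix(self.orientations[i])
            out[i] = mixture.species[int(self.species_labels[i])].patch_vectors @ rot.T
        return out

    def validate(self, mixture: MixtureSpec) -> None:
        """Raise if any hard-core overlap exists."""
        e, _ = total_energy(self, mixture)
        if not np.isfinite(e):
            raise ValueError("configuration contains hard-core overlaps")


@dataclass
class GibbsState:
    """Two coupled boxes exchanging volume and particles."""

    box_a: Configuration
    box_b: Configuration

    @property
    def total_volume(self) -> float:
        return self.box_a.box_length**3 + self.box_b.box_length**3

    def total_per_species(self) -> np.ndarray:
        n_sp = int(max(self.box_a.species_labels.max(initial=0),
                       self.box_b.species_labels.max(initial=0))) + 1
        out = np.zeros(n_sp, dtype=int)
        for cfg in (self.box_a, self.box_b):
            for s in cfg.species_labels:
                out[int(s)] += 1
        return out


@dataclass
class BondGraph:
    """Bond edges (i, patch_a, j, patch_g) with one-bond-per-patch enforced."""

    edges: np.ndarray  # (M, 4)
    n_particles: int

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_particles, dtype=int)
        for i, _, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbor_lists(self):
        nbrs = [[] for _ in range(self.n_particles)]
        for i, _, j, _ in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs


@dataclass
class MoveMix:
    """Per-move-type probabilities; the rest of the unit goes to AVB-U."""

    p_rototranslation: float = 0.8
    p_avb_bond: float = 0.1
    max_displacement: float = 0.1
    max_rotation: float = 0.1


def _kernel_args(cfg: Configuration, mixture: MixtureSpec):
    patches = cfg.lab_patches(mixture)
    colors = mixture.patch_color_table().astype(np.int64)
    compat = mixture.matrix.entries.astype(np.int8)
    kf = mixture.kf
    return patches, colors, compat, kf


def total_energy(cfg: Configuration, mixture: MixtureSpec):
    """Total energy and bond graph (energy = -eps * number of bonds)."""
    patches, colors, compat, kf = _kernel_args(cfg, mixture)
    n = cfg.n_particles
    idx = np.arange(n, dtype=np.int64)
    max_edges = n * mixture.n_patches
    edges = np.zeros((max_edges, 4), dtype=np.int64)
    m = K.bond_list_kernel(cfg.positions, patches, cfg.species_labels, colors,
                           compat, cfg.box_length, kf.sigma, kf.delta,
                           kf.cos_theta_max, idx, n, edges)
    if m < 0:
        return np.inf, None
    graph = BondGraph(edges[:m].copy(), n)
    # one-bond-per-patch: narrow patches make double bonding geometrically
    # impossible; assert rather than silently trusting it
    seen = set()
    for i, a, j, g in graph.edges:
        for key in ((int(i), int(a)), (int(j), int(g))):
            if key in seen:
                raise RuntimeError(f"patch {key} engaged in two bonds")
            seen.add(key)
    return -kf.epsilon * m, graph


def bond_graph(cfg: Configuration, mixture: MixtureSpec) -> BondGraph:
    e, graph = total_energy(cfg, mixture)
    if graph is None:
        raise ValueError("configuration contains hard-core overlaps")
    return graph


def avb_acceptance(direction: str, delta_u: float, beta: float, n_in: int,
                   n_total: int, n_pair: int, v_b: float, volume: float) -> float:
    """Acceptance probability of an AVB move (reference arithmetic).

    Mirrors the kernel exactly; used for detailed-balance checks.
    """
    v_in = n_pair * v_b
    v_out = volume - v_in
    if direction == "B":
        n_out = n_total - 1 - n_in
        ratio = np.exp(-beta * delta_u) * (n_out / (n_in + 1.0)) * (v_in / v_out)
    elif direction == "U":
        ratio = np.exp(-beta * delta_u) * (n_in / (n_total - n_in)) * (v_out / v_in)
    else:
        raise ValueError("direction must be 'B' or 'U'")
    return min(1.0, float(ratio))


@dataclass
class NVTResult:
    sweeps: np.ndarray
    energies: np.ndarray
    n_bonds: np.ndarray
    largest_cluster: np.ndarray
    crystal_fraction: np.ndarray
    acceptance: dict
    config: Configuration
    seed: int


def _body_patches(mixture: MixtureSpec) -> np.ndarray:
    return np.array([s.patch_vectors for s in mixture.species])


def run_nvt(
    cfg: Configuration,
    mixture: MixtureSpec,
    T: float,
    n_sweeps: int,
    move_mix: MoveMix | None = None,
    seed: int = 0,
    sample_every: int = 1000,
    measure_crystal: bool = False,
) -> NVTResult:
    """Metropolis NVT run; mutates ``cfg`` in place and returns observables.

    A sweep is N trial moves split between rototranslations and AVB-B/U per
    ``move_mix``.  Runs with equal seeds are bit-reproducible.
    """
    if move_mix is None:
        move_mix = MoveMix()
    patches, colors, compat, kf = _kernel_args(cfg, mixture)
    n = cfg.n_particles
    idx = np.arange(n, dtype=np.int64)
    body = _body_patches(mixture)
    vb = bonding_volume(kf)
    counters = np.zeros(6, dtype=np.int64)
    K.seed_kernel_rng(seed)
    sweeps_done = 0
    rows = []
    e, graph = total_energy(cfg, mixture)
    while sweeps_done < n_sweeps:
        chunk = min(sample_every, n_sweeps - sweeps_done)
        K.sweep_nvt(cfg.positions, patches, cfg.orientations, cfg.species_labels,
                    colors, compat, body, cfg.box_length,
                    kf.sigma, kf.delta, kf.cos_theta_max, kf.epsilon, 1.0 / T,
                    idx, n, move_mix.max_displacement, move_mix.max_rotation,
                    move_mix.p_rototranslation, move_mix.p_avb_bond, vb,
                    chunk, counters)
        sweeps_done += chunk
        cfg.positions %= cfg.box_length
        e, graph = total_energy(cfg, mixture)
        nb = len(graph.edges)
        lc = largest_cluster(graph)
        xf = crystal_fraction(cfg, mixture)[0] if measure_crystal else np.nan
        rows.append((sweeps_done, e, nb, lc, xf))
    arr = np.array(rows)
    acc = {
        "rototranslation": counters[0] / max(counters[1], 1),
        "avb_bond": counters[2] / max(counters[3], 1),
        "avb_unbond": counters[4] / max(counters[5], 1),
    }
    return NVTResult(arr[:, 0], arr[:, 1], arr[:, 2].astype(int),
                     arr[:, 3].astype(int), arr[:, 4], acc, cfg, seed)


def largest_cluster(graph: BondGraph) -> int:
    """Size of the largest bonded cluster."""
    parent = list(range(graph.n_particles))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, _, j, _ in graph.edges:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
    if graph.n_particles == 0:
        return 0
    counts = {}
    for i in range(graph.n_particles):
        r = find(i)
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


# -- Gibbs ensemble --------------------------------------------------------


@dataclass
class GibbsResultMC:
    rho_a: np.ndarray
    rho_b: np.ndarray
    x_a: np.ndarray
    x_b: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    state: GibbsState
    seed: int
    acceptance: dict

    def branch_summary(self, equilibration: float = 0.2, n_blocks: int = 10):
        """Block-averaged (rho, x1) of the dilute and dense branches.

        Boxes can swap roles during a run, so samples are assigned to
        branches by instantaneous density before averaging.  Branch
        compositions are particle-count weighted (ratio of summed counts),
        which keeps the estimator well behaved when a branch holds only a
        handful of particles.
        """
        m = len(self.rho_a)
        k0 = int(equilibration * m)
        ra, rb = self.rho_a[k0:], self.rho_b[k0:]
        xa, xb = self.x_a[k0:], self.x_b[k0:]
        na, nb = self.n_a[k0:], self.n_b[k0:]
        lo = ra < rb
        lo_rho = np.where(lo, ra, rb)
        hi_rho = np.where(lo, rb, ra)
        lo_x = np.where(lo, xa, xb)
        hi_x = np.where(lo, xb, xa)
        lo_n = np.where(lo, na, nb)
        hi_n = np.where(lo, nb, na)

        def block_stats(v, weights=None):
            blocks = np.array_split(np.arange(len(v)), n_blocks)
            means = []
            for b in blocks:
                if not len(b):
                    continue
                if weights is None:
                    means.append(v[b].mean())
                else:
                    wsum = weights[b].sum()
                    means.append((v[b] * weights[b]).sum() / max(wsum, 1e-300))
            means = np.array(means)
            return means.mean(), means.std(ddof=1) / np.sqrt(len(means))

        return {
            "dilute_rho": block_stats(lo_rho),
            "dense_rho": block_stats(hi_rho),
            "dilute_x": block_stats(lo_x, weights=lo_n),
            "dense_x": block_stats(hi_x, weights=hi_n),
        }


def run_gibbs(
    state: GibbsState,
    mixture: MixtureSpec,
    T: float,
    n_sweeps: int,
    seed: int = 0,
    move_mix: MoveMix | None = None,
    sample_every: int = 200,
    transfer_attempts: int | None = None,
    vol_max_lnstep: float = 0.02,
) -> GibbsResultMC:
    """Gibbs-ensemble run: NVT moves in each box plus one volume-exchange
    move and ``transfer_attempts`` particle transfers per sweep, all inside a
    numba kernel.  Total volume and per-species counts are conserved exactly
    (audited on return); volume moves that would shrink a box below twice
    the interaction range are rejected.  Runs with equal seeds are
    bit-reproducible.  Returns sampled (rho, x) time series per box and the
    final state.
    """
    if move_mix is None:
        move_mix = MoveMix()
    K.seed_kernel_rng(seed + 1)
    kf = mixture.kf
    colors = mixture.patch_color_table().astype(np.int64)
    compat = mixture.matrix.entries.astype(np.int8)
    body = _body_patches(mixture)
    vb = bonding_volume(kf)
    na0, nb0 = state.box_a.n_particles, state.box_b.n_particles
    n = na0 + nb0
    pos = np.concatenate([state.box_a.positions, state.box_b.positions])
    quat = np.concatenate([state.box_a.orientations, state.box_b.orientations])
    species = np.concatenate([state.box_a.species_labels, state.box_b.species_labels])
    merged = Configuration(pos, quat, species, max(state.box_a.box_length,
                                                  state.box_b.box_length))
    patches = merged.lab_patches(mixture)
    idx_a = np.full(n, -1, dtype=np.int64)
    idx_b = np.full(n, -1, dtype=np.int64)
    idx_a[:na0] = np.arange(na0)
    idx_b[:nb0] = np.arange(na0, n)
    counts = np.array([na0, nb0], dtype=np.int64)
    box_lengths = np.array([state.box_a.box_length, state.box_b.box_length])
    total_v0 = float(np.sum(box_lengths**3))
    totals0 = state.total_per_species()
    if transfer_attempts is None:
        transfer_attempts = max(1, n // 10)
    counters = np.zeros(6, dtype=np.int64)
    gibbs_counters = np.zeros(4, dtype=np.int64)
    rows = []
    done = 0
    while done < n_sweeps:
        chunk = min(sample_every, n_sweeps - done)
        K.sweep_gibbs(pos, patches, quat, species, colors, compat, body,
                      box_lengths, kf.sigma, kf.delta, kf.cos_theta_max,
                      kf.epsilon, 1.0 / T, idx_a, idx_b, counts,
                      move_mix.max_displacement, move_mix.max_rotation,
                      move_mix.p_rototranslation, move_mix.p_avb_bond, vb,
                      chunk, transfer_attempts, vol_max_lnstep, total_v0,
                      counters, gibbs_counters)
        done += chunk
        na, nb = int(counts[0]), int(counts[1])
        va, vb_ = box_lengths[0] ** 3, box_lengths[1] ** 3
        sp_a = species[idx_a[:na]]
        sp_b = species[idx_b[:nb]]
        rows.append((na / va, nb / vb_,
                     float(np.sum(sp_a == 0)) / max(na, 1),
                     float(np.sum(sp_b == 0)) / max(nb, 1), na, nb))
    # rebuild per-box configurations
    def rebuild(idx, count, length):
        sel = idx[:count]
        return Configuration(pos[sel] % length, quat[sel], species[sel], length)

    state.box_a = rebuild(idx_a, int(counts[0]), float(box_lengths[0]))
    state.box_b = rebuild(idx_b, int(counts[1]), float(box_lengths[1]))
    # conservation audit (exact bookkeeping invariants)
    assert abs(state.total_volume - total_v0) < 1e-9 * total_v0
    assert np.array_equal(state.total_per_species(), totals0)
    arr = np.array(rows)
    return GibbsResultMC(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3],
                         arr[:, 4], arr[:, 5], state, seed,
                         {"volume": gibbs_counters[0] / max(gibbs_counters[1], 1),
                          "transfer": gibbs_counters[2] / max(gibbs_counters[3], 1),
                          "rototranslation": counters[0] / max(counters[1], 1)})


# -- crystal analysis ------------------------------------------------------


def crystal_fraction(cfg: Configuration, mixture: MixtureSpec,
                     neighbor_mode: str = "distance"):
    """Fraction of particles in a cubic-diamond-like environment.

    A particle qualifies when it has exactly four neighbors and every one of
    its four bonds is *staggered*: the minimal dihedral angle between the
    other neighbors of the two bonded particles, measured about the bond
    axis, exceeds 30 degrees (ideal cubic diamond: 60; hexagonal diamond has
    one eclipsed bond at 0).  Returns ``(fraction,
    largest_crystalline_cluster)``.

    ``neighbor_mode`` selects the neighborhood: ``"distance"`` (any center
    within the well range; coloring-independent, the right choice for
    geometric ground-truth lattices) or ``"bonds"`` (the color-compatible
    bond network; the right choice during assembly, where unbonded gas
    particles loiter inside the open diamond cages).
    """
    mask, nbrs = _cubic_mask(cfg, mixture, neighbor_mode)
    n = cfg.n_particles
    frac = float(mask.mean()) if n else 0.0
    comp = _largest_component(mask, nbrs)
    return frac, len(comp)


def crystal_species_balance(cfg: Configuration, mixture: MixtureSpec,
                            neighbor_mode: str = "distance"):
    """Species counts inside the largest crystalline cluster."""
    mask, nbrs = _cubic_mask(cfg, mixture, neighbor_mode)
    comp = _largest_component(mask, nbrs)
    labels = cfg.species_labels[comp] if comp else np.array([], dtype=int)
    return np.array([int(np.sum(labels == s)) for s in range(mixture.n_species)])


def _largest_component(mask, nbrs):
    n = len(mask)
    seen = np.zeros(n, dtype=bool)
    best = []
    for i in range(n):
        if not mask[i] or seen[i]:
            continue
        comp, stack = [], [i]
        seen[i] = True
        while stack:
            a = stack.pop()
            comp.append(a)
            for b in nbrs[a]:
                if mask[b] and not seen[b]:
                    seen[b] = True
                    stack.append(b)
        if len(comp) > len(best):
            best = comp
    return best


def _cubic_mask(cfg, mixture, neighbor_mode: str = "distance"):
    """Per-particle cubic-diamond classification and the neighbor lists."""
    pos = cfg.positions
    n = cfg.n_particles
    box = cfg.box_length
    rc = mixture.kf.well_range
    # O(N^2) neighbor search, adequate at desk scale
    d = pos[None, :, :] - pos[:, None, :]
    d -= box * np.round(d / box)
    r2 = np.sum(d * d, axis=2)
    np.fill_diagonal(r2, np.inf)
    if neighbor_mode == "distance":
        nbrs = [np.flatnonzero(r2[i] < rc * rc) for i in range(n)]
    elif neighbor_mode == "bonds":
        graph = bond_graph(cfg, mixture)
        lists = graph.neighbor_lists()
        nbrs = [np.array(sorted(lst), dtype=int) for lst in lists]
    else:
        raise ValueError("neighbor_mode must be 'distance' or 'bonds'")
    mask = np.zeros(n, dtype=bool)
    for i in range(n):
        if len(nbrs[i]) != 4:
            continue
        ok = True
        for j in nbrs[i]:
            if len(nbrs[j]) < 2:
                ok = False  # dihedral not measurable: unclassifiable bond
                break
            axis = d[i, j] / np.linalg.norm(d[i, j])
            min_dih = np.pi
            for k in nbrs[i]:
                if k == j:
                    continue
                u = d[i, k]
                up = u - (u @ axis) * axis
                nu = np.linalg.norm(up)
                if nu < 1e-9:
                    continue
                up /= nu
                for m in nbrs[j]:
                    if m == i:
                        continue
                    wv = d[j, m]
                    wp = wv - (wv @ axis) * axis
                    nw = np.linalg.norm(wp)
                    if nw < 1e-9:
                        continue
                    ang = np.arccos(np.clip(up @ (wp / nw), -1.0, 1.0))
                    min_dih = min(min_dih, ang)
            if min_dih < np.pi / 6:
                ok = False
                break
        mask[i] = ok
    return mask, nbrs
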