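"""Species, patches, colors, the interaction matrix, and the Kern-Frenkel potential.

A patchy particle is a hard sphere of diameter ``sigma`` decorated with
``N_p`` attractive sites (patches) placed at fixed body-frame unit vectors.
Each patch carries a *color*; a symmetric boolean interaction matrix
``Upsilon`` states which colors may bond.  Two particles bond when their
center distance lies in ``[sigma, sigma + delta]`` and a compatible patch
pair is mutually aligned within the angular half-width ``theta_max``
(Kern-Frenkel criterion): the square well of depth ``epsilon`` is switched
on only if both ``cos(angle between patch axis and the center line))``
exceed ``cos_theta_max``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import minimum_image, quat_to_matrix

__all__ = [
    "KernFrenkelParams",
    "SpeciesSpec",
    "InteractionMatrix",
    "MixtureSpec",
    "TETRAHEDRAL_VECTORS",
    "HARD_CORE_ENERGY",
    "pair_energy",
    "bonding_volume",
    "build_n2c8s2",
]

#: The four tetrahedral patch directions (rows), unit norm.
TETRAHEDRAL_VECTORS = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / np.sqrt(3.0)

#: Sentinel energy returned on hard-core overlap.
HARD_CORE_ENERGY = np.inf


@dataclass(frozen=True)
class KernFrenkelParams:
    """Kern-Frenkel square-well parameters.

    epsilon : well depth (energy unit; 1 by convention)
    delta : well width, in units of sigma
    cos_theta_max : cosine of the angular half-width of a patch
    sigma : hard-core diameter (length unit; 1 by convention)
    """

    epsilon: float = 1.0
    delta: float = 0.2
    cos_theta_max: float = 0.98
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.delta > 0):
            raise ValueError(f"delta must be positive, got {self.delta}")
        if not (0 < self.cos_theta_max <= 1):
            raise ValueError(f"cos_theta_max must be in (0, 1], got {self.cos_theta_max}")
        if not (self.sigma > 0 and self.epsilon > 0):
            raise ValueError("sigma and epsilon must be positive")

    @property
    def well_range(self) -> float:
        """Outer cutoff sigma + delta*sigma."""
        return self.sigma * (1.0 + self.delta)


@dataclass(frozen=True)
class SpeciesSpec:
    """Patch geometry and coloring of one species.

    patch_vectors : (N_p, 3) body-frame unit vectors
    patch_colors : (N_p,) integer color indices into the interaction matrix
    """

    patch_vectors: np.ndarray
    patch_colors: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "patch_vectors", np.asarray(self.patch_vectors, dtype=float))
        object.__setattr__(self, "patch_colors", np.asarray(self.patch_colors, dtype=int))
        norms = np.linalg.norm(self.patch_vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("patch vectors must have unit norm")
        if len(self.patch_colors) != len(self.patch_vectors):
            raise ValueError("patch_colors and patch_vectors must have equal length")

    @property
    def n_patches(self) -> int:
        return len(self.patch_colors)


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric boolean color-compatibility table Upsilon."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=int)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("interaction matrix must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("interaction matrix must be symmetric")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")
        object.__setattr__(self, "entries", m)

    @property
    def n_colors(self) -> int:
        return self.entries.shape[0]

    @property
    def trace(self) -> int:
        """Number of self-complementary colors."""
        return int(np.trace(self.entries))

    def compatible(self, a: int, g: int) -> bool:
        return bool(self.entries[a, g])

    def partners_of(self, color: int) -> np.ndarray:
        return np.flatnonzero(self.entries[color])

    # -- serialization ---------------------------------------------------

    def to_csv(self, path) -> None:
        header = "," + ",".join(str(c) for c in range(self.n_colors))
        rows = [
            f"{c}," + ",".join(str(v) for v in self.entries[c]) for c in range(self.n_colors)
        ]
        with open(path, "w") as fh:
            fh.write(header + "\n" + "\n".join(rows) + "\n")

    @classmethod
    def from_csv(cls, path) -> "InteractionMatrix":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        body = [ln.split(",")[1:] for ln in lines[1:]]
        return cls(np.array(body, dtype=int))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"entries": self.entries.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "InteractionMatrix":
        with open(path) as fh:
            return cls(np.array(json.load(fh)["entries"], dtype=int))


@dataclass(frozen=True)
class MixtureSpec:
    """A multicomponent patchy mixture: species, composition, potential, matrix.

    All species share the same diameter and the same number of patches; they
    differ only in patch colors (and possibly placements).
    """

    species: tuple
    composition: np.ndarray
    kf: KernFrenkelParams = field(default_factory=KernFrenkelParams)
    matrix: InteractionMatrix = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        x = np.asarray(self.composition, dtype=float)
        object.__setattr__(self, "composition", x)
        if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-12:
            raise ValueError("composition must be nonnegative and sum to 1")
        if len(x) != len(self.species):
            raise ValueError("composition length must equal number of species")
        n_p = {s.n_patches for s in self.species}
        if len(n_p) != 1:
            raise ValueError("all species must have the same number of patches")
        if self.matrix is None:
            raise ValueError("an interaction matrix is required")
        for s in self.species:
            if np.any(s.patch_colors < 0) or np.any(s.patch_colors >= self.matrix.n_colors):
                raise ValueError("patch colors must index into the interaction matrix")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_patches(self) -> int:
        return self.species[0].n_patches

    def with_composition(self, x) -> "MixtureSpec":
        return replace(self, composition=np.asarray(x, dtype=float))

    def patch_color_table(self) -> np.ndarray:
        """(N_s, N_p) array of color indices."""
        return np.array([s.patch_colors for s in self.species])


def bonding_volume(kf: KernFrenkelParams) -> float:
    """Kern-Frenkel bonding volume V_b in units of sigma^3.

    The pose-space volume over which two compatible patches stay bonded:
    the spherical shell between sigma and sigma+delta times the two angular
    acceptance factors (1 - cos theta_max)/2, one per patch:

        V_b = (pi / 3) * [(sigma + delta)^3 - sigma^3] * (1 - cos_theta_max)^2
    """
    s3 = kf.sigma**3
    shell = (kf.sigma + kf.delta * kf.sigma) ** 3 - s3
    return (np.pi / 3.0) * shell * (1.0 - kf.cos_theta_max) ** 2


def pair_energy(
    p1,
    p2,
    s1: SpeciesSpec,
    s2: SpeciesSpec,
    kf: KernFrenkelParams,
    matrix: InteractionMatrix,
    box_length: float | None = None,
):
    """Kern-Frenkel pair energy of two posed particles.

    Parameters
    ----------
    p1, p2 : (position, quaternion) pose tuples
    box_length : cubic periodic box edge; ``None`` for open boundaries

    Returns
    -------
    (energy, bond) : energy is ``inf`` on hard-core overlap, ``-epsilon`` if a
        compatible, mutually aligned patch pair exists, else ``0``.  ``bond``
        is the (patch_on_1, patch_on_2) index pair of the most aligned
        bonding pair, or ``None``.  At most one bond per pair is counted.
    """
    pos1, q1 = p1
    pos2, q2 = p2
    for q in (q1, q2):
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise ValueError("orientations must be unit quaternions")
    dr = np.asarray(pos2, float) - np.asarray(pos1, float)
    if box_length is not None:
        if box_length < 2.0 * kf.well_range:
            raise ValueError("box smaller than 2*(sigma+delta): minimum image ambiguous")
        dr = minimum_image(dr, box_length)
    r = float(np.linalg.norm(dr))
    if r < kf.sigma:
        return HARD_CORE_ENERGY, None
    if r > kf.well_range:
        return 0.0, None
    rhat = dr / r
    v1 = s1.patch_vectors @ quat_to_matrix(q1).T  # lab-frame patches of 1
    v2 = s2.patch_vectors @ quat_to_matrix(q2).T
    c1 = v1 @ rhat  # alignment of 1's patches with +rhat
    c2 = v2 @ -rhat  # alignment of 2's patches with -rhat
    best = None
    best_score = -np.inf
    for a in range(s1.n_patches):
        if c1[a] < kf.cos_theta_max:
            continue
        for g in range(s2.n_patches):
            if c2[g] < kf.cos_theta_max:
                continue
            if not matrix.compatible(int(s1.patch_colors[a]), int(s2.patch_colors[g])):
                continue
            score = c1[a] + c2[g]
            if score > best_score:
                best_score = score
                best = (a, g)
    if best is None:
        return 0.0, None
    return -kf.epsilon, best


# -- the N2c8s2 design ----------------------------------------------------

#: Color partner map of the N2c8s2 matrix: two self-complementary colors on
#: species 0, one intra-species pair on species 1, two cross-species pairs.
_N2C8S2_PARTNERS = {0: 0, 1: 1, 2: 6, 3: 7, 4: 5, 5: 4, 6: 2, 7: 3}


def n2c8s2_matrix() -> InteractionMatrix:
    """The 8x8 N2c8s2 interaction matrix (symmetric, one 1 per row, trace 2)."""
    m = np.zeros((8, 8), dtype=int)
    for a, g in _N2C8S2_PARTNERS.items():
        m[a, g] = 1
    return InteractionMatrix(m)


def build_n2c8s2(
    composition=(0.5, 0.5), kf: KernFrenkelParams | None = None
) -> MixtureSpec:
    """The minimal SAT-designed binary cubic-diamond mixture.

    Two species with tetrahedral patches, eight colors, two self-interacting
    colors (both on species 0).  By bond exclusivity the equimolar mixture is
    azeotropic; pure components can only chain (effective valence two).
    """
    if kf is None:
        kf = KernFrenkelParams(delta=0.2, cos_theta_max=0.98)
    sp0 = SpeciesSpec(TETRAHEDRAL_VECTORS, [0, 2, 3, 1])
    sp1 = SpeciesSpec(TETRAHEDRAL_VECTORS, [4, 6, 7, 5])
    return MixtureSpec(
        species=(sp0, sp1),
        composition=np.asarray(composition, dtype=float),
        kf=kf,
        matrix=n2c8s2_matrix(),
    )
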