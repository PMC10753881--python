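"""Serialization: mixture YAML/JSON configs and extended-XYZ configurations."""

from __future__ import annotations

import json

import numpy as np
import yaml

from .interactions import (
    InteractionMatrix,
    KernFrenkelParams,
    MixtureSpec,
    SpeciesSpec,
)
from .mcsim import Configuration

__all__ = [
    "mixture_to_dict",
    "mixture_from_dict",
    "load_mixture",
    "save_mixture",
    "write_xyz",
    "read_xyz",
]

_MIXTURE_KEYS = {"species", "composition", "kern_frenkel", "interaction_matrix"}
_KF_KEYS = {"epsilon", "delta", "cos_theta_max", "sigma"}
_SPECIES_KEYS = {"patch_vectors", "patch_colors"}


def mixture_to_dict(mixture: MixtureSpec) -> dict:
    return {
        "species": [
            {
                "patch_vectors": s.patch_vectors.tolist(),
                "patch_colors": s.patch_colors.tolist(),
            }
            for s in mixture.species
        ],
        "composition": mixture.composition.tolist(),
        "kern_frenkel": {
            "epsilon": mixture.kf.epsilon,
            "delta": mixture.kf.delta,
            "cos_theta_max": mixture.kf.cos_theta_max,
            "sigma": mixture.kf.sigma,
        },
        "interaction_matrix": mixture.matrix.entries.tolist(),
    }


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def mixture_from_dict(data: dict) -> MixtureSpec:
    _check_keys(data, _MIXTURE_KEYS, "mixture config")
    kf_d = data.get("kern_frenkel", {})
    _check_keys(kf_d, _KF_KEYS, "kern_frenkel block")
    species = []
    for blk in data["species"]:
        _check_keys(blk, _SPECIES_KEYS, "species block")
        species.append(SpeciesSpec(np.array(blk["patch_vectors"]), blk["patch_colors"]))
    return MixtureSpec(
        species=tuple(species),
        composition=np.array(data["composition"], dtype=float),
        kf=KernFrenkelParams(**kf_d),
        matrix=InteractionMatrix(np.array(data["interaction_matrix"], dtype=int)),
    )


def load_mixture(path) -> MixtureSpec:
    text = open(path).read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return mixture_from_dict(data)


def save_mixture(mixture: MixtureSpec, path) -> None:
    data = mixture_to_dict(mixture)
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(data, fh, indent=1)
        else:
            yaml.safe_dump(data, fh)


def write_xyz(cfg: Configuration, path, comment: str = "") -> None:
    """Extended XYZ with species label and quaternion columns."""
    with open(path, "w") as fh:
        fh.write(f"{cfg.n_particles}\n")
        fh.write(
            f'Lattice="{cfg.box_length} 0 0 0 {cfg.box_length} 0 0 0 {cfg.box_length}" '
            'Properties=species:S:1:pos:R:3:quat:R:4 ' + comment + "\n"
        )
        for i in range(cfg.n_particles):
            x, y, z = cfg.positions[i]
            qw, qx, qy, qz = cfg.orientations[i]
            fh.write(
                f"S{int(cfg.species_labels[i])} {x:.10f} {y:.10f} {z:.10f} "
                f"{qw:.10f} {qx:.10f} {qy:.10f} {qz:.10f}\n"
            )


def read_xyz(path) -> Configuration:
    with open(path) as fh:
        n = int(fh.readline())
        header = fh.readline()
        box = float(header.split('"')[1].split()[0])
        pos = np.empty((n, 3))
        quat = np.empty((n, 4))
        species = np.empty(n, dtype=np.int64)
        for i in range(n):
            parts = fh.readline().split()
            species[i] = int(parts[0].lstrip("S"))
            pos[i] = [float(v) for v in parts[1:4]]
            quat[i] = [float(v) for v in parts[4:8]]
    return Configuration(pos, quat, species, box)
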