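"""Download-free fixtures: toy proteins and ground-truth trajectories.

Toy proteins are ideal alpha-helical C-alpha traces with charges at chosen
positions, emitted both as PDB text and as the coarse-grained model built
from that text (so the two are identical by construction).  Synthetic
trajectories carry a prescribed rotation-translation coupling slope, 1D
diffusion coefficient and noise level, giving the analysis stages labelled
ground truth.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .simulator import Trajectory, write_trajectory
from .structure_io import (
    CGProtein,
    DEFAULT_CHARGE_SCHEME,
    build_bdna,
    coarse_grain_protein,
    load_structure,
    write_bdna,
)

__all__ = [
    "ToyProteinSpec",
    "SyntheticTrajectorySpec",
    "make_toy_protein",
    "make_synthetic_trajectory",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class ToyProteinSpec:
    """Ideal helix: ~1.5 Å rise and ~100 degrees of twist per residue.

    ``charges`` maps 1-based residue positions to +1/-1; charged positions
    become LYS/GLU so the default charge scheme reproduces them.
    """

    n_residues: int = 20
    rise: float = 1.5
    twist_deg: float = 100.0
    radius: float = 2.3
    charges: dict[int, int] = field(default_factory=dict)
    contact_cutoff: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues")
        bad = [p for p in self.charges if not 1 <= p <= self.n_residues]
        if bad:
            raise ValueError(f"charged positions out of range: {bad}")
        if any(s not in (-1, 1) for s in self.charges.values()):
            raise ValueError("charge signs must be +1 or -1")


def _helix_coords(spec: ToyProteinSpec) -> np.ndarray:
    i = np.arange(spec.n_residues)
    phi = np.radians(spec.twist_deg) * i
    return np.column_stack([
        spec.radius * np.cos(phi),
        spec.radius * np.sin(phi),
        spec.rise * i,
    ])


def toy_protein_pdb(spec: ToyProteinSpec) -> str:
    """PDB text for the helix (C-alpha trace, chain A)."""
    coords = _helix_coords(spec)
    lines = []
    for k in range(spec.n_residues):
        sign = spec.charges.get(k + 1, 0)
        res = {1: "LYS", -1: "GLU", 0: "ALA"}[sign]
        x, y, z = coords[k]
        lines.append(
            f"ATOM  {k + 1:5d}  CA  {res} A{k + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_toy_protein(spec: ToyProteinSpec) -> tuple[CGProtein, str]:
    """Build the toy helix; returns (coarse-grained model, PDB text).

    The model is coarse-grained from the PDB text itself, so re-reading the
    text reproduces it exactly.
    """
    pdb = toy_protein_pdb(spec)
    atoms = load_structure(pdb, source=f"toy_helix_n{spec.n_residues}")
    protein = coarse_grain_protein(
        atoms, DEFAULT_CHARGE_SCHEME,
        contact_cutoff=spec.contact_cutoff,
        label=f"toy_helix_n{spec.n_residues}_q{len(spec.charges)}",
    )
    return protein, pdb


@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    """Stochastic trace with known coupling, diffusion and noise.

    Z performs a Gaussian random walk with the prescribed diffusion
    coefficient (step variance 2 D per frame).  In coupled frames theta
    tracks slope * Z plus Gaussian noise; in the remaining frames theta
    performs an independent mean-reverting walk.  The radial coordinate
    fluctuates about its mean.
    """

    n_frames: int = 5000
    slope: float = -2.0 * math.pi / 34.0   # rad/Å ground truth
    coupled_fraction: float = 1.0
    diffusion_coefficient: float = 0.5     # Å^2 per frame
    angle_noise: float = 0.0               # rad
    radial_mean: float = 15.0
    radial_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupled_fraction <= 1.0:
            raise ValueError("coupled_fraction must be in [0, 1]")
        if self.angle_noise < 0 or self.diffusion_coefficient < 0:
            raise ValueError("noise and diffusion coefficient must be >= 0")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


def make_synthetic_trajectory(spec: SyntheticTrajectorySpec) -> Trajectory:
    """Single-bead trajectory whose COM realizes the prescribed statistics."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    step_sd = math.sqrt(2.0 * spec.diffusion_coefficient)
    z = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, step_sd, n - 1))])

    n_coupled = int(round(spec.coupled_fraction * n))
    theta = np.empty(n)
    theta[:n_coupled] = (
        spec.slope * z[:n_coupled]
        + rng.normal(0.0, spec.angle_noise, n_coupled)
    )
    if n_coupled < n:
        anchor = theta[n_coupled - 1] if n_coupled else 0.0
        walk_sd = max(spec.angle_noise, 0.05)
        cur = anchor
        for k in range(n_coupled, n):
            cur += rng.normal(0.0, walk_sd) - 0.02 * (cur - anchor)
            theta[k] = cur

    radius = np.maximum(
        rng.normal(spec.radial_mean, spec.radial_sigma, n), 0.1
    )
    frames = np.empty((n, 1, 3))
    frames[:, 0, 0] = radius * np.cos(theta)
    frames[:, 0, 1] = radius * np.sin(theta)
    frames[:, 0, 2] = z
    coupled_mask = [True] * n_coupled + [False] * (n - n_coupled)
    return Trajectory(
        times=np.arange(n, dtype=float),
        frames=frames,
        metadata={
            "generator": "synthetic",
            "ground_truth": asdict(spec),
            "coupled_frames": coupled_mask,
            "z_period": 0.0,
            "chain_ids": ["A"],
            "charges": [0.0],
        },
    )


_SUITE_TRAJECTORIES = {
    "sliding": SyntheticTrajectorySpec(
        n_frames=5000, slope=-2.0 * math.pi / 34.0, coupled_fraction=1.0,
        angle_noise=0.1, seed=101),
    "hopping": SyntheticTrajectorySpec(
        n_frames=5000, slope=-2.0 * math.pi / 34.0, coupled_fraction=0.0,
        angle_noise=0.2, seed=102),
    "intermediate": SyntheticTrajectorySpec(
        n_frames=5000, slope=-0.10, coupled_fraction=1.0,
        angle_noise=0.3, seed=103),
}

_SUITE_HELICES = {
    # charges on one helical face (i, i+3/i+4 ladder)
    "toy_helix_q6": {2: 1, 5: 1, 9: 1, 12: 1, 16: 1, 19: 1},
    "toy_helix_q5": {2: 1, 5: 1, 9: 1, 12: 1, 16: 1},
    "toy_helix_q4": {2: 1, 5: 1, 9: 1, 12: 1},
}


def make_fixture_suite(out_dir) -> dict:
    """Write the canonical fixture set and its ground-truth manifest.

    Produces toy helices bearing 6/5/4 positive charges, 20-bp and 100-bp
    DNA models, and three synthetic trajectories spanning the sliding,
    hopping and intermediate regimes.  Regeneration with the same seeds is
    byte-identical.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"proteins": {}, "dna": {}, "trajectories": {}}

    for name, charges in _SUITE_HELICES.items():
        spec = ToyProteinSpec(n_residues=20, charges=charges)
        protein, pdb = make_toy_protein(spec)
        path = os.path.join(out_dir, f"{name}.pdb")
        with open(path, "w") as fh:
            fh.write(pdb)
        manifest["proteins"][name] = {
            "file": f"{name}.pdb",
            "n_residues": spec.n_residues,
            "net_charge": protein.net_charge,
            "charged_positions": sorted(charges),
        }

    for n_bp in (20, 100):
        dna = build_bdna("GCAT" * (n_bp // 4))
        path = os.path.join(out_dir, f"dna{n_bp}.cg")
        write_bdna(dna, path)
        manifest["dna"][f"dna{n_bp}"] = {
            "file": f"dna{n_bp}.cg",
            "n_bp": n_bp,
            "n_beads": dna.n_beads,
            "net_charge": dna.net_charge,
        }

    for name, spec in _SUITE_TRAJECTORIES.items():
        traj = make_synthetic_trajectory(spec)
        path = os.path.join(out_dir, f"traj_{name}.h5")
        write_trajectory(traj, path)
        truth = asdict(spec)
        truth["expected_slope"] = (
            spec.slope if spec.coupled_fraction == 1.0
            else (None if spec.coupled_fraction > 0 else 0.0)
        )
        manifest["trajectories"][name] = {"file": f"traj_{name}.h5", **truth}

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
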