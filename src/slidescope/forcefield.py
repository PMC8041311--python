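"""Coarse-grained potential: native topology terms plus Debye-Hückel salt.

Functional forms
----------------
bonds        K_b (b - b0)^2
angles       K_a (theta - theta0)^2
dihedrals    K_d [(1 - cos(dphi)) + 1/2 (1 - cos 3 dphi)]
contacts     K_c [5 (A/r)^12 - 6 (A/r)^10]          (native pairs)
repulsion    K_rep (C/r)^12                          (all other pairs)
charge       K_el B(kappa) q_i q_j exp(-kappa r) / (eps_r r)

Energies are in kcal/mol, distances in Å, charges in elementary charges.
In reduced simulation units the contact energy scale (1 kcal/mol) plays the
role of the unit energy, so these numbers are used as-is with k_B = 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from . import _kernels
from .structure_io import BDNADuplex, CGProtein

__all__ = [
    "ForceFieldParams",
    "ElectrostaticModel",
    "EnergyBreakdown",
    "System",
    "kappa_from_molar",
    "debye_huckel_pair",
    "build_system",
    "energy",
    "forces",
]


@dataclass(frozen=True)
class ForceFieldParams:
    """Force constants; defaults are the published values."""

    k_bond: float = 100.0           # kcal/mol/Å^2
    k_angle: float = 20.0           # kcal/mol
    k_dihedral: float = 1.0         # kcal/mol
    k_contact: float = 1.0          # kcal/mol
    k_repulsion: float = 1.0        # kcal/mol
    k_electrostatics: float = 332.0  # kcal Å/mol/e^2
    dielectric: float = 70.0
    backbone_radius: float = 2.0    # Å

    def __post_init__(self) -> None:
        for name in ("k_bond", "k_angle", "k_dihedral", "k_contact",
                     "k_repulsion", "k_electrostatics"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def kappa_from_molar(
    concentration: float,
    temperature: float = 300.0,
    dielectric: float = 70.0,
) -> float:
    """Inverse Debye length (Å^-1) for a monovalent salt solution.

    kappa^2 = 2 N_A e^2 (1000 C) / (eps0 eps_r k_B T); kappa(0) = 0 and
    kappa grows as sqrt(C).
    """
    if concentration < 0:
        raise ValueError("salt concentration must be non-negative")
    if concentration == 0:
        return 0.0
    number_density = 2.0 * constants.N_A * 1000.0 * concentration  # ions / m^3
    kappa_sq = (
        number_density * constants.e**2
        / (constants.epsilon_0 * dielectric * constants.k * temperature)
    )
    return math.sqrt(kappa_sq) * 1e-10


@dataclass(frozen=True)
class ElectrostaticModel:
    """Salt-dependent screening of charge-charge interactions.

    ``ion_radius`` enters the salt coefficient B(kappa) = exp(kappa a) /
    (1 + kappa a), which tends to 1 at zero salt.
    """

    salt_molar: float = 0.01
    temperature: float = 300.0
    dielectric: float = 70.0
    ion_radius: float = 4.24        # Å

    def __post_init__(self) -> None:
        if self.salt_molar < 0:
            raise ValueError("salt concentration must be non-negative")

    @property
    def kappa(self) -> float:
        return kappa_from_molar(self.salt_molar, self.temperature, self.dielectric)

    @property
    def b_coefficient(self) -> float:
        ka = self.kappa * self.ion_radius
        return math.exp(ka) / (1.0 + ka)


def debye_huckel_pair(
    r: float,
    q_i: float,
    q_j: float,
    model: ElectrostaticModel,
    params: ForceFieldParams = ForceFieldParams(),
) -> float:
    """Screened Coulomb energy (kcal/mol) of one charge pair at distance r."""
    if r <= 0:
        raise ValueError("overlapping charges: r must be positive")
    kappa = model.kappa
    return (
        params.k_electrostatics * model.b_coefficient * q_i * q_j
        * math.exp(-kappa * r) / (params.dielectric * r)
    )


@dataclass(frozen=True)
class EnergyBreakdown:
    bonds: float
    angles: float
    dihedrals: float
    contacts: float
    repulsion: float
    electrostatics: float

    @property
    def total(self) -> float:
        return (self.bonds + self.angles + self.dihedrals
                + self.contacts + self.repulsion + self.electrostatics)

    def as_dict(self) -> dict[str, float]:
        return {
            "bonds": self.bonds, "angles": self.angles,
            "dihedrals": self.dihedrals, "contacts": self.contacts,
            "repulsion": self.repulsion, "electrostatics": self.electrostatics,
            "total": self.total,
        }


@dataclass
class System:
    """Protein (+ optional static DNA) with precomputed interaction lists.

    Protein beads come first in the combined coordinate array; DNA beads
    follow and never move.  Nonbonded exclusions within the protein are the
    1-2, 1-3 and 1-4 neighbours implied by the bonded terms, plus native
    contacts; protein-DNA pairs interact through repulsion and (for charged
    pairs) Debye-Hückel only.  DNA-DNA interactions are constant and skipped.
    """

    n_protein: int
    n_total: int
    positions0: np.ndarray
    charges: np.ndarray
    bonds: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray
    angle_t0: np.ndarray
    dihedrals: np.ndarray
    dihedral_p0: np.ndarray
    contacts: np.ndarray
    contact_r0: np.ndarray
    rep_pairs: np.ndarray
    rep_c: np.ndarray
    elec_pairs: np.ndarray
    elec_qq: np.ndarray
    z_period: float
    params: ForceFieldParams
    model: ElectrostaticModel
    elec_cutoff: float = 0.0        # Å; 0 disables
    rep_cutoff_factor: float = 0.0  # in units of C_ij; 0 disables
    protein_chain_ids: np.ndarray = field(default=None)

    @property
    def elec_prefactor(self) -> float:
        return (self.params.k_electrostatics * self.model.b_coefficient
                / self.params.dielectric)

    @property
    def kappa(self) -> float:
        return self.model.kappa

    def _kernel_args(self):
        p = self.params
        return (
            self.bonds, self.bond_r0, p.k_bond,
            self.angles, self.angle_t0, p.k_angle,
            self.dihedrals, self.dihedral_p0, p.k_dihedral,
            self.contacts, self.contact_r0, p.k_contact,
            self.rep_pairs, self.rep_c, p.k_repulsion,
            self.elec_pairs, self.elec_qq, self.elec_prefactor, self.kappa,
            self.z_period, self.elec_cutoff, self.rep_cutoff_factor,
        )


def build_system(
    protein: CGProtein,
    dna: BDNADuplex | None = None,
    model: ElectrostaticModel = ElectrostaticModel(),
    params: ForceFieldParams = ForceFieldParams(),
    z_periodic: bool = True,
    elec_cutoff: float = 0.0,
    rep_cutoff_factor: float = 0.0,
    dna_bead_radius: float | None = None,
) -> System:
    """Assemble the pair lists for energy/force evaluation.

    With ``z_periodic`` and a DNA present, nonbonded interactions use the
    minimum image along Z with period equal to the DNA length, emulating an
    infinite duplex.
    """
    protein.validate()
    np_ = protein.n_beads
    if dna is not None:
        all_pos = np.vstack([protein.positions, dna.positions])
        all_q = np.concatenate([protein.charges, dna.charges])
    else:
        all_pos = protein.positions.copy()
        all_q = protein.charges.copy()
    n_total = all_pos.shape[0]

    excluded: set[tuple[int, int]] = set()
    for i, j in protein.bonds.tolist():
        excluded.add((min(i, j), max(i, j)))
    for i, _, k in protein.angles.tolist():
        excluded.add((min(i, k), max(i, k)))
    for i, _, _, l in protein.dihedrals.tolist():
        excluded.add((min(i, l), max(i, l)))
    native = {tuple(sorted(p)) for p in protein.contacts.tolist()}

    radius = protein.repulsion_radii
    dna_radius = params.backbone_radius if dna_bead_radius is None else dna_bead_radius

    rep_pairs: list[tuple[int, int]] = []
    rep_c: list[float] = []
    elec_pairs: list[tuple[int, int]] = []
    elec_qq: list[float] = []

    for i, j in itertools.combinations(range(np_), 2):
        if (i, j) in excluded or (i, j) in native:
            continue
        rep_pairs.append((i, j))
        rep_c.append(float(radius[i] + radius[j]))
        qq = protein.charges[i] * protein.charges[j]
        if qq != 0.0:
            elec_pairs.append((i, j))
            elec_qq.append(float(qq))

    if dna is not None:
        charged_p = np.where(protein.charges != 0.0)[0]
        charged_d = np.where(dna.charges != 0.0)[0]
        for i in range(np_):
            for j in range(dna.n_beads):
                rep_pairs.append((i, np_ + j))
                rep_c.append(float(radius[i] + dna_radius))
        for i in charged_p:
            for j in charged_d:
                elec_pairs.append((int(i), np_ + int(j)))
                elec_qq.append(float(protein.charges[i] * dna.charges[j]))

    return System(
        n_protein=np_,
        n_total=n_total,
        positions0=all_pos,
        charges=all_q,
        bonds=np.ascontiguousarray(protein.bonds, dtype=np.int64),
        bond_r0=np.ascontiguousarray(protein.bond_r0, dtype=np.float64),
        angles=np.ascontiguousarray(protein.angles, dtype=np.int64),
        angle_t0=np.ascontiguousarray(protein.angle_t0, dtype=np.float64),
        dihedrals=np.ascontiguousarray(protein.dihedrals, dtype=np.int64),
        dihedral_p0=np.ascontiguousarray(protein.dihedral_p0, dtype=np.float64),
        contacts=np.ascontiguousarray(protein.contacts, dtype=np.int64),
        contact_r0=np.ascontiguousarray(protein.contact_r0, dtype=np.float64),
        rep_pairs=np.array(rep_pairs, dtype=np.int64).reshape(-1, 2),
        rep_c=np.array(rep_c, dtype=np.float64),
        elec_pairs=np.array(elec_pairs, dtype=np.int64).reshape(-1, 2),
        elec_qq=np.array(elec_qq, dtype=np.float64),
        z_period=float(dna.z_length) if (dna is not None and z_periodic) else 0.0,
        params=params,
        model=model,
        elec_cutoff=float(elec_cutoff),
        rep_cutoff_factor=float(rep_cutoff_factor),
        protein_chain_ids=protein.chain_ids.copy(),
    )


def _check_positions(positions: np.ndarray, system: System) -> np.ndarray:
    positions = np.ascontiguousarray(positions, dtype=np.float64)
    if positions.shape != (system.n_total, 3):
        raise ValueError(
            f"positions must have shape ({system.n_total}, 3), got {positions.shape}"
        )
    return positions


def energy(positions: np.ndarray, system: System) -> EnergyBreakdown:
    """Evaluate every energy term at the given coordinates."""
    pos = _check_positions(positions, system)
    scratch = np.zeros_like(pos)
    p = system.params
    e_bond = _kernels.bond_term(pos, scratch, system.bonds, system.bond_r0, p.k_bond)
    e_ang = _kernels.angle_term(pos, scratch, system.angles, system.angle_t0, p.k_angle)
    e_dih = _kernels.dihedral_term(pos, scratch, system.dihedrals,
                                   system.dihedral_p0, p.k_dihedral)
    e_con = _kernels.contact_term(pos, scratch, system.contacts,
                                  system.contact_r0, p.k_contact)
    e_rep = _kernels.repulsion_term(pos, scratch, system.rep_pairs, system.rep_c,
                                    p.k_repulsion, system.z_period,
                                    system.rep_cutoff_factor)
    e_el = _kernels.electrostatic_term(pos, scratch, system.elec_pairs,
                                       system.elec_qq, system.elec_prefactor,
                                       system.kappa, system.z_period,
                                       system.elec_cutoff)
    return EnergyBreakdown(e_bond, e_ang, e_dih, e_con, e_rep, e_el)


def forces(positions: np.ndarray, system: System) -> tuple[np.ndarray, EnergyBreakdown]:
    """Analytic forces F = -grad E plus the matching energy breakdown."""
    pos = _check_positions(positions, system)
    f = np.zeros_like(pos)
    p = system.params
    e_bond = _kernels.bond_term(pos, f, system.bonds, system.bond_r0, p.k_bond)
    e_ang = _kernels.angle_term(pos, f, system.angles, system.angle_t0, p.k_angle)
    e_dih = _kernels.dihedral_term(pos, f, system.dihedrals,
                                   system.dihedral_p0, p.k_dihedral)
    e_con = _kernels.contact_term(pos, f, system.contacts,
                                  system.contact_r0, p.k_contact)
    e_rep = _kernels.repulsion_term(pos, f, system.rep_pairs, system.rep_c,
                                    p.k_repulsion, system.z_period,
                                    system.rep_cutoff_factor)
    e_el = _kernels.electrostatic_term(pos, f, system.elec_pairs, system.elec_qq,
                                       system.elec_prefactor, system.kappa,
                                       system.z_period, system.elec_cutoff)
    return f, EnergyBreakdown(e_bond, e_ang, e_dih, e_con, e_rep, e_el)
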