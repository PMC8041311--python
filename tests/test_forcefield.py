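import math

import numpy as np
import pytest
from scipy import constants
from scipy.spatial.transform import Rotation

from slidescope.forcefield import (
    ElectrostaticModel,
    ForceFieldParams,
    build_system,
    debye_huckel_pair,
    energy,
    forces,
    kappa_from_molar,
)
from slidescope.structure_io import build_bdna
from slidescope.synthetic_data import ToyProteinSpec, make_toy_protein


# ---------------------------------------------------------------------------
# Debye screening
# ---------------------------------------------------------------------------

class TestKappa:
    def test_zero_salt(self):
        assert kappa_from_molar(0.0) == 0.0

    def test_square_root_law(self):
        assert kappa_from_molar(0.04) / kappa_from_molar(0.01) == pytest.approx(2.0)

    def test_against_closed_form_debye_length(self):
        # independent evaluation of the 1:1-salt Debye length
        c, t, eps = 0.01, 300.0, 70.0
        ionic = 1000.0 * c * constants.N_A          # ions of each sign / m^3
        lam = math.sqrt(
            constants.epsilon_0 * eps * constants.k * t
            / (2.0 * ionic * constants.e ** 2)
        )
        assert kappa_from_molar(c, t, eps) == pytest.approx(1e-10 / lam, rel=1e-12)

    def test_negative_concentration(self):
        with pytest.raises(ValueError):
            kappa_from_molar(-0.01)


class TestDebyeHuckelPair:
    def test_neutral_bead_is_zero(self):
        model = ElectrostaticModel(salt_molar=0.02)
        for r in (1.0, 5.0, 50.0):
            assert debye_huckel_pair(r, 0.0, 1.0, model) == 0.0

    def test_unscreened_value(self):
        # kappa = 0, B = 1: 332 / (70 * 10) kcal/mol
        model = ElectrostaticModel(salt_molar=0.0)
        val = debye_huckel_pair(10.0, 1.0, 1.0, model)
        assert val == pytest.approx(332.0 / 700.0, rel=1e-12)
        assert val == pytest.approx(0.4743, abs=1e-4)

    def test_screening_monotonic_toward_zero(self):
        vals = [
            debye_huckel_pair(8.0, 1.0, -1.0, ElectrostaticModel(salt_molar=c))
            for c in (0.005, 0.01, 0.02, 0.04, 0.06)
        ]
        assert all(v < 0 for v in vals)
        assert all(b > a for a, b in zip(vals, vals[1:]))   # rises toward 0

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            debye_huckel_pair(0.0, 1.0, 1.0, ElectrostaticModel())

    def test_b_coefficient_limit(self):
        assert ElectrostaticModel(salt_molar=0.0).b_coefficient == 1.0
        assert ElectrostaticModel(salt_molar=0.05).b_coefficient > 1.0


# ---------------------------------------------------------------------------
# brute-force energy oracle
# ---------------------------------------------------------------------------

def _oracle_energy(pos, protein, dna, model, params, z_period):
    """Naive O(N^2) re-implementation of every term, independent of kernels."""
    def dist(i, j, minimage):
        d = pos[i] - pos[j]
        if minimage and z_period > 0:
            d[2] -= z_period * round(d[2] / z_period)
        return math.sqrt((d ** 2).sum())

    e = dict.fromkeys(
        ["bonds", "angles", "dihedrals", "contacts", "repulsion",
         "electrostatics"], 0.0)
    for (i, j), b0 in zip(protein.bonds, protein.bond_r0):
        e["bonds"] += params.k_bond * (dist(i, j, False) - b0) ** 2
    for (i, j, k), t0 in zip(protein.angles, protein.angle_t0):
        u, v = pos[i] - pos[j], pos[k] - pos[j]
        th = math.acos(np.clip(
            u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
        e["angles"] += params.k_angle * (th - t0) ** 2
    for (i, j, k, l), p0 in zip(protein.dihedrals, protein.dihedral_p0):
        b1, b2, b3 = pos[j] - pos[i], pos[k] - pos[j], pos[l] - pos[k]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        phi = math.atan2(np.cross(n1, n2) @ b2 / np.linalg.norm(b2), n1 @ n2)
        dphi = phi - p0
        e["dihedrals"] += params.k_dihedral * (
            (1 - math.cos(dphi)) + 0.5 * (1 - math.cos(3 * dphi)))
    native = {tuple(sorted(p)) for p in protein.contacts.tolist()}
    for (i, j), a0 in zip(protein.contacts, protein.contact_r0):
        r = dist(i, j, False)
        e["contacts"] += params.k_contact * (5 * (a0 / r) ** 12 - 6 * (a0 / r) ** 10)

    npb = protein.n_beads
    charges = (np.concatenate([protein.charges, dna.charges]) if dna is not None
               else protein.charges)
    pref = params.k_electrostatics * model.b_coefficient / params.dielectric
    kappa = model.kappa
    n_total = pos.shape[0]
    for i in range(n_total):
        for j in range(i + 1, n_total):
            if i >= npb and j >= npb:
                continue                     # DNA-DNA skipped (static)
            if i < npb and j < npb:
                if abs(i - j) <= 3 or (i, j) in native:   # single unbroken chain
                    continue
                c = protein.repulsion_radii[i] + protein.repulsion_radii[j]
            else:
                c = protein.repulsion_radii[min(i, j)] + params.backbone_radius
            r = dist(i, j, True)
            e["repulsion"] += params.k_repulsion * (c / r) ** 12
            qq = charges[i] * charges[j]
            if qq != 0.0:
                e["electrostatics"] += pref * qq * math.exp(-kappa * r) / r
    return e


def _random_system(n_res, seed, with_dna=False, charged=None):
    charged = charged or {2: 1, 5: 1, 7: -1, 11: 1}
    charged = {p: s for p, s in charged.items() if p <= n_res}
    protein, _ = make_toy_protein(ToyProteinSpec(n_residues=n_res, charges=charged))
    dna = build_bdna("GCAT" * 3) if with_dna else None
    model = ElectrostaticModel(salt_molar=0.02)
    system = build_system(protein, dna, model=model)
    rng = np.random.default_rng(seed)
    pos = system.positions0.copy()
    if with_dna:
        pos[: protein.n_beads] += np.array([14.0, 2.0, 10.0])
    pos[: protein.n_beads] += rng.normal(0.0, 0.25, (protein.n_beads, 3))
    return protein, dna, model, system, pos


class TestEnergy:
    @pytest.mark.parametrize("with_dna", [False, True])
    def test_matches_bruteforce_oracle(self, with_dna):
        protein, dna, model, system, pos = _random_system(20, 0, with_dna)
        br = energy(pos, system)
        ref = _oracle_energy(pos, protein, dna, model, system.params,
                             system.z_period)
        for term, val in ref.items():
            assert getattr(br, term) == pytest.approx(val, rel=1e-9, abs=1e-12), term

    def test_breakdown_total_is_sum(self):
        *_, system, pos = _random_system(15, 3)
        br = energy(pos, system)
        parts = (br.bonds + br.angles + br.dihedrals + br.contacts
                 + br.repulsion + br.electrostatics)
        assert br.total == pytest.approx(parts, rel=1e-12)

    def test_native_structure_is_bonded_minimum(self, toy_q6):
        system = build_system(toy_q6, None, model=ElectrostaticModel(salt_molar=0.0))
        br = energy(system.positions0, system)
        assert abs(br.bonds) < 1e-18
        assert abs(br.angles) < 1e-18
        assert abs(br.dihedrals) < 1e-18
        # each native contact sits at its 12-10 minimum: -k_contact apiece
        assert br.contacts == pytest.approx(-len(toy_q6.contacts), rel=1e-12)

    def test_repulsion_unit_at_contact_radius(self):
        protein, _ = make_toy_protein(ToyProteinSpec(n_residues=4))
        system = build_system(protein, None)
        pos = system.positions0.copy()
        # beads 0 and 3 are a repulsive (non-native, non-bonded) pair? no:
        # |0-3| = 3 is excluded; use a 5-bead chain and the (0, 4) pair
        protein, _ = make_toy_protein(ToyProteinSpec(n_residues=5, contact_cutoff=0.1))
        system = build_system(protein, None)
        pos = system.positions0.copy()
        c = protein.repulsion_radii[0] + protein.repulsion_radii[4]
        # place bead 4 at distance C from bead 0, far from the others in z
        direction = np.array([0.0, 0.0, -1.0])
        pos[4] = pos[0] + c * direction
        br = energy(pos, system)
        rep_04 = system.params.k_repulsion * 1.0
        others = sum(
            system.params.k_repulsion
            * ((system.rep_c[k] / np.linalg.norm(pos[i] - pos[j])) ** 12)
            for k, (i, j) in enumerate(system.rep_pairs)
            if (i, j) != (0, 4)
        )
        assert br.repulsion == pytest.approx(rep_04 + others, rel=1e-9)

    def test_translation_rotation_invariance(self):
        *_, system, pos = _random_system(18, 5)
        br0 = energy(pos, system)
        rot = Rotation.from_euler("zyx", [0.3, -1.1, 2.0]).as_matrix()
        moved = pos @ rot.T + np.array([11.0, -7.0, 3.0])
        br1 = energy(moved, system)
        for term in ("bonds", "angles", "dihedrals", "contacts",
                     "repulsion", "electrostatics"):
            a, b = getattr(br0, term), getattr(br1, term)
            assert b == pytest.approx(a, rel=1e-9, abs=1e-12), term

    def test_electrostatics_decreases_with_kappa(self):
        protein, _ = make_toy_protein(
            ToyProteinSpec(n_residues=10, charges={2: 1, 9: 1}))
        mags = []
        for salt in (0.0, 0.01, 0.03, 0.06):
            system = build_system(protein, None,
                                  model=ElectrostaticModel(salt_molar=salt))
            mags.append(abs(energy(system.positions0, system).electrostatics))
        assert all(b < a for a, b in zip(mags, mags[1:]))

    def test_index_out_of_range(self):
        *_, system, pos = _random_system(10, 1)
        with pytest.raises(ValueError, match="shape"):
            energy(pos[:-1], system)


class TestForces:
    @pytest.mark.parametrize("n_res,seed,with_dna", [
        (20, 1, False), (35, 2, False), (50, 3, False), (20, 4, True),
    ])
    def test_matches_finite_differences(self, n_res, seed, with_dna):
        *_, system, pos = _random_system(n_res, seed, with_dna)
        f, _ = forces(pos, system)
        h = 1e-5
        rng = np.random.default_rng(seed + 100)
        # probe a random subset of coordinates to keep runtime bounded
        idx = rng.choice(system.n_total * 3, size=min(90, system.n_total * 3),
                         replace=False)
        for flat in idx:
            i, d = divmod(int(flat), 3)
            p = pos.copy()
            p[i, d] += h
            ep = energy(p, system).total
            p[i, d] -= 2 * h
            em = energy(p, system).total
            assert f[i, d] == pytest.approx(-(ep - em) / (2 * h), abs=1e-5)

    def test_native_bonded_forces_vanish(self, toy_neutral):
        system = build_system(toy_neutral, None,
                              model=ElectrostaticModel(salt_molar=0.0))
        # isolate bonded terms: kill nonbonded pairs
        system.rep_pairs = np.empty((0, 2), dtype=np.int64)
        system.rep_c = np.empty(0)
        system.contacts = np.empty((0, 2), dtype=np.int64)
        system.contact_r0 = np.empty(0)
        f, _ = forces(system.positions0, system)
        assert np.abs(f).max() <= 1e-8

    def test_newtons_third_law_pair(self):
        protein, _ = make_toy_protein(
            ToyProteinSpec(n_residues=10, charges={1: 1, 10: 1}))
        system = build_system(protein, None, model=ElectrostaticModel(salt_molar=0.0))
        pos = system.positions0.copy()
        f, _ = forces(pos, system)
        axis = pos[9] - pos[0]
        # net electrostatic push is repulsive: force on 9 has positive
        # component along the 0->9 axis, force on 0 the opposite
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)

    def test_net_force_zero(self):
        *_, system, pos = _random_system(25, 7)
        f, _ = forces(pos, system)
        assert np.abs(f.sum(axis=0)).max() <= 1e-9

    def test_two_isolated_charges_equal_opposite(self):
        protein, _ = make_toy_protein(
            ToyProteinSpec(n_residues=10, charges={1: 1, 10: 1}))
        system = build_system(protein, None, model=ElectrostaticModel(salt_molar=0.0))
        # keep only the electrostatic pair between beads 0 and 9
        keep = [k for k, (i, j) in enumerate(system.elec_pairs.tolist())
                if (i, j) == (0, 9)]
        system.elec_pairs = system.elec_pairs[keep]
        system.elec_qq = system.elec_qq[keep]
        for name in ("bonds", "angles", "dihedrals", "contacts", "rep_pairs"):
            arr = getattr(system, name)
            setattr(system, name, arr[:0])
        for name in ("bond_r0", "angle_t0", "dihedral_p0", "contact_r0", "rep_c"):
            arr = getattr(system, name)
            setattr(system, name, arr[:0])
        pos = system.positions0
        f, _ = forces(pos, system)
        assert np.allclose(f[0], -f[9], atol=1e-12)
        axis = (pos[9] - pos[0]) / np.linalg.norm(pos[9] - pos[0])
        assert f[9] @ axis > 0          # like charges repel
        cross = np.cross(f[9], axis)
        assert np.abs(cross).max() < 1e-12   # force along the pair axis


class TestParams:
    def test_defaults_as_printed(self):
        p = ForceFieldParams()
        assert (p.k_bond, p.k_angle, p.k_dihedral) == (100.0, 20.0, 1.0)
        assert (p.k_contact, p.k_repulsion) == (1.0, 1.0)
        assert p.k_electrostatics == 332.0
        assert p.dielectric == 70.0
        assert p.backbone_radius == 2.0

    def test_negative_constant_rejected(self):
        with pytest.raises(ValueError):
            ForceFieldParams(k_bond=-1.0)
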