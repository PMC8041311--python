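"""Numba-compiled inner loops for energies, forces and Langevin stepping.

All kernels accumulate forces in place and return the energy of their term.
Nonbonded pair kernels apply a minimum-image convention along Z only (the
DNA axis); ``z_period <= 0`` disables it.  Cutoff arguments of 0 disable the
cutoff.
"""

import math

import numpy as np
from numba import njit

__all__ = [
    "bond_term", "angle_term", "dihedral_term",
    "contact_term", "repulsion_term", "electrostatic_term",
    "baoab_chunk",
]


@njit(cache=True)
def bond_term(pos, forces, bonds, r0, k):
    e = 0.0
    for n in range(bonds.shape[0]):
        i, j = bonds[n, 0], bonds[n, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        db = r - r0[n]
        e += k * db * db
        g = -2.0 * k * db / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz
    return e


@njit(cache=True)
def angle_term(pos, forces, angles, t0, k):
    e = 0.0
    for n in range(angles.shape[0]):
        ia, ib, ic = angles[n, 0], angles[n, 1], angles[n, 2]
        ux = pos[ia, 0] - pos[ib, 0]
        uy = pos[ia, 1] - pos[ib, 1]
        uz = pos[ia, 2] - pos[ib, 2]
        vx = pos[ic, 0] - pos[ib, 0]
        vy = pos[ic, 1] - pos[ib, 1]
        vz = pos[ic, 2] - pos[ib, 2]
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = math.acos(c)
        dt = theta - t0[n]
        e += k * dt * dt
        s = math.sqrt(1.0 - c * c)
        if s < 1e-10:
            s = 1e-10
        coef = -2.0 * k * dt            # -dE/dtheta
        # dtheta/da = (u_hat*c - v_hat)/(|u| s); likewise for c
        fax = coef * (ux / nu * c - vx / nv) / (nu * s)
        fay = coef * (uy / nu * c - vy / nv) / (nu * s)
        faz = coef * (uz / nu * c - vz / nv) / (nu * s)
        fcx = coef * (vx / nv * c - ux / nu) / (nv * s)
        fcy = coef * (vy / nv * c - uy / nu) / (nv * s)
        fcz = coef * (vz / nv * c - uz / nu) / (nv * s)
        forces[ia, 0] += fax
        forces[ia, 1] += fay
        forces[ia, 2] += faz
        forces[ic, 0] += fcx
        forces[ic, 1] += fcy
        forces[ic, 2] += fcz
        forces[ib, 0] -= fax + fcx
        forces[ib, 1] -= fay + fcy
        forces[ib, 2] -= faz + fcz
    return e


@njit(cache=True)
def dihedral_term(pos, forces, dihedrals, p0, k):
    e = 0.0
    for n in range(dihedrals.shape[0]):
        ia, ib, ic, id_ = dihedrals[n, 0], dihedrals[n, 1], dihedrals[n, 2], dihedrals[n, 3]
        b1x = pos[ib, 0] - pos[ia, 0]
        b1y = pos[ib, 1] - pos[ia, 1]
        b1z = pos[ib, 2] - pos[ia, 2]
        b2x = pos[ic, 0] - pos[ib, 0]
        b2y = pos[ic, 1] - pos[ib, 1]
        b2z = pos[ic, 2] - pos[ib, 2]
        b3x = pos[id_, 0] - pos[ic, 0]
        b3y = pos[id_, 1] - pos[ic, 1]
        b3z = pos[id_, 2] - pos[ic, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx = n1y * n2z - n1z * n2y
        my = n1z * n2x - n1x * n2z
        mz = n1x * n2y - n1y * n2x
        sinp = (mx * b2x + my * b2y + mz * b2z) / nb2
        cosp = n1x * n2x + n1y * n2y + n1z * n2z
        phi = math.atan2(sinp, cosp)
        dphi = phi - p0[n]
        e += k * ((1.0 - math.cos(dphi)) + 0.5 * (1.0 - math.cos(3.0 * dphi)))
        dedphi = k * (math.sin(dphi) + 1.5 * math.sin(3.0 * dphi))
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-18 or n2sq < 1e-18:
            continue
        ga = -nb2 / n1sq
        gd = nb2 / n2sq
        dax = ga * n1x
        day = ga * n1y
        daz = ga * n1z
        ddx = gd * n2x
        ddy = gd * n2y
        ddz = gd * n2z
        t1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        t2 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        dbx = -(1.0 + t1) * dax + t2 * ddx
        dby = -(1.0 + t1) * day + t2 * ddy
        dbz = -(1.0 + t1) * daz + t2 * ddz
        dcx = t1 * dax - (1.0 + t2) * ddx
        dcy = t1 * day - (1.0 + t2) * ddy
        dcz = t1 * daz - (1.0 + t2) * ddz
        forces[ia, 0] -= dedphi * dax
        forces[ia, 1] -= dedphi * day
        forces[ia, 2] -= dedphi * daz
        forces[ib, 0] -= dedphi * dbx
        forces[ib, 1] -= dedphi * dby
        forces[ib, 2] -= dedphi * dbz
        forces[ic, 0] -= dedphi * dcx
        forces[ic, 1] -= dedphi * dcy
        forces[ic, 2] -= dedphi * dcz
        forces[id_, 0] -= dedphi * ddx
        forces[id_, 1] -= dedphi * ddy
        forces[id_, 2] -= dedphi * ddz
    return e


@njit(cache=True, inline="always")
def _min_image_dz(dz, z_period):
    if z_period > 0.0:
        dz -= z_period * round(dz / z_period)
    return dz


@njit(cache=True)
def contact_term(pos, forces, pairs, a0, k):
    """Native-contact 12-10 attraction: k*[5(A/r)^12 - 6(A/r)^10]."""
    e = 0.0
    for n in range(pairs.shape[0]):
        i, j = pairs[n, 0], pairs[n, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        a2 = a0[n] * a0[n] / r2
        a10 = a2 * a2 * a2 * a2 * a2
        a12 = a10 * a2
        e += k * (5.0 * a12 - 6.0 * a10)
        g = 60.0 * k * (a12 - a10) / r2      # -dE/dr / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz
    return e


@njit(cache=True)
def repulsion_term(pos, forces, pairs, cij, k, z_period, cutoff_factor):
    """Excluded volume k*(C/r)^12 over non-native, non-bonded pairs."""
    e = 0.0
    for n in range(pairs.shape[0]):
        i, j = pairs[n, 0], pairs[n, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = _min_image_dz(pos[i, 2] - pos[j, 2], z_period)
        r2 = dx * dx + dy * dy + dz * dz
        c = cij[n]
        if cutoff_factor > 0.0 and r2 > (cutoff_factor * c) ** 2:
            continue
        c2 = c * c / r2
        c12 = c2 * c2 * c2 * c2 * c2 * c2
        e += k * c12
        g = 12.0 * k * c12 / r2
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz
    return e


@njit(cache=True)
def electrostatic_term(pos, forces, pairs, qq, prefactor, kappa, z_period, cutoff):
    """Debye-Hückel: prefactor * q_i q_j * exp(-kappa r) / r."""
    e = 0.0
    cut2 = cutoff * cutoff
    for n in range(pairs.shape[0]):
        i, j = pairs[n, 0], pairs[n, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = _min_image_dz(pos[i, 2] - pos[j, 2], z_period)
        r2 = dx * dx + dy * dy + dz * dz
        if cutoff > 0.0 and r2 > cut2:
            continue
        r = math.sqrt(r2)
        u = prefactor * qq[n] * math.exp(-kappa * r) / r
        e += u
        g = u * (kappa * r + 1.0) / r2       # -dE/dr / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz
    return e


@njit(cache=True)
def _total_forces(pos, forces,
                  bonds, bond_r0, k_bond,
                  angles, angle_t0, k_angle,
                  dihedrals, dihedral_p0, k_dihedral,
                  contacts, contact_r0, k_contact,
                  rep_pairs, rep_c, k_rep,
                  elec_pairs, elec_qq, elec_pref, kappa,
                  z_period, elec_cutoff, rep_cutoff_factor):
    forces[:] = 0.0
    e = bond_term(pos, forces, bonds, bond_r0, k_bond)
    e += angle_term(pos, forces, angles, angle_t0, k_angle)
    e += dihedral_term(pos, forces, dihedrals, dihedral_p0, k_dihedral)
    e += contact_term(pos, forces, contacts, contact_r0, k_contact)
    e += repulsion_term(pos, forces, rep_pairs, rep_c, k_rep,
                        z_period, rep_cutoff_factor)
    e += electrostatic_term(pos, forces, elec_pairs, elec_qq, elec_pref,
                            kappa, z_period, elec_cutoff)
    return e


@njit(cache=True)
def baoab_chunk(pos, vel, forces, noise, n_mobile, dt, gamma, kT,
                half_box, max_disp,
                bonds, bond_r0, k_bond,
                angles, angle_t0, k_angle,
                dihedrals, dihedral_p0, k_dihedral,
                contacts, contact_r0, k_contact,
                rep_pairs, rep_c, k_rep,
                elec_pairs, elec_qq, elec_pref, kappa,
                z_period, elec_cutoff, rep_cutoff_factor):
    """Advance the first ``n_mobile`` beads by ``noise.shape[0]`` BAOAB steps.

    Unit bead masses; k_B = 1 in reduced units.  X/Y walls at +/- half_box
    reflect; Z is handled by the minimum-image convention inside the pair
    kernels, so positions along Z stay unwrapped.  Returns the index of the
    first unstable step (displacement > max_disp for any bead), or -1.
    """
    n_steps = noise.shape[0]
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kT * (1.0 - c1 * c1))
    half_dt = 0.5 * dt
    for step in range(n_steps):
        for i in range(n_mobile):
            for d in range(3):
                vel[i, d] += half_dt * forces[i, d]
        for i in range(n_mobile):
            for d in range(3):
                pos[i, d] += half_dt * vel[i, d]
        for i in range(n_mobile):
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + c2 * noise[step, i, d]
        for i in range(n_mobile):
            for d in range(3):
                pos[i, d] += half_dt * vel[i, d]
        # reflecting walls in X and Y
        if half_box > 0.0:
            for i in range(n_mobile):
                for d in range(2):
                    if pos[i, d] > half_box:
                        pos[i, d] = 2.0 * half_box - pos[i, d]
                        vel[i, d] = -vel[i, d]
                    elif pos[i, d] < -half_box:
                        pos[i, d] = -2.0 * half_box - pos[i, d]
                        vel[i, d] = -vel[i, d]
        _total_forces(pos, forces,
                      bonds, bond_r0, k_bond,
                      angles, angle_t0, k_angle,
                      dihedrals, dihedral_p0, k_dihedral,
                      contacts, contact_r0, k_contact,
                      rep_pairs, rep_c, k_rep,
                      elec_pairs, elec_qq, elec_pref, kappa,
                      z_period, elec_cutoff, rep_cutoff_factor)
        for i in range(n_mobile):
            for d in range(3):
                vel[i, d] += half_dt * forces[i, d]
        for i in range(n_mobile):
            disp = dt * math.sqrt(vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
            if disp > max_disp or not math.isfinite(disp):
                return step
    return -1
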