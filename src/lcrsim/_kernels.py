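"""Numba kernels: force evaluation, Verlet pair list, BAOAB integration.

Everything here operates on plain arrays; :mod:`lcrsim.forcefield` and
:mod:`lcrsim.simulator` own the user-facing API and marshal a ``System`` +
``ForceFieldParams`` into the argument list these kernels expect.

Units: nm, ps, kJ/mol, Da, elementary charge.  With these units the
Boltzmann constant is 0.00831446 kJ/mol/K and velocities come out in nm/ps.

Potential terms (all constants live in ``ForceFieldParams``):

* bond: stiff harmonic about the fixed bead spacing (0.38 nm);
* bending: harmonic in the angle, or a tabulated potential (cubic Hermite);
* torsion: cosine series ``sum_n k_n (1 + cos(n*phi - phi0_n))``, or a table;
* excluded volume + hydrophobicity: WCA repulsion plus an attractive
  Lennard-Jones tail scaled by the combined hydrophobicity of the pair,
  truncated and shifted to zero at the van der Waals cutoff;
* electrostatics: Debye-Hückel screened Coulomb, truncated and shifted at
  the Coulomb cutoff;
* scaffold: harmonic excluded-volume penalty against the hourglass wall and
  blob spheres; optional confining outer cylinder.

Truncate-and-shift makes every energy continuous at its cutoff; forces keep
the unshifted derivative (discontinuous at the cutoff), the usual trade-off
of plain cutoff schemes.
"""

import numpy as np
from numba import njit

KB = 0.00831446261815324        # kJ/mol/K
COULOMB_F = 138.935458          # kJ·mol⁻¹·nm·e⁻², Coulomb prefactor in vacuum

# Bending angles (rad) between which the torsion term is switched off: the
# dihedral gradient diverges at collinearity, so the term tapers from full
# strength at TORSION_TAPER_ON to zero at TORSION_TAPER_OFF.
TORSION_TAPER_ON = 2.6
TORSION_TAPER_OFF = 3.0


@njit(cache=True)
def build_pairs(pos, chain_id, excl_depth, cutoff, active, pi, pj):
    """Collect bead pairs within ``cutoff`` where both beads are ``active``,
    excluding pairs separated by <= ``excl_depth`` bonds within one chain.
    Returns the pair count, or -1 if the preallocated arrays are too small.

    Used twice per system: once over all beads with the van der Waals
    cutoff, once over charged beads only with the (longer) Coulomb cutoff —
    charged beads are a minority in FG Nups, so the long-range list stays
    small."""
    n = pos.shape[0]
    cap = pi.shape[0]
    c2 = cutoff * cutoff
    m = 0
    for i in range(n):
        if not active[i]:
            continue
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        for j in range(i + 1, n):
            if not active[j]:
                continue
            if chain_id[i] == chain_id[j] and j - i <= excl_depth:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < c2:
                if m >= cap:
                    return -1
                pi[m] = i
                pj[m] = j
                m += 1
    return m


@njit(cache=True, inline="always")
def _hermite(x, x0, dx, u, du):
    """Cubic Hermite interpolation of a table (values + derivatives on a
    uniform grid); returns (value, derivative).  Clamps outside the grid."""
    n = u.shape[0]
    t = (x - x0) / dx
    if t <= 0.0:
        return u[0] + du[0] * (x - (x0)), du[0]
    if t >= n - 1:
        xr = x - (x0 + (n - 1) * dx)
        return u[n - 1] + du[n - 1] * xr, du[n - 1]
    i = int(t)
    s = t - i
    h00 = (1.0 + 2.0 * s) * (1.0 - s) * (1.0 - s)
    h10 = s * (1.0 - s) * (1.0 - s)
    h01 = s * s * (3.0 - 2.0 * s)
    h11 = s * s * (s - 1.0)
    val = h00 * u[i] + h10 * dx * du[i] + h01 * u[i + 1] + h11 * dx * du[i + 1]
    d00 = 6.0 * s * (s - 1.0)
    d10 = (1.0 - s) * (1.0 - 3.0 * s)
    d01 = -d00
    d11 = s * (3.0 * s - 2.0)
    der = (d00 * u[i] + d01 * u[i + 1]) / dx + d10 * du[i] + d11 * du[i + 1]
    return val, der


@njit(cache=True)
def compute_forces(
    pos, forces,
    # bonded
    bonds, bond_k, bond_r0,
    angles, bend_mode, bend_k, bend_theta0, bend_x0, bend_dx, bend_u, bend_du,
    dihedrals, tors_mode, tors_ks, tors_mult, tors_phi0,
    tors_x0, tors_dx, tors_u, tors_du,
    # nonbonded (split pair lists: vdW over all beads, Coulomb over charged)
    pi, pj, npairs, ci, cj, ncoul,
    sigma, eps_rep, eps_hp_max, hp_geometric, h, hsqrt, q,
    coul_c, kappa, rc_vdw, rc_coul,
    # scaffold / confinement
    scaffold_on, sc_rw, sc_re, sc_hl, sc_contact, sc_k, blobs,
    confine_radius, confine_k,
    # term masks
    do_angles, do_att, do_elec,
):
    """Total potential energy; per-bead forces accumulated into ``forces``
    (overwritten).  Term masks let the minimizer stage-in the potential."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    energy = 0.0

    # --- bonds ---
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0
        energy += 0.5 * bond_k * dr * dr
        fs = -bond_k * dr / r
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz

    if do_angles:
        # --- bending ---
        for a in range(angles.shape[0]):
            i = angles[a, 0]
            j = angles[a, 1]
            k = angles[a, 2]
            ux = pos[i, 0] - pos[j, 0]
            uy = pos[i, 1] - pos[j, 1]
            uz = pos[i, 2] - pos[j, 2]
            vx = pos[k, 0] - pos[j, 0]
            vy = pos[k, 1] - pos[j, 1]
            vz = pos[k, 2] - pos[j, 2]
            ru = np.sqrt(ux * ux + uy * uy + uz * uz)
            rv = np.sqrt(vx * vx + vy * vy + vz * vz)
            ct = (ux * vx + uy * vy + uz * vz) / (ru * rv)
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            theta = np.arccos(ct)
            if bend_mode == 0:
                dth = theta - bend_theta0
                energy += 0.5 * bend_k * dth * dth
                dudth = bend_k * dth
            else:
                uval, dudth = _hermite(theta, bend_x0, bend_dx, bend_u, bend_du)
                energy += uval
            st = np.sqrt(1.0 - ct * ct)
            if st < 1e-8:
                st = 1e-8
            c = dudth / st
            # dtheta/dri = -(v_hat - ct*u_hat)/(ru*st); F_i = -dU/dtheta*dtheta/dri
            fix = c * (vx / rv - ct * ux / ru) / ru
            fiy = c * (vy / rv - ct * uy / ru) / ru
            fiz = c * (vz / rv - ct * uz / ru) / ru
            fkx = c * (ux / ru - ct * vx / rv) / rv
            fky = c * (uy / ru - ct * vy / rv) / rv
            fkz = c * (uz / ru - ct * vz / rv) / rv
            forces[i, 0] += fix
            forces[i, 1] += fiy
            forces[i, 2] += fiz
            forces[k, 0] += fkx
            forces[k, 1] += fky
            forces[k, 2] += fkz
            forces[j, 0] -= fix + fkx
            forces[j, 1] -= fiy + fky
            forces[j, 2] -= fiz + fkz

        # --- torsion ---
        # The dihedral angle is ill-defined when three consecutive beads
        # become collinear, and its gradient carries 1/|b x b'|^2 factors
        # that diverge there.  With a soft bending potential such states are
        # thermally accessible, so the torsion energy is tapered smoothly to
        # zero (cosine switch on both flanking bending angles) before the
        # singularity; the taper's own gradient is included analytically.
        for d in range(dihedrals.shape[0]):
            i = dihedrals[d, 0]
            j = dihedrals[d, 1]
            k = dihedrals[d, 2]
            l = dihedrals[d, 3]
            b1x = pos[j, 0] - pos[i, 0]
            b1y = pos[j, 1] - pos[i, 1]
            b1z = pos[j, 2] - pos[i, 2]
            b2x = pos[k, 0] - pos[j, 0]
            b2y = pos[k, 1] - pos[j, 1]
            b2z = pos[k, 2] - pos[j, 2]
            b3x = pos[l, 0] - pos[k, 0]
            b3y = pos[l, 1] - pos[k, 1]
            b3z = pos[l, 2] - pos[k, 2]
            rb1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            rb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            rb3 = np.sqrt(b3x * b3x + b3y * b3y + b3z * b3z)
            if rb1 < 1e-12 or rb2 < 1e-12 or rb3 < 1e-12:
                continue
            # flanking bending angles theta1 = angle(i,j,k), theta2 = angle(j,k,l)
            ct1 = -(b1x * b2x + b1y * b2y + b1z * b2z) / (rb1 * rb2)
            ct2 = -(b2x * b3x + b2y * b3y + b2z * b3z) / (rb2 * rb3)
            if ct1 > 1.0:
                ct1 = 1.0
            elif ct1 < -1.0:
                ct1 = -1.0
            if ct2 > 1.0:
                ct2 = 1.0
            elif ct2 < -1.0:
                ct2 = -1.0
            th1 = np.arccos(ct1)
            th2 = np.arccos(ct2)
            if th1 >= TORSION_TAPER_OFF or th2 >= TORSION_TAPER_OFF:
                continue
            span = TORSION_TAPER_OFF - TORSION_TAPER_ON
            if th1 <= TORSION_TAPER_ON:
                sw1, dsw1 = 1.0, 0.0
            else:
                xx = (th1 - TORSION_TAPER_ON) / span
                sw1 = 0.5 * (1.0 + np.cos(np.pi * xx))
                dsw1 = -0.5 * np.pi / span * np.sin(np.pi * xx)
            if th2 <= TORSION_TAPER_ON:
                sw2, dsw2 = 1.0, 0.0
            else:
                xx = (th2 - TORSION_TAPER_ON) / span
                sw2 = 0.5 * (1.0 + np.cos(np.pi * xx))
                dsw2 = -0.5 * np.pi / span * np.sin(np.pi * xx)
            # n1 = b1 x b2, n2 = b2 x b3
            n1x = b1y * b2z - b1z * b2y
            n1y = b1z * b2x - b1x * b2z
            n1z = b1x * b2y - b1y * b2x
            n2x = b2y * b3z - b2z * b3y
            n2y = b2z * b3x - b2x * b3z
            n2z = b2x * b3y - b2y * b3x
            n1sq = n1x * n1x + n1y * n1y + n1z * n1z
            n2sq = n2x * n2x + n2y * n2y + n2z * n2z
            if n1sq < 1e-16 or n2sq < 1e-16:
                continue
            # phi = atan2((n1 x n2).b2_hat, n1.n2)
            mx = n1y * n2z - n1z * n2y
            my = n1z * n2x - n1x * n2z
            mz = n1x * n2y - n1y * n2x
            sy = (mx * b2x + my * b2y + mz * b2z) / rb2
            sxc = n1x * n2x + n1y * n2y + n1z * n2z
            phi = np.arctan2(sy, sxc)
            if tors_mode == 0:
                ut = 0.0
                dudphi = 0.0
                for t in range(tors_ks.shape[0]):
                    arg = tors_mult[t] * phi - tors_phi0[t]
                    ut += tors_ks[t] * (1.0 + np.cos(arg))
                    dudphi += -tors_ks[t] * tors_mult[t] * np.sin(arg)
            else:
                ut, dudphi = _hermite(phi, tors_x0, tors_dx, tors_u, tors_du)
            energy += sw1 * sw2 * ut
            # phi-gradient part:
            # dphi/dri = -(rb2/n1sq) n1 ; dphi/drl = (rb2/n2sq) n2
            c1 = -rb2 / n1sq
            c2 = rb2 / n2sq
            gix = c1 * n1x
            giy = c1 * n1y
            giz = c1 * n1z
            glx = c2 * n2x
            gly = c2 * n2y
            glz = c2 * n2z
            s1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (rb2 * rb2)
            s2 = (b3x * b2x + b3y * b2y + b3z * b2z) / (rb2 * rb2)
            gjx = -(1.0 + s1) * gix + s2 * glx
            gjy = -(1.0 + s1) * giy + s2 * gly
            gjz = -(1.0 + s1) * giz + s2 * glz
            gkx = -(1.0 + s2) * glx + s1 * gix
            gky = -(1.0 + s2) * gly + s1 * giy
            gkz = -(1.0 + s2) * glz + s1 * giz
            w = sw1 * sw2 * dudphi
            forces[i, 0] -= w * gix
            forces[i, 1] -= w * giy
            forces[i, 2] -= w * giz
            forces[j, 0] -= w * gjx
            forces[j, 1] -= w * gjy
            forces[j, 2] -= w * gjz
            forces[k, 0] -= w * gkx
            forces[k, 1] -= w * gky
            forces[k, 2] -= w * gkz
            forces[l, 0] -= w * glx
            forces[l, 1] -= w * gly
            forces[l, 2] -= w * glz
            # taper-gradient parts: dE = (dsw1 * sw2 * ut) dtheta1
            #                           + (sw1 * dsw2 * ut) dtheta2
            if dsw1 != 0.0:
                st1 = np.sqrt(1.0 - ct1 * ct1)
                if st1 < 1e-8:
                    st1 = 1e-8
                # triple (i, j, k): u = ri - rj = -b1, v = rk - rj = b2
                w1 = dsw1 * sw2 * ut
                # dtheta/dri = -(v_hat - ct*u_hat)/(ru*st)
                tix = -((b2x / rb2) - ct1 * (-b1x / rb1)) / (rb1 * st1)
                tiy = -((b2y / rb2) - ct1 * (-b1y / rb1)) / (rb1 * st1)
                tiz = -((b2z / rb2) - ct1 * (-b1z / rb1)) / (rb1 * st1)
                tkx = -((-b1x / rb1) - ct1 * (b2x / rb2)) / (rb2 * st1)
                tky = -((-b1y / rb1) - ct1 * (b2y / rb2)) / (rb2 * st1)
                tkz = -((-b1z / rb1) - ct1 * (b2z / rb2)) / (rb2 * st1)
                forces[i, 0] -= w1 * tix
                forces[i, 1] -= w1 * tiy
                forces[i, 2] -= w1 * tiz
                forces[k, 0] -= w1 * tkx
                forces[k, 1] -= w1 * tky
                forces[k, 2] -= w1 * tkz
                forces[j, 0] += w1 * (tix + tkx)
                forces[j, 1] += w1 * (tiy + tky)
                forces[j, 2] += w1 * (tiz + tkz)
            if dsw2 != 0.0:
                st2 = np.sqrt(1.0 - ct2 * ct2)
                if st2 < 1e-8:
                    st2 = 1e-8
                # triple (j, k, l): u = rj - rk = -b2, v = rl - rk = b3
                w2 = sw1 * dsw2 * ut
                tjx = -((b3x / rb3) - ct2 * (-b2x / rb2)) / (rb2 * st2)
                tjy = -((b3y / rb3) - ct2 * (-b2y / rb2)) / (rb2 * st2)
                tjz = -((b3z / rb3) - ct2 * (-b2z / rb2)) / (rb2 * st2)
                tlx = -((-b2x / rb2) - ct2 * (b3x / rb3)) / (rb3 * st2)
                tly = -((-b2y / rb2) - ct2 * (b3y / rb3)) / (rb3 * st2)
                tlz = -((-b2z / rb2) - ct2 * (b3z / rb3)) / (rb3 * st2)
                forces[j, 0] -= w2 * tjx
                forces[j, 1] -= w2 * tjy
                forces[j, 2] -= w2 * tjz
                forces[l, 0] -= w2 * tlx
                forces[l, 1] -= w2 * tly
                forces[l, 2] -= w2 * tlz
                forces[k, 0] += w2 * (tjx + tlx)
                forces[k, 1] += w2 * (tjy + tly)
                forces[k, 2] += w2 * (tjz + tlz)

    # --- excluded volume + hydrophobic tail (sqrt-free inner loop) ---
    sig2 = sigma * sigma
    rc2 = rc_vdw * rc_vdw
    rmin2 = 2.0 ** (1.0 / 3.0) * sig2      # (2^(1/6) sigma)^2
    sr6c = (sig2 / rc2) ** 3
    ljc = 4.0 * (sr6c * sr6c - sr6c)       # attractive-tail value at the cutoff
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        if do_att:
            if hp_geometric:
                eps_hp = eps_hp_max * hsqrt[i] * hsqrt[j]
            else:
                eps_hp = eps_hp_max * 0.5 * (h[i] + h[j])
        else:
            eps_hp = 0.0
        if r2 >= rmin2 and eps_hp == 0.0:
            continue                       # outside the core, no attraction
        sr2 = sig2 / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        lj = 4.0 * (sr12 - sr6)
        dlj_r = -(48.0 * sr12 - 24.0 * sr6) / r2   # (dlj/dr) / r
        if r2 < rmin2:
            energy += eps_rep * (lj + 1.0) + eps_hp * (-1.0 - ljc)
            fs = -eps_rep * dlj_r
        else:
            energy += eps_hp * (lj - ljc)
            fs = -eps_hp * dlj_r
        if fs != 0.0:
            forces[i, 0] += fs * dx
            forces[i, 1] += fs * dy
            forces[i, 2] += fs * dz
            forces[j, 0] -= fs * dx
            forces[j, 1] -= fs * dy
            forces[j, 2] -= fs * dz

    # --- Debye-Hückel electrostatics (charged-bead pair list) ---
    if do_elec:
        shift_c = np.exp(-kappa * rc_coul) / rc_coul
        for p in range(ncoul):
            i = ci[p]
            j = cj[p]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r >= rc_coul:
                continue
            pref = coul_c * q[i] * q[j]
            ex = np.exp(-kappa * r)
            energy += pref * (ex / r - shift_c)
            fs = pref * ex * (kappa * r + 1.0) / (r2 * r)
            forces[i, 0] += fs * dx
            forces[i, 1] += fs * dy
            forces[i, 2] += fs * dz
            forces[j, 0] -= fs * dx
            forces[j, 1] -= fs * dy
            forces[j, 2] -= fs * dz

    # --- scaffold wall + blobs ---
    if scaffold_on:
        a2 = sc_re - sc_rw
        for i in range(n):
            z = pos[i, 2]
            if -sc_hl <= z <= sc_hl:
                rho = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
                rz = sc_rw + a2 * (z / sc_hl) ** 2
                delta = rho - (rz - sc_contact)
                if delta > 0.0 and rho > 1e-12:
                    energy += 0.5 * sc_k * delta * delta
                    drdz = 2.0 * a2 * z / (sc_hl * sc_hl)
                    forces[i, 0] += -sc_k * delta * pos[i, 0] / rho
                    forces[i, 1] += -sc_k * delta * pos[i, 1] / rho
                    forces[i, 2] += sc_k * delta * drdz
        for b in range(blobs.shape[0]):
            cx, cy, cz, br = blobs[b, 0], blobs[b, 1], blobs[b, 2], blobs[b, 3]
            for i in range(n):
                dx = pos[i, 0] - cx
                dy = pos[i, 1] - cy
                dz = pos[i, 2] - cz
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                delta = (br + sc_contact) - d
                if delta > 0.0 and d > 1e-12:
                    energy += 0.5 * sc_k * delta * delta
                    fs = sc_k * delta / d
                    forces[i, 0] += fs * dx
                    forces[i, 1] += fs * dy
                    forces[i, 2] += fs * dz

    if confine_radius > 0.0:
        for i in range(n):
            rho = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
            delta = rho - confine_radius
            if delta > 0.0 and rho > 1e-12:
                energy += 0.5 * confine_k * delta * delta
                forces[i, 0] += -confine_k * delta * pos[i, 0] / rho
                forces[i, 1] += -confine_k * delta * pos[i, 1] / rho

    return energy


@njit(cache=True)
def baoab_block(
    pos, vel, inv_mass, forces, noise,
    dt, gamma, kT,
    # pair-list state
    pi, pj, npairs, ci, cj, ncoul, ref_pos, skin,
    cutoff_vdw_list, cutoff_coul_list, charged, chain_id, excl_depth,
    # frame saving
    frames, save_idx, save_every, step0,
    # force-field arguments (same order as compute_forces)
    bonds, bond_k, bond_r0,
    angles, bend_mode, bend_k, bend_theta0, bend_x0, bend_dx, bend_u, bend_du,
    dihedrals, tors_mode, tors_ks, tors_mult, tors_phi0,
    tors_x0, tors_dx, tors_u, tors_du,
    sigma, eps_rep, eps_hp_max, hp_geometric, h, hsqrt, q,
    coul_c, kappa, rc_vdw, rc_coul,
    scaffold_on, sc_rw, sc_re, sc_hl, sc_contact, sc_k, blobs,
    confine_radius, confine_k,
    do_angles, do_att, do_elec,
):
    """Integrate one block of BAOAB Langevin steps.

    ``noise`` is (n_steps, N, 3) pre-drawn standard normals (seeded outside).
    Tethered beads carry ``inv_mass = 0``: the friction/noise update leaves
    their (zero) velocity untouched, so they never move.  With ``gamma = 0``
    the scheme reduces to velocity Verlet.

    Returns (status, npairs, ncoul, save_idx, ke_sum, ke_count, err_step):
    status 0 = ok, 1 = pair-list overflow (state restored by caller),
    2 = non-finite coordinates (err_step is the offending step).
    """
    n = pos.shape[0]
    nsteps = noise.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    half = 0.5 * dt
    ke_sum = 0.0
    ke_count = 0
    rebuild_trigger = 0.25 * skin * skin
    for t in range(nsteps):
        for i in range(n):
            im = inv_mass[i]
            # B: half kick
            vel[i, 0] += half * forces[i, 0] * im
            vel[i, 1] += half * forces[i, 1] * im
            vel[i, 2] += half * forces[i, 2] * im
            # A: half drift
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
            # O: friction + noise
            s = c2 * np.sqrt(kT * im)
            vel[i, 0] = c1 * vel[i, 0] + s * noise[t, i, 0]
            vel[i, 1] = c1 * vel[i, 1] + s * noise[t, i, 1]
            vel[i, 2] = c1 * vel[i, 2] + s * noise[t, i, 2]
            # A: half drift
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        # pair-list freshness
        needs = False
        for i in range(n):
            dx = pos[i, 0] - ref_pos[i, 0]
            dy = pos[i, 1] - ref_pos[i, 1]
            dz = pos[i, 2] - ref_pos[i, 2]
            if dx * dx + dy * dy + dz * dz > rebuild_trigger:
                needs = True
                break
        if needs:
            all_active = np.ones(n, dtype=np.bool_)
            npairs = build_pairs(pos, chain_id, excl_depth, cutoff_vdw_list,
                                 all_active, pi, pj)
            ncoul = build_pairs(pos, chain_id, excl_depth, cutoff_coul_list,
                                charged, ci, cj)
            if npairs < 0 or ncoul < 0:
                return 1, npairs, ncoul, save_idx, ke_sum, ke_count, step0 + t
            for i in range(n):
                ref_pos[i, 0] = pos[i, 0]
                ref_pos[i, 1] = pos[i, 1]
                ref_pos[i, 2] = pos[i, 2]
        compute_forces(
            pos, forces,
            bonds, bond_k, bond_r0,
            angles, bend_mode, bend_k, bend_theta0, bend_x0, bend_dx,
            bend_u, bend_du,
            dihedrals, tors_mode, tors_ks, tors_mult, tors_phi0,
            tors_x0, tors_dx, tors_u, tors_du,
            pi, pj, npairs, ci, cj, ncoul,
            sigma, eps_rep, eps_hp_max, hp_geometric, h, hsqrt, q,
            coul_c, kappa, rc_vdw, rc_coul,
            scaffold_on, sc_rw, sc_re, sc_hl, sc_contact, sc_k, blobs,
            confine_radius, confine_k,
            do_angles, do_att, do_elec,
        )
        ke = 0.0
        for i in range(n):
            im = inv_mass[i]
            # B: half kick
            vel[i, 0] += half * forces[i, 0] * im
            vel[i, 1] += half * forces[i, 1] * im
            vel[i, 2] += half * forces[i, 2] * im
            if im > 0.0:
                ke += 0.5 * (
                    vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
                ) / im
        if not np.isfinite(ke):
            return 2, npairs, ncoul, save_idx, ke_sum, ke_count, step0 + t
        ke_sum += ke
        ke_count += 1
        if (step0 + t + 1) % save_every == 0:
            for i in range(n):
                frames[save_idx, i, 0] = pos[i, 0]
                frames[save_idx, i, 1] = pos[i, 1]
                frames[save_idx, i, 2] = pos[i, 2]
            save_idx += 1
    return 0, npairs, ncoul, save_idx, ke_sum, ke_count, -1
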