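"""Numba kernels for pairwise forces/energies and neighbor-list construction.

All kernels take flat numpy arrays and are single-threaded and deterministic.
Pair interactions: Ashbaugh-Hatch (lambda-scaled Lennard-Jones with WCA
limit at lambda=0, shifted to zero at its cutoff) and shift-truncated
Debye-Hueckel electrostatics.  Arithmetic-mean combining rules for sigma and
lambda.  Directly bonded (1-2) pairs are excluded via ``bonded_next``.
"""

import math

import numpy as np
from numba import njit

TWO_POW_SIXTH = 2.0 ** (1.0 / 6.0)


@njit(cache=True)
def _min_image(d, box):
    return d - box * np.round(d / box)


@njit(cache=True)
def pair_forces(
    pos,           # (N,3) wrapped positions, nm
    box,           # cubic box edge, nm
    pi, pj,        # candidate pair index arrays (i < j)
    sigma, lam, charge,   # per-bead parameters
    bonded_next,   # bool (N,): bead i bonded to i+1
    eps_ah, rc_ah, rc_dh, kappa, coul_pref,
    overlap_floor,  # fraction of sigma_ij below which a pair counts as overlap
    forces,        # (N,3) output, accumulated in place
):
    """Accumulate AH + DH forces; return (e_ah, e_dh, n_overlaps)."""
    e_ah = 0.0
    e_dh = 0.0
    n_overlap = 0
    shift_dh = math.exp(-kappa * rc_dh) / rc_dh
    for n in range(pi.shape[0]):
        i = pi[n]
        j = pj[n]
        if j == i + 1 and bonded_next[i]:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        r = math.sqrt(r2)
        if r <= 0.0:
            n_overlap += 1
            continue
        sij = 0.5 * (sigma[i] + sigma[j])
        if r < overlap_floor * sij:
            n_overlap += 1
        fmag = 0.0  # dU/dr, to be negated into force
        # Ashbaugh-Hatch
        if r <= rc_ah:
            lij = 0.5 * (lam[i] + lam[j])
            sr6 = (sij / r) ** 6
            ulj = 4.0 * eps_ah * (sr6 * sr6 - sr6)
            dulj = -24.0 * eps_ah * (2.0 * sr6 * sr6 - sr6) / r
            src6 = (sij / rc_ah) ** 6
            ulj_rc = 4.0 * eps_ah * (src6 * src6 - src6)
            if r <= TWO_POW_SIXTH * sij:
                e_ah += ulj - lij * ulj_rc + eps_ah * (1.0 - lij)
                fmag += dulj
            else:
                e_ah += lij * (ulj - ulj_rc)
                fmag += lij * dulj
        # Debye-Hueckel (shift-truncated)
        qq = charge[i] * charge[j]
        if qq != 0.0 and r <= rc_dh:
            pref = coul_pref * qq
            e_dh += pref * (math.exp(-kappa * r) / r - shift_dh)
            fmag += -pref * math.exp(-kappa * r) * (kappa * r + 1.0) / r2
        if fmag != 0.0:
            fx = -fmag * dx / r
            fy = -fmag * dy / r
            fz = -fmag * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return e_ah, e_dh, n_overlap


@njit(cache=True)
def bond_forces(pos, box, bi, bj, r0, k, forces):
    """Accumulate harmonic bond forces (minimum image); return bond energy."""
    e = 0.0
    for n in range(bi.shape[0]):
        i = bi[n]
        j = bj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[n]
        e += 0.5 * k[n] * dr * dr
        if r > 0.0:
            fmag = -k[n] * dr / r
            fx = fmag * dx
            fy = fmag * dy
            fz = fmag * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return e


@njit(cache=True)
def all_pairs_within(pos, box, rlist):
    """Brute-force (i<j) pair list within rlist under minimum image."""
    n = pos.shape[0]
    cap = 64
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    count = 0
    r2max = rlist * rlist
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            if dx * dx + dy * dy + dz * dz <= r2max:
                if count == cap:
                    cap *= 2
                    new_i = np.empty(cap, dtype=np.int64)
                    new_j = np.empty(cap, dtype=np.int64)
                    new_i[:count] = pi[:count]
                    new_j[:count] = pj[:count]
                    pi = new_i
                    pj = new_j
                pi[count] = i
                pj[count] = j
                count += 1
    return pi[:count], pj[:count]


@njit(cache=True)
def max_displacement(pos, ref, box):
    """Largest per-bead minimum-image displacement between two wrapped frames."""
    n = pos.shape[0]
    dmax = 0.0
    for i in range(n):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > dmax:
            dmax = d2
    return math.sqrt(dmax)


@njit(cache=True)
def chain_com_repulsion(pos, box, chain_id, mass, n_chains, d0, k_rep, forces):
    """Soft half-harmonic repulsion between chain centers of mass.

    Used during pre-equilibration to keep chains dispersed; the force on a
    chain is distributed over its beads proportionally to bead mass, so it
    acts as a pure center-of-mass push.  Chain COMs are computed on
    bond-walk-unwrapped coordinates (beads of one chain are assumed
    contiguous in index order).  Returns the repulsion energy.
    """
    n = pos.shape[0]
    com = np.zeros((n_chains, 3))
    mtot = np.zeros(n_chains)
    ux = 0.0
    uy = 0.0
    uz = 0.0
    for i in range(n):
        c = chain_id[i]
        if i == 0 or chain_id[i - 1] != c:
            ux = pos[i, 0]
            uy = pos[i, 1]
            uz = pos[i, 2]
        else:
            dx = pos[i, 0] - pos[i - 1, 0]
            dy = pos[i, 1] - pos[i - 1, 1]
            dz = pos[i, 2] - pos[i - 1, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            ux += dx
            uy += dy
            uz += dz
        com[c, 0] += mass[i] * ux
        com[c, 1] += mass[i] * uy
        com[c, 2] += mass[i] * uz
        mtot[c] += mass[i]
    for c in range(n_chains):
        com[c, 0] /= mtot[c]
        com[c, 1] /= mtot[c]
        com[c, 2] /= mtot[c]
    e = 0.0
    fcom = np.zeros((n_chains, 3))
    for a in range(n_chains):
        for b in range(a + 1, n_chains):
            dx = com[a, 0] - com[b, 0]
            dy = com[a, 1] - com[b, 1]
            dz = com[a, 2] - com[b, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r < d0 and r > 0.0:
                e += 0.5 * k_rep * (d0 - r) ** 2
                fmag = k_rep * (d0 - r) / r
                fcom[a, 0] += fmag * dx
                fcom[a, 1] += fmag * dy
                fcom[a, 2] += fmag * dz
                fcom[b, 0] -= fmag * dx
                fcom[b, 1] -= fmag * dy
                fcom[b, 2] -= fmag * dz
    for i in range(n):
        c = chain_id[i]
        w = mass[i] / mtot[c]
        forces[i, 0] += w * fcom[c, 0]
        forces[i, 1] += w * fcom[c, 1]
        forces[i, 2] += w * fcom[c, 2]
    return e
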