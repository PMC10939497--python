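"""Numba-compiled inner loops for energy/force evaluation.

The pure-numpy implementation in :mod:`polycg.force_field` remains the
reference route; these kernels must agree with it to floating-point
round-off and are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NB_HP, NB_CATION_PI, NB_EXCLUDED = 1, 2, 3


@njit(cache=True, fastmath=False)
def _dielectric(r, Ss, z):
    """Returns (eps_r, deps_dr) for the distance-dependent dielectric."""
    x = r / (2.0 * z)
    if x < 1.0e-4:
        g = 1.0 - x * x / 3.0 + x**4 / 15.0
        dg = -2.0 * x / 3.0 + 4.0 * x**3 / 15.0
    elif x > 30.0:
        g = 0.0
        dg = 0.0
    else:
        s = np.sinh(x)
        c = np.cosh(x)
        g = (x / s) ** 2
        dg = 2.0 * x * (s - x * c) / s**3
    eps = Ss * (1.0 - g)
    deps = -Ss * dg / (2.0 * z)
    return eps, deps


@njit(cache=True, fastmath=False)
def nonbonded_kernel(
    pos, box, nb_i, nb_j, cls, eps_ij, eps_cp, qq, shift,
    sigma, eps_rep, rm, coulomb, kappa, Ss, z, rc2, forces,
):
    """Accumulates nonbonded forces in-place; returns (energy, overlap_index).

    ``box <= 0`` disables periodicity; ``rc2 <= 0`` disables the cutoff.
    ``overlap_index`` is the first pair-table index with r < 1e-6 nm, or -1.
    """
    energy = 0.0
    for k in range(nb_i.size):
        i = nb_i[k]
        j = nb_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if box > 0.0:
            dx -= box * np.round(dx / box)
            dy -= box * np.round(dy / box)
            dz -= box * np.round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1.0e-12:
            return energy, k
        if rc2 > 0.0 and r2 >= rc2:
            continue
        r = np.sqrt(r2)
        e = 0.0
        de = 0.0
        c = cls[k]
        if c == NB_HP or c == NB_EXCLUDED:
            s2 = (sigma / r) ** 2
            s6 = s2 * s2 * s2
            s8 = s6 * s2
            eij = eps_ij[k]
            if r <= sigma:
                e = eps_rep * s8 - eij * (4.0 / 3.0 * s6 - 1.0 / 3.0)
                de = (-8.0 * eps_rep * s8 + 8.0 * eij * s6) / r
            else:
                e = (eps_rep - eij) * s8
                de = -8.0 * (eps_rep - eij) * s8 / r
        elif c == NB_CATION_PI:
            u2 = (rm / r) ** 2
            u6 = u2 * u2 * u2
            u8 = u6 * u2
            ecp = eps_cp[k]
            e = ecp * (3.0 * u8 - 4.0 * u6)
            de = ecp * 24.0 * (u6 - u8) / r
        q = qq[k]
        if q != 0.0:
            eps, deps = _dielectric(r, Ss, z)
            ee = coulomb * q * np.exp(-kappa * r) / (eps * r)
            e += ee
            de += ee * (-kappa - 1.0 / r - deps / eps)
        energy += e - shift[k]
        fs = -de / r
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz
    return energy, -1


@njit(cache=True, fastmath=False)
def bonded_kernel(pos, box, bond_i, bond_j, bond_b, bond_k, forces):
    """Harmonic bonds; accumulates forces in-place.

    Returns (energy, overlap_index) with overlap_index = -1 when no bonded
    pair has collapsed to r < 1e-6 nm.
    """
    energy = 0.0
    for n in range(bond_i.size):
        i = bond_i[n]
        j = bond_j[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if box > 0.0:
            dx -= box * np.round(dx / box)
            dy -= box * np.round(dy / box)
            dz -= box * np.round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1.0e-12:
            return energy, n
        r = np.sqrt(r2)
        dr = r - bond_b[n]
        energy += bond_k[n] * dr * dr
        fs = -2.0 * bond_k[n] * dr / r
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz
    return energy, -1
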