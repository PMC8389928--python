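"""Jit-compiled inner loops for the energy/force evaluation.

The kernel is an all-pairs double loop with minimum-image distances and
per-axis early rejection; at the bead counts of desk-scale runs (tens to
hundreds of chains) this beats neighbour-list bookkeeping.  Positions
must be wrapped into [0, box), so a single +-box correction realises the
minimum image.  Exactness against the vectorised numpy path is enforced
by the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def energy_forces_kernel(
    pos,
    box,
    chain_id,
    idx_in_chain,
    bonds,
    angles,
    k_b,
    r0,
    k_theta,
    cos_theta0,
    eps,
    sigma,
    rc,
    e_shift,
    excl_sep,
):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    half = 0.5 * box

    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > half:
            dx -= box
        elif dx < -half:
            dx += box
        if dy > half:
            dy -= box
        elif dy < -half:
            dy += box
        if dz > half:
            dz -= box
        elif dz < -half:
            dz += box
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        energy += 0.5 * k_b * dr * dr
        fscal = -k_b * dr / r
        forces[i, 0] += fscal * dx
        forces[i, 1] += fscal * dy
        forces[i, 2] += fscal * dz
        forces[j, 0] -= fscal * dx
        forces[j, 1] -= fscal * dy
        forces[j, 2] -= fscal * dz

    if k_theta > 0.0:
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
            if ux > half:
                ux -= box
            elif ux < -half:
                ux += box
            if uy > half:
                uy -= box
            elif uy < -half:
                uy += box
            if uz > half:
                uz -= box
            elif uz < -half:
                uz += box
            if vx > half:
                vx -= box
            elif vx < -half:
                vx += box
            if vy > half:
                vy -= box
            elif vy < -half:
                vy += box
            if vz > half:
                vz -= box
            elif vz < -half:
                vz += box
            lu2 = ux * ux + uy * uy + uz * uz
            lv2 = vx * vx + vy * vy + vz * vz
            lu = np.sqrt(lu2)
            lv = np.sqrt(lv2)
            cth = (ux * vx + uy * vy + uz * vz) / (lu * lv)
            if cth > 1.0:
                cth = 1.0
            elif cth < -1.0:
                cth = -1.0
            diff = cth - cos_theta0
            energy += 0.5 * k_theta * diff * diff
            dvdcos = k_theta * diff
            ilulv = 1.0 / (lu * lv)
            fix = -dvdcos * (vx * ilulv - cth * ux / lu2)
            fiy = -dvdcos * (vy * ilulv - cth * uy / lu2)
            fiz = -dvdcos * (vz * ilulv - cth * uz / lu2)
            fkx = -dvdcos * (ux * ilulv - cth * vx / lv2)
            fky = -dvdcos * (uy * ilulv - cth * vy / lv2)
            fkz = -dvdcos * (uz * ilulv - cth * vz / lv2)
            forces[i, 0] += fix
            forces[i, 1] += fiy
            forces[i, 2] += fiz
            forces[k, 0] += fkx
            forces[k, 1] += fky
            forces[k, 2] += fkz
            forces[j, 0] -= fix + fkx
            forces[j, 1] -= fiy + fky
            forces[j, 2] -= fiz + fkz

    rc2 = rc * rc
    sig2 = sigma * sigma
    for i in range(n - 1):
        ci = chain_id[i]
        ii = idx_in_chain[i]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            if dx > half:
                dx -= box
            elif dx < -half:
                dx += box
            if dx > rc or dx < -rc:
                continue
            dy = yi - pos[j, 1]
            if dy > half:
                dy -= box
            elif dy < -half:
                dy += box
            if dy > rc or dy < -rc:
                continue
            dz = zi - pos[j, 2]
            if dz > half:
                dz -= box
            elif dz < -half:
                dz += box
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rc2:
                continue
            if ci == chain_id[j]:
                sep = idx_in_chain[j] - ii
                if sep < 0:
                    sep = -sep
                if sep <= excl_sep:
                    continue
            sr2 = sig2 / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            energy += 4.0 * eps * (sr12 - sr6) - e_shift
            fr = 24.0 * eps * (2.0 * sr12 - sr6) / r2
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz

    return energy, forces
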