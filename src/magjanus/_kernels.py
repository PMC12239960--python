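"""Compiled (numba) integration core.

Mirrors the reference force terms in :mod:`magjanus.interactions` — the
test suite asserts the two agree — and advances the overdamped equations
of motion with explicit Euler steps.  Orientations are propagated by the
exponential map of the angular-velocity vector and re-orthonormalised
every step.

Stability: the point-dipole pair force grows as 1/r^4 when two magnetic
reference points approach (caps facing each other), which a fixed Euler
step cannot integrate.  Each nominal timestep is therefore advanced by
adaptive sub-steps bounded so that no particle moves more than
``SUB_DISP`` or rotates more than ``SUB_ROT`` per sub-step; in smooth
regimes this reduces to a single plain Euler step of the nominal size.
The total number of extra sub-steps is reported as a diagnostic, and a
step that would require more than ``MAX_SUBSTEPS`` aborts the run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

RCUT2 = 2.0 ** (1.0 / 3.0)      # squared WCA cutoff (sigma = 1)
WALL_SIGMA = 0.5
WALL_RCUT = 2.0 ** (1.0 / 6.0) * WALL_SIGMA
SUB_DISP = 0.005                # max displacement per sub-step, sigma
SUB_ROT = 0.02                  # max rotation per sub-step, rad
MAX_SUBSTEPS = 2000             # abort threshold per nominal step
MAX_CONTACTS = 8
#: short-range regularisation of the point-dipole pair interaction: below
#: this magnetic-point separation the 1/r powers saturate (the point
#: approximation of an extended cap is invalid there and would otherwise
#: make cap-facing pairs collapse onto the singularity)
DIPOLE_RMIN = 0.8

STATUS_OK = 0
STATUS_COINCIDENT = 1
STATUS_BLOWUP = 2


@njit(cache=True)
def _compute_loads(r, u, muh, mstar, soff, wcen, wcap, B,
                   wall_c, wall_e1, wall_e2, wall_a, wall_lam,
                   bond_cut, gamma, v_stick, F, T):
    """Fill total forces/torques (about centres), friction included.

    Returns a status code (0 ok, 1 coincident particles).
    """
    n = r.shape[0]
    nw = wall_c.shape[0]
    F[:] = 0.0
    T[:] = 0.0

    # magnetic points and dipole vectors
    rm = np.empty((n, 3))
    mv = np.empty((n, 3))
    for i in range(n):
        for k in range(3):
            rm[i, k] = r[i, k] - soff[i] * u[i, k]
            mv[i, k] = mstar[i] * muh[i, k]

    in_chain = np.zeros(n, dtype=np.bool_)
    bond2 = bond_cut * bond_cut

    # pair terms
    for i in range(n):
        for j in range(i + 1, n):
            dx = r[i, 0] - r[j, 0]
            dy = r[i, 1] - r[j, 1]
            dz = r[i, 2] - r[j, 2]
            rc2 = dx * dx + dy * dy + dz * dz
            if rc2 < 1e-20:
                return STATUS_COINCIDENT
            if rc2 < bond2:
                in_chain[i] = True
                in_chain[j] = True
            # WCA between centres
            if rc2 < RCUT2:
                inv2 = 1.0 / rc2
                sr6 = inv2 * inv2 * inv2
                fm = 24.0 * (2.0 * sr6 * sr6 - sr6) * inv2
                F[i, 0] += fm * dx
                F[i, 1] += fm * dy
                F[i, 2] += fm * dz
                F[j, 0] -= fm * dx
                F[j, 1] -= fm * dy
                F[j, 2] -= fm * dz
            # dipole-dipole between magnetic points
            ex = rm[i, 0] - rm[j, 0]
            ey = rm[i, 1] - rm[j, 1]
            ez = rm[i, 2] - rm[j, 2]
            rm2 = ex * ex + ey * ey + ez * ez
            if rm2 < 1e-20:
                return STATUS_COINCIDENT
            rmag = np.sqrt(rm2)
            nx = ex / rmag
            ny = ey / rmag
            nz = ez / rmag
            if rmag < DIPOLE_RMIN:
                rmag = DIPOLE_RMIN
                rm2 = DIPOLE_RMIN * DIPOLE_RMIN
            mi_n = mv[i, 0] * nx + mv[i, 1] * ny + mv[i, 2] * nz
            mj_n = mv[j, 0] * nx + mv[j, 1] * ny + mv[j, 2] * nz
            mi_mj = (mv[i, 0] * mv[j, 0] + mv[i, 1] * mv[j, 1]
                     + mv[i, 2] * mv[j, 2])
            c = 3.0 / (rm2 * rm2)
            fx = c * (mi_n * mv[j, 0] + mj_n * mv[i, 0]
                      + (mi_mj - 5.0 * mi_n * mj_n) * nx)
            fy = c * (mi_n * mv[j, 1] + mj_n * mv[i, 1]
                      + (mi_mj - 5.0 * mi_n * mj_n) * ny)
            fz = c * (mi_n * mv[j, 2] + mj_n * mv[i, 2]
                      + (mi_mj - 5.0 * mi_n * mj_n) * nz)
            inv3 = 1.0 / (rm2 * rmag)
            # dipole field of j at i and of i at j
            bix = inv3 * (3.0 * mj_n * nx - mv[j, 0])
            biy = inv3 * (3.0 * mj_n * ny - mv[j, 1])
            biz = inv3 * (3.0 * mj_n * nz - mv[j, 2])
            bjx = inv3 * (3.0 * mi_n * nx - mv[i, 0])
            bjy = inv3 * (3.0 * mi_n * ny - mv[i, 1])
            bjz = inv3 * (3.0 * mi_n * nz - mv[i, 2])
            F[i, 0] += fx
            F[i, 1] += fy
            F[i, 2] += fz
            F[j, 0] -= fx
            F[j, 1] -= fy
            F[j, 2] -= fz
            # orientation torques mu x B
            T[i, 0] += mv[i, 1] * biz - mv[i, 2] * biy
            T[i, 1] += mv[i, 2] * bix - mv[i, 0] * biz
            T[i, 2] += mv[i, 0] * biy - mv[i, 1] * bix
            T[j, 0] += mv[j, 1] * bjz - mv[j, 2] * bjy
            T[j, 1] += mv[j, 2] * bjx - mv[j, 0] * bjz
            T[j, 2] += mv[j, 0] * bjy - mv[j, 1] * bjx
            # lever arms (r_m - r_c) x (+/- f)
            lx = -soff[i] * u[i, 0]
            ly = -soff[i] * u[i, 1]
            lz = -soff[i] * u[i, 2]
            T[i, 0] += ly * fz - lz * fy
            T[i, 1] += lz * fx - lx * fz
            T[i, 2] += lx * fy - ly * fx
            lx = -soff[j] * u[j, 0]
            ly = -soff[j] * u[j, 1]
            lz = -soff[j] * u[j, 2]
            T[j, 0] += ly * (-fz) - lz * (-fy)
            T[j, 1] += lz * (-fx) - lx * (-fz)
            T[j, 2] += lx * (-fy) - ly * (-fx)

    # single-particle terms: gravity/buoyancy, external field, walls, friction
    for i in range(n):
        # gravity + buoyancy
        F[i, 2] -= wcen[i] + wcap[i]
        # torque (-s u) x (0, 0, -wcap)
        T[i, 0] += (-soff[i] * u[i, 1]) * (-wcap[i])
        T[i, 1] -= (-soff[i] * u[i, 0]) * (-wcap[i])
        # external field torque mu x B
        T[i, 0] += mv[i, 1] * B[2] - mv[i, 2] * B[1]
        T[i, 1] += mv[i, 2] * B[0] - mv[i, 0] * B[2]
        T[i, 2] += mv[i, 0] * B[1] - mv[i, 1] * B[0]

        # wall contacts
        ncon = 0
        con_n = np.empty((MAX_CONTACTS, 3))
        con_N = np.empty(MAX_CONTACTS)
        con_lam = np.empty((MAX_CONTACTS, 2))
        for w in range(nw):
            dx = r[i, 0] - wall_c[w, 0]
            dy = r[i, 1] - wall_c[w, 1]
            dz = r[i, 2] - wall_c[w, 2]
            t1 = dx * wall_e1[w, 0] + dy * wall_e1[w, 1] + dz * wall_e1[w, 2]
            t2 = dx * wall_e2[w, 0] + dy * wall_e2[w, 1] + dz * wall_e2[w, 2]
            if t1 > wall_a[w, 0]:
                t1 = wall_a[w, 0]
            elif t1 < -wall_a[w, 0]:
                t1 = -wall_a[w, 0]
            if t2 > wall_a[w, 1]:
                t2 = wall_a[w, 1]
            elif t2 < -wall_a[w, 1]:
                t2 = -wall_a[w, 1]
            vx = dx - t1 * wall_e1[w, 0] - t2 * wall_e2[w, 0]
            vy = dy - t1 * wall_e1[w, 1] - t2 * wall_e2[w, 1]
            vz = dz - t1 * wall_e1[w, 2] - t2 * wall_e2[w, 2]
            d2 = vx * vx + vy * vy + vz * vz
            if d2 >= WALL_RCUT * WALL_RCUT or d2 < 1e-20:
                continue
            d = np.sqrt(d2)
            q6 = (WALL_SIGMA / d) ** 6
            nmag = 24.0 * (2.0 * q6 * q6 - q6) / d
            nhx = vx / d
            nhy = vy / d
            nhz = vz / d
            F[i, 0] += nmag * nhx
            F[i, 1] += nmag * nhy
            F[i, 2] += nmag * nhz
            if ncon < MAX_CONTACTS:
                con_n[ncon, 0] = nhx
                con_n[ncon, 1] = nhy
                con_n[ncon, 2] = nhz
                con_N[ncon] = nmag
                con_lam[ncon, 0] = wall_lam[w, 0]
                con_lam[ncon, 1] = wall_lam[w, 1]
                ncon += 1

        # Coulomb friction: chain-arranged particles only (singles roll)
        if in_chain[i]:
            for c_ in range(ncon):
                nN = con_N[c_]
                if nN <= 0.0:
                    continue
                nhx = con_n[c_, 0]
                nhy = con_n[c_, 1]
                nhz = con_n[c_, 2]
                lam_s = con_lam[c_, 0]
                lam_d = con_lam[c_, 1]
                fn = F[i, 0] * nhx + F[i, 1] * nhy + F[i, 2] * nhz
                ftx = F[i, 0] - fn * nhx
                fty = F[i, 1] - fn * nhy
                ftz = F[i, 2] - fn * nhz
                fmag = np.sqrt(ftx * ftx + fty * fty + ftz * ftz)
                thr = lam_s * nN
                if gamma * v_stick > thr:
                    thr = gamma * v_stick
                if fmag <= thr:
                    F[i, 0] -= ftx
                    F[i, 1] -= fty
                    F[i, 2] -= ftz
                elif fmag > 0.0:
                    sc = lam_d * nN / fmag
                    F[i, 0] -= sc * ftx
                    F[i, 1] -= sc * fty
                    F[i, 2] -= sc * ftz
                tn = T[i, 0] * nhx + T[i, 1] * nhy + T[i, 2] * nhz
                cap = lam_s * nN * 0.5
                if abs(tn) <= cap:
                    T[i, 0] -= tn * nhx
                    T[i, 1] -= tn * nhy
                    T[i, 2] -= tn * nhz
                else:
                    red = lam_d * nN * 0.5
                    if tn < 0.0:
                        red = -red
                    T[i, 0] -= red * nhx
                    T[i, 1] -= red * nhy
                    T[i, 2] -= red * nhz
    return STATUS_OK


@njit(cache=True)
def _rotate(vec, ax, ay, az, angle):
    """Rodrigues rotation of ``vec`` about unit axis (ax, ay, az)."""
    c = np.cos(angle)
    s = np.sin(angle)
    dot = vec[0] * ax + vec[1] * ay + vec[2] * az
    cx = ay * vec[2] - az * vec[1]
    cy = az * vec[0] - ax * vec[2]
    cz = ax * vec[1] - ay * vec[0]
    vec[0] = vec[0] * c + cx * s + ax * dot * (1.0 - c)
    vec[1] = vec[1] * c + cy * s + ay * dot * (1.0 - c)
    vec[2] = vec[2] * c + cz * s + az * dot * (1.0 - c)


@njit(cache=True)
def run(r, u, muh, mstar, soff, wcen, wcap, Bseq,
        wall_c, wall_e1, wall_e2, wall_a, wall_lam,
        dt, gamma, gamma_r, bond_cut, v_stick, stride,
        out_r, out_u, out_muh):
    """Integrate ``n_steps = Bseq.shape[0]`` nominal Euler steps with
    adaptive sub-stepping, recording every ``stride`` steps plus the
    final state.

    Returns (status, step_of_failure, n_extra_substeps).
    """
    n = r.shape[0]
    n_steps = Bseq.shape[0]
    F = np.empty((n, 3))
    T = np.empty((n, 3))
    n_extra = 0

    for step in range(n_steps):
        if step % stride == 0:
            f = step // stride
            out_r[f] = r
            out_u[f] = u
            out_muh[f] = muh
        t_rem = dt
        nsub = 0
        while t_rem > 1e-12 * dt:
            status = _compute_loads(
                r, u, muh, mstar, soff, wcen, wcap, Bseq[step],
                wall_c, wall_e1, wall_e2, wall_a, wall_lam,
                bond_cut, gamma, v_stick, F, T,
            )
            if status != STATUS_OK:
                return status, step, n_extra
            vmax = 0.0
            wmax = 0.0
            for i in range(n):
                v = np.sqrt(F[i, 0] ** 2 + F[i, 1] ** 2 + F[i, 2] ** 2) / gamma
                w = np.sqrt(T[i, 0] ** 2 + T[i, 1] ** 2 + T[i, 2] ** 2) / gamma_r
                if v > vmax:
                    vmax = v
                if w > wmax:
                    wmax = w
            dt_sub = t_rem
            if vmax * dt_sub > SUB_DISP:
                dt_sub = SUB_DISP / vmax
            if wmax * dt_sub > SUB_ROT:
                dt_sub2 = SUB_ROT / wmax
                if dt_sub2 < dt_sub:
                    dt_sub = dt_sub2
            nsub += 1
            if nsub > MAX_SUBSTEPS:
                return STATUS_BLOWUP, step, n_extra
            for i in range(n):
                r[i, 0] += dt_sub / gamma * F[i, 0]
                r[i, 1] += dt_sub / gamma * F[i, 1]
                r[i, 2] += dt_sub / gamma * F[i, 2]
                wx = T[i, 0] / gamma_r
                wy = T[i, 1] / gamma_r
                wz = T[i, 2] / gamma_r
                wmag = np.sqrt(wx * wx + wy * wy + wz * wz)
                angle = wmag * dt_sub
                if angle > 1e-14:
                    ax = wx / wmag
                    ay = wy / wmag
                    az = wz / wmag
                    _rotate(u[i], ax, ay, az, angle)
                    _rotate(muh[i], ax, ay, az, angle)
                # re-orthonormalise the body frame
                un = np.sqrt(u[i, 0] ** 2 + u[i, 1] ** 2 + u[i, 2] ** 2)
                u[i, 0] /= un
                u[i, 1] /= un
                u[i, 2] /= un
                dot = (muh[i, 0] * u[i, 0] + muh[i, 1] * u[i, 1]
                       + muh[i, 2] * u[i, 2])
                muh[i, 0] -= dot * u[i, 0]
                muh[i, 1] -= dot * u[i, 1]
                muh[i, 2] -= dot * u[i, 2]
                mn = np.sqrt(muh[i, 0] ** 2 + muh[i, 1] ** 2 + muh[i, 2] ** 2)
                muh[i, 0] /= mn
                muh[i, 1] /= mn
                muh[i, 2] /= mn
            t_rem -= dt_sub
        n_extra += nsub - 1

    f = n_steps // stride
    if f < out_r.shape[0]:
        out_r[f] = r
        out_u[f] = u
        out_muh[f] = muh
    return STATUS_OK, n_steps, n_extra
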