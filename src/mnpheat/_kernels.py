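"""Compiled inner loops of the rotational Langevin integrator.

The splitting per step dt is

    B: half kick      w += (dt/2) (mu e x B) / I
    AO: exact free Langevin flight over dt -- the angular velocity and the
        integrated rotation angle are drawn jointly from the exact
        Ornstein-Uhlenbeck solution (Chandrasekhar covariances), so the
        free-rotor orientational diffusion is exact at any dt
    R: rigid rotation of e by the accumulated angle (Rodrigues)
    B: half kick with the torque at the new orientation

Pair geometry (neighbor CSR, unit vectors, 1/r^3) is precomputed once
because positions never move.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def compute_torques(e, indptr, indices, rhat, inv_r3, b_ext, pref, mu, tq, bint):
    """Torques mu e_i x B_i and interaction-only fields, in place.

    pref = (mu0/4pi) * mu.  b_ext is the (3,) external field at this instant.
    """
    n = e.shape[0]
    for i in range(n):
        bix = 0.0
        biy = 0.0
        biz = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            rx = rhat[p, 0]
            ry = rhat[p, 1]
            rz = rhat[p, 2]
            proj = 3.0 * (e[j, 0] * rx + e[j, 1] * ry + e[j, 2] * rz)
            f = pref * inv_r3[p]
            bix += f * (proj * rx - e[j, 0])
            biy += f * (proj * ry - e[j, 1])
            biz += f * (proj * rz - e[j, 2])
        bint[i, 0] = bix
        bint[i, 1] = biy
        bint[i, 2] = biz
        bx = bix + b_ext[0]
        by = biy + b_ext[1]
        bz = biz + b_ext[2]
        ex = e[i, 0]
        ey = e[i, 1]
        ez = e[i, 2]
        tq[i, 0] = mu * (ey * bz - ez * by)
        tq[i, 1] = mu * (ez * bx - ex * bz)
        tq[i, 2] = mu * (ex * by - ey * bx)


@njit(cache=True)
def run_chunk(e, w, tq, bint, indptr, indices, rhat, inv_r3,
              b_static, ac_amp, ac_omega, dt,
              mu, pref, inv_inertia,
              c1, drift_c, sw, cth1, cth2,
              xi1, xi2, step0, stride,
              m_out, rec0, record,
              e_sum, b_sum, w2_sum):
    """Advance the state by xi1.shape[0] steps; returns the record count.

    xi1, xi2 : (n_steps_chunk, N, 3) standard normal draws.
    m_out : (n_records_total, 3) magnetization samples (filled from rec0).
    record : when False (burn-in) nothing is sampled or accumulated.
    """
    nsteps = xi1.shape[0]
    n = e.shape[0]
    half = 0.5 * dt * inv_inertia
    rec = rec0
    b_now = np.empty(3)
    for s in range(nsteps):
        gstep = step0 + s
        # B: half kick with the torque carried from the previous step
        for i in range(n):
            w[i, 0] += half * tq[i, 0]
            w[i, 1] += half * tq[i, 1]
            w[i, 2] += half * tq[i, 2]
        # AO + R: exact free Langevin flight, then rigid rotation
        for i in range(n):
            dthx = drift_c * w[i, 0] + cth1 * xi1[s, i, 0] + cth2 * xi2[s, i, 0]
            dthy = drift_c * w[i, 1] + cth1 * xi1[s, i, 1] + cth2 * xi2[s, i, 1]
            dthz = drift_c * w[i, 2] + cth1 * xi1[s, i, 2] + cth2 * xi2[s, i, 2]
            w[i, 0] = c1 * w[i, 0] + sw * xi1[s, i, 0]
            w[i, 1] = c1 * w[i, 1] + sw * xi1[s, i, 1]
            w[i, 2] = c1 * w[i, 2] + sw * xi1[s, i, 2]
            th2 = dthx * dthx + dthy * dthy + dthz * dthz
            if th2 > 0.0:
                th = np.sqrt(th2)
                nx = dthx / th
                ny = dthy / th
                nz = dthz / th
                ct = np.cos(th)
                st = np.sin(th)
                ex = e[i, 0]
                ey = e[i, 1]
                ez = e[i, 2]
                dot = nx * ex + ny * ey + nz * ez
                cx = ny * ez - nz * ey
                cy = nz * ex - nx * ez
                cz = nx * ey - ny * ex
                ex2 = ct * ex + st * cx + (1.0 - ct) * dot * nx
                ey2 = ct * ey + st * cy + (1.0 - ct) * dot * ny
                ez2 = ct * ez + st * cz + (1.0 - ct) * dot * nz
                inv = 1.0 / np.sqrt(ex2 * ex2 + ey2 * ey2 + ez2 * ez2)
                e[i, 0] = ex2 * inv
                e[i, 1] = ey2 * inv
                e[i, 2] = ez2 * inv
        # torque at the new orientation (and new time, if driven)
        t_next = (gstep + 1) * dt
        if ac_omega != 0.0:
            sfac = np.sin(ac_omega * t_next)
            b_now[0] = b_static[0] + ac_amp[0] * sfac
            b_now[1] = b_static[1] + ac_amp[1] * sfac
            b_now[2] = b_static[2] + ac_amp[2] * sfac
        else:
            b_now[0] = b_static[0]
            b_now[1] = b_static[1]
            b_now[2] = b_static[2]
        compute_torques(e, indptr, indices, rhat, inv_r3, b_now, pref, mu,
                        tq, bint)
        # B: second half kick
        for i in range(n):
            w[i, 0] += half * tq[i, 0]
            w[i, 1] += half * tq[i, 1]
            w[i, 2] += half * tq[i, 2]
        if record:
            for k in range(3):
                acc = 0.0
                for i in range(n):
                    acc += w[i, k] * w[i, k]
                w2_sum[k] += acc
            if (gstep + 1) % stride == 0:
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(n):
                    mx += e[i, 0]
                    my += e[i, 1]
                    mz += e[i, 2]
                    e_sum[i, 0] += e[i, 0]
                    e_sum[i, 1] += e[i, 1]
                    e_sum[i, 2] += e[i, 2]
                    b_sum[i, 0] += bint[i, 0]
                    b_sum[i, 1] += bint[i, 1]
                    b_sum[i, 2] += bint[i, 2]
                m_out[rec, 0] = mu * mx
                m_out[rec, 1] = mu * my
                m_out[rec, 2] = mu * mz
                rec += 1
    return rec
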