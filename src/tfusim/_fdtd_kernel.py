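"""Numba inner loop of the staggered-grid FDTD solver.

Kept separate from the public solver module so the pure-numpy reference
path stays readable; both paths implement the identical update scheme.
"""

import math

import numba
import numpy as np


@numba.njit(cache=True, fastmath=False)
def fdtd_loop(
    p,
    px,
    py,
    ux,
    uy,
    inv_rho_x,
    inv_rho_y,
    kappa,
    decay,
    ax_u,
    bx_u,
    ay_u,
    by_u,
    ax_p,
    bx_p,
    ay_p,
    by_p,
    src_i,
    src_j,
    src_amp,
    src_fx,
    src_hard,
    omega,
    ramp_time,
    on_time,
    dt,
    nt,
    inv_dx,
    t0,
    t1,
    max_p,
    p2_acc,
    ix_acc,
    iy_acc,
    rec_i,
    rec_j,
    history,
    nan_check_interval,
):
    nx, ny = p.shape
    n_src = src_i.shape[0]
    n_rec = rec_i.shape[0]
    win_samples = 0
    for step in range(nt):
        t = (step + 1) * dt

        for i in range(nx - 1):
            au = ax_u[i]
            bu = bx_u[i] * inv_dx
            for j in range(ny):
                ux[i, j] = au * ux[i, j] - bu * inv_rho_x[i, j] * (p[i + 1, j] - p[i, j])
        for i in range(nx):
            for j in range(ny - 1):
                uy[i, j] = ay_u[j] * uy[i, j] - by_u[j] * inv_dx * inv_rho_y[i, j] * (
                    p[i, j + 1] - p[i, j]
                )

        for i in range(1, nx - 1):
            ap = ax_p[i]
            bp = bx_p[i] * inv_dx
            for j in range(ny):
                px[i, j] = (ap * px[i, j] - bp * kappa[i, j] * (ux[i, j] - ux[i - 1, j])) * decay[i, j]
        for i in range(nx):
            for j in range(1, ny - 1):
                py[i, j] = (
                    ay_p[j] * py[i, j] - by_p[j] * inv_dx * kappa[i, j] * (uy[i, j] - uy[i, j - 1])
                ) * decay[i, j]

        if t <= on_time:
            s = math.sin(omega * t)
            if t < ramp_time:
                s *= 0.5 * (1.0 - math.cos(math.pi * t / ramp_time))
            if src_hard:
                for k in range(n_src):
                    drive = src_amp[k] * s
                    px[src_i[k], src_j[k]] = 0.5 * drive
                    py[src_i[k], src_j[k]] = 0.5 * drive
            else:
                for k in range(n_src):
                    drive = src_amp[k] * s
                    px[src_i[k], src_j[k]] += src_fx[k] * drive
                    py[src_i[k], src_j[k]] += (1.0 - src_fx[k]) * drive

        in_window = t0 < t <= t1
        for i in range(nx):
            for j in range(ny):
                v = px[i, j] + py[i, j]
                p[i, j] = v
                av = abs(v)
                if av > max_p[i, j]:
                    max_p[i, j] = av
                if in_window:
                    p2_acc[i, j] += v * v
        if in_window:
            # vector acoustic intensity <p u>, velocities centred on pixels
            for i in range(1, nx - 1):
                for j in range(1, ny - 1):
                    v = p[i, j]
                    ix_acc[i, j] += v * 0.5 * (ux[i - 1, j] + ux[i, j])
                    iy_acc[i, j] += v * 0.5 * (uy[i, j - 1] + uy[i, j])
            win_samples += 1

        for k in range(n_rec):
            history[k, step] = p[rec_i[k], rec_j[k]]

        if step % nan_check_interval == 0 and not math.isfinite(p[nx // 2, ny // 2]):
            return win_samples, step

    return win_samples, -1
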