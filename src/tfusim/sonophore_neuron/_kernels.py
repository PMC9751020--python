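"""Numba kernels for the microscale integrators.

Scalar duplicates of the gating-rate formulas live here; they must match
``rates.py`` exactly (cross-checked by unit test).  The molecular
pressure enters through a dense precomputed (z_grid, pm_grid) linear
interpolant.
"""

import math

import numba
import numpy as np

# indices into the mechanical constants vector (see bls._mech_constants)
_A, _DELTA, _P0, _KS, _EPS, _RHOL, _MUL, _MUS, _D0, _DGL, _XI, _CG, _KH, _RGT, _CM0 = range(15)


@numba.njit(cache=True)
def _efun(x):
    if abs(x) < 1e-8:
        return 1.0 - 0.5 * x
    return x / math.expm1(x)


@numba.njit(cache=True)
def _alpha_m(v, vt):
    return 1.28e3 * _efun((13.0 - (v - vt)) / 4.0)


@numba.njit(cache=True)
def _beta_m(v, vt):
    return 1.4e3 * _efun(((v - vt) - 40.0) / 5.0)


@numba.njit(cache=True)
def _alpha_h(v, vt):
    return 0.128e3 * math.exp(-((v - vt) - 17.0) / 18.0)


@numba.njit(cache=True)
def _beta_h(v, vt):
    return 4.0e3 / (1.0 + math.exp(-((v - vt) - 40.0) / 5.0))


@numba.njit(cache=True)
def _alpha_n(v, vt):
    return 0.16e3 * _efun((15.0 - (v - vt)) / 5.0)


@numba.njit(cache=True)
def _beta_n(v, vt):
    return 0.5e3 * math.exp(-((v - vt) - 10.0) / 40.0)


@numba.njit(cache=True)
def _p_inf(v):
    return 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))


@numba.njit(cache=True)
def _tau_p(v, tau_max):
    return tau_max / (3.3 * math.exp((v + 35.0) / 20.0) + math.exp(-(v + 35.0) / 20.0))


@numba.njit(cache=True)
def _cm_of_z(Z, a, delta, cm0):
    tiny = a * 1e-12
    if abs(Z) < tiny:
        return cm0
    return (
        cm0
        * delta
        / (a * a)
        * (Z + (a * a - Z * Z - Z * delta) / (2.0 * Z) * math.log1p(2.0 * Z / delta))
    )


@numba.njit(cache=True)
def _mech_rhs(t, Z, dZ, ng, PA, Qm, omega, C, zg, pmg):
    a = C[_A]
    a2 = a * a
    S0 = math.pi * a2
    S = math.pi * (a2 + Z * Z)
    V = S0 * C[_DELTA] + math.pi * Z * (a2 + Z * Z / 3.0)
    inv_r = 2.0 * Z / (a2 + Z * Z)

    p_in = ng * C[_RGT] / V
    p_m = np.interp(Z, zg, pmg)
    p_s = C[_KS] * inv_r * (S - S0) / S0
    p_ec = -(S0 / S) * Qm * Qm / (2.0 * C[_EPS])
    p_tot = p_in + p_m - C[_P0] - p_s + p_ec + PA * math.sin(omega * t)

    # net pressure acts through |1/R| (dV/dZ > 0 for either bowing
    # direction); the quadratic kinematic term keeps the signed
    # curvature; dissipation must oppose the motion for either sign
    abs_inv_r = abs(inv_r)
    dd_z = (
        abs_inv_r * p_tot / C[_RHOL]
        - 1.5 * dZ * dZ * inv_r
        - 4.0 * dZ * inv_r * inv_r * (3.0 * C[_D0] * C[_MUS] * abs_inv_r + C[_MUL]) / C[_RHOL]
    )
    d_ng = 2.0 * S * C[_DGL] / C[_XI] * (C[_CG] - p_in / C[_KH])
    return dd_z, d_ng


@numba.njit(cache=True)
def _mech_rk4_step(t, Z, dZ, ng, dt, PA, Qm, omega, C, zg, pmg):
    k1a, k1n = _mech_rhs(t, Z, dZ, ng, PA, Qm, omega, C, zg, pmg)
    z2 = Z + 0.5 * dt * dZ
    v2 = dZ + 0.5 * dt * k1a
    k2a, k2n = _mech_rhs(t + 0.5 * dt, z2, v2, ng + 0.5 * dt * k1n, PA, Qm, omega, C, zg, pmg)
    z3 = Z + 0.5 * dt * v2
    v3 = dZ + 0.5 * dt * k2a
    k3a, k3n = _mech_rhs(t + 0.5 * dt, z3, v3, ng + 0.5 * dt * k2n, PA, Qm, omega, C, zg, pmg)
    z4 = Z + dt * v3
    v4 = dZ + dt * k3a
    k4a, k4n = _mech_rhs(t + dt, z4, v4, ng + dt * k3n, PA, Qm, omega, C, zg, pmg)

    z_new = Z + dt / 6.0 * (dZ + 2.0 * v2 + 2.0 * v3 + v4)
    v_new = dZ + dt / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
    ng_new = ng + dt / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
    return z_new, v_new, ng_new


@numba.njit(cache=True)
def _stable_h(Z, C, zg, dpmg, dt):
    """Step bound from the local stiffness of the mechanical system.

    Three fast scales limit an explicit integrator: the viscous damping
    rate (grows as 1/R^2 at large deflection), the gas-exchange rate,
    and the oscillation frequency on the molecular-repulsion wall
    (from the local |dPM/dZ|).
    """
    a = C[_A]
    a2 = a * a
    inv_r = 2.0 * Z / (a2 + Z * Z)
    air = abs(inv_r)
    lam_visc = 4.0 * inv_r * inv_r * (3.0 * C[_D0] * C[_MUS] * air + C[_MUL]) / C[_RHOL]
    S = math.pi * (a2 + Z * Z)
    V = math.pi * a2 * C[_DELTA] + math.pi * Z * (a2 + Z * Z / 3.0)
    lam_ng = 2.0 * S * C[_DGL] / C[_XI] * C[_RGT] / (V * C[_KH])
    om_wall = math.sqrt(air * np.interp(Z, zg, dpmg) / C[_RHOL])
    h = 1.2 / (lam_visc + lam_ng + om_wall + 1e-30)
    return h if h < dt else dt


@numba.njit(cache=True)
def _mech_step_adaptive(t, Z, dZ, ng, dt, PA, Qm, omega, C, zg, pmg, dpmg):
    """One macro step, substepped to respect the local stability bound."""
    delta = C[_DELTA]
    remaining = dt
    while remaining > 1e-30:
        h = _stable_h(Z, C, zg, dpmg, dt)
        # fast approaches can stiffen within the step: check the
        # projected end position too
        h2 = _stable_h(Z + dZ * h, C, zg, dpmg, dt)
        if h2 < h:
            h = h2
        if h > remaining:
            h = remaining
        Z, dZ, ng = _mech_rk4_step(t, Z, dZ, ng, h, PA, Qm, omega, C, zg, pmg)
        t += h
        remaining -= h
        if Z <= -0.5 * delta or not math.isfinite(Z):
            return Z, dZ, ng, False
    return Z, dZ, ng, True


@numba.njit(cache=True)
def mech_cycles(PA, Qm, omega, C, zg, pmg, dpmg, z0, ng0, steps_per_cycle, max_cycles, tol):
    """Drive the cavity until the Z cycle repeats within tol.

    Returns (z_cycle, ng_end, n_cycles, status) with status 0 = ok,
    1 = leaflet contact, 2 = no convergence.
    """
    period = 2.0 * math.pi / omega
    dt = period / steps_per_cycle
    z_fail = -0.5 * C[_DELTA]

    Z = z0
    dZ = 0.0
    ng = ng0
    prev = np.empty(steps_per_cycle)
    cur = np.empty(steps_per_cycle)
    for i in range(steps_per_cycle):
        prev[i] = z0

    t = 0.0
    for cyc in range(max_cycles):
        for i in range(steps_per_cycle):
            Z, dZ, ng, ok = _mech_step_adaptive(t, Z, dZ, ng, dt, PA, Qm, omega, C, zg, pmg, dpmg)
            t += dt
            if not ok:
                return cur, ng, cyc + 1, 1
            cur[i] = Z
        scale = 1e-12
        diff = 0.0
        for i in range(steps_per_cycle):
            az = abs(cur[i])
            if az > scale:
                scale = az
            d = abs(cur[i] - prev[i])
            if d > diff:
                diff = d
        if cyc > 0 and diff <= tol * scale:
            return cur, ng, cyc + 1, 0
        for i in range(steps_per_cycle):
            prev[i] = cur[i]
    return cur, ng, max_cycles, 2


@numba.njit(cache=True)
def _membrane_current(v, m, h, n, p, NP):
    g_na, e_na, g_kd, e_k, g_m, g_leak, e_leak = NP[0], NP[1], NP[2], NP[3], NP[4], NP[5], NP[6]
    i_na = g_na * m * m * m * h * (v - e_na)
    i_kd = g_kd * n * n * n * n * (v - e_k)
    i_m = g_m * p * (v - e_k)
    i_leak = g_leak * (v - e_leak)
    return i_na + i_kd + i_m + i_leak


@numba.njit(cache=True)
def _gate_rates_analytic(v_mv, NP):
    vt = NP[7]
    tau_max = NP[8]
    am = _alpha_m(v_mv, vt)
    bm = _beta_m(v_mv, vt)
    ah = _alpha_h(v_mv, vt)
    bh = _beta_h(v_mv, vt)
    an = _alpha_n(v_mv, vt)
    bn = _beta_n(v_mv, vt)
    pinf = _p_inf(v_mv)
    taup = _tau_p(v_mv, tau_max)
    ap = pinf / taup
    bp = (1.0 - pinf) / taup
    return am, bm, ah, bh, an, bn, ap, bp


@numba.njit(cache=True)
def _is_on(t, onset, duration, prf, dc):
    if t < onset or t >= onset + duration:
        return False
    if dc >= 1.0:
        return True
    period = 1.0 / prf
    phase = (t - onset) % period
    return phase < dc / prf


@numba.njit(cache=True)
def _rush_larsen(x, a, b, dt):
    """Exponential gate update; unconditionally stable for any rate."""
    s = a + b
    if s <= 0.0:
        return x
    x_inf = a / s
    return x_inf + (x - x_inf) * math.exp(-dt * s)


@numba.njit(cache=True)
def full_nbls(
    PA, omega, C, zg, pmg, dpmg, NP,
    z0, ng0, qm0, m0, h0, n0, p0,
    onset, duration, prf, dc,
    total_time, steps_per_cycle, stride,
):
    """Co-integration of mechanics and charge-cast electrics.

    The mechanical triple (Z, dZ, ng) advances with fixed-step RK4 at
    sub-acoustic-cycle resolution while the membrane charge (Heun) and
    the gates (Rush-Larsen exponential updates, stable against the rate
    blow-up at strongly hyperpolarised instantaneous potentials) ride on
    the same step.  Records every ``stride`` steps: (t, Qm, Vm, Z).
    Status 1 flags leaflet contact.
    """
    period = 2.0 * math.pi / omega
    dt = period / steps_per_cycle
    nt = int(total_time / dt)
    n_rec = nt // stride + 1
    t_rec = np.empty(n_rec)
    qm_rec = np.empty(n_rec)
    vm_rec = np.empty(n_rec)
    z_rec = np.empty(n_rec)
    z_fail = -0.5 * C[_DELTA]
    a = C[_A]
    delta = C[_DELTA]
    cm0 = C[_CM0]

    Z, dZ, ng, qm, m, h, n, p = z0, 0.0, ng0, qm0, m0, h0, n0, p0
    k = 0
    t = 0.0
    for step in range(nt):
        if step % stride == 0 and k < n_rec:
            cm = _cm_of_z(Z, a, delta, cm0)
            t_rec[k] = t
            qm_rec[k] = qm
            vm_rec[k] = qm / cm
            z_rec[k] = Z
            k += 1

        pa_t = PA if _is_on(t, onset, duration, prf, dc) else 0.0

        # mechanics: adaptive RK4 on (Z, dZ, ng) with Qm frozen over the step
        Z_new, dZ_new, ng_new, ok = _mech_step_adaptive(
            t, Z, dZ, ng, dt, pa_t, qm, omega, C, zg, pmg, dpmg
        )
        if not ok:
            return t_rec[:k], qm_rec[:k], vm_rec[:k], z_rec[:k], 1

        # electrics at the instantaneous potential
        v_old = qm / _cm_of_z(Z, a, delta, cm0)
        am, bm, ah, bh, an, bn, ap, bp = _gate_rates_analytic(v_old * 1e3, NP)
        dq1 = -_membrane_current(v_old, m, h, n, p, NP)
        m = _rush_larsen(m, am, bm, dt)
        h = _rush_larsen(h, ah, bh, dt)
        n = _rush_larsen(n, an, bn, dt)
        p = _rush_larsen(p, ap, bp, dt)
        v_new = (qm + dt * dq1) / _cm_of_z(Z_new, a, delta, cm0)
        dq2 = -_membrane_current(v_new, m, h, n, p, NP)
        qm += 0.5 * dt * (dq1 + dq2)

        Z, dZ, ng = Z_new, dZ_new, ng_new
        t += dt
        if not math.isfinite(qm):
            return t_rec[:k], qm_rec[:k], vm_rec[:k], z_rec[:k], 1

    return t_rec[:k], qm_rec[:k], vm_rec[:k], z_rec[:k], 0


@numba.njit(cache=True)
def _sonic_vars(qm, on, qg, inv_cm_on, rates_on, NP, cm0):
    """Effective potential and rates: tabulated ON, analytic OFF."""
    if on:
        v = qm * np.interp(qm, qg, inv_cm_on)
        am = np.interp(qm, qg, rates_on[0])
        bm = np.interp(qm, qg, rates_on[1])
        ah = np.interp(qm, qg, rates_on[2])
        bh = np.interp(qm, qg, rates_on[3])
        an = np.interp(qm, qg, rates_on[4])
        bn = np.interp(qm, qg, rates_on[5])
        ap = np.interp(qm, qg, rates_on[6])
        bp = np.interp(qm, qg, rates_on[7])
    else:
        v = qm / cm0
        am, bm, ah, bh, an, bn, ap, bp = _gate_rates_analytic(v * 1e3, NP)
    return v, am, bm, ah, bh, an, bn, ap, bp


@numba.njit(cache=True)
def sonic_run(
    qg, inv_cm_on, rates_on, NP, cm0,
    qm0, m0, h0, n0, p0,
    onset, duration, prf, dc,
    total_time, dt, stride,
):
    """Effective-variable integration with PRF/duty-cycle gating.

    Gates advance by Rush-Larsen exponential updates (the tabulated
    effective rates can be enormous at hyperpolarised charge values);
    the charge advances by Heun's method.  Records every ``stride``
    steps: (t, Qm, Vm, m, h, n, p).  Vm is the effective potential
    Qm*<1/Cm> during ON and Qm/Cm0 during OFF.
    """
    nt = int(total_time / dt)
    n_rec = nt // stride + 1
    t_rec = np.empty(n_rec)
    qm_rec = np.empty(n_rec)
    vm_rec = np.empty(n_rec)
    gates_rec = np.empty((n_rec, 4))

    qm, m, h, n, p = qm0, m0, h0, n0, p0
    k = 0
    t = 0.0
    for step in range(nt):
        on = _is_on(t, onset, duration, prf, dc)
        if step % stride == 0 and k < n_rec:
            if on:
                v_now = qm * np.interp(qm, qg, inv_cm_on)
            else:
                v_now = qm / cm0
            t_rec[k] = t
            qm_rec[k] = qm
            vm_rec[k] = v_now
            gates_rec[k, 0] = m
            gates_rec[k, 1] = h
            gates_rec[k, 2] = n
            gates_rec[k, 3] = p
            k += 1

        v, am, bm, ah, bh, an, bn, ap, bp = _sonic_vars(
            qm, on, qg, inv_cm_on, rates_on, NP, cm0
        )
        dq1 = -_membrane_current(v, m, h, n, p, NP)
        m = _rush_larsen(m, am, bm, dt)
        h = _rush_larsen(h, ah, bh, dt)
        n = _rush_larsen(n, an, bn, dt)
        p = _rush_larsen(p, ap, bp, dt)
        on2 = _is_on(t + dt, onset, duration, prf, dc)
        v2, am, bm, ah, bh, an, bn, ap, bp = _sonic_vars(
            qm + dt * dq1, on2, qg, inv_cm_on, rates_on, NP, cm0
        )
        dq2 = -_membrane_current(v2, m, h, n, p, NP)
        qm += 0.5 * dt * (dq1 + dq2)
        t += dt
        if not math.isfinite(qm):
            return t_rec[:k], qm_rec[:k], vm_rec[:k], gates_rec[:k], 1

    return t_rec[:k], qm_rec[:k], vm_rec[:k], gates_rec[:k], 0
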