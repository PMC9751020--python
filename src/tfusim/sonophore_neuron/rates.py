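"""Voltage-dependent gating rates of the regular-spiking membrane.

All functions take the membrane potential in mV and return rates in
s^-1.  ``efun(x) = x / (exp(x) - 1)`` is evaluated with a series branch
near zero to avoid the removable singularity.
"""

from __future__ import annotations

import numpy as np

VT_DEFAULT_MV = -56.2
TAU_MAX_DEFAULT = 0.608  # s


def efun(x):
    x = np.asarray(x, dtype=np.float64)
    small = np.abs(x) < 1e-8
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 - x / 2.0, safe / np.expm1(safe))
    return out


def alpha_m(v_mv, v_t_mv=VT_DEFAULT_MV):
    u = (13.0 - (v_mv - v_t_mv)) / 4.0
    return 1.28 * efun(u) * 1e3


def beta_m(v_mv, v_t_mv=VT_DEFAULT_MV):
    u = ((v_mv - v_t_mv) - 40.0) / 5.0
    return 1.4 * efun(u) * 1e3


def alpha_h(v_mv, v_t_mv=VT_DEFAULT_MV):
    return 0.128 * np.exp(-((v_mv - v_t_mv) - 17.0) / 18.0) * 1e3


def beta_h(v_mv, v_t_mv=VT_DEFAULT_MV):
    return 4.0 / (1.0 + np.exp(-((v_mv - v_t_mv) - 40.0) / 5.0)) * 1e3


def alpha_n(v_mv, v_t_mv=VT_DEFAULT_MV):
    u = (15.0 - (v_mv - v_t_mv)) / 5.0
    return 0.16 * efun(u) * 1e3


def beta_n(v_mv, v_t_mv=VT_DEFAULT_MV):
    return 0.5 * np.exp(-((v_mv - v_t_mv) - 10.0) / 40.0) * 1e3


def p_inf(v_mv):
    return 1.0 / (1.0 + np.exp(-(v_mv + 35.0) / 10.0))


def tau_p(v_mv, tau_max=TAU_MAX_DEFAULT):
    return tau_max / (
        3.3 * np.exp((v_mv + 35.0) / 20.0) + np.exp(-(v_mv + 35.0) / 20.0)
    )


def alpha_p(v_mv, tau_max=TAU_MAX_DEFAULT):
    return p_inf(v_mv) / tau_p(v_mv, tau_max)


def beta_p(v_mv, tau_max=TAU_MAX_DEFAULT):
    return (1.0 - p_inf(v_mv)) / tau_p(v_mv, tau_max)


GATES = ("m", "h", "n", "p")

RATE_FUNCTIONS = {
    "m": (alpha_m, beta_m),
    "h": (alpha_h, beta_h),
    "n": (alpha_n, beta_n),
    "p": (alpha_p, beta_p),
}


def steady_state(gate: str, v_mv):
    """x_inf = alpha / (alpha + beta) for one gate."""
    a, b = RATE_FUNCTIONS[gate]
    av, bv = a(v_mv), b(v_mv)
    return av / (av + bv)
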