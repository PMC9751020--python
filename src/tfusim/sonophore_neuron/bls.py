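"""Bilayer-sonophore mechanics.

Spherical-cap geometry of the deflected leaflets, the deflection-
dependent membrane capacitance, the intermolecular (molecular) pressure
evaluated by Gauss–Legendre quadrature over the leaflet, and the
periodic steady state of the driven cavity.

The apex deflection Z is positive for outward bowing; the leaflets touch
at Z = -Delta/2, which is a hard mechanical-failure boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from tfusim.errors import ConvergenceError, MechanicalFailureError
from tfusim.sonophore_neuron.params import BLSParams

_Z_TINY_FACTOR = 1e-12  # |Z| below a*this uses small-deflection limits


# ---------------------------------------------------------------------------
# geometry


def leaflet_area(Z, params: BLSParams):
    """S(Z) = pi (a^2 + Z^2)."""
    return math.pi * (params.a ** 2 + np.asarray(Z) ** 2)


def cavity_volume(Z, params: BLSParams):
    """V(Z) = pi a^2 Delta + pi Z (a^2 + Z^2/3)."""
    Z = np.asarray(Z)
    return math.pi * params.a ** 2 * params.Delta + math.pi * Z * (
        params.a ** 2 + Z ** 2 / 3.0
    )


def curvature_inverse(Z, params: BLSParams):
    """1/R(Z) = 2Z / (a^2 + Z^2); smooth through Z = 0."""
    Z = np.asarray(Z)
    return 2.0 * Z / (params.a ** 2 + Z ** 2)


def cap_profile(Z: float, r, params: BLSParams):
    """Local deflection z(r) of the spherical cap, z(0)=Z, z(a)=0."""
    a = params.a
    r = np.asarray(r)
    if abs(Z) < a * _Z_TINY_FACTOR:
        return Z * (1.0 - (r / a) ** 2)
    R = (a * a + Z * Z) / (2.0 * Z)
    return (Z - R) + math.copysign(1.0, Z) * np.sqrt(R * R - r * r)


# ---------------------------------------------------------------------------
# capacitance


def capacitance(Z, params: BLSParams):
    """Deflection-dependent membrane capacitance; equals Cm0 at Z = 0."""
    Z = np.asarray(Z, dtype=np.float64)
    a, Delta, Cm0 = params.a, params.Delta, params.Cm0
    if np.any(Z <= -Delta / 2.0):
        raise MechanicalFailureError("capacitance undefined for Z <= -Delta/2")
    tiny = a * _Z_TINY_FACTOR
    safe = np.where(np.abs(Z) < tiny, tiny, Z)
    full = (
        Cm0
        * Delta
        / (a * a)
        * (safe + (a * a - safe * safe - safe * Delta) / (2.0 * safe) * np.log1p(2.0 * safe / Delta))
    )
    return np.where(np.abs(Z) < tiny, Cm0, full)


# ---------------------------------------------------------------------------
# pressures


def molecular_pressure(Z: float, params: BLSParams, n_nodes: int = 64) -> float:
    """Intermolecular pressure by radial quadrature over the leaflet.

    PM(Z) = (2 pi / S(Z)) * int_0^a Ar [ (D*/zeta)^x - (D*/zeta)^y ] r dr
    with the local gap zeta(r) = Delta + 2 z(r).
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    r = 0.5 * params.a * (nodes + 1.0)
    w = 0.5 * params.a * weights
    zeta = params.Delta + 2.0 * cap_profile(Z, r, params)
    u = params.delta_star / zeta
    integrand = params.Ar * (u ** params.x_rep - u ** params.y_att) * r
    return float(2.0 * math.pi * np.sum(w * integrand) / leaflet_area(Z, params))


def tension_pressure(Z, params: BLSParams):
    """Leaflet-tension (restoring) pressure ks/R * (S - S0)/S0."""
    S = leaflet_area(Z, params)
    return params.ks * curvature_inverse(Z, params) * (S - params.S0) / params.S0


def electric_pressure(Z, Qm, params: BLSParams):
    """Attractive electrostatic pressure -(S0/S) Qm^2 / (2 eps0 eps_r)."""
    S = leaflet_area(Z, params)
    return -(params.S0 / S) * np.asarray(Qm) ** 2 / (2.0 * params.eps0 * params.eps_r)


def internal_pressure(Z, ng, params: BLSParams):
    """Ideal-gas internal pressure ng Rg T / V(Z)."""
    return np.asarray(ng) * params.Rg * params.T / cavity_volume(Z, params)


# ---------------------------------------------------------------------------
# tabulated PM for the fast integrators


@dataclass
class PMInterpolant:
    """Dense linear interpolant of PM(Z) shared by the compiled kernels.

    ``dpm_grid`` holds |dPM/dZ|, used by the integrators to bound their
    step on the stiff repulsion wall.
    """

    z_grid: np.ndarray
    pm_grid: np.ndarray
    dpm_grid: np.ndarray

    def __call__(self, Z):
        return np.interp(Z, self.z_grid, self.pm_grid)


def build_pm_interpolant(
    params: BLSParams, n_points: int = 6000, z_max: Optional[float] = None,
    n_nodes: int = 64,
) -> PMInterpolant:
    z_min = -0.499 * params.Delta
    z_max = 5.0 * params.a if z_max is None else z_max
    zg = np.linspace(z_min, z_max, n_points)
    pm = np.array([molecular_pressure(z, params, n_nodes) for z in zg])
    dpm = np.abs(np.gradient(pm, zg))
    return PMInterpolant(z_grid=zg, pm_grid=pm, dpm_grid=dpm)


# ---------------------------------------------------------------------------
# equilibria


def equilibrium_deflection(Qm: float, params: BLSParams, pm: Optional[PMInterpolant] = None) -> float:
    """Static deflection where molecular, tension and electric pressures
    balance, with the gas content at Henry equilibrium (Pin = P0)."""
    pm_of = pm if pm is not None else lambda z: molecular_pressure(z, params)

    def residual(z):
        return float(pm_of(z)) + float(electric_pressure(z, Qm, params)) - float(
            tension_pressure(z, params)
        )

    lo, hi = -0.45 * params.Delta, params.a
    if residual(lo) * residual(hi) > 0:
        raise ConvergenceError("equilibrium deflection is not bracketed")
    return brentq(residual, lo, hi, xtol=1e-16)


def equilibrium_gas(Z: float, params: BLSParams) -> float:
    """Gas content with the internal pressure at the ambient value."""
    return params.P0 * float(cavity_volume(Z, params)) / (params.Rg * params.T)


# ---------------------------------------------------------------------------
# periodic steady state of the driven cavity


def mechanical_steady_cycle(
    PA: float,
    Qm: float,
    params: BLSParams,
    f: float,
    steps_per_cycle: int = 2000,
    max_cycles: int = 200,
    tol: float = 1e-3,
    pm: Optional[PMInterpolant] = None,
):
    """Integrate the cavity to its periodic steady state at drive PA.

    Returns ``(t, Z, Cm, info)`` for the last stabilised acoustic cycle,
    where ``t`` spans one period.  Raises ``ConvergenceError`` when the
    cycle-to-cycle deflection change does not fall below ``tol`` within
    ``max_cycles`` and ``MechanicalFailureError`` on leaflet contact.
    """
    from tfusim.sonophore_neuron._kernels import mech_cycles

    if PA < 0:
        raise ConvergenceError("PA must be non-negative")
    pm = pm if pm is not None else build_pm_interpolant(params)
    z0 = equilibrium_deflection(Qm, params, pm)
    ng0 = equilibrium_gas(z0, params)

    z_cycle, ng_end, n_cycles, status = mech_cycles(
        PA, Qm, 2.0 * math.pi * f, _mech_constants(params),
        pm.z_grid, pm.pm_grid, pm.dpm_grid,
        z0, ng0, steps_per_cycle, max_cycles, tol,
    )
    if status == 1:
        raise MechanicalFailureError(
            f"leaflet contact (Z <= -Delta/2) at PA={PA:g} Pa, Qm={Qm:g} C/m^2"
        )
    if status == 2:
        raise ConvergenceError(
            f"no periodic steady state within {max_cycles} cycles at "
            f"PA={PA:g} Pa, Qm={Qm:g} C/m^2"
        )
    period = 1.0 / f
    t = np.arange(steps_per_cycle) * (period / steps_per_cycle)
    cm = capacitance(z_cycle, params)
    info = {"n_cycles": int(n_cycles), "ng_end": float(ng_end), "z0": z0}
    return t, z_cycle, cm, info


def _mech_constants(params: BLSParams) -> np.ndarray:
    """Pack the constants consumed by the compiled mechanical RHS."""
    return np.array(
        [
            params.a,
            params.Delta,
            params.P0,
            params.ks,
            params.eps0 * params.eps_r,
            params.rho_l,
            params.mu_l,
            params.mu_s,
            params.delta0,
            params.Dgl,
            params.xi,
            params.Cg,
            params.kH,
            params.Rg * params.T,
            params.Cm0,
        ]
    )
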