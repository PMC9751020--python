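"""Parameter sets of the microscale model.

``BLSParams`` carries the sonophore constants plus two derived
quantities fixed at construction time: the resting inter-leaflet gap
``Delta`` and the dissolved-gas concentration ``Cg = P0/kH`` (Henry
equilibrium with the ambient pressure).

``Delta`` is the root of the resting molecular-pressure balance.  With
``delta_balance="electrostatic"`` (default, the reference formulation:
the gap is written as a function of the resting charge) the molecular
repulsion balances the electrostatic attraction of the resting membrane
charge, ``Ar[(D*/D)^x - (D*/D)^y] = qm0^2/(2 eps0 eps_r)``, which makes
Z = 0 the exact rest state of the driven cavity once the internal gas
pressure equilibrates with the ambient pressure.  The alternative
``delta_balance="ambient"`` balances the ambient pressure instead,
``Ar[(D*/D)^x - (D*/D)^y] = P0``.

``RSNeuronParams`` is the standard regular-spiking cortical point-neuron
membrane (Na, delayed-rectifier K, slow non-inactivating K, leak) from
the published reference parameterisation; these values are
reference-derived defaults, editable through configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from tfusim.errors import ConfigError


@dataclass(frozen=True)
class BLSParams:
    """Bilayer-sonophore constants (SI units)."""

    a: float = 32.0e-9  # sonophore radius, m
    T: float = 309.15  # K
    Rg: float = 8.314  # Pa m^3 / (mol K)
    Ar: float = 1.0e5  # intermolecular pressure coefficient, Pa
    x_rep: float = 5.0  # repulsion exponent
    y_att: float = 3.3  # attraction exponent
    delta_star: float = 1.4e-9  # zero-force inter-leaflet spacing, m
    P0: float = 1.0e5  # ambient pressure, Pa
    ks: float = 0.24  # area compression modulus, N/m
    eps0: float = 8.854e-12  # F/m
    eps_r: float = 1.0
    rho_l: float = 1075.0  # kg/m^3
    mu_l: float = 7.0e-4  # Pa s
    mu_s: float = 0.035  # Pa s
    delta0: float = 2.0e-9  # leaflet thickness, m
    Dgl: float = 3.6e-9  # m^2/s
    xi: float = 0.5e-9  # gas boundary layer, m
    Cm0: float = 1.0e-2  # F/m^2 (1 uF/cm^2)
    kH: float = 1.013e5  # Henry constant, Pa m^3/mol
    qm0: float = -71.9e-5  # resting charge entering the gap balance, C/m^2
    delta_balance: str = "electrostatic"
    Delta: float = field(init=False)  # resting gap, m (derived)
    Cg: float = field(init=False)  # dissolved gas concentration, mol/m^3

    def __post_init__(self):
        for name in (
            "a", "T", "Rg", "Ar", "delta_star", "P0", "ks", "eps0", "eps_r",
            "rho_l", "mu_l", "mu_s", "delta0", "Dgl", "xi", "Cm0", "kH",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"BLS parameter {name} must be strictly positive")
        if self.delta_balance not in ("electrostatic", "ambient"):
            raise ConfigError("delta_balance must be 'electrostatic' or 'ambient'")
        object.__setattr__(self, "Delta", self._solve_resting_gap())
        object.__setattr__(self, "Cg", self.P0 / self.kH)

    def resting_gap_pressure(self) -> float:
        """Compression the molecular repulsion balances at rest."""
        if self.delta_balance == "electrostatic":
            return self.qm0 ** 2 / (2.0 * self.eps0 * self.eps_r)
        return self.P0

    def _solve_resting_gap(self) -> float:
        target = self.resting_gap_pressure()

        def residual(delta):
            u = self.delta_star / delta
            return self.Ar * (u ** self.x_rep - u ** self.y_att) - target

        # repulsion dominates for Delta < Delta*, so bracket below it
        delta = brentq(residual, 0.05 * self.delta_star, self.delta_star, xtol=1e-18)
        if abs(residual(delta)) > 1e-6 * self.P0:
            raise ConfigError("resting-gap root did not satisfy its residual bound")
        return delta

    @property
    def S0(self) -> float:
        """Resting leaflet area, m^2."""
        return math.pi * self.a * self.a

    @property
    def ng0(self) -> float:
        """Gas content at ambient internal pressure and zero deflection."""
        V0 = math.pi * self.a * self.a * self.Delta
        return self.P0 * V0 / (self.Rg * self.T)


@dataclass(frozen=True)
class RSNeuronParams:
    """Regular-spiking cortical neuron membrane (SI units)."""

    g_na: float = 560.0  # S/m^2
    e_na: float = 50.0e-3  # V
    g_kd: float = 60.0  # S/m^2
    e_k: float = -90.0e-3  # V
    g_m: float = 0.75  # S/m^2 (slow non-inactivating K)
    g_leak: float = 0.205  # S/m^2
    e_leak: float = -70.3e-3  # V
    v_t: float = -56.2e-3  # V, spike-threshold shift of the rate laws
    tau_max: float = 0.608  # s, slow K adaptation time scale

    def as_tuple(self):
        return (
            self.g_na, self.e_na, self.g_kd, self.e_k,
            self.g_m, self.g_leak, self.e_leak,
        )
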