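"""Time-domain simulation of the sonicated point neuron.

``simulate_sonic`` integrates the charge-cast membrane equations with
table-interpolated effective variables during ultrasound-ON intervals
(PRF / duty-cycle gating) and the standard resting-capacitance membrane
during OFF intervals.  ``simulate_full_nbls`` co-integrates the cavity
mechanics and the electrics at sub-acoustic-cycle resolution and serves
as the validation oracle for the effective-variable route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from tfusim.errors import ConfigError, NumericalError, RangeError
from tfusim.sonophore_neuron import rates as rate_mod
from tfusim.sonophore_neuron.bls import (
    PMInterpolant,
    _mech_constants,
    build_pm_interpolant,
    equilibrium_deflection,
    equilibrium_gas,
)
from tfusim.sonophore_neuron.lookup import LookupTable
from tfusim.sonophore_neuron.params import BLSParams, RSNeuronParams


@dataclass(frozen=True)
class StimulusProtocol:
    """Pulsed sonication protocol delivered to the point neuron."""

    PA: float  # Pa
    f: float = 250e3  # Hz
    prf: float = 500.0  # Hz
    duty_cycle: float = 1.0
    duration: float = 100e-3  # s
    onset: float = 0.0  # s

    def __post_init__(self):
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ConfigError("duty_cycle must be in [0, 1]")
        if self.PA < 0:
            raise ConfigError("PA must be non-negative")
        if self.duty_cycle < 1.0 and self.f < 10.0 * self.prf:
            raise ConfigError("carrier frequency must be >> PRF")
        if self.duration <= 0 or self.onset < 0:
            raise ConfigError("invalid protocol timing")

    @property
    def total_time(self) -> float:
        return self.onset + self.duration

    @property
    def stim_window(self):
        return (self.onset, self.onset + self.duration)


@dataclass
class TraceResult:
    """Uniformly sampled response of one simulation."""

    t: np.ndarray  # s
    qm: np.ndarray  # C/m^2
    vm: np.ndarray  # V (effective/instantaneous membrane potential)
    gates: Optional[np.ndarray] = None  # (n, 4): m, h, n, p
    z: Optional[np.ndarray] = None  # m (full-model runs only)
    cm0: float = 1e-2

    @property
    def vm_charge(self) -> np.ndarray:
        """Charge-equivalent potential Qm/Cm0 (comparison basis that is
        common to the effective-variable and full co-integration runs)."""
        return self.qm / self.cm0

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"t_s": self.t, "qm_c_per_m2": self.qm, "vm_v": self.vm}
        if self.gates is not None:
            for k, name in enumerate(("m", "h", "n", "p")):
                cols[name] = self.gates[:, k]
        pd.DataFrame(cols).to_csv(path, index=False)


def _neuron_vector(neuron: RSNeuronParams) -> np.ndarray:
    return np.array(
        [
            neuron.g_na, neuron.e_na, neuron.g_kd, neuron.e_k,
            neuron.g_m, neuron.g_leak, neuron.e_leak,
            neuron.v_t * 1e3, neuron.tau_max,
        ]
    )


def rest_state(neuron: Optional[RSNeuronParams] = None, cm0: float = 1e-2):
    """Resting charge and steady-state gates of the unsonicated membrane."""
    neuron = neuron or RSNeuronParams()

    def current(v_mv):
        v = v_mv * 1e-3
        m = rate_mod.steady_state("m", v_mv)
        h = rate_mod.steady_state("h", v_mv)
        n = rate_mod.steady_state("n", v_mv)
        p = rate_mod.steady_state("p", v_mv)
        return (
            neuron.g_na * m**3 * h * (v - neuron.e_na)
            + neuron.g_kd * n**4 * (v - neuron.e_k)
            + neuron.g_m * p * (v - neuron.e_k)
            + neuron.g_leak * (v - neuron.e_leak)
        )

    v_rest_mv = brentq(current, -90.0, -50.0, xtol=1e-12)
    qm0 = v_rest_mv * 1e-3 * cm0
    gates = np.array([float(rate_mod.steady_state(g, v_rest_mv)) for g in "mhnp"])
    return qm0, gates


def simulate_sonic(
    protocol: StimulusProtocol,
    table: LookupTable,
    neuron: Optional[RSNeuronParams] = None,
    dt: float = 1e-6,
    stride: int = 5,
) -> TraceResult:
    """Effective-variable integration of the sonicated neuron."""
    from tfusim.sonophore_neuron._kernels import sonic_run

    neuron = neuron or RSNeuronParams()
    if abs(protocol.f - table.f) > 1e-6 * table.f:
        raise RangeError("protocol frequency does not match the lookup table")
    inv_cm_on, rates_on = table.slice_at(protocol.PA)  # RangeError if outside

    qm0, gates0 = rest_state(neuron, table.cm0)
    t, qm, vm, gates, status = sonic_run(
        table.qm, inv_cm_on, rates_on, _neuron_vector(neuron), table.cm0,
        qm0, gates0[0], gates0[1], gates0[2], gates0[3],
        protocol.onset, protocol.duration, protocol.prf, protocol.duty_cycle,
        protocol.total_time, dt, stride,
    )
    if status != 0:
        raise NumericalError("effective-variable integration diverged")
    return TraceResult(t=t, qm=qm, vm=vm, gates=gates, cm0=table.cm0)


def simulate_full_nbls(
    protocol: StimulusProtocol,
    params: Optional[BLSParams] = None,
    neuron: Optional[RSNeuronParams] = None,
    max_duration: float = 50e-3,
    steps_per_cycle: int = 2500,
    stride: Optional[int] = None,
    pm: Optional[PMInterpolant] = None,
) -> TraceResult:
    """Brute-force co-integration oracle (expensive by design)."""
    from tfusim.sonophore_neuron._kernels import full_nbls

    params = params or BLSParams()
    neuron = neuron or RSNeuronParams()
    if protocol.duration > max_duration:
        raise ConfigError(
            f"oracle duration {protocol.duration:g}s exceeds the "
            f"{max_duration:g}s cap"
        )
    pm = pm if pm is not None else build_pm_interpolant(params)
    qm0, gates0 = rest_state(neuron, params.Cm0)
    z0 = equilibrium_deflection(qm0, params, pm)
    ng0 = equilibrium_gas(z0, params)
    if stride is None:
        stride = max(steps_per_cycle // 40, 1)

    t, qm, vm, z, status = full_nbls(
        protocol.PA, 2.0 * math.pi * protocol.f, _mech_constants(params),
        pm.z_grid, pm.pm_grid, pm.dpm_grid, _neuron_vector(neuron),
        z0, ng0, qm0, gates0[0], gates0[1], gates0[2], gates0[3],
        protocol.onset, protocol.duration, protocol.prf, protocol.duty_cycle,
        protocol.total_time, steps_per_cycle, stride,
    )
    if status != 0:
        raise NumericalError("full co-integration failed (leaflet contact or divergence)")
    return TraceResult(t=t, qm=qm, vm=vm, z=z, cm0=params.Cm0)
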