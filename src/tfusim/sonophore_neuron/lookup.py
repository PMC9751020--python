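"""Cycle-averaged effective variables tabulated over (PA, Qm).

For every node the cavity is driven to its periodic steady state and the
inverse capacitance and the gating rates (evaluated at the instantaneous
potential V(t) = Qm/Cm(t)) are averaged over the final acoustic cycle.
The PA = 0 rows bypass the mechanics and reproduce the unsonicated
membrane (1/Cm0 and the analytic rates) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from tfusim.errors import ConvergenceError, MechanicalFailureError, RangeError
from tfusim.sonophore_neuron import rates as rate_mod
from tfusim.sonophore_neuron.bls import (
    PMInterpolant,
    build_pm_interpolant,
    mechanical_steady_cycle,
)
from tfusim.sonophore_neuron.params import BLSParams, RSNeuronParams

FORMAT_VERSION = 1

#: row order of the rate arrays
RATE_NAMES = (
    "alpha_m", "beta_m", "alpha_h", "beta_h",
    "alpha_n", "beta_n", "alpha_p", "beta_p",
)


@dataclass
class LookupTable:
    """Effective variables on a rectilinear (PA, Qm) grid."""

    pa: np.ndarray  # Pa, (n_pa,)
    qm: np.ndarray  # C/m^2, (n_qm,)
    inv_cm: np.ndarray  # m^2/F, (n_pa, n_qm), <1/Cm> over the cycle
    rates: np.ndarray  # s^-1, (8, n_pa, n_qm), ordered as RATE_NAMES
    f: float  # Hz
    a: float  # sonophore radius, m
    cm0: float  # F/m^2
    v_t_mv: float = rate_mod.VT_DEFAULT_MV
    tau_max: float = rate_mod.TAU_MAX_DEFAULT

    def __post_init__(self):
        if np.any(np.diff(self.pa) <= 0) or np.any(np.diff(self.qm) <= 0):
            raise RangeError("lookup axes must be strictly increasing")

    # -- queries ------------------------------------------------------------

    def _check_pa(self, pa: float) -> None:
        if pa < self.pa[0] - 1e-9 or pa > self.pa[-1] + 1e-9:
            raise RangeError(
                f"PA={pa:g} Pa outside the tabulated range "
                f"[{self.pa[0]:g}, {self.pa[-1]:g}]"
            )

    def slice_at(self, pa: float):
        """1D slices over the Qm axis, interpolated in PA.

        The inverse capacitance interpolates linearly; the rates
        interpolate geometrically (log-space) because their span across
        one PA step is exponential in the potential excursion.
        """
        self._check_pa(pa)
        inv_cm = np.empty_like(self.qm)
        rates = np.empty((8, self.qm.size))
        i = int(np.searchsorted(self.pa, pa, side="right")) - 1
        i = min(max(i, 0), self.pa.size - 2)
        w = (pa - self.pa[i]) / (self.pa[i + 1] - self.pa[i])
        w = min(max(w, 0.0), 1.0)
        inv_cm[:] = (1.0 - w) * self.inv_cm[i] + w * self.inv_cm[i + 1]
        rates[:] = np.exp(
            (1.0 - w) * np.log(self.rates[:, i, :]) + w * np.log(self.rates[:, i + 1, :])
        )
        return inv_cm, rates

    def interp(self, pa: float, qm: float) -> dict:
        """Bilinear interpolation of every effective variable."""
        self._check_pa(pa)
        if qm < self.qm[0] or qm > self.qm[-1]:
            raise RangeError(f"Qm={qm:g} C/m^2 outside the tabulated range")
        inv_cm_row, rate_rows = self.slice_at(pa)
        out = {"inv_cm": float(np.interp(qm, self.qm, inv_cm_row))}
        out["v_eff"] = qm * out["inv_cm"]
        for k, name in enumerate(RATE_NAMES):
            out[name] = float(np.interp(qm, self.qm, rate_rows[k]))
        return out

    # -- persistence --------------------------------------------------------

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["format_version"] = FORMAT_VERSION
            fh.attrs["f"] = self.f
            fh.attrs["a"] = self.a
            fh.attrs["cm0"] = self.cm0
            fh.attrs["v_t_mv"] = self.v_t_mv
            fh.attrs["tau_max"] = self.tau_max
            fh.create_dataset("pa", data=self.pa)
            fh.create_dataset("qm", data=self.qm)
            fh.create_dataset("inv_cm", data=self.inv_cm)
            fh.create_dataset("rates", data=self.rates)

    @classmethod
    def from_hdf5(cls, path) -> "LookupTable":
        import h5py

        with h5py.File(path, "r") as fh:
            if int(fh.attrs["format_version"]) != FORMAT_VERSION:
                raise RangeError("unsupported lookup-table format version")
            return cls(
                pa=fh["pa"][...],
                qm=fh["qm"][...],
                inv_cm=fh["inv_cm"][...],
                rates=fh["rates"][...],
                f=float(fh.attrs["f"]),
                a=float(fh.attrs["a"]),
                cm0=float(fh.attrs["cm0"]),
                v_t_mv=float(fh.attrs["v_t_mv"]),
                tau_max=float(fh.attrs["tau_max"]),
            )


def default_pa_grid(pa_max: float = 150e3, step: float = 10e3) -> np.ndarray:
    """PA axis {0, step, ..., >= pa_max}."""
    n = int(np.ceil(pa_max / step))
    return np.arange(n + 1) * step


def default_qm_grid() -> np.ndarray:
    """Qm axis -100..+50 nC/cm^2 in 1 nC/cm^2 steps (SI: C/m^2)."""
    return np.arange(-100, 51) * 1e-5


def _analytic_rates(v_mv: np.ndarray, neuron: RSNeuronParams) -> np.ndarray:
    vt = neuron.v_t * 1e3
    return np.stack(
        [
            rate_mod.alpha_m(v_mv, vt),
            rate_mod.beta_m(v_mv, vt),
            rate_mod.alpha_h(v_mv, vt),
            rate_mod.beta_h(v_mv, vt),
            rate_mod.alpha_n(v_mv, vt),
            rate_mod.beta_n(v_mv, vt),
            rate_mod.alpha_p(v_mv, neuron.tau_max),
            rate_mod.beta_p(v_mv, neuron.tau_max),
        ]
    )


def build_lookup_table(
    params: BLSParams,
    f: float,
    pa_grid: Optional[np.ndarray] = None,
    qm_grid: Optional[np.ndarray] = None,
    neuron: Optional[RSNeuronParams] = None,
    steps_per_cycle: int = 2000,
    max_cycles: int = 200,
    tol: float = 1e-3,
    pm: Optional[PMInterpolant] = None,
) -> LookupTable:
    """Fill every (PA, Qm) node by period-averaging the driven cavity."""
    pa_grid = default_pa_grid() if pa_grid is None else np.asarray(pa_grid, float)
    qm_grid = default_qm_grid() if qm_grid is None else np.asarray(qm_grid, float)
    neuron = neuron or RSNeuronParams()
    if pa_grid[0] != 0.0:
        raise RangeError("PA grid must include 0")
    if np.any(np.diff(pa_grid) <= 0) or np.any(np.diff(qm_grid) <= 0):
        raise RangeError("lookup grids must be strictly increasing")
    pm = pm if pm is not None else build_pm_interpolant(params)

    n_pa, n_qm = pa_grid.size, qm_grid.size
    inv_cm = np.empty((n_pa, n_qm))
    rates = np.empty((8, n_pa, n_qm))

    # PA = 0: unsonicated membrane, exactly
    inv_cm[0, :] = 1.0 / params.Cm0
    rates[:, 0, :] = _analytic_rates(qm_grid / params.Cm0 * 1e3, neuron)

    for i in range(1, n_pa):
        for j in range(n_qm):
            try:
                _, _, cm_cycle, _ = mechanical_steady_cycle(
                    pa_grid[i], qm_grid[j], params, f,
                    steps_per_cycle=steps_per_cycle, max_cycles=max_cycles,
                    tol=tol, pm=pm,
                )
            except (ConvergenceError, MechanicalFailureError) as err:
                raise type(err)(
                    f"lookup node PA={pa_grid[i]:g} Pa, Qm={qm_grid[j]:g} "
                    f"C/m^2: {err}"
                ) from err
            inv_cm[i, j] = np.mean(1.0 / cm_cycle)
            v_mv = qm_grid[j] / cm_cycle * 1e3
            rates[:, i, j] = _analytic_rates(v_mv, neuron).mean(axis=1)

    return LookupTable(
        pa=pa_grid, qm=qm_grid, inv_cm=inv_cm, rates=rates,
        f=f, a=params.a, cm0=params.Cm0,
        v_t_mv=neuron.v_t * 1e3, tau_max=neuron.tau_max,
    )
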