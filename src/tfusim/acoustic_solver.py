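"""Linear acoustic propagation in a heterogeneous absorbing 2D medium.

First-order coupled pressure/velocity equations on a staggered grid
(FDTD) with a split-field perfectly-matched absorbing layer on all four
sides.  Absorption follows a power law ``alpha(f) = alpha0 * f_MHz**gamma``
in dB/cm, applied as an exponential amplitude loss per step.

The solver records a running per-pixel maximum of |p| and, inside the
configured averaging window, the running means of p**2 and of the vector
p*u.  The primary time-averaged intensity raster is the magnitude of the
mean acoustic-intensity vector ``|<p u>|`` (exact for any linear field,
including the focal region where pressure and velocity dephase); the
plane-wave impedance estimator ``<p^2>/(rho c)`` is also kept, and is
what :func:`compute_avg_intensity` applies to recorded pixel histories.
Both coincide for travelling plane waves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from tfusim.errors import ConfigError, GeometryError, NumericalError
from tfusim.head_model import BRAIN, MediumMap, SourceDefinition, build_water_map

DB_TO_NEPER = math.log(10.0) / 20.0


def steady_state_time(grid_length_x: float, grid_length_y: float, v_min: float) -> float:
    """Grid-diagonal transit time: sqrt(sx^2 + sy^2) / v_min."""
    if v_min <= 0:
        raise ConfigError("v_min must be strictly positive")
    if grid_length_x < 0 or grid_length_y < 0:
        raise ConfigError("grid lengths must be non-negative")
    return math.hypot(grid_length_x, grid_length_y) / v_min


@dataclass
class SolverConfig:
    """Time stepping, boundary and recording parameters."""

    cfl: float = 0.5
    dt: Optional[float] = None  # derived from cfl when None
    total_time: Optional[float] = None  # defaults to the source window
    boundary_layer_thickness: int = 20  # PML width, pixels
    absorption_exponent: float = 1.0  # gamma in alpha0 * f_MHz**gamma
    record_window: Optional[Tuple[float, float]] = None  # defaults to full run
    check_steady_state: bool = True
    nan_check_interval: int = 200

    def resolve_dt(self, dx: float, c_max: float) -> float:
        dt = self.dt if self.dt is not None else self.cfl * dx / c_max
        if dt > self.cfl * dx / c_max * (1.0 + 1e-12):
            raise ConfigError(
                f"dt={dt:g} violates the CFL bound {self.cfl * dx / c_max:g}"
            )
        return dt


@dataclass
class FieldMaps:
    """Maximum-pressure and time-averaged-intensity rasters."""

    max_pressure: np.ndarray  # Pa, (nx, ny)
    avg_intensity: np.ndarray  # W/m^2, |<p u>|, (nx, ny)
    avg_intensity_impedance: Optional[np.ndarray] = None  # W/m^2, <p^2>/(rho c)
    dx: float = 0.0
    origin: Tuple[float, float] = (0.0, 0.0)
    history: Optional[np.ndarray] = None  # (n_recorded_pixels, nt)
    history_dt: Optional[float] = None
    record_pixels: Optional[np.ndarray] = None  # (n, 2) int

    def to_hdf5(self, path, config_echo: Optional[dict] = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["dx"] = self.dx
            f.attrs["origin"] = self.origin
            f.create_dataset("max_pressure", data=self.max_pressure)
            f.create_dataset("avg_intensity", data=self.avg_intensity)
            if config_echo:
                for k, v in config_echo.items():
                    f.attrs[f"config_{k}"] = v


def _pml_profile(n: int, layer: int, dx: float, c_ref: float) -> np.ndarray:
    """Quadratic damping profile sigma(x) on a 1D axis of n points."""
    sigma = np.zeros(n)
    if layer <= 0:
        return sigma
    sigma_max = 3.0 * c_ref * math.log(1e6) / (2.0 * layer * dx)
    ramp = ((np.arange(layer) + 1.0) / layer) ** 2
    sigma[:layer] = sigma_max * ramp[::-1]
    sigma[-layer:] = sigma_max * ramp
    return sigma


def simulate(
    medium: MediumMap,
    source: SourceDefinition,
    config: Optional[SolverConfig] = None,
    record_pixels: Optional[Sequence[Tuple[int, int]]] = None,
    backend: str = "numba",
) -> FieldMaps:
    """Propagate the gated sinusoidal drive and collect field maps.

    ``record_pixels`` selects pixels whose full pressure time series is
    stored in ``FieldMaps.history``; everywhere else only the running
    maximum and the intensity accumulator are kept.  ``backend`` picks
    the compiled inner loop ("numba", default) or the vectorised numpy
    reference path ("numpy"); both implement the same update scheme.
    """
    config = config or SolverConfig()
    nx, ny = medium.shape
    dx = medium.dx
    c = medium.sound_speed
    rho = medium.density
    c_max = float(c.max())

    dt = config.resolve_dt(dx, c_max)
    total_time = config.total_time if config.total_time is not None else source.total_time
    nt = int(round(total_time / dt))

    if config.check_steady_state and source.amplitude.max() > 0:
        t_ss = steady_state_time(nx * dx, ny * dx, float(c.min()))
        if total_time < t_ss * (1.0 - 1e-9):
            raise ConfigError(
                f"total_time {total_time:g}s is below the steady-state "
                f"time {t_ss:g}s of this grid"
            )

    t0, t1 = config.record_window or (0.0, total_time)
    if not (0.0 <= t0 < t1 <= total_time * (1 + 1e-12)):
        raise ConfigError("record_window must lie within [0, total_time]")

    kappa = rho * c * c  # bulk modulus
    inv_rho_x = 2.0 / (rho[1:, :] + rho[:-1, :])  # staggered x faces
    inv_rho_y = 2.0 / (rho[:, 1:] + rho[:, :-1])

    layer = config.boundary_layer_thickness
    sx = _pml_profile(nx, layer, dx, c_max)
    sy = _pml_profile(ny, layer, dx, c_max)
    sx_stag = 0.5 * (sx[1:] + sx[:-1])
    sy_stag = 0.5 * (sy[1:] + sy[:-1])

    # semi-implicit PML factors
    ax_u = (1.0 - 0.5 * dt * sx_stag) / (1.0 + 0.5 * dt * sx_stag)
    bx_u = dt / (1.0 + 0.5 * dt * sx_stag)
    ay_u = (1.0 - 0.5 * dt * sy_stag) / (1.0 + 0.5 * dt * sy_stag)
    by_u = dt / (1.0 + 0.5 * dt * sy_stag)
    ax_p = ((1.0 - 0.5 * dt * sx) / (1.0 + 0.5 * dt * sx))[:, None]
    bx_p = (dt / (1.0 + 0.5 * dt * sx))[:, None]
    ay_p = ((1.0 - 0.5 * dt * sy) / (1.0 + 0.5 * dt * sy))[None, :]
    by_p = (dt / (1.0 + 0.5 * dt * sy))[None, :]

    # power-law absorption -> amplitude decay per step
    f_mhz = source.frequency / 1e6
    alpha_np = medium.alpha0 * (f_mhz ** config.absorption_exponent) * 100.0 * DB_TO_NEPER
    decay = np.exp(-alpha_np * c * dt)

    ux = np.zeros((nx - 1, ny))
    uy = np.zeros((nx, ny - 1))
    px = np.zeros((nx, ny))
    py = np.zeros((nx, ny))
    p = np.zeros((nx, ny))

    max_p = np.zeros((nx, ny))
    p2_acc = np.zeros((nx, ny))
    ix_acc = np.zeros((nx, ny))
    iy_acc = np.zeros((nx, ny))

    src_idx = np.where(source.mask)
    src_hard = source.mode == "hard"
    if src_hard:
        src_amp = source.amplitude[src_idx]
        src_fx = np.full(src_amp.shape, 0.5)
    else:
        # soft injection: dp per step 2 c dt/dx * A radiates surface
        # pressure amplitude A from a (curved) sheet source; the split
        # between px and py follows the local propagation normal
        src_amp = 2.0 * c[src_idx] * dt / dx * source.amplitude[src_idx]
        if source.normal_x2 is not None:
            src_fx = source.normal_x2[src_idx]
        else:
            src_fx = np.full(src_amp.shape, 0.5)
    omega = 2.0 * math.pi * source.frequency
    ramp_time = source.ramp_cycles / source.frequency

    rec_idx = None
    history = None
    if record_pixels is not None:
        rec = np.asarray(record_pixels, dtype=np.int64).reshape(-1, 2)
        rec_idx = (rec[:, 0], rec[:, 1])
        history = np.zeros((rec.shape[0], nt))

    inv_dx = 1.0 / dx

    if backend == "numba":
        from tfusim._fdtd_kernel import fdtd_loop

        empty = np.empty(0, dtype=np.int64)
        win_samples, bad_step = fdtd_loop(
            p, px, py, ux, uy,
            inv_rho_x, inv_rho_y, kappa, decay,
            ax_u, bx_u, ay_u, by_u,
            ax_p[:, 0], bx_p[:, 0], ay_p[0, :], by_p[0, :],
            src_idx[0].astype(np.int64), src_idx[1].astype(np.int64), src_amp,
            src_fx, src_hard, omega, ramp_time, source.on_time, dt, nt, inv_dx, t0, t1,
            max_p, p2_acc, ix_acc, iy_acc,
            rec_idx[0] if rec_idx is not None else empty,
            rec_idx[1] if rec_idx is not None else empty,
            history if history is not None else np.empty((0, 0)),
            config.nan_check_interval,
        )
        if bad_step >= 0:
            raise NumericalError(f"non-finite pressure at step {bad_step}")
        return _finalize(
            max_p, p2_acc, ix_acc, iy_acc, win_samples, medium, record_pixels, history, dt
        )
    if backend != "numpy":
        raise ConfigError(f"unknown solver backend {backend!r}")

    win_samples = 0

    for step in range(nt):
        t = (step + 1) * dt  # time at which the updated field is valid

        np.multiply(ux, ax_u[:, None], out=ux)
        ux -= (bx_u[:, None] * inv_rho_x * inv_dx) * (p[1:, :] - p[:-1, :])
        np.multiply(uy, ay_u[None, :], out=uy)
        uy -= (by_u[None, :] * inv_rho_y * inv_dx) * (p[:, 1:] - p[:, :-1])

        np.multiply(px, ax_p, out=px)
        px[1:-1, :] -= (bx_p[1:-1] * kappa[1:-1, :] * inv_dx) * (ux[1:, :] - ux[:-1, :])
        np.multiply(py, ay_p, out=py)
        py[:, 1:-1] -= (by_p[:, 1:-1] * kappa[:, 1:-1] * inv_dx) * (uy[:, 1:] - uy[:, :-1])

        np.multiply(px, decay, out=px)
        np.multiply(py, decay, out=py)

        # drive while the gate is open
        if t <= source.on_time:
            env = math.sin(omega * t)
            if t < ramp_time:
                env *= 0.5 * (1.0 - math.cos(math.pi * t / ramp_time))
            drive = src_amp * env
            if src_hard:
                px[src_idx] = 0.5 * drive
                py[src_idx] = 0.5 * drive
            else:
                px[src_idx] += src_fx * drive
                py[src_idx] += (1.0 - src_fx) * drive

        np.add(px, py, out=p)

        np.maximum(max_p, np.abs(p), out=max_p)
        if t0 < t <= t1:
            p2_acc += p * p
            ix_acc[1:-1, 1:-1] += p[1:-1, 1:-1] * 0.5 * (ux[:-1, 1:-1] + ux[1:, 1:-1])
            iy_acc[1:-1, 1:-1] += p[1:-1, 1:-1] * 0.5 * (uy[1:-1, :-1] + uy[1:-1, 1:])
            win_samples += 1
        if history is not None:
            history[:, step] = p[rec_idx]

        if step % config.nan_check_interval == 0 and not np.isfinite(p[nx // 2, ny // 2]):
            raise NumericalError(f"non-finite pressure at step {step}")

    if not np.all(np.isfinite(max_p)):
        raise NumericalError(f"non-finite pressure at the end of the run (step {nt})")

    return _finalize(
        max_p, p2_acc, ix_acc, iy_acc, win_samples, medium, record_pixels, history, dt
    )


def _finalize(
    max_p, p2_acc, ix_acc, iy_acc, win_samples, medium, record_pixels, history, dt
) -> FieldMaps:
    n = max(win_samples, 1)
    impedance = p2_acc / n / (medium.density * medium.sound_speed)
    vector = np.hypot(ix_acc, iy_acc) / n
    return FieldMaps(
        max_pressure=max_p,
        avg_intensity=vector,
        avg_intensity_impedance=impedance,
        dx=medium.dx,
        history=history,
        history_dt=dt,
        record_pixels=(np.asarray(record_pixels) if record_pixels is not None else None),
    )


def compute_avg_intensity(
    pressure_history: np.ndarray,
    rho: np.ndarray,
    c: np.ndarray,
    dt: float,
    window: Tuple[float, float],
    frequency: Optional[float] = None,
) -> np.ndarray:
    """Plane-wave-impedance intensity ``<p^2>_window / (rho c)`` per pixel.

    ``pressure_history`` has shape (n_pixels, nt) sampled every ``dt``
    seconds; ``rho`` and ``c`` are per-pixel scalars or arrays.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ConfigError("averaging window is empty")
    if frequency is not None and (t1 - t0) < 1.0 / frequency:
        raise ConfigError("averaging window is shorter than one acoustic period")
    nt = pressure_history.shape[-1]
    i0 = int(math.floor(t0 / dt))
    i1 = min(int(math.ceil(t1 / dt)), nt)
    if i1 <= i0:
        raise ConfigError("averaging window contains no samples")
    seg = pressure_history[..., i0:i1]
    return np.mean(seg * seg, axis=-1) / (np.asarray(rho) * np.asarray(c))


@dataclass
class CalibrationReport:
    max_intensity: float  # W/m^2
    max_pressure: float  # Pa
    passes: bool
    threshold: float  # W/m^2


def free_water_calibration(
    geometry,
    amplitude: float,
    threshold: float,
    duty_cycle: float = 0.9,
    window: float = 500e-6,
    config: Optional[SolverConfig] = None,
    media=None,
) -> CalibrationReport:
    """Run the all-water solve and compare the intensity peak to a bound.

    ``threshold`` is in W/m^2.  The drive is the configured transducer
    arc at the given amplitude; intensity is averaged over the full
    on+off window so the duty cycle scales the delivered power.
    """
    from dataclasses import replace as dc_replace

    from tfusim.head_model import build_transducer_source

    if threshold <= 0:
        raise ConfigError("threshold must be > 0")
    geometry = dc_replace(geometry, source_amplitude=amplitude)
    medium = build_water_map(geometry, media)
    source = build_transducer_source(geometry, duty_cycle, window)
    field = simulate(medium, source, config)
    max_i = float(field.avg_intensity.max())
    return CalibrationReport(
        max_intensity=max_i,
        max_pressure=float(field.max_pressure.max()),
        passes=bool(max_i <= threshold),
        threshold=threshold,
    )


def region_summary(field: FieldMaps, medium: MediumMap) -> dict:
    """Per-region (water/skull/brain) peak pressure and intensity."""
    from tfusim.head_model import LABEL_NAMES

    out = {}
    for lbl, name in LABEL_NAMES.items():
        m = medium.labels == lbl
        if not m.any():
            continue
        out[name] = {
            "max_pressure": float(field.max_pressure[m].max()),
            "max_avg_intensity": float(field.avg_intensity[m].max()),
        }
    return out


def brain_region_peaks(field: FieldMaps, medium: MediumMap) -> Tuple[float, float]:
    """Peak max-pressure and peak avg-intensity inside the brain disc."""
    m = medium.labels == BRAIN
    if not m.any():
        raise GeometryError("medium map has no brain region")
    return float(field.max_pressure[m].max()), float(field.avg_intensity[m].max())
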