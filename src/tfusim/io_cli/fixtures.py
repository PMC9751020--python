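"""Deterministic synthetic inputs for tests and demos."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict

import numpy as np

from tfusim.acoustic_solver import FieldMaps
from tfusim.errors import ConfigError
from tfusim.head_model import HeadGeometryConfig, build_line_source, build_water_map


@dataclass(frozen=True)
class FixtureSpec:
    """One named synthetic fixture; deterministic given its seed."""

    kind: str  # gaussian-focus | plane-wave-medium | synthetic-spike-trace
    params: Dict[str, Any] = field(default_factory=dict)
    seed: int = 0


def generate_fixture(spec: FixtureSpec):
    if spec.kind == "gaussian-focus":
        return _gaussian_focus(**spec.params)
    if spec.kind == "plane-wave-medium":
        return _plane_wave_medium(**spec.params)
    if spec.kind == "synthetic-spike-trace":
        return _spike_trace(seed=spec.seed, **spec.params)
    raise ConfigError(f"unknown fixture kind {spec.kind!r}")


def _gaussian_focus(
    nx: int = 281,
    ny: int = 281,
    dx: float = 1e-3,
    peak: float = 0.6e6,
    center_x: float = 0.14,
    sigma: float = 8e-3,
    rho_c: float = 998.0 * 1481.0,
) -> FieldMaps:
    """Analytic Gaussian max-pressure map centred on the grid axis."""
    x = (np.arange(nx) + 0.5) * dx
    y = (2 * np.arange(ny) + 1 - ny) * (0.5 * dx)  # offsets from the axis
    r2 = (x[:, None] - center_x) ** 2 + y[None, :] ** 2
    p = peak * np.exp(-r2 / (2.0 * sigma**2))
    return FieldMaps(
        max_pressure=p,
        avg_intensity=p**2 / (2.0 * rho_c),
        dx=dx,
    )


def _plane_wave_medium(
    nx: int = 400,
    ny: int = 81,
    dx: float = 0.5e-3,
    amplitude: float = 100e3,
    x_source: float = 20e-3,
    window: float = 150e-6,
    absorbing: bool = False,
):
    """Homogeneous water map plus a full-height line source."""
    geometry = HeadGeometryConfig(
        grid_nx=nx, grid_ny=ny, dx=dx, source_amplitude=amplitude
    )
    medium = build_water_map(geometry)
    if not absorbing:
        medium.alpha0[:] = 0.0
    source = build_line_source(
        geometry, x_position=x_source, duty_cycle=1.0, window=window, mode="hard"
    )
    return medium, source, geometry


def _spike_trace(
    seed: int = 0,
    crossing_times=(10e-3, 20e-3, 30e-3),
    duration: float = 50e-3,
    dt: float = 1e-5,
    baseline: float = -70e-3,
    peak: float = 30e-3,
    width: float = 1e-3,
    noise: float = 0.0,
):
    """Flat trace with triangular depolarisations crossing 0 V at the
    requested times."""
    t = np.arange(0.0, duration, dt)
    vm = np.full_like(t, baseline)
    for tc in crossing_times:
        # rising edge hits 0 V exactly at tc
        rise = width * (-baseline) / (peak - baseline)
        start = tc - rise
        tri = np.clip(1.0 - np.abs(t - (start + width)) / width, 0.0, None)
        vm = np.maximum(vm, baseline + (peak - baseline) * tri)
    if noise > 0:
        rng = np.random.default_rng(seed)
        vm = vm + rng.normal(0.0, noise, size=vm.size)
    return t, vm
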