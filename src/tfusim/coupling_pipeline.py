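"""Macro-to-micro orchestration.

For every (skull thickness, duty cycle) condition: run the acoustic
solve, sample the maximum-pressure map at the 15 focal-region positions
(3 lateral rows x 5 axial columns, left side plus near-axis row), drive
the point neuron at each sampled pressure with the matching pulsed
protocol, and tabulate spike latency and firing rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from tfusim.acoustic_solver import FieldMaps, SolverConfig, simulate, steady_state_time
from tfusim.errors import GeometryError
from tfusim.head_model import (
    BRAIN,
    HeadGeometryConfig,
    MediumMap,
    MediumProperties,
    build_head_map,
    build_transducer_source,
)
from tfusim.sonophore_neuron import (
    BLSParams,
    LookupTable,
    RSNeuronParams,
    StimulusProtocol,
    build_lookup_table,
    compute_firing_rate,
    compute_latency,
    detect_spikes,
    simulate_sonic,
)
from tfusim.sonophore_neuron.bls import build_pm_interpolant
from tfusim.sonophore_neuron.lookup import default_qm_grid

logger = logging.getLogger(__name__)

#: lateral sampling rows of the focal region (m, offsets from the axis)
DEFAULT_Y_ROWS = (-10.19e-3, -5.56e-3, -0.92e-3)


@dataclass(frozen=True)
class ROISpec:
    """3 x 5 sampling grid across the focal region."""

    y_rows: Tuple[float, ...] = DEFAULT_Y_ROWS
    n_columns: int = 5
    column_spacing: float = 5e-3
    x_start: Optional[float] = None  # None: start at the focal peak
    mirror: bool = False  # sample +|y| rows instead of the printed -|y| side

    def __post_init__(self):
        if self.n_columns * len(self.y_rows) != 15:
            raise GeometryError("ROI must sample 15 positions (columns x rows)")

    @property
    def x_extent(self) -> float:
        return (self.n_columns - 1) * self.column_spacing


@dataclass(frozen=True)
class SamplePoint:
    x: float  # m
    y: float  # m
    max_pressure: float  # Pa


@dataclass(frozen=True)
class ResponseRecord:
    skull_thickness: float  # m
    duty_cycle: float
    x: float  # m
    y: float  # m
    PA: float  # Pa
    latency: Optional[float]  # s, None when no spikes
    firing_rate: Optional[float]  # spikes/s, None when < 2 spikes
    n_spikes: int = 0


def extract_roi_points(
    field: FieldMaps,
    medium: MediumMap,
    roi: ROISpec,
) -> List[SamplePoint]:
    """Nearest-pixel max-pressure samples at the 15 ROI positions."""
    if medium.head_center is None:
        raise GeometryError("medium map carries no head geometry")
    dx = field.dx
    nx, ny = field.max_pressure.shape
    axis_y = 0.5 * ny * dx
    j_axis = min(int(axis_y / dx), ny - 1)

    if roi.x_start is None:
        x_start = _focal_peak_x(field, medium, roi, j_axis, axis_y)
    else:
        x_start = roi.x_start

    points = []
    for y_off in roi.y_rows:
        if roi.mirror:
            y_off = -y_off
        for k in range(roi.n_columns):
            x = x_start + k * roi.column_spacing
            y = axis_y + y_off
            i = int(round(x / dx - 0.5))
            j = int(round(y / dx - 0.5))
            if not (0 <= i < nx and 0 <= j < ny):
                raise GeometryError(f"ROI point ({x:g}, {y:g}) m is outside the grid")
            if medium.labels[i, j] != BRAIN:
                raise GeometryError(
                    f"ROI point ({x * 1e3:.2f}, {y * 1e3:.2f}) mm is outside the brain region"
                )
            points.append(SamplePoint(x=x, y=y, max_pressure=float(field.max_pressure[i, j])))
    return points


def _focal_peak_x(field: FieldMaps, medium: MediumMap, roi: ROISpec, j_axis: int, axis_y: float) -> float:
    """Axial position of the strongest on-axis pressure from which the
    whole 3 x 5 sampling grid stays inside the brain disc.

    The validity restriction matters: reflections can place the raw
    on-axis maximum right at the inner skull boundary, where the
    off-axis rows would fall outside the brain.
    """
    dx = field.dx
    nx, ny = field.max_pressure.shape
    row = field.max_pressure[:, j_axis]
    candidates = np.where(medium.labels[:, j_axis] == BRAIN)[0]
    if candidates.size == 0:
        raise GeometryError("axis transect contains no brain pixels")

    max_off = max(abs(y) for y in roi.y_rows)
    xc, _ = medium.head_center
    r_ok = (medium.brain_radius or 0.0) ** 2

    def grid_fits(i: int) -> bool:
        x_last = (i + 0.5) * dx + roi.x_extent
        for x in ((i + 0.5) * dx, x_last):
            if (x - xc) ** 2 + max_off**2 > r_ok:
                return False
        return x_last < nx * dx

    valid = [i for i in candidates if grid_fits(i)]
    if not valid:
        raise GeometryError("no axial position fits the 15-point ROI in the brain")
    best = valid[int(np.argmax(row[valid]))]
    return (best + 0.5) * dx


@dataclass
class MultiscaleConfig:
    """Everything needed for the full macro-to-micro sweep."""

    geometry: HeadGeometryConfig = field(default_factory=HeadGeometryConfig)
    media: Optional[Dict[str, MediumProperties]] = None
    solver: SolverConfig = field(default_factory=SolverConfig)
    roi: ROISpec = field(default_factory=ROISpec)
    bls: BLSParams = field(default_factory=BLSParams)
    neuron: RSNeuronParams = field(default_factory=RSNeuronParams)
    skull_thicknesses: Tuple[float, ...] = (5.4e-3, 7.6e-3, 10.5e-3)
    duty_cycles: Tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    window: float = 500e-6  # macroscale pulsing window
    prf: float = 500.0  # microscale pulse repetition frequency
    protocol_duration: float = 100e-3
    table_pa_step: float = 10e3
    table_qm_grid: Optional[np.ndarray] = None
    sonic_dt: float = 1e-6
    spike_threshold: float = 0.0  # V
    spike_refractory: float = 1e-3  # s


def _build_table_for(pressures: Sequence[float], cfg: MultiscaleConfig) -> LookupTable:
    """Lookup table whose PA axis covers the sampled pressures."""
    pa_max = max(max(pressures, default=0.0), cfg.table_pa_step)
    n = int(math.ceil(pa_max / cfg.table_pa_step))
    pa_grid = np.arange(n + 1) * cfg.table_pa_step
    qm_grid = cfg.table_qm_grid if cfg.table_qm_grid is not None else default_qm_grid()
    logger.info("building lookup table: PA 0..%g kPa, %d x %d nodes",
                pa_grid[-1] / 1e3, pa_grid.size, qm_grid.size)
    return build_lookup_table(
        cfg.bls, cfg.geometry.source_frequency, pa_grid=pa_grid,
        qm_grid=qm_grid, neuron=cfg.neuron,
        pm=build_pm_interpolant(cfg.bls),
    )


def run_multiscale(
    cfg: MultiscaleConfig,
    table: Optional[LookupTable] = None,
    keep_fields: bool = False,
):
    """Run every (skull thickness, duty cycle) condition end to end.

    Returns ``(records, fields)`` where ``records`` is a list of
    :class:`ResponseRecord` (15 per condition) and ``fields`` maps
    ``(skull, dc)`` to the solved :class:`FieldMaps` when
    ``keep_fields`` is set.
    """
    samples: Dict[Tuple[float, float], List[SamplePoint]] = {}
    fields: Dict[Tuple[float, float], FieldMaps] = {}

    t_ss = steady_state_time(
        cfg.geometry.grid_nx * cfg.geometry.dx,
        cfg.geometry.grid_ny * cfg.geometry.dx,
        min(m.sound_speed for m in (cfg.media or _default_media()).values()),
    )
    logger.info("steady-state bound t_ss = %.1f us (window %.1f us)",
                t_ss * 1e6, cfg.window * 1e6)

    for skull in cfg.skull_thicknesses:
        geometry = cfg.geometry.with_skull(skull)
        medium = build_head_map(geometry, cfg.media)
        for dc in cfg.duty_cycles:
            try:
                source = build_transducer_source(geometry, dc, cfg.window)
                field_maps = simulate(medium, source, cfg.solver)
                samples[(skull, dc)] = extract_roi_points(field_maps, medium, cfg.roi)
                if keep_fields:
                    fields[(skull, dc)] = field_maps
            except Exception as err:
                raise type(err)(
                    f"macroscale stage failed at skull={skull * 1e3:g} mm, "
                    f"DC={dc:g}: {err}"
                ) from err
            logger.info("macro solve done: skull=%.1f mm DC=%.0f%%", skull * 1e3, dc * 100)

    if table is None:
        all_pa = [pt.max_pressure for pts in samples.values() for pt in pts]
        table = _build_table_for(all_pa, cfg)

    records: List[ResponseRecord] = []
    for (skull, dc), pts in samples.items():
        for pt in pts:
            try:
                protocol = StimulusProtocol(
                    PA=pt.max_pressure,
                    f=cfg.geometry.source_frequency,
                    prf=cfg.prf,
                    duty_cycle=dc,
                    duration=cfg.protocol_duration,
                )
                trace = simulate_sonic(protocol, table, cfg.neuron, dt=cfg.sonic_dt)
                spikes = detect_spikes(
                    trace.t, trace.vm_charge,
                    threshold=cfg.spike_threshold, refractory=cfg.spike_refractory,
                )
                latency = compute_latency(spikes, protocol.onset)
                rate = compute_firing_rate(spikes, protocol.stim_window)
            except Exception as err:
                raise type(err)(
                    f"microscale stage failed at skull={skull * 1e3:g} mm, "
                    f"DC={dc:g}, point=({pt.x * 1e3:.2f}, {pt.y * 1e3:.2f}) mm: {err}"
                ) from err
            records.append(
                ResponseRecord(
                    skull_thickness=skull, duty_cycle=dc, x=pt.x, y=pt.y,
                    PA=pt.max_pressure, latency=latency, firing_rate=rate,
                    n_spikes=int(len(spikes)),
                )
            )
    return records, fields


def _default_media():
    from tfusim.head_model import DEFAULT_MEDIA

    return DEFAULT_MEDIA


def records_to_dataframe(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    """CSV-facing table (mm / kPa / ms / spikes-per-second units)."""
    return pd.DataFrame(
        {
            "skull_mm": [r.skull_thickness * 1e3 for r in records],
            "dc": [r.duty_cycle for r in records],
            "x_mm": [r.x * 1e3 for r in records],
            "y_mm": [r.y * 1e3 for r in records],
            "pa_kpa": [r.PA / 1e3 for r in records],
            "latency_ms": [None if r.latency is None else r.latency * 1e3 for r in records],
            "firing_rate_sps": [r.firing_rate for r in records],
            "n_spikes": [r.n_spikes for r in records],
        }
    )


def summarize(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    """Per-condition summary: activation count and latency/rate spreads."""
    if not records:
        raise ValueError("no records to summarise")
    df = records_to_dataframe(records)
    rows = []
    for (skull, dc), grp in df.groupby(["skull_mm", "dc"], sort=True):
        lat = grp["latency_ms"].dropna()
        fr = grp["firing_rate_sps"].dropna()
        rows.append(
            {
                "skull_mm": skull,
                "dc": dc,
                "n_points": len(grp),
                "n_activated": int((grp["n_spikes"] > 0).sum()),
                "latency_ms_min": lat.min() if len(lat) else None,
                "latency_ms_median": lat.median() if len(lat) else None,
                "latency_ms_max": lat.max() if len(lat) else None,
                "firing_rate_min": fr.min() if len(fr) else None,
                "firing_rate_median": fr.median() if len(fr) else None,
                "firing_rate_max": fr.max() if len(fr) else None,
            }
        )
    return pd.DataFrame(rows)
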