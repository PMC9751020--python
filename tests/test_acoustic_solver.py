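import math

import numpy as np
import pytest

from tfusim.errors import ConfigError
from tfusim.head_model import (
    HeadGeometryConfig,
    build_line_source,
    build_transducer_source,
    build_water_map,
)
from tfusim.acoustic_solver import (
    SolverConfig,
    compute_avg_intensity,
    free_water_calibration,
    simulate,
    steady_state_time,
)

WATER_RHO_C = 998.0 * 1481.0


class TestSteadyStateTime:
    def test_zero_grid(self):
        assert steady_state_time(0.0, 0.0, 1481.0) == 0.0

    def test_direct_evaluation(self):
        # sqrt(0.2^2 + 0.2^2) / 1481 = 1.91e-4 s
        t = steady_state_time(0.20, 0.20, 1481.0)
        assert t == pytest.approx(1.9098e-4, rel=1e-3)

    def test_printed_value_inverts_to_diagonal(self):
        # 190 us at 1481 m/s implies a grid diagonal of ~0.281 m
        diag = 190e-6 * 1481.0
        assert diag == pytest.approx(0.2814, rel=1e-3)
        t = steady_state_time(diag / math.sqrt(2), diag / math.sqrt(2), 1481.0)
        assert t == pytest.approx(190e-6, rel=1e-9)

    def test_invalid_vmin(self):
        with pytest.raises(ConfigError):
            steady_state_time(0.1, 0.1, 0.0)


def _plane_wave_setup(amplitude=100e3):
    geo = HeadGeometryConfig(
        grid_nx=300, grid_ny=81, dx=0.5e-3, source_amplitude=amplitude
    )
    med = build_water_map(geo)
    med.alpha0[:] = 0.0
    src = build_line_source(geo, x_position=20e-3, window=120e-6, mode="hard")
    return geo, med, src


class TestSimulate:
    def test_zero_amplitude_gives_zero_fields(self):
        geo, med, _ = _plane_wave_setup(amplitude=0.0)
        src = build_line_source(geo, 20e-3, window=50e-6, amplitude=0.0)
        cfg = SolverConfig(check_steady_state=False)
        fld = simulate(med, src, cfg)
        assert fld.max_pressure.max() == 0.0
        assert fld.avg_intensity.max() == 0.0

    def test_plane_wave_amplitude_within_2pct(self):
        geo, med, src = _plane_wave_setup()
        cfg = SolverConfig(check_steady_state=False)
        fld = simulate(med, src, cfg, record_pixels=[(160, 40)])
        t = np.arange(1, fld.history.shape[1] + 1) * fld.history_dt
        steady = np.abs(fld.history[0][t > 80e-6]).max()
        assert steady == pytest.approx(100e3, rel=0.02)

    def test_no_absorption_amplitude_does_not_decay(self):
        # travelling-wave energy conservation observable: equal steady
        # amplitude at two probes along the path when alpha0 = 0
        geo, med, src = _plane_wave_setup()
        cfg = SolverConfig(check_steady_state=False)
        fld = simulate(med, src, cfg, record_pixels=[(120, 40), (200, 40)])
        t = np.arange(1, fld.history.shape[1] + 1) * fld.history_dt
        sel = t > 90e-6
        a0 = np.sqrt(2 * np.mean(fld.history[0][sel] ** 2))
        a1 = np.sqrt(2 * np.mean(fld.history[1][sel] ** 2))
        assert a1 == pytest.approx(a0, rel=0.01)

    def test_linear_amplitude_scaling(self):
        geo, med, src = _plane_wave_setup()
        cfg = SolverConfig(check_steady_state=False, total_time=60e-6)
        f1 = simulate(med, src, cfg)
        src2 = build_line_source(geo, 20e-3, window=120e-6, amplitude=300e3, mode="hard")
        f2 = simulate(med, src2, cfg)
        mask = f1.max_pressure > 1e3
        ratio = f2.max_pressure[mask] / f1.max_pressure[mask]
        assert np.allclose(ratio, 3.0, rtol=1e-3)
        imask = f1.avg_intensity > 1e-2
        iratio = f2.avg_intensity[imask] / f1.avg_intensity[imask]
        assert np.allclose(iratio, 9.0, rtol=2e-3)

    def test_cfl_violation_raises(self):
        geo, med, src = _plane_wave_setup()
        cfg = SolverConfig(dt=1e-6, check_steady_state=False)
        with pytest.raises(ConfigError):
            simulate(med, src, cfg)

    def test_focused_field_mirror_symmetric(self, coarse_head_solution):
        _, _, fld = coarse_head_solution
        p = fld.max_pressure
        assert np.allclose(p, p[:, ::-1], rtol=1e-9, atol=1e-6)

    def test_focal_pressure_grid_convergence(self):
        """Halving dx changes the free-field focal peak by < 5%."""
        vals = {}
        for dx, ny in ((0.5e-3, 561), (0.25e-3, 1121)):
            geo = HeadGeometryConfig(grid_nx=int(0.11 / dx), grid_ny=ny, dx=dx)
            src = build_transducer_source(geo, 1.0, 200e-6)
            med = build_water_map(geo)
            cfg = SolverConfig(check_steady_state=False, total_time=200e-6)
            vals[dx] = simulate(med, src, cfg).max_pressure.max()
        assert vals[0.25e-3] == pytest.approx(vals[0.5e-3], rel=0.05)

    def test_backend_equivalence(self):
        geo = HeadGeometryConfig(grid_nx=120, grid_ny=61, dx=1e-3)
        med = build_water_map(geo)
        src = build_line_source(geo, 20e-3, window=40e-6)
        cfg = SolverConfig(check_steady_state=False)
        a = simulate(med, src, cfg, backend="numba")
        b = simulate(med, src, cfg, backend="numpy")
        assert np.allclose(a.max_pressure, b.max_pressure, rtol=1e-12, atol=1e-9)
        assert np.allclose(a.avg_intensity, b.avg_intensity, rtol=1e-12, atol=1e-12)


class TestComputeAvgIntensity:
    def test_sinusoid_value(self):
        f = 250e3
        dt = 1e-8
        t = np.arange(0, 200e-6, dt)
        p = 100e3 * np.sin(2 * np.pi * f * t)
        i = compute_avg_intensity(p[None, :], 998.0, 1481.0, dt, (0.0, 200e-6), f)
        # p0^2 / (2 rho c) = 3.38e3 W/m^2 = 0.338 W/cm^2
        assert i[0] == pytest.approx(100e3**2 / (2 * WATER_RHO_C), rel=1e-3)
        assert i[0] / 1e4 == pytest.approx(0.338, rel=0.005)

    def test_zero_trace(self):
        i = compute_avg_intensity(np.zeros((1, 1000)), 998.0, 1481.0, 1e-8, (0, 1e-5))
        assert i[0] == 0.0

    def test_half_silent_window_halves_intensity(self):
        f = 250e3
        dt = 1e-8
        n = 20000  # 200 us
        t = np.arange(n) * dt
        p = 100e3 * np.sin(2 * np.pi * f * t)
        p_gated = p.copy()
        p_gated[n // 2:] = 0.0
        full = compute_avg_intensity(p[None, :], 998.0, 1481.0, dt, (0, n * dt), f)
        gated = compute_avg_intensity(p_gated[None, :], 998.0, 1481.0, dt, (0, n * dt), f)
        assert gated[0] == pytest.approx(0.5 * full[0], rel=1e-9)

    def test_short_window_raises(self):
        with pytest.raises(ConfigError):
            compute_avg_intensity(np.zeros((1, 10)), 998.0, 1481.0, 1e-8, (0, 1e-6), 250e3)


class TestFreeWaterCalibration:
    def test_zero_amplitude_passes(self):
        geo = HeadGeometryConfig(grid_nx=281, grid_ny=281, dx=1e-3)
        rep = free_water_calibration(geo, 0.0, threshold=3e4)
        assert rep.max_intensity == 0.0
        assert rep.passes

    def test_quadratic_amplitude_scaling(self):
        geo = HeadGeometryConfig(grid_nx=281, grid_ny=281, dx=1e-3)
        r1 = free_water_calibration(geo, 50e3, threshold=3e4)
        r2 = free_water_calibration(geo, 100e3, threshold=3e4)
        assert r2.max_intensity / r1.max_intensity == pytest.approx(4.0, rel=1e-3)

    def test_invalid_threshold(self):
        geo = HeadGeometryConfig(grid_nx=281, grid_ny=281, dx=1e-3)
        with pytest.raises(ConfigError):
            free_water_calibration(geo, 100e3, threshold=0.0)
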