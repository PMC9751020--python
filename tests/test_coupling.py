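import numpy as np
import pytest

from tfusim.errors import GeometryError
from tfusim.head_model import build_head_map
from tfusim.acoustic_solver import FieldMaps
from tfusim.coupling_pipeline import (
    ROISpec,
    ResponseRecord,
    extract_roi_points,
    records_to_dataframe,
    run_multiscale,
    summarize,
)
from tfusim.io_cli.fixtures import FixtureSpec, generate_fixture


def _uniform_field(medium, value=1e5):
    shape = medium.labels.shape
    return FieldMaps(
        max_pressure=np.full(shape, value),
        avg_intensity=np.zeros(shape),
        dx=medium.dx,
    )


class TestROISpec:
    def test_default_rows_are_printed_offsets(self):
        roi = ROISpec()
        assert roi.y_rows == (-10.19e-3, -5.56e-3, -0.92e-3)
        assert roi.n_columns * len(roi.y_rows) == 15
        assert roi.x_extent == pytest.approx(20e-3)

    def test_wrong_point_count_rejected(self):
        with pytest.raises(GeometryError):
            ROISpec(n_columns=4)


class TestExtractRoiPoints:
    def test_uniform_map_returns_constant(self, coarse_head_solution):
        geo, medium, _ = coarse_head_solution
        field = _uniform_field(medium, 2.5e5)
        pts = extract_roi_points(field, medium, ROISpec(x_start=geo.focus_x))
        assert len(pts) == 15
        assert all(p.max_pressure == 2.5e5 for p in pts)

    def test_gaussian_focus_recovers_structure(self, coarse_head_solution):
        geo, medium, _ = coarse_head_solution
        fx = FixtureSpec(
            "gaussian-focus",
            {"nx": geo.grid_nx, "ny": geo.grid_ny, "dx": geo.dx,
             "peak": 0.6e6, "center_x": geo.focus_x, "sigma": 8e-3},
        )
        field = generate_fixture(fx)
        pts = extract_roi_points(field, medium, ROISpec(x_start=geo.focus_x))
        by_row = {y: [] for y in sorted({round(p.y, 9) for p in pts})}
        for p in pts:
            by_row[round(p.y, 9)].append(p)
        rows = list(by_row.values())
        # near-axis row (largest y, offsets are negative) carries the
        # largest samples; samples decay with |y|
        row_peaks = [max(p.max_pressure for p in row) for row in rows]
        assert row_peaks == sorted(row_peaks)
        # first column of the near-axis row sits closest to the peak
        near = max(rows, key=lambda r: max(p.max_pressure for p in r))
        first = min(near, key=lambda p: p.x)
        expected = 0.6e6 * np.exp(-(first.y - 0.5 * geo.grid_ny * geo.dx) ** 2 / (2 * 8e-3**2))
        assert first.max_pressure == pytest.approx(expected, rel=0.02)

    def test_samples_decay_along_x_for_gaussian(self, coarse_head_solution):
        geo, medium, _ = coarse_head_solution
        field = generate_fixture(FixtureSpec(
            "gaussian-focus",
            {"nx": geo.grid_nx, "ny": geo.grid_ny, "dx": geo.dx,
             "center_x": geo.focus_x, "sigma": 8e-3},
        ))
        pts = extract_roi_points(field, medium, ROISpec(x_start=geo.focus_x))
        near_axis = sorted(
            (p for p in pts if abs(p.y - 0.5 * geo.grid_ny * geo.dx + 0.92e-3) < 1e-6),
            key=lambda p: p.x,
        )
        vals = [p.max_pressure for p in near_axis]
        assert vals == sorted(vals, reverse=True)

    def test_roi_outside_brain_raises(self, coarse_head_solution):
        geo, medium, _ = coarse_head_solution
        field = _uniform_field(medium)
        with pytest.raises(GeometryError):
            extract_roi_points(field, medium, ROISpec(x_start=0.25))

    def test_mirrored_rows_match_within_solver_tolerance(self, coarse_head_solution):
        geo, medium, field = coarse_head_solution
        left = extract_roi_points(field, medium, ROISpec(x_start=geo.focus_x))
        right = extract_roi_points(field, medium, ROISpec(x_start=geo.focus_x, mirror=True))
        for a, b in zip(left, right):
            assert b.max_pressure == pytest.approx(a.max_pressure, rel=1e-6)


class TestSummarize:
    def test_all_none_records(self):
        recs = [
            ResponseRecord(5.4e-3, 0.4, 0.08, 0.14, 0.0, None, None, 0)
            for _ in range(3)
        ]
        s = summarize(recs)
        assert int(s.loc[0, "n_activated"]) == 0
        assert s.loc[0, "latency_ms_min"] is None or np.isnan(s.loc[0, "latency_ms_min"])

    def test_single_record(self):
        recs = [ResponseRecord(5.4e-3, 0.4, 0.08, 0.14, 1e5, 12e-3, 100.0, 3)]
        s = summarize(recs)
        for col in ("latency_ms_min", "latency_ms_median", "latency_ms_max"):
            assert s.loc[0, col] == pytest.approx(12.0)

    def test_three_record_medians(self):
        lats = [10e-3, 20e-3, 40e-3]
        recs = [
            ResponseRecord(5.4e-3, 0.4, 0.08, 0.14, 1e5, lat, 50.0 + i, 5)
            for i, lat in enumerate(lats)
        ]
        s = summarize(recs)
        assert s.loc[0, "latency_ms_median"] == pytest.approx(20.0)
        assert s.loc[0, "firing_rate_median"] == pytest.approx(51.0)
        assert int(s.loc[0, "n_activated"]) == 3

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize([])


class TestRecordsDataFrame:
    def test_units_and_none_handling(self):
        recs = [
            ResponseRecord(5.4e-3, 0.9, 0.0782, 0.1396, 2.3e5, 12.5e-3, 101.0, 4),
            ResponseRecord(10.5e-3, 0.4, 0.0782, 0.1396, 0.0, None, None, 0),
        ]
        df = records_to_dataframe(recs)
        assert df.loc[0, "skull_mm"] == pytest.approx(5.4)
        assert df.loc[0, "pa_kpa"] == pytest.approx(230.0)
        assert df.loc[0, "latency_ms"] == pytest.approx(12.5)
        assert np.isnan(df.loc[1, "latency_ms"])


@pytest.fixture(scope="module")
def tiny_multiscale_cfg(bls, neuron):
    """Smallest physical config that exercises the whole pipeline."""
    from tfusim.acoustic_solver import SolverConfig
    from tfusim.coupling_pipeline import MultiscaleConfig
    from tfusim.head_model import HeadGeometryConfig

    return MultiscaleConfig(
        geometry=HeadGeometryConfig(grid_nx=231, grid_ny=231, dx=1.25e-3),
        solver=SolverConfig(),
        bls=bls,
        neuron=neuron,
        skull_thicknesses=(5.4e-3,),
        duty_cycles=(0.9,),
        table_qm_grid=np.arange(-100, 51, 2) * 1e-5,
        protocol_duration=50e-3,
    )


class TestRunMultiscale:
    def test_single_condition_end_to_end(self, tiny_multiscale_cfg):
        records, _ = run_multiscale(tiny_multiscale_cfg)
        assert len(records) == 15
        df = records_to_dataframe(records)
        assert (df["pa_kpa"] > 0).all()
        # latency None exactly when no spikes; firing rate None when < 2
        for r in records:
            assert (r.latency is None) == (r.n_spikes == 0)
            assert (r.firing_rate is None) == (r.n_spikes < 2)

    def test_determinism(self, tiny_multiscale_cfg):
        r1, _ = run_multiscale(tiny_multiscale_cfg)
        r2, _ = run_multiscale(tiny_multiscale_cfg)
        assert records_to_dataframe(r1).equals(records_to_dataframe(r2))
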