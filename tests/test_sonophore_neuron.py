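import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfusim.errors import ConfigError, MechanicalFailureError, RangeError
from tfusim.sonophore_neuron import (
    BLSParams,
    StimulusProtocol,
    capacitance,
    compute_firing_rate,
    compute_latency,
    detect_spikes,
    mechanical_steady_cycle,
    molecular_pressure,
    rest_state,
    simulate_sonic,
)
from tfusim.sonophore_neuron import rates as rate_mod
from tfusim.sonophore_neuron import bls as bls_mod
from tfusim.sonophore_neuron import _kernels as kern


class TestParams:
    def test_resting_gap_residual(self, bls):
        u = bls.delta_star / bls.Delta
        residual = bls.Ar * (u**bls.x_rep - u**bls.y_att) - bls.resting_gap_pressure()
        assert abs(residual) < 1e-6 * bls.P0

    def test_ambient_balance_variant(self):
        p = BLSParams(delta_balance="ambient")
        u = p.delta_star / p.Delta
        assert p.Ar * (u**p.x_rep - u**p.y_att) == pytest.approx(p.P0, rel=1e-9)

    def test_henry_concentration(self, bls):
        assert bls.Cg == pytest.approx(bls.P0 / bls.kH)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ConfigError):
            BLSParams(a=-1e-9)


class TestCapacitance:
    def test_limit_at_zero_deflection(self, bls):
        assert float(capacitance(0.0, bls)) == bls.Cm0
        assert float(capacitance(1e-16, bls)) == pytest.approx(bls.Cm0, rel=1e-6)
        assert float(capacitance(-1e-16, bls)) == pytest.approx(bls.Cm0, rel=1e-6)

    def test_monotone_through_small_deflections(self, bls):
        # expansion lowers, compression raises the capacitance
        assert float(capacitance(5e-9, bls)) < bls.Cm0 < float(capacitance(-0.3e-9, bls))

    def test_contact_raises(self, bls):
        with pytest.raises(MechanicalFailureError):
            capacitance(-bls.Delta, bls)

    def test_kernel_matches_reference(self, bls):
        for z in (-0.4e-9, -1e-12, 0.0, 1e-12, 2e-9, 20e-9):
            ref = float(capacitance(z, bls))
            fast = kern._cm_of_z(z, bls.a, bls.Delta, bls.Cm0)
            assert fast == pytest.approx(ref, rel=1e-9)


class TestMolecularPressure:
    def test_matches_ambient_balance_at_zero(self, bls):
        # by construction of Delta, PM(0) equals the resting compression
        assert molecular_pressure(0.0, bls) == pytest.approx(
            bls.resting_gap_pressure(), rel=1e-6
        )

    def test_quadrature_refinement(self, bls):
        for z in (-0.3 * bls.Delta, 0.0, 3e-9):
            coarse = molecular_pressure(z, bls, n_nodes=64)
            fine = molecular_pressure(z, bls, n_nodes=256)
            assert coarse == pytest.approx(fine, rel=1e-6)

    def test_decays_with_expansion(self, bls):
        assert molecular_pressure(5e-9, bls) < molecular_pressure(0.0, bls)


class TestRates:
    def test_removable_singularities(self):
        # alpha_m is singular at V - VT = 13 mV, alpha_n at 15 mV
        vt = rate_mod.VT_DEFAULT_MV
        for fn, v in ((rate_mod.alpha_m, vt + 13.0), (rate_mod.alpha_n, vt + 15.0)):
            left, mid, right = fn(v - 1e-6), fn(v), fn(v + 1e-6)
            assert left == pytest.approx(right, rel=1e-4)
            assert mid == pytest.approx(left, rel=1e-4)

    def test_all_rates_positive(self):
        v = np.linspace(-150.0, 80.0, 400)
        for gate, (a, b) in rate_mod.RATE_FUNCTIONS.items():
            assert (a(v) > 0).all(), gate
            assert (b(v) > 0).all(), gate

    def test_kernel_rates_match_reference(self):
        vt = rate_mod.VT_DEFAULT_MV
        for v in (-120.0, -71.9, -56.2 + 13.0, -30.0, 10.0, 50.0):
            assert kern._alpha_m(v, vt) == pytest.approx(float(rate_mod.alpha_m(v)), rel=1e-9)
            assert kern._beta_m(v, vt) == pytest.approx(float(rate_mod.beta_m(v)), rel=1e-9)
            assert kern._alpha_h(v, vt) == pytest.approx(float(rate_mod.alpha_h(v)), rel=1e-9)
            assert kern._beta_h(v, vt) == pytest.approx(float(rate_mod.beta_h(v)), rel=1e-9)
            assert kern._alpha_n(v, vt) == pytest.approx(float(rate_mod.alpha_n(v)), rel=1e-9)
            assert kern._beta_n(v, vt) == pytest.approx(float(rate_mod.beta_n(v)), rel=1e-9)


class TestMechanicalSteadyCycle:
    def test_rest_is_stationary_without_drive(self, bls, pm):
        qm0, _ = rest_state()
        t, z, cm, info = mechanical_steady_cycle(0.0, qm0, bls, 250e3, pm=pm)
        assert (cm.max() - cm.min()) / cm.mean() < 1e-3
        z_eq = bls_mod.equilibrium_deflection(qm0, bls, pm)
        assert np.allclose(z, z_eq, atol=1e-13)

    def test_driven_cycle_changes_mean_inverse_capacitance(self, bls, pm):
        qm0, _ = rest_state()
        _, _, cm, _ = mechanical_steady_cycle(100e3, qm0, bls, 250e3, pm=pm)
        assert abs(np.mean(1.0 / cm) * bls.Cm0 - 1.0) > 0.05

    def test_timestep_refinement_oracle(self, bls, pm):
        """Coarse integration agrees with a 10x finer reference < 1%."""
        qm0, _ = rest_state()
        _, _, cm_c, _ = mechanical_steady_cycle(
            100e3, qm0, bls, 250e3, steps_per_cycle=1000, pm=pm
        )
        _, _, cm_f, _ = mechanical_steady_cycle(
            100e3, qm0, bls, 250e3, steps_per_cycle=10000, pm=pm
        )
        coarse = np.mean(1.0 / cm_c)
        fine = np.mean(1.0 / cm_f)
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_leaflets_never_touch(self, bls, pm):
        qm0, _ = rest_state()
        for pa in (50e3, 150e3, 300e3):
            _, z, _, _ = mechanical_steady_cycle(pa, qm0, bls, 250e3, pm=pm)
            assert z.min() > -0.5 * bls.Delta


class TestSpikeMetrics:
    def test_flat_trace_no_spikes(self):
        t = np.arange(0, 50e-3, 1e-5)
        vm = np.full_like(t, -70e-3)
        assert detect_spikes(t, vm).size == 0

    def test_three_injected_crossings(self):
        from tfusim.io_cli.fixtures import FixtureSpec, generate_fixture

        t, vm = generate_fixture(
            FixtureSpec("synthetic-spike-trace", {"crossing_times": (10e-3, 20e-3, 30e-3)})
        )
        spikes = detect_spikes(t, vm)
        assert spikes.size == 3
        assert np.allclose(spikes, [10e-3, 20e-3, 30e-3], atol=2e-5)

    def test_refractory_merges_nearby_crossings(self):
        t = np.arange(0, 10e-3, 1e-5)
        vm = np.full_like(t, -70e-3)
        for tc in (5e-3, 5.2e-3):  # 0.2 ms apart
            vm[np.abs(t - tc) < 5e-5] = 10e-3
        spikes = detect_spikes(t, vm, refractory=1e-3)
        assert spikes.size == 1

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(1e-3, 48e-3), max_size=8))
    def test_detected_spikes_respect_refractory(self, times):
        t = np.arange(0, 50e-3, 1e-5)
        vm = np.full_like(t, -70e-3)
        for tc in times:
            vm[np.abs(t - tc) < 1e-4] = 10e-3
        spikes = detect_spikes(t, vm, refractory=1e-3)
        if spikes.size > 1:
            assert np.diff(spikes).min() >= 1e-3 - 1e-9

    def test_latency_examples(self):
        assert compute_latency([12e-3, 20e-3, 31e-3], 0.0) == pytest.approx(12e-3)
        assert compute_latency([], 0.0) is None
        assert compute_latency([5e-3], 2e-3) == pytest.approx(3e-3)

    def test_firing_rate_examples(self):
        assert compute_firing_rate([10e-3, 20e-3, 30e-3], (0, 0.1)) == pytest.approx(100.0)
        assert compute_firing_rate([10e-3], (0, 0.1)) is None
        assert compute_firing_rate([10e-3, 20e-3, 40e-3], (0, 0.1)) == pytest.approx(75.0)


class TestSimulateSonic:
    def test_pa_zero_keeps_rest(self, table_small, neuron):
        proto = StimulusProtocol(PA=0.0, duration=100e-3)
        tr = simulate_sonic(proto, table_small, neuron)
        qm0, _ = rest_state(neuron, table_small.cm0)
        assert np.abs(tr.vm - qm0 / table_small.cm0).max() < 0.5e-3
        assert detect_spikes(tr.t, tr.vm_charge).size == 0

    def test_gates_stay_bounded(self, table_small, neuron):
        for pa in (0.0, 100e3, 150e3):
            proto = StimulusProtocol(PA=pa, duty_cycle=0.9, prf=500.0, duration=50e-3)
            tr = simulate_sonic(proto, table_small, neuron)
            assert tr.gates.min() >= 0.0
            assert tr.gates.max() <= 1.0

    def test_off_interval_potential_is_charge_over_cm0(self, table_small, neuron):
        proto = StimulusProtocol(PA=100e3, duty_cycle=0.4, prf=500.0, duration=20e-3)
        tr = simulate_sonic(proto, table_small, neuron)
        phase = np.mod(tr.t, 1.0 / proto.prf)
        off = phase >= proto.duty_cycle / proto.prf
        assert np.array_equal(tr.vm[off], tr.qm[off] / table_small.cm0)

    def test_spike_count_monotone_in_pa(self, table_small, neuron):
        counts = []
        for pa in (0.0, 50e3, 100e3, 150e3):
            proto = StimulusProtocol(PA=pa, duration=100e-3)
            tr = simulate_sonic(proto, table_small, neuron)
            counts.append(detect_spikes(tr.t, tr.vm_charge).size)
        assert counts == sorted(counts)
        assert counts[0] == 0 and counts[-1] > 0

    def test_pa_outside_table_raises(self, table_small, neuron):
        with pytest.raises(RangeError):
            simulate_sonic(StimulusProtocol(PA=500e3), table_small, neuron)

    def test_invalid_protocols(self):
        with pytest.raises(ConfigError):
            StimulusProtocol(PA=1e5, duty_cycle=1.5)
        with pytest.raises(ConfigError):
            StimulusProtocol(PA=-1.0)
        with pytest.raises(ConfigError):
            StimulusProtocol(PA=1e5, f=1e3, prf=500.0, duty_cycle=0.5)
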