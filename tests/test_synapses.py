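"""Dual-exponential synapse, Mg block, receptor construction, calcium pools."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mspncalc.channels import FARADAY
from mspncalc.synapses import (CalciumPool, SynapseSpec, SynapticEvent,
                               calcium_nernst, load_source_params, make_nmda,
                               make_synapse_pair, mg_block, nmda_calcium_flux,
                               norm_const, peak_time, syn_conductance,
                               update_pool)

AMPA = SynapseSpec(tau1=1.1e-3, tau2=5.75e-3, gmax=342e-12)


class TestDualExponential:
    def test_ampa_peak_time(self):
        tp = peak_time(1.1e-3, 5.75e-3)
        assert tp == pytest.approx(2.2497e-3, rel=1e-3)

    def test_ampa_norm_const(self):
        assert norm_const(1.1e-3, 5.75e-3) == pytest.approx(1.829, rel=1e-3)

    def test_peak_equals_gmax(self):
        tp = peak_time(AMPA.tau1, AMPA.tau2)
        assert syn_conductance(tp, AMPA) == pytest.approx(AMPA.gmax, rel=1e-9)

    def test_zero_at_event_time(self):
        assert syn_conductance(0.0, AMPA) == 0.0

    def test_value_at_10ms(self):
        g = syn_conductance(10e-3, AMPA)
        assert g / AMPA.gmax == pytest.approx(0.321, abs=2e-3)

    def test_equal_taus_alpha_function_peak(self):
        spec = SynapseSpec(tau1=2e-3, tau2=2e-3, gmax=1e-9)
        tgrid = np.linspace(0, 20e-3, 20001)
        g = syn_conductance(tgrid, spec)
        assert g.max() == pytest.approx(spec.gmax, rel=1e-6)
        assert tgrid[np.argmax(g)] == pytest.approx(2e-3, abs=1e-5)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(t1=st.floats(1e-3, 0.2), t2=st.floats(1e-3, 0.2))
    def test_normalization_for_any_tau_pair(self, t1, t2):
        # regardless of which time constant is larger, the normalized
        # waveform peaks at gmax
        spec = SynapseSpec(tau1=t1, tau2=t2, gmax=1e-9)
        tgrid = np.linspace(0, 5 * max(t1, t2), 4001)
        g = syn_conductance(tgrid, spec)
        assert g.max() == pytest.approx(spec.gmax, rel=1e-4)
        assert np.all(g >= 0)


class TestMgBlock:
    def test_no_magnesium_means_no_block(self):
        a = make_nmda("GluN2A")
        v = np.linspace(-100, 40, 15)
        assert np.allclose(mg_block(v, a, mg=0.0), 1.0)

    def test_glun2a_half_block_voltage(self):
        a = make_nmda("GluN2A")
        v_half = 16.129 * math.log(1.0 / 3.57)
        assert v_half == pytest.approx(-20.5, abs=0.1)
        assert mg_block(v_half, a, mg=1.0) == pytest.approx(0.5, rel=1e-6)

    def test_glun2d_weak_block(self):
        d = make_nmda("GluN2D")
        assert mg_block(-20.5, d, mg=1.0) == pytest.approx(0.918, abs=2e-3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(v=st.floats(-110, 50), dv=st.floats(0.1, 30),
           mg=st.floats(0.01, 5.0))
    def test_monotone_in_voltage_and_bounded(self, v, dv, mg):
        a = make_nmda("GluN2A")
        lo, hi = mg_block(v, a, mg=mg), mg_block(v + dv, a, mg=mg)
        assert 0.0 < lo < hi <= 1.0

    def test_block_ordering_across_subunits(self):
        # GluN2A/B (A = 3.57) are the most Mg-sensitive; C and D much less
        vals = {k: float(mg_block(-60.0, make_nmda(k), mg=1.0))
                for k in ("GluN2A", "GluN2B", "GluN2C", "GluN2D")}
        assert vals["GluN2A"] == vals["GluN2B"]
        assert vals["GluN2A"] < vals["GluN2C"] < vals["GluN2D"]


class TestMakeNMDA:
    @pytest.mark.parametrize("label, gmax, tau, mg_a", [
        ("GluN2A", 0.94e-9, 25e-3, 3.57),
        ("GluN2B", 0.94e-9, 150e-3, 3.57),
        ("GluN2C", 0.325e-9, 125e-3, 25.0),
        ("GluN2D", 0.119e-9, 850e-3, 40.0),
    ])
    def test_pure_subunit_table_values(self, label, gmax, tau, mg_a):
        p = make_nmda(label)
        assert p.gmax == pytest.approx(gmax, rel=1e-12)
        assert p.tau_decay == pytest.approx(tau, rel=1e-12)
        assert p.mg_A == mg_a
        assert p.tau_rise == pytest.approx(2.25e-3, rel=1e-12)

    def test_mixture_weighted_decay(self):
        mix = make_nmda("GluN2A+B")
        assert mix.tau_decay == pytest.approx(0.75 * 25e-3 + 0.25 * 150e-3)
        assert mix.gmax == pytest.approx(0.94e-9)
        assert mix.mg_A == 3.57

    def test_conductance_scaled_variant(self):
        scaled = make_nmda("GluN2A+B", conductance_scale=0.75)
        assert scaled.gmax == pytest.approx(0.705e-9)
        assert scaled.tau_decay == pytest.approx(56.25e-3)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            make_nmda("GluN2X")


class TestSynapsePair:
    def test_ding_cortical_ratio(self):
        ampa, nmda = make_synapse_pair(load_source_params("ding", "cortical"))
        assert ampa.gmax == pytest.approx(342e-12)
        assert nmda.gmax == pytest.approx(2.75 * 342e-12)
        assert nmda.gmax == pytest.approx(940e-12, rel=1e-3)
        assert nmda.tau_decay == pytest.approx(56.25e-3)

    def test_smeal_thalamic_decay(self):
        _, nmda = make_synapse_pair(load_source_params("smeal", "thalamic"))
        assert nmda.tau_decay == pytest.approx(96.5e-3)
        assert nmda.gmax == pytest.approx(2.6 * 342e-12)

    def test_ding_thalamic_mixture_weights(self):
        _, nmda = make_synapse_pair(load_source_params("ding", "thalamic"))
        assert nmda.tau_decay == pytest.approx(0.58 * 25e-3 + 0.42 * 150e-3)

    def test_unknown_dataset_rejected(self):
        with pytest.raises(ValueError):
            load_source_params("nosuch", "cortical")


class TestCalciumFluxAndPool:
    def test_closed_receptor_no_flux(self):
        assert nmda_calcium_flux(0.0, -65.0) == 0.0

    def test_zero_at_calcium_reversal(self):
        for driving in ("linear", "ghk"):
            e_ca = calcium_nernst(5e-5, 2.0)
            i = nmda_calcium_flux(1e-9, e_ca, driving=driving)
            assert abs(i) < 1e-18

    def test_linear_in_conductance(self):
        i1 = nmda_calcium_flux(1e-9, -65.0)
        i2 = nmda_calcium_flux(2e-9, -65.0)
        assert i2 == pytest.approx(2 * i1)

    def test_fraction_calibration(self):
        # at -65 mV the calcium current is 10% of the total NMDA current
        g = 1e-9
        total = g * (-65e-3 - 0.0)
        assert nmda_calcium_flux(g, -65.0) == pytest.approx(0.1 * total)

    def test_pool_fixed_point(self):
        pool = CalciumPool(label="nmda", concentration=5e-5)
        out = update_pool(pool, 0.0, 1e-3)
        assert out.concentration == pytest.approx(pool.rest)

    def test_pool_first_order_decay(self):
        pool = CalciumPool(label="nmda", concentration=5e-5 + 1e-3)
        out = pool
        nsteps = 500
        dt = pool.decay_tau / nsteps
        for _ in range(nsteps):
            out = update_pool(out, 0.0, dt)
        assert out.concentration - pool.rest == pytest.approx(1e-3 / math.e, rel=1e-6)

    def test_pool_steady_state_under_constant_influx(self):
        pool = CalciumPool(label="nmda", concentration=5e-5,
                           decay_tau=0.02, effective_volume=1e-19)
        i_ca = -1e-12  # inward
        out = pool
        for _ in range(5000):
            out = update_pool(out, i_ca, 1e-4)
        expected = pool.rest + (-i_ca) * pool.decay_tau / (2 * FARADAY
                                                           * pool.effective_volume)
        assert out.concentration == pytest.approx(expected, rel=1e-4)

    def test_charge_conservation_long_decay(self):
        # with decay_tau -> inf, the concentration increment equals
        # integral(i_ca) dt / (2 F vol)
        pool = CalciumPool(label="nmda", concentration=5e-5,
                           decay_tau=1e6, effective_volume=1e-19)
        dt, i_ca, n = 1e-4, -2e-12, 300
        out = pool
        for _ in range(n):
            out = update_pool(out, i_ca, dt)
        expected = pool.rest + (-i_ca) * n * dt / (2 * FARADAY
                                                   * pool.effective_volume)
        assert out.concentration == pytest.approx(expected, rel=1e-3)

    def test_nr_pool_source_validation(self):
        with pytest.raises(ValueError):
            CalciumPool(label="nr", concentration=0.0,
                        source_currents=frozenset({"CaT"}))

    def test_event_time_validation(self):
        with pytest.raises(ValueError):
            SynapticEvent(time=-1.0, spine_id="x")
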