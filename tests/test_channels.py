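"""Closed-form checks of the channel gating library."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mspncalc.channels import (CaDepParams, bk_rates, channel_current,
                               gate_inf_tau, ghk_current, kdr_inf_tau,
                               sigmoid, sk_inf)


class TestSigmoid:
    def test_half_activation_at_vhalf(self):
        # NaF activation: vhalf -25 mV -> 0.5
        assert sigmoid(-25.0, 1.0, -25.0, -9.2) == pytest.approx(0.5)
        # Kir: vhalf -102 mV
        assert sigmoid(-102.0, 1.0, -102.0, 13.0) == pytest.approx(0.5)

    def test_deep_hyperpolarization_closes_naf(self):
        # direct evaluation of the printed sigmoid at -115 mV
        val = sigmoid(-115.0, 1.0, -25.0, -9.2)
        assert val == pytest.approx(1.0 / (1.0 + np.exp(9.7826086957)), rel=1e-9)
        assert val < 1e-4

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            sigmoid(0.0, 1.0, 0.0, 0.0)


class TestGateInfTau:
    def test_kaf_activation_at_zero_mv(self, lib):
        gate = lib["KaF"].gates[0]
        inf, tau = gate_inf_tau(gate, 0.0)
        # alpha = 1500/(1+exp(-4/-17)), beta = 600/(1+exp(-10/9)) s^-1
        alpha = 1500.0 / (1.0 + np.exp(4.0 / 17.0))
        beta = 600.0 / (1.0 + np.exp(-10.0 / 9.0))
        assert inf == pytest.approx(alpha / (alpha + beta), rel=1e-9)
        assert inf == pytest.approx(0.5946, abs=2e-4)
        assert tau == pytest.approx(1.5 / (alpha + beta), rel=1e-9)

    def test_alpha_beta_symmetry_point(self, lib):
        # where alpha == beta the steady state is exactly 1/2
        gate = lib["KaF"].gates[0]
        v = np.linspace(-80, 40, 20001)
        a = 1500.0 / (1.0 + np.exp((v - 4.0) / -17.0))
        b = 600.0 / (1.0 + np.exp((v - 10.0) / 9.0))
        v_eq = v[np.argmin(np.abs(a - b))]
        inf, _ = gate_inf_tau(gate, v_eq)
        assert inf == pytest.approx(0.5, abs=1e-3)

    def test_kas_inactivation_brute_force(self, lib):
        # independent evaluation of the KaS h row at -95 mV
        gate = lib["KaS"].gates[1]
        alpha = 2.5 / (1.0 + np.exp((-95.0 + 95.0) / 16.0))
        beta = 2.0 / (1.0 + np.exp((-95.0 - 50.0) / -70.0))
        assert alpha == pytest.approx(1.25)
        inf, tau = gate_inf_tau(gate, -95.0)
        assert inf == pytest.approx(alpha / (alpha + beta), rel=1e-9)
        assert tau == pytest.approx(2.5 / (alpha + beta), rel=1e-9)

    def test_all_gates_bounded_and_tau_positive(self, lib, vgrid):
        for spec in lib.channels.values():
            for gate in spec.gates:
                if gate.form in ("bk", "sk"):
                    continue
                inf, tau = gate_inf_tau(gate, vgrid)
                assert np.all((inf >= 0.0) & (inf <= 1.0)), (spec.name, gate.name)
                assert np.all(tau > 0.0), (spec.name, gate.name)

    def test_activation_monotonicity(self, lib, vgrid):
        incr = [("NaF", 0), ("Kdr", 0), ("KaF", 0), ("KaS", 0)]
        decr = [("NaF", 1), ("KaF", 1), ("KaS", 1)]
        for name, gi in incr:
            inf, _ = gate_inf_tau(lib[name].gates[gi], vgrid)
            assert np.all(np.diff(inf) >= -1e-12), name
        for name, gi in decr:
            inf, _ = gate_inf_tau(lib[name].gates[gi], vgrid)
            assert np.all(np.diff(inf) <= 1e-12), name


class TestKdr:
    def test_half_activation_and_tau(self):
        inf, tau = kdr_inf_tau(-13.0)
        assert inf == pytest.approx(0.5)
        assert tau == pytest.approx(0.0125)  # 0.05 * 1/2 * scale 0.5 s

    def test_saturation_at_depolarized(self):
        inf, _ = kdr_inf_tau(50.0)
        assert inf == pytest.approx(1.0 / (1.0 + np.exp(-63.0 / 9.09)), rel=1e-9)
        assert inf > 0.998

    def test_monotone_increasing(self, vgrid):
        inf, tau = kdr_inf_tau(vgrid)
        assert np.all(np.diff(inf) > 0)
        assert np.all(tau > 0)


class TestBK:
    def test_alpha_at_symmetry_point(self):
        # v = 0 makes the exponential 1; ca = K gives alpha = B/2
        alpha, _ = bk_rates(0.0, 0.003)
        assert alpha == pytest.approx(240.0)

    def test_saturation_limits(self):
        alpha, _ = bk_rates(0.0, 1e6)
        assert alpha == pytest.approx(480.0, rel=1e-4)
        _, beta = bk_rates(0.0, 0.0)
        assert beta == pytest.approx(280.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(v=st.floats(-100, 60), ca=st.floats(1e-6, 10.0))
    def test_rates_positive_and_monotone_in_ca(self, v, ca):
        a1, b1 = bk_rates(v, ca)
        a2, b2 = bk_rates(v, ca * 2.0)
        assert a1 + b1 > 0
        assert a2 >= a1
        assert b2 <= b1


class TestSK:
    def test_ec50_and_limits(self):
        assert sk_inf(5.7e-4) == pytest.approx(0.5)
        assert sk_inf(0.0) == 0.0
        # 2x EC50 -> 2^5.4/(1+2^5.4)
        x = 2.0 ** 5.4
        assert sk_inf(1.14e-3) == pytest.approx(x / (1 + x), rel=1e-9)
        assert sk_inf(1.14e-3) == pytest.approx(0.977, abs=1e-3)


class TestGHK:
    def test_equilibrium_zero(self):
        assert ghk_current(1e-7, 0.0, 2.0, 2.0) == pytest.approx(0.0, abs=1e-18)

    def test_zero_at_nernst(self):
        from mspncalc.channels import FARADAY, GAS_CONSTANT
        ca_in, ca_out, temp = 1e-4, 2.0, 305.0
        vrev = GAS_CONSTANT * temp / (2 * FARADAY) * np.log(ca_out / ca_in) * 1e3
        i = ghk_current(1e-7, vrev, ca_in, ca_out, temp)
        assert abs(i) < 1e-12 * abs(ghk_current(1e-7, -80.0, ca_in, ca_out, temp))

    def test_v_to_zero_limit(self):
        # the removed singularity equals the analytic limit P z F (cin - cout)
        from mspncalc.channels import FARADAY
        p, cin, cout = 1e-7, 1e-5, 2.0
        limit = p * 2.0 * FARADAY * (cin - cout)
        assert ghk_current(p, 0.0, cin, cout) == pytest.approx(limit, rel=1e-9)
        for eps in (1e-6, -1e-6):
            assert ghk_current(p, eps, cin, cout) == pytest.approx(limit, rel=1e-6)

    def test_inward_at_rest(self):
        assert ghk_current(1e-7, -80.0, 5e-5, 2.0) < 0


class TestChannelCurrent:
    def test_zero_at_reversal_and_closed(self, lib):
        naf = lib["NaF"]
        assert channel_current(naf, [0.5, 0.5], naf.reversal, 90000.0) == 0.0
        assert channel_current(naf, [0.0, 0.5], 0.0, 90000.0) == 0.0

    def test_somatic_naf_arithmetic(self, lib):
        # Gbar 90,000 S/m^2, m = h = 0.5, v = 0, ENa = +50 mV
        i = channel_current(lib["NaF"], [0.5, 0.5], 0.0, 90000.0)
        assert i == pytest.approx(90000.0 * 0.5 ** 3 * 0.5 * (-0.050), rel=1e-9)

    def test_ohmic_sign_change_at_reversal(self, lib):
        kir = lib["Kir"]
        below = channel_current(kir, [0.5], kir.reversal - 5.0, 8.0)
        above = channel_current(kir, [0.5], kir.reversal + 5.0, 8.0)
        assert below < 0 < above

    def test_gate_state_validated(self, lib):
        with pytest.raises(ValueError):
            channel_current(lib["Kir"], [1.5], 0.0, 8.0)


def test_density_table_regions(densities):
    regions = {"soma", "prox_dend", "mid_dend", "dist_dend", "spine"}
    for name, table in densities.items():
        assert set(table) == regions, name
        assert all(v >= 0 for v in table.values())
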