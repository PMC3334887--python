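"""Solver-level behavior: settling, determinism, AP detection, protocols.

These tests run the compiled model briefly; the slow pairing sweeps live in
the acceptance suite.
"""

import numpy as np
import pytest

import mspncalc as m
from mspncalc import simulation as sim


@pytest.fixture(scope="module")
def pack():
    cell = m.MSPNCell()
    settings = m.SolverSettings()
    compiled = cell.compile(settings.dt)
    state, rest = sim.initialize(compiled, settings, cell=cell)
    return cell, compiled, settings, state, rest


class TestInitialization:
    def test_resting_potential_near_target(self, pack):
        _, _, _, _, rest = pack
        target = m.PassiveParams().resting_potential_target
        assert rest == pytest.approx(target, abs=2.0)

    def test_stimulus_free_run_is_stationary(self, pack):
        cell, compiled, settings, state, rest = pack
        tr, _ = sim.integrate(compiled, sim.StimulusProgram(duration=1.0),
                              state, settings, record_v=["soma"], record_ca=[])
        assert np.all(np.abs(tr.v["soma"] - rest) < 1.0)

    def test_gates_at_steady_state_after_settling(self, pack):
        cell, compiled, settings, state, _ = pack
        # voltage-table gates must sit at inf(v) for each compartment
        from mspncalc.model import GATE_TABLE
        v_mv = state.v * 1e3
        x = np.clip((v_mv - compiled.vmin) / compiled.dv, 0,
                    compiled.inf_tab.shape[1] - 1.001)
        j = x.astype(int)
        w = x - j
        for gk in range(compiled.inf_tab.shape[0]):
            if compiled.special[gk] != GATE_TABLE:
                continue
            inf = (compiled.inf_tab[gk, j] * (1 - w)
                   + compiled.inf_tab[gk, j + 1] * w)
            # slow gates (KaS inactivation has a ~1 s time constant) still
            # track the last mV of settling drift; 2% bounds all of them
            assert np.max(np.abs(state.gates[gk] - inf)) < 0.02

    def test_gate_states_bounded(self, pack):
        *_, state, _ = pack
        assert np.all((state.gates >= 0.0) & (state.gates <= 1.0))
        assert np.all(state.ca_pools >= 0.0)

    def test_settling_is_deterministic(self, pack):
        cell, compiled, settings, state, _ = pack
        again, _ = sim.initialize(compiled, settings, cell=cell)
        np.testing.assert_array_equal(state.v, again.v)
        np.testing.assert_array_equal(state.gates, again.gates)


class TestDeterminism:
    def test_identical_runs_bit_identical(self, pack):
        cell, compiled, settings, state, _ = pack
        program = sim.StimulusProgram(
            duration=0.2, steps=[sim.CurrentStep(0.05, 0.1, 300e-12)],
            events=[m.SynapticEvent(time=0.06, spine_id=cell.stim_spines[0])])
        tr1, _ = sim.integrate(compiled, program, state, settings, cell=cell)
        tr2, _ = sim.integrate(compiled, program, state, settings, cell=cell)
        for key in tr1.v:
            np.testing.assert_array_equal(tr1.v[key], tr2.v[key])
        for key in tr1.ca:
            np.testing.assert_array_equal(tr1.ca[key], tr2.ca[key])


class TestAPDetection:
    def test_subthreshold_trace_empty(self):
        t = np.arange(0, 0.1, 1e-4)
        assert sim.find_ap_peaks(t, np.full_like(t, -70.0)).size == 0

    def test_two_constructed_peaks(self):
        t = np.arange(0, 0.1, 1e-4)
        v = np.full_like(t, -80.0)
        for pt in (0.03, 0.07):
            v += 110.0 * np.exp(-((t - pt) / 1e-3) ** 2)
        peaks = sim.find_ap_peaks(t, v)
        assert peaks.size == 2
        np.testing.assert_allclose(peaks, [0.03, 0.07], atol=1e-3)

    def test_refractory_spacing_merges_close_maxima(self):
        t = np.arange(0, 0.05, 1e-4)
        v = np.full_like(t, -80.0)
        v += 110.0 * np.exp(-((t - 0.02) / 3e-4) ** 2)
        v += 100.0 * np.exp(-((t - 0.0208) / 3e-4) ** 2)
        assert sim.find_ap_peaks(t, v).size == 1


class TestMinimalCurrent:
    def test_threshold_bracketing_30ms(self, pack):
        cell, compiled, settings, state, _ = pack
        amp = sim.min_current_single_ap(compiled, state, 30e-3, settings)

        def n_spikes(a):
            program = sim.StimulusProgram(
                duration=0.15, steps=[sim.CurrentStep(0.02, 30e-3, a)])
            tr, _ = sim.integrate(compiled, program, state, settings,
                                  record_v=["soma"], record_ca=[])
            return sim.count_aps(tr.time, tr.v["soma"])

        assert n_spikes(amp) == 1
        assert n_spikes(amp - 1e-12) == 0

    def test_strength_duration_tradeoff(self, pack):
        cell, compiled, settings, state, _ = pack
        amp5 = sim.min_current_single_ap(compiled, state, 5e-3, settings)
        amp30 = sim.min_current_single_ap(compiled, state, 30e-3, settings)
        assert amp5 > amp30


class TestIVProtocol:
    @pytest.fixture(scope="class")
    def iv(self, pack):
        cell, compiled, settings, state, _ = pack
        return sim.iv_protocol(compiled, state, settings)

    def test_fifteen_steps(self, iv):
        amps, defl, traces = iv
        assert len(amps) == 15
        np.testing.assert_allclose(amps[0], -500e-12)
        np.testing.assert_allclose(amps[-1], 200e-12, rtol=1e-9)

    def test_zero_step_zero_deflection(self, iv):
        amps, defl, _ = iv
        i0 = int(np.argmin(np.abs(amps)))
        assert abs(defl[i0]) < 0.5

    def test_inward_rectification(self, iv):
        # Kir makes the cell leakier when strongly hyperpolarized
        amps, defl, _ = iv
        r_strong = defl[0] / (amps[0] * 1e12)    # mV/pA at -500 pA
        i = int(np.argmin(np.abs(amps + 50e-12)))
        r_weak = defl[i] / (amps[i] * 1e12)
        assert 0 < r_strong < r_weak

    def test_deflections_monotone_in_current(self, iv):
        _, defl, _ = iv
        assert np.all(np.diff(defl) > 0)


class TestStimulusConstruction:
    def test_no_ap_control_has_no_steps(self):
        trial = sim.TrialConfig(delta_t=10.0, with_ap=False)
        program = sim.schedule_stdp_trial(trial, ["spineA", "spineB"],
                                          amplitude=4e-10, latency=0.01)
        assert program.steps == []
        assert len(program.events) == 2

    def test_step_onset_realizes_interval(self):
        trial = sim.TrialConfig(delta_t=11.0, protocol="dep30ms")
        program = sim.schedule_stdp_trial(trial, ["s"], amplitude=4e-10,
                                          latency=0.008, t_syn=0.2)
        assert program.steps[0].onset == pytest.approx(0.2 + 0.011 - 0.008)

    def test_triplet_three_steps_at_50hz(self):
        steps = sim.protocol_steps("triplet", onset=0.1, amplitude=5e-10)
        assert len(steps) == 3
        onsets = [s.onset for s in steps]
        np.testing.assert_allclose(np.diff(onsets), 20e-3)
        assert all(s.duration == pytest.approx(5e-3) for s in steps)

    def test_interval_bounds_validated(self):
        with pytest.raises(ValueError):
            sim.TrialConfig(delta_t=150.0)


class TestPoissonEvents:
    def test_zero_rate_empty(self):
        assert sim.poisson_events(0.0, 10.0, ["a", "b"], seed=3) == []

    def test_seed_reproducibility(self):
        e1 = sim.poisson_events(5.0, 2.0, ["a", "b"], seed=42)
        e2 = sim.poisson_events(5.0, 2.0, ["a", "b"], seed=42)
        assert [(e.time, e.spine_id) for e in e1] == \
            [(e.time, e.spine_id) for e in e2]
        e3 = sim.poisson_events(5.0, 2.0, ["a", "b"], seed=43)
        assert [(e.time) for e in e3] != [(e.time) for e in e1]

    def test_count_within_poisson_interval(self):
        # 10 Hz for 10 s: 99% interval around 100 events
        events = sim.poisson_events(10.0, 10.0, ["a"], seed=7)
        assert 74 <= len(events) <= 127

    def test_events_sorted_and_in_range(self):
        events = sim.poisson_events(20.0, 1.0, ["a", "b", "c"], seed=1)
        times = [e.time for e in events]
        assert times == sorted(times)
        assert all(0 <= t < 1.0 for t in times)


def test_traceset_rejects_nonfinite():
    t = np.linspace(0, 1, 11)
    bad = np.full_like(t, np.nan)
    with pytest.raises(ValueError):
        sim.TraceSet(time=t, v={"soma": bad}, ca={})


def test_solver_settings_validation():
    with pytest.raises(ValueError):
        m.SolverSettings(dt=0.0)
    with pytest.raises(ValueError):
        m.SolverSettings(dt=1e-4, record_dt=1e-5)


def test_traceset_exports(tmp_path):
    t = np.linspace(0, 0.01, 11)
    ts = sim.TraceSet(time=t, v={"soma": np.full_like(t, -80.0)},
                      ca={"spine": np.linspace(0, 1, 11)})
    df = ts.to_frame()
    assert set(df["series"]) == {"v:soma", "ca:spine"}
    assert len(df) == 22
    h5 = tmp_path / "traces.h5"
    ts.to_hdf5(h5)
    import h5py
    with h5py.File(h5) as fh:
        np.testing.assert_allclose(fh["time_s"][:], t)
        np.testing.assert_allclose(fh["ca"]["spine"][:], ts.ca["spine"])
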