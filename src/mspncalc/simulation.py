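"""Time integration and stimulation protocols.

The solver advances the compiled cell with a backward-Euler cable solve and
exponential-Euler gate updates (see `_kernel`).  On top of it sit the
experiment primitives: steady-state initialization with a settling pre-run,
action-potential detection, rheobase-style minimal-current searches, the
three pairing protocols (30 ms depolarization to one AP, 5 ms
depolarization to one AP, 50 Hz AP triplet), pairing-interval scheduling,
Poisson background input, and the current-step I-V protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ._kernel import run_kernel
from .model import CompiledModel, MSPNCell, SimState
from .synapses import SynapticEvent

PROTOCOLS = ("dep30ms", "dep5ms", "triplet")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverSettings:
    """Integration controls; dt defaults to 25 us, all times in seconds."""

    dt: float = 25e-6
    record_dt: float = 1e-4
    settle_time: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.record_dt < self.dt:
            raise ValueError("record_dt must be >= dt")


@dataclass(frozen=True)
class CurrentStep:
    onset: float       # s
    duration: float    # s
    amplitude: float   # A
    compartment: str = "soma"


@dataclass
class StimulusProgram:
    """Executable trial description: somatic steps plus synaptic events."""

    duration: float
    steps: list[CurrentStep] = field(default_factory=list)
    events: list[SynapticEvent] = field(default_factory=list)


@dataclass
class TraceSet:
    """Recorded series on a common time base (voltages mV, calcium uM)."""

    time: np.ndarray
    v: dict[str, np.ndarray]
    ca: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for series in (*self.v.values(), *self.ca.values()):
            if series.shape != self.time.shape:
                raise ValueError("all series must share the time base")
            if not np.all(np.isfinite(series)):
                raise ValueError("non-finite samples in trace")

    def to_frame(self):
        """Tidy long-format table: time_s, series, value (mV or uM)."""
        import pandas as pd
        rows = []
        for prefix, group in (("v", self.v), ("ca", self.ca)):
            for name, series in group.items():
                rows.append(pd.DataFrame({
                    "time_s": self.time,
                    "series": f"{prefix}:{name}",
                    "value": series,
                }))
        return pd.concat(rows, ignore_index=True)

    def to_hdf5(self, path) -> None:
        """Write all series into an HDF5 container (groups ``v`` and ``ca``)."""
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_s", data=self.time)
            for group, series_map in (("v", self.v), ("ca", self.ca)):
                g = fh.create_group(group)
                for name, series in series_map.items():
                    g.create_dataset(name, data=series)


def _default_record_ids(cell: MSPNCell) -> list[str]:
    ids = ["soma"]
    for cid in ("p0", "p0.s0", "p0.s0.t0.seg1", "p0.s0.t0.seg3"):
        if cid in cell.morph:
            ids.append(cid)
    ids.extend(cell.stim_spines)
    return ids


def integrate(compiled: CompiledModel, program: StimulusProgram,
              state: SimState, settings: SolverSettings,
              cell: MSPNCell | None = None,
              record_v: list[str] | None = None,
              record_ca: list[str] | None = None,
              ) -> tuple[TraceSet, SimState]:
    """Run one trial from ``state`` (which is not modified) and record traces."""
    dt = settings.dt
    nsteps = int(round(program.duration / dt))
    rec_stride = max(int(round(settings.record_dt / dt)), 1)

    if record_v is None:
        record_v = _default_record_ids(cell) if cell is not None else ["soma"]
    if record_ca is None:
        record_ca = list(cell.stim_spines) if cell is not None else []
    rec_v_idx = np.asarray([compiled.comp_index[c] for c in record_v], dtype=np.int64)
    rec_ca_idx = np.asarray([compiled.comp_index[c] for c in record_ca], dtype=np.int64)

    nst = len(program.steps)
    stim_on = np.zeros(max(nst, 1))
    stim_off = np.zeros(max(nst, 1))
    stim_amp = np.zeros(max(nst, 1))
    stim_comp = np.zeros(max(nst, 1), dtype=np.int64)
    for q, st in enumerate(program.steps):
        stim_on[q] = st.onset
        stim_off[q] = st.onset + st.duration
        stim_amp[q] = st.amplitude
        stim_comp[q] = compiled.comp_index[st.compartment]
    if nst == 0:
        stim_off[0] = -1.0  # never active

    ev = sorted(program.events, key=lambda e: e.time)
    ev_times: list[float] = []
    ev_syn: list[int] = []
    for e in ev:
        for rec in e.receptor_set:
            key = (e.spine_id, rec)
            if key not in compiled.syn_index:
                raise SimulationError(f"no {rec} synapse on {e.spine_id!r}")
            ev_times.append(e.time)
            ev_syn.append(compiled.syn_index[key])
    ev_t = np.asarray(ev_times, dtype=float)
    ev_s = np.asarray(ev_syn, dtype=np.int64)

    out = state.copy()
    bk = compiled.bk
    sk = compiled.sk
    vrec, carec, ok, nrows = run_kernel(
        nsteps, dt,
        compiled.parent, compiled.cm, compiled.ga, compiled.gleak, compiled.eleak,
        stim_on, stim_off, stim_amp, stim_comp,
        compiled.special, compiled.inf_tab, compiled.fac_tab,
        compiled.vmin, compiled.dv,
        bk[0], bk[1], bk[2], bk[3], bk[4], bk[5], sk[0], sk[1], sk[2],
        compiled.ch_mode, compiled.ch_erev, compiled.ch_g1, compiled.ch_g2,
        compiled.ch_e1, compiled.ch_e2, compiled.ch_gbar, compiled.ch_pool,
        compiled.ca_out, compiled.rt_inv,
        compiled.pool_rest, compiled.pool_decay, compiled.pool_tau2fv,
        compiled.syn_comp, compiled.syn_gmax, compiled.syn_k,
        compiled.syn_faca, compiled.syn_facb, compiled.syn_erev,
        compiled.syn_mga, compiled.syn_mgscale, compiled.mg_conc,
        compiled.syn_kappa, compiled.nmda_ca_linear, compiled.eca,
        ev_t, ev_s,
        out.v, out.gates, out.ca_pools, out.syn_a, out.syn_b,
        rec_stride, rec_v_idx, rec_ca_idx,
    )
    if not ok:
        raise SimulationError("numerical divergence: |V| exceeded 200 mV")
    t = np.arange(nrows) * settings.record_dt
    traces = TraceSet(
        time=t,
        v={c: vrec[:nrows, i] * 1e3 for i, c in enumerate(record_v)},
        ca={c: carec[:nrows, i] * 1e3 for i, c in enumerate(record_ca)},
    )
    return traces, out


def initialize(compiled: CompiledModel, settings: SolverSettings,
               cell: MSPNCell | None = None,
               drift_tol: float = 0.5) -> tuple[SimState, float]:
    """Settle the model to steady state; returns (state, resting potential mV).

    Gates start at their steady-state values for the nominal resting
    potential and pools at rest, then a stimulus-free pre-run of at least
    ``settings.settle_time`` (>= 0.5 s) lets the true resting point emerge.
    A residual drift above ``drift_tol`` (mV/s) raises.
    """
    state = compiled.initial_state()
    program = StimulusProgram(duration=max(settings.settle_time, 0.5))
    traces, settled = integrate(compiled, program, state, settings, cell=cell,
                                record_v=["soma"], record_ca=[])
    vsoma = traces.v["soma"]
    tail = max(int(0.1 / settings.record_dt), 2)
    drift = abs(vsoma[-1] - vsoma[-tail]) / (settings.record_dt * tail)
    if drift > drift_tol:
        raise SimulationError(
            f"failed to settle: residual drift {drift:.3f} mV/s > {drift_tol}")
    return settled, float(vsoma[-1])


def find_ap_peaks(time: np.ndarray, v: np.ndarray, threshold: float = 0.0,
                  refractory: float = 2e-3) -> np.ndarray:
    """Times of action-potential peaks: local maxima above ``threshold`` (mV)
    separated by at least the refractory spacing."""
    if len(time) < 3:
        return np.empty(0)
    dt = time[1] - time[0]
    idx, _ = find_peaks(v, height=threshold,
                        distance=max(int(round(refractory / dt)), 1))
    return time[idx]


def count_aps(time, v, **kw) -> int:
    return int(find_ap_peaks(time, v, **kw).shape[0])


def min_current_single_ap(compiled: CompiledModel, state: SimState,
                          duration: float, settings: SolverSettings,
                          cell: MSPNCell | None = None,
                          max_amp: float = 2e-9,
                          resolution: float = 1e-12) -> float:
    """Smallest somatic step amplitude (A) of ``duration`` evoking exactly one AP.

    Bisection to 1 pA; the returned amplitude minus one step evokes none.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    onset = 0.02
    total = onset + duration + 0.1

    def n_spikes(amp: float) -> int:
        program = StimulusProgram(duration=total,
                                  steps=[CurrentStep(onset, duration, amp)])
        tr, _ = integrate(compiled, program, state, settings, cell=cell,
                          record_v=["soma"], record_ca=[])
        return count_aps(tr.time, tr.v["soma"])

    lo, hi = 0.0, max_amp
    if n_spikes(hi) < 1:
        raise SimulationError("no amplitude <= 2 nA evokes an AP")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if n_spikes(mid) >= 1:
            hi = mid
        else:
            lo = mid
    amp = hi
    if n_spikes(amp) != 1:
        raise SimulationError("threshold amplitude does not evoke exactly one AP")
    return amp


@dataclass(frozen=True)
class TrialConfig:
    """One pairing trial: protocol, interval, site, receptor condition."""

    delta_t: float                 # ms, AP-peak time minus presynaptic time
    protocol: str = "dep30ms"
    site: str = "secondary"
    with_ap: bool = True

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not -100.0 <= self.delta_t <= 100.0:
            raise ValueError("delta_t outside [-100, +100] ms")


def protocol_steps(protocol: str, onset: float, amplitude: float) -> list[CurrentStep]:
    """Somatic current steps of one protocol starting at ``onset``."""
    if protocol == "dep30ms":
        return [CurrentStep(onset, 30e-3, amplitude)]
    if protocol == "dep5ms":
        return [CurrentStep(onset, 5e-3, amplitude)]
    # AP triplet at 50 Hz: three 5 ms steps, 20 ms apart
    return [CurrentStep(onset + k * 20e-3, 5e-3, amplitude) for k in range(3)]


def schedule_stdp_trial(trial: TrialConfig, spines: list[str],
                        amplitude: float, latency: float,
                        t_syn: float = 0.2,
                        peak_window: float = 0.5) -> StimulusProgram:
    """Build the stimulus program realizing a pairing interval ``delta_t``.

    The somatic step onset is placed at ``t_syn + delta_t - latency`` where
    ``latency`` is the pre-calibrated delay from step onset to (first) AP
    peak, so the AP peak lands at ``t_syn + delta_t``.  The no-AP control
    simply omits the somatic steps.
    """
    events = [SynapticEvent(time=t_syn, spine_id=s) for s in spines]
    steps: list[CurrentStep] = []
    if trial.with_ap:
        onset = t_syn + trial.delta_t * 1e-3 - latency
        if onset < 0:
            raise SimulationError("t_syn too early for the requested delta_t")
        steps = protocol_steps(trial.protocol, onset, amplitude)
    duration = t_syn + peak_window
    return StimulusProgram(duration=duration, steps=steps, events=events)


def poisson_events(rate: float, duration: float, targets: list[str],
                   seed: int) -> list[SynapticEvent]:
    """Homogeneous Poisson event train per target spine (reproducible)."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    events: list[SynapticEvent] = []
    for spine in targets:
        if rate == 0:
            continue
        t = 0.0
        while True:
            t += rng.exponential(1.0 / rate)
            if t >= duration:
                break
            events.append(SynapticEvent(time=t, spine_id=spine))
    return sorted(events, key=lambda e: e.time)


def iv_protocol(compiled: CompiledModel, state: SimState,
                settings: SolverSettings, cell: MSPNCell | None = None,
                amplitudes: np.ndarray | None = None,
                step_duration: float = 0.5):
    """Current steps from -500 to +200 pA in 50 pA increments.

    Returns (amplitudes A, steady-state deflections mV, traces); the
    deflection is the mean voltage over the last 100 ms of the step minus
    the pre-step rest.
    """
    if amplitudes is None:
        amplitudes = np.arange(-500e-12, 200e-12 + 1e-15, 50e-12)
    onset = 0.1
    total = onset + step_duration + 0.1
    deflections = []
    traces = []
    for amp in amplitudes:
        program = StimulusProgram(
            duration=total, steps=[CurrentStep(onset, step_duration, amp)])
        tr, _ = integrate(compiled, program, state, settings, cell=cell,
                          record_v=["soma"], record_ca=[])
        t = tr.time
        v = tr.v["soma"]
        rest = v[(t > onset - 0.05) & (t < onset)].mean()
        tail = v[(t > onset + step_duration - 0.1) & (t < onset + step_duration)]
        deflections.append(float(tail.mean() - rest))
        traces.append(tr)
    return np.asarray(amplitudes), np.asarray(deflections), traces
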