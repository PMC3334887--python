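"""High-level pairing experiments on the model cell.

`PairingExperiment` owns one fully configured cell (site, receptor
condition, protocol), settles it once, calibrates the somatic step
amplitude (minimal current for exactly one AP plus a small margin) and the
step-onset-to-AP-peak latency once, and then runs pairing trials over
pairing intervals, sharing the settled state and the no-AP control between
trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import simulation as sim
from .model import MSPNCell
from .synapses import NMDASubunitParams, make_nmda


@dataclass
class TrialResult:
    delta_t: float            # ms (nominal; None-like nan for control)
    peak_ca: float            # uM, spine NMDA-pool peak in the window
    realized_dt: float        # ms, measured AP peak minus synaptic time
    traces: sim.TraceSet | None = None


@dataclass
class SweepResult:
    """Raw pairing sweep: per-interval peaks plus the shared no-AP control."""

    delta_ts: np.ndarray      # ms
    peaks: np.ndarray         # uM
    control_peak: float       # uM
    protocol: str
    site: str
    condition: str
    realized_dts: np.ndarray | None = None


class PairingExperiment:
    """One cell + protocol; runs calibrated pairing trials.

    Parameters mirror `MSPNCell`; ``margin`` is the current added above the
    minimal single-AP amplitude (the protocol only specifies "depolarization
    to one AP").  With the small default margin the cell's long
    latency-to-first-spike places the AP near the end of the
    depolarization, which keeps negative pairing intervals free of
    step/glutamate overlap; the calibration enforces exactly one AP (the
    margin is halved back automatically if a second spike appears).
    """

    def __init__(self, protocol: str = "dep30ms", site: str = "secondary",
                 nmda: NMDASubunitParams | None = None,
                 settings: sim.SolverSettings | None = None,
                 background_spines: int = 0,
                 margin: float = 10e-12,
                 t_syn: float = 0.2,
                 peak_window: float = 0.5,
                 keep_traces: bool = False,
                 config: dict | None = None):
        if protocol not in sim.PROTOCOLS:
            raise ValueError(f"unknown protocol {protocol!r}")
        self.protocol = protocol
        self.site = site
        self.settings = settings or sim.SolverSettings()
        self.margin = margin
        self.t_syn = t_syn
        self.peak_window = peak_window
        self.keep_traces = keep_traces
        self.cell = MSPNCell(site=site, nmda=nmda or make_nmda("GluN2A+B"),
                             background_spines=background_spines, config=config)
        self.compiled = self.cell.compile(self.settings.dt)
        self.state, self.rest = sim.initialize(self.compiled, self.settings,
                                               cell=self.cell)
        self._amplitude: float | None = None
        self._latency: float | None = None
        self._control: TrialResult | None = None
        self.calibration_log: dict[str, float] = {"rest_mV": self.rest}

    # -- calibration -----------------------------------------------------
    @property
    def step_duration(self) -> float:
        return 30e-3 if self.protocol == "dep30ms" else 5e-3

    def calibrate(self) -> tuple[float, float]:
        """(step amplitude A, onset->AP-peak latency s), computed once."""
        if self._amplitude is None:
            base = sim.min_current_single_ap(
                self.compiled, self.state, self.step_duration, self.settings,
                cell=self.cell)
            amp = base + self.margin
            if self.protocol == "triplet":
                # each of the three 5 ms steps must fire; the AHP after the
                # first spike raises the threshold of the later steps
                for _ in range(60):
                    if self._n_spikes(amp) >= 3:
                        break
                    amp *= 1.1
                if self._n_spikes(amp) != 3:
                    raise sim.SimulationError(
                        "triplet calibration did not yield exactly 3 APs")
            else:
                # the margin must not recruit a second AP within the step
                for _ in range(40):
                    if self._n_spikes(amp) <= 1 or amp <= base:
                        break
                    amp = base + 0.5 * (amp - base)
            self._amplitude = amp
            self._latency = self._measure_latency(amp)
            self.calibration_log.update(
                amplitude_pA=self._amplitude * 1e12,
                latency_ms=self._latency * 1e3)
        return self._amplitude, self._latency

    def _n_spikes(self, amp: float) -> int:
        onset = 0.02
        program = sim.StimulusProgram(
            duration=onset + 0.15,
            steps=sim.protocol_steps(self.protocol, onset, amp))
        tr, _ = sim.integrate(self.compiled, program, self.state, self.settings,
                              record_v=["soma"], record_ca=[])
        return sim.count_aps(tr.time, tr.v["soma"])

    def _measure_latency(self, amp: float) -> float:
        onset = 0.05
        program = sim.StimulusProgram(
            duration=onset + 0.15,
            steps=sim.protocol_steps(self.protocol, onset, amp))
        tr, _ = sim.integrate(self.compiled, program, self.state, self.settings,
                              record_v=["soma"], record_ca=[])
        peaks = sim.find_ap_peaks(tr.time, tr.v["soma"])
        if peaks.shape[0] == 0:
            raise sim.SimulationError("calibration step evoked no AP")
        return float(peaks[0] - onset)

    # -- trials ----------------------------------------------------------
    def run_trial(self, delta_t: float | None, with_ap: bool = True,
                  extra_events=None, keep_traces: bool | None = None
                  ) -> TrialResult:
        """One pairing trial; ``with_ap=False`` (or delta_t None) runs the
        no-AP control.  The realized AP peak must land within +-1 ms of the
        nominal interval (one recalibration is attempted, except when
        background input deliberately jitters the spike)."""
        if delta_t is None:
            with_ap = False
            delta_t = 0.0
        amp, lat = self.calibrate() if with_ap else (0.0, 0.0)
        trial = sim.TrialConfig(delta_t=delta_t, protocol=self.protocol,
                                site=self.site, with_ap=with_ap)
        program = sim.schedule_stdp_trial(
            trial, self.cell.stim_spines, amp, lat,
            t_syn=self.t_syn, peak_window=self.peak_window)
        jittered = bool(extra_events)
        if extra_events:
            program.events = sorted(program.events + list(extra_events),
                                    key=lambda e: e.time)
        traces, _ = sim.integrate(self.compiled, program, self.state,
                                  self.settings, cell=self.cell)
        realized = self._realized_dt(traces)
        if with_ap and not jittered and not np.isnan(realized) \
                and abs(realized - delta_t) > 0.25:
            # one recalibration with the realized latency; the hard +-1 ms
            # contract is enforced after it
            self._latency = lat + (realized - delta_t) * 1e-3
            program = sim.schedule_stdp_trial(
                trial, self.cell.stim_spines, amp, self._latency,
                t_syn=self.t_syn, peak_window=self.peak_window)
            traces, _ = sim.integrate(self.compiled, program, self.state,
                                      self.settings, cell=self.cell)
            realized = self._realized_dt(traces)
            if abs(realized - delta_t) > 1.0:
                raise sim.SimulationError(
                    f"realized delta_t {realized:.2f} ms misses nominal "
                    f"{delta_t:.2f} ms by more than 1 ms")
        peak = self._peak_ca(traces)
        keep = self.keep_traces if keep_traces is None else keep_traces
        return TrialResult(delta_t=delta_t if with_ap else float("nan"),
                           peak_ca=peak, realized_dt=realized,
                           traces=traces if keep else None)

    def _realized_dt(self, traces: sim.TraceSet) -> float:
        peaks = sim.find_ap_peaks(traces.time, traces.v["soma"])
        if peaks.shape[0] == 0:
            return float("nan")
        return float((peaks[0] - self.t_syn) * 1e3)

    def _peak_ca(self, traces: sim.TraceSet) -> float:
        t = traces.time
        ca = traces.ca[self.cell.recorded_spine]
        win = (t >= self.t_syn) & (t <= self.t_syn + self.peak_window)
        return float(ca[win].max())

    def control(self) -> TrialResult:
        if self._control is None:
            self._control = self.run_trial(None, with_ap=False)
        return self._control

    def sweep(self, delta_ts, extra_events_fn=None) -> SweepResult:
        """Run trials at each pairing interval plus the shared control.

        ``extra_events_fn(delta_t)`` may supply background events per trial.
        """
        delta_ts = np.asarray(list(delta_ts), dtype=float)
        if delta_ts.size == 0:
            raise ValueError("sweep needs at least one pairing interval")
        peaks = np.empty(delta_ts.shape)
        realized = np.empty(delta_ts.shape)
        for i, dtms in enumerate(delta_ts):
            extra = extra_events_fn(dtms) if extra_events_fn else None
            res = self.run_trial(float(dtms), extra_events=extra)
            peaks[i] = res.peak_ca
            realized[i] = res.realized_dt
        control = self.control().peak_ca
        return SweepResult(delta_ts=delta_ts, peaks=peaks, control_peak=control,
                           protocol=self.protocol, site=self.site,
                           condition=self.cell.nmda.label,
                           realized_dts=realized)


def jitter_sweep(base: PairingExperiment, delta_ts, rates_hz, seeds,
                 n_background: int = 40) -> list[SweepResult]:
    """Repeat a sweep with low-level Poisson background input on extra spines.

    One sweep per (rate, seed) pair; background events jitter the AP within
    the somatic depolarization without changing the nominal intervals.
    """
    results = []
    for rate, seed in zip(rates_hz, seeds):
        exp = PairingExperiment(
            protocol=base.protocol, site=base.site, nmda=base.cell.nmda,
            settings=base.settings, background_spines=n_background,
            margin=base.margin, t_syn=base.t_syn, peak_window=base.peak_window)

        def events_for(_dtms, _rate=rate, _seed=seed, _exp=exp):
            return sim.poisson_events(
                _rate, _exp.t_syn + _exp.peak_window,
                _exp.cell.background_spines_ids, _seed)

        # the tonic background depolarization systematically shortens the
        # first-spike latency; absorb that mean shift with one pilot trial
        # (the experimenter keeps the AP on target), leaving the
        # event-realization jitter in place
        exp.calibrate()
        offsets = []
        for d in (float(delta_ts[0]), float(delta_ts[-1])):
            pilot = exp.run_trial(d, extra_events=events_for(d))
            if not np.isnan(pilot.realized_dt):
                offsets.append(pilot.realized_dt - d)
        if offsets:
            exp._latency += float(np.mean(offsets)) * 1e-3
        results.append(exp.sweep(delta_ts, extra_events_fn=events_for))
    return results
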