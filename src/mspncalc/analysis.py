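"""Summary measures: peak calcium, normalization, pairing curves, AP metrics.

Everything here is pure post-processing of recorded traces or sweep
results; the normalization (percent of the no-AP control) makes the curves
invariant to any overall calcium scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiments import SweepResult
from .simulation import find_ap_peaks


class AnalysisError(ValueError):
    pass


@dataclass
class CalciumCurve:
    """Normalized peak-calcium-vs-pairing-interval curve (percent of control)."""

    delta_t: np.ndarray          # ms, sorted ascending
    normalized_peak: np.ndarray  # % of no-AP control
    control_peak: float          # uM
    protocol: str = ""
    site: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if np.any(self.normalized_peak <= 0):
            raise AnalysisError("normalized peaks must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "delta_t_ms": self.delta_t,
            "normalized_peak_pct": self.normalized_peak,
            "protocol": self.protocol,
            "site": self.site,
            "condition": self.condition,
        })


@dataclass
class APMetrics:
    half_width: float | None       # ms
    latency_to_first_spike: float | None  # ms
    spike_count: int
    rheobase: float | None = None  # pA

    def __post_init__(self) -> None:
        if self.spike_count > 0 and self.half_width is not None \
                and self.half_width <= 0:
            raise AnalysisError("half width must be positive when a spike exists")


def peak_in_window(time: np.ndarray, series: np.ndarray,
                   window: tuple[float, float]) -> tuple[float, float]:
    """Maximum of a series restricted to [t0, t1]; returns (value, time)."""
    t0, t1 = window
    mask = (time >= t0) & (time <= t1)
    if not np.any(mask):
        raise AnalysisError("empty analysis window")
    seg = series[mask]
    tseg = time[mask]
    i = int(np.argmax(seg))
    return float(seg[i]), float(tseg[i])


def normalize_percent(peak: float, control_peak: float) -> float:
    """Peak as a percentage of the no-AP control peak."""
    if control_peak <= 0:
        raise AnalysisError("control peak must be positive")
    return 100.0 * peak / control_peak


def ap_threshold_time(time: np.ndarray, v: np.ndarray, peak_time: float,
                      dvdt_crit: float = 10.0) -> tuple[float, float]:
    """(threshold time, threshold voltage) by the dV/dt criterion (mV/ms),
    searching backward from the AP peak."""
    dt_ms = (time[1] - time[0]) * 1e3
    ip = int(np.searchsorted(time, peak_time))
    dvdt = np.gradient(v, dt_ms)
    i = min(ip, len(v) - 1)
    while i > 0 and dvdt[i] < dvdt_crit:   # step back off the peak top
        i -= 1
    while i > 0 and dvdt[i] >= dvdt_crit:  # walk down the upstroke
        i -= 1
    return float(time[i]), float(v[i])


def ap_halfwidth(time: np.ndarray, v: np.ndarray, peak_time: float,
                 dvdt_crit: float = 10.0) -> float:
    """Full width (ms) at half amplitude of one AP.

    Amplitude is measured from the dV/dt-threshold voltage to the peak;
    crossing times are linearly interpolated.
    """
    ip = int(np.argmin(np.abs(time - peak_time)))
    if v[ip] < np.max(v) - 200.0:  # not remotely a peak
        raise AnalysisError("no AP peak at the given time")
    _, vthr = ap_threshold_time(time, v, peak_time, dvdt_crit)
    vpeak = v[ip]
    if vpeak <= vthr:
        raise AnalysisError("no AP peak above threshold")
    vhalf = 0.5 * (vpeak + vthr)

    i = ip
    while i > 0 and v[i] > vhalf:
        i -= 1
    if v[i] == v[i + 1]:
        t_rise = time[i]
    else:
        t_rise = time[i] + (vhalf - v[i]) / (v[i + 1] - v[i]) * (time[i + 1] - time[i])
    j = ip
    while j < len(v) - 1 and v[j] > vhalf:
        j += 1
    if j == len(v) - 1 and v[j] > vhalf:
        raise AnalysisError("AP does not repolarize within the trace")
    if v[j] == v[j - 1]:
        t_fall = time[j]
    else:
        t_fall = time[j - 1] + (vhalf - v[j - 1]) / (v[j] - v[j - 1]) * (time[j] - time[j - 1])
    return float((t_fall - t_rise) * 1e3)


def latency_to_first_spike(time: np.ndarray, v: np.ndarray,
                           stimulus_onset: float) -> float | None:
    """First AP peak time minus stimulus onset (ms); None without a spike."""
    if not time[0] <= stimulus_onset <= time[-1]:
        raise AnalysisError("stimulus onset outside the trace")
    peaks = find_ap_peaks(time, v)
    peaks = peaks[peaks >= stimulus_onset]
    if peaks.shape[0] == 0:
        return None
    return float((peaks[0] - stimulus_onset) * 1e3)


def ap_metrics(time: np.ndarray, v: np.ndarray, stimulus_onset: float,
               rheobase: float | None = None) -> APMetrics:
    peaks = find_ap_peaks(time, v)
    if peaks.shape[0] == 0:
        return APMetrics(half_width=None, latency_to_first_spike=None,
                         spike_count=0, rheobase=rheobase)
    return APMetrics(
        half_width=ap_halfwidth(time, v, peaks[0]),
        latency_to_first_spike=latency_to_first_spike(time, v, stimulus_onset),
        spike_count=int(peaks.shape[0]),
        rheobase=rheobase)


def build_calcium_curve(sweep: SweepResult,
                        control_peak: float | None = None) -> CalciumCurve:
    """Normalize a pairing sweep by its (or an explicit) no-AP control peak.

    Passing ``control_peak`` supports normalizing one receptor condition by
    another condition's control (e.g. a GluN2B-blocked curve by the intact
    A+B control)."""
    ctrl = sweep.control_peak if control_peak is None else control_peak
    if ctrl is None or ctrl <= 0:
        raise AnalysisError("sweep lacks a positive no-AP control peak")
    order = np.argsort(sweep.delta_ts)
    return CalciumCurve(
        delta_t=sweep.delta_ts[order],
        normalized_peak=100.0 * sweep.peaks[order] / ctrl,
        control_peak=ctrl, protocol=sweep.protocol, site=sweep.site,
        condition=sweep.condition)


def threshold_crossing(curve: CalciumCurve, level: float) -> float | None:
    """Smallest positive pairing interval where the curve first falls below
    ``level`` (%), linearly interpolated between grid points; None if never."""
    dts = curve.delta_t
    vals = curve.normalized_peak
    pos = dts >= 0
    dts, vals = dts[pos], vals[pos]
    if dts.size == 0:
        return None
    # a descending crossing: the curve falls through the level; points where
    # the curve has not yet risen to the level do not count
    for i in range(1, dts.size):
        if vals[i - 1] >= level > vals[i]:
            f = (vals[i - 1] - level) / (vals[i - 1] - vals[i])
            return float(dts[i - 1] + f * (dts[i] - dts[i - 1]))
    if np.all(vals < level):
        return float(dts[0])
    return None
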