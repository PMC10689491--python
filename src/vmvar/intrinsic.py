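"""Current-step protocol analysis: excitability and passive properties.

From 500-ms current steps (-450 to +550 pA in 50-pA increments by default):
the f-I curve and rheobase, AP threshold (10 mV/ms rule) and half-width at the
rheobase sweep, spike-frequency accommodation (4th/1st inter-spike interval on
the lowest sweep with five spikes), the after-depolarization following brief
3-AP trains gated to downstates, and input resistance from the steady-state
deflection of the -100 pA sweep at 300 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spikes import APEvent, detect_aps
from .states import StateSegment, state_at
from .trace import StepProtocol, ValidationError, VmTrace

__all__ = [
    "IntrinsicSummary",
    "fi_curve",
    "ap_shape",
    "accommodation",
    "adp_amplitude",
    "input_resistance",
    "analyze_protocol",
]

IR_SWEEP_PA = -100.0
IR_MEASURE_S = 0.300  # after step onset
IR_MEASURE_HALF_WINDOW_S = 0.005
ADP_DELAY_S = 0.005


@dataclass
class IntrinsicSummary:
    fi: dict[float, int]  # current (pA) -> AP count
    rheobase: float | None  # pA
    max_ap_freq: float | None  # Hz
    ap_threshold: float | None  # mV
    first_ap_half_width: float | None  # ms
    hw_ratio_3_1: float | None
    accommodation: float | None  # 4th SI / 1st SI
    accommodation_sweep_pa: float | None
    input_resistance: float | None  # MOhm
    resting_vm: float | None  # mV


def _step_events(protocol: StepProtocol, sweep: VmTrace) -> list[APEvent]:
    """Spikes of one sweep restricted to the step window."""
    events = detect_aps(sweep)
    a, b = protocol.step_onset, protocol.step_onset + protocol.step_dur
    return [e for e in events if a <= e.peak_time < b]


def fi_curve(
    protocol: StepProtocol,
) -> tuple[dict[float, int], float | None, float | None]:
    """AP count per injected current, rheobase, and maximum firing frequency.

    Rheobase is the smallest current eliciting at least one spike (None when
    no sweep spikes); maximum frequency is the largest per-sweep count divided
    by the step duration.
    """
    counts: dict[float, int] = {}
    for current, sweep in zip(protocol.currents, protocol.sweeps):
        counts[float(current)] = len(_step_events(protocol, sweep))
    spiking = sorted(c for c, n in counts.items() if n >= 1)
    rheobase = spiking[0] if spiking else None
    max_freq = max(counts.values()) / protocol.step_dur if spiking else None
    return counts, rheobase, max_freq


def ap_shape(
    protocol: StepProtocol, rheobase: float
) -> tuple[float, float | None, float | None]:
    """Threshold, first-AP half-width, and 3rd/1st half-width ratio at rheobase.

    The half-width ratio needs at least three spikes in the sweep and is
    otherwise None.
    """
    sweep = protocol.sweep_at(rheobase)
    events = _step_events(protocol, sweep)
    if not events:
        raise ValidationError("rheobase sweep contains no spikes")
    first = events[0]
    hw_ratio = None
    if len(events) >= 3:
        hw3, hw1 = events[2].half_width, first.half_width
        if hw3 is not None and hw1 is not None and hw1 > 0:
            hw_ratio = hw3 / hw1
    return first.threshold_vm, first.half_width, hw_ratio


def accommodation(
    protocol: StepProtocol,
) -> tuple[float | None, float | None]:
    """Spike-frequency accommodation: 4th/1st inter-spike interval.

    Uses the first five spikes of the lowest-current sweep containing at least
    five; returns ``(ratio, sweep_current_pa)``, both None when no sweep
    qualifies.
    """
    for current, sweep in zip(protocol.currents, protocol.sweeps):
        events = _step_events(protocol, sweep)
        if len(events) >= 5:
            peaks = np.array([e.peak_time for e in events[:5]])
            isis = np.diff(peaks)
            return float(isis[3] / isis[0]), float(current)
    return None, None


def adp_amplitude(
    trace: VmTrace,
    train_times: list[float],
    segments: list[StateSegment],
    baseline_window_s: float = 0.05,
    max_trials: int = 6,
) -> float:
    """After-depolarization amplitude from averaged downstate 3-AP trains.

    Only trains whose onset falls inside a downstate qualify; three to six
    eligible trials (the first six in temporal order) are averaged, and the
    ADP is the mean Vm 5 ms after the peak of the last spike minus the
    pre-train baseline.
    """
    eligible = [t for t in sorted(train_times) if state_at(segments, t) == "down"]
    if len(eligible) < 3:
        raise ValidationError(
            f"only {len(eligible)} downstate train(s); at least 3 required"
        )
    eligible = eligible[:max_trials]
    fs = trace.fs
    pre = int(round(baseline_window_s * fs))
    gap = int(round(0.005 * fs))  # keep the first spike's foot out of baseline
    post = int(round(0.08 * fs))
    snippets, baselines = [], []
    for t in eligible:
        i0 = trace.index_of(t)
        if i0 - gap - pre < 0 or i0 + post > trace.n_samples:
            continue
        snippets.append(trace.samples[i0 - pre : i0 + post])
        baselines.append(np.mean(trace.samples[i0 - gap - pre : i0 - gap]))
    if len(snippets) < 3:
        raise ValidationError("fewer than 3 complete train snippets")
    avg = np.mean(snippets, axis=0)
    baseline = float(np.mean(baselines))
    seg = VmTrace(samples=avg, fs=fs)
    events = detect_aps(seg)
    if not events:
        raise ValidationError("no spikes detected in the averaged train")
    i_last_peak = seg.index_of(events[-1].peak_time)
    i_adp = i_last_peak + int(round(ADP_DELAY_S * fs))
    if i_adp >= avg.size:
        raise ValidationError("ADP measurement point beyond the snippet")
    return float(avg[i_adp] - baseline)


def input_resistance(protocol: StepProtocol) -> float:
    """Input resistance (MOhm) from the -100 pA sweep.

    The deflection is the mean Vm over a 10-ms window centered 300 ms after
    step onset, relative to the pre-step baseline; R = dV / I.
    """
    sweep = protocol.sweep_at(IR_SWEEP_PA)
    base = np.mean(sweep.window(0.0, protocol.step_onset))
    t_meas = protocol.step_onset + IR_MEASURE_S
    v_ss = np.mean(
        sweep.window(t_meas - IR_MEASURE_HALF_WINDOW_S, t_meas + IR_MEASURE_HALF_WINDOW_S)
    )
    dv = float(v_ss - base)  # mV
    return dv / (IR_SWEEP_PA * 1e-3)  # mV / nA = MOhm


def analyze_protocol(protocol: StepProtocol) -> IntrinsicSummary:
    """Full intrinsic-property summary for one cell's step protocol."""
    fi, rheobase, max_freq = fi_curve(protocol)
    thr = hw = hw_ratio = None
    if rheobase is not None:
        thr, hw, hw_ratio = ap_shape(protocol, rheobase)
    accom, accom_sweep = accommodation(protocol)
    try:
        r_in = input_resistance(protocol)
    except ValidationError:
        r_in = None
    resting = None
    if protocol.sweeps:
        resting = float(np.mean(protocol.sweeps[0].window(0.0, protocol.step_onset)))
    return IntrinsicSummary(
        fi=fi,
        rheobase=rheobase,
        max_ap_freq=max_freq,
        ap_threshold=thr,
        first_ap_half_width=hw,
        hw_ratio_3_1=hw_ratio,
        accommodation=accom,
        accommodation_sweep_pa=accom_sweep,
        input_resistance=r_in,
        resting_vm=resting,
    )
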