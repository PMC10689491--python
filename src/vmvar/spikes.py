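"""Action-potential detection and spontaneous/evoked spiking metrics.

Spikes are detected where the (lightly smoothed) voltage derivative crosses
+10 mV/ms and the subsequent peak rises at least 30 mV above the voltage at
the crossing within 5 ms; a 2-ms refractory window suppresses doublet
re-triggering. The membrane potential at the derivative crossing is the AP
threshold; half-width is measured at half amplitude between threshold and
peak.

Evoked firing per trial is the post-stimulus spike count minus the
pre-stimulus count (200-ms windows, negative values retained); onset jitter is
the SD of first-spike latencies inside a 70-ms post-stimulus window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import TrialSet, ValidationError, VmTrace

__all__ = [
    "APEvent",
    "CellAPSummary",
    "detect_aps",
    "spontaneous_metrics",
    "evoked_counts",
    "first_ap_jitter",
    "classify_cell",
]

DVDT_THRESHOLD = 10.0  # mV/ms
MIN_PROMINENCE = 30.0  # mV above threshold-crossing Vm within the search window
PEAK_SEARCH_MS = 5.0
REFRACTORY_MS = 2.0
SMOOTH_MS = 0.1
SPONT_WINDOW_S = 120.0
FIRST_AP_WINDOW_S = 0.070


@dataclass
class APEvent:
    onset_time: float  # s, dV/dt threshold crossing
    peak_time: float  # s
    peak_vm: float  # mV
    threshold_vm: float  # mV at the crossing
    half_width: float | None  # ms at half amplitude (threshold -> peak)


@dataclass
class CellAPSummary:
    is_active: bool
    spont_rate: float  # Hz over the spontaneous window
    evoked_mean: float | None
    evoked_cv: float | None
    ap_per_successful_trial: float | None
    first_ap_onsets_ms: np.ndarray
    ap_jitter_ms: float | None
    outcome_fractions: dict[str, float] = field(default_factory=dict)
    cell_class: str | None = None  # "AP-EPSP" | "EPSP-only"


def events_to_frame(events: list["APEvent"], cell_id: str,
                    context: str = "spont") -> "pd.DataFrame":
    """AP event table (cell_id, onset_s, peak_s, threshold_mv, half_width_ms,
    context in {spont, pre, post}) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"cell_id": cell_id, "onset_s": e.onset_time, "peak_s": e.peak_time,
             "threshold_mv": e.threshold_vm, "half_width_ms": e.half_width,
             "context": context}
            for e in events
        ]
    )


def _smooth(x: np.ndarray, fs: float, width_ms: float) -> np.ndarray:
    n = max(int(round(width_ms * fs / 1000.0)), 1)
    if n % 2 == 0:
        n += 1  # odd window keeps the filter zero-phase
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def detect_aps(
    trace: VmTrace,
    dvdt_threshold: float = DVDT_THRESHOLD,
    min_prominence: float = MIN_PROMINENCE,
    refractory_ms: float = REFRACTORY_MS,
    smooth_ms: float = SMOOTH_MS,
) -> list[APEvent]:
    """Detect spikes in a trace; returns an empty list for spike-free traces.

    Requires fs >= 10 kHz so the upstroke is resolved well enough for the
    derivative criterion.
    """
    if trace.fs < 10_000:
        raise ValidationError("spike detection requires fs >= 10 kHz")
    x = _smooth(trace.samples, trace.fs, smooth_ms)
    dvdt = np.gradient(x) * trace.fs / 1000.0  # mV/ms
    raw = trace.samples
    # forward-difference slope of interval [k, k+1], mV/ms
    dvdt_raw = np.diff(raw) * trace.fs / 1000.0
    crossings = np.flatnonzero((dvdt[:-1] < dvdt_threshold) & (dvdt[1:] >= dvdt_threshold)) + 1
    events: list[APEvent] = []
    search = int(round(PEAK_SEARCH_MS * trace.fs / 1000.0))
    refractory = int(round(refractory_ms * trace.fs / 1000.0))
    last_peak = -np.inf
    for i in crossings:
        hi = min(i + search, raw.size)
        if hi - i < 2:
            continue
        j = i + int(np.argmax(raw[i:hi]))
        if j - last_peak < refractory:
            continue
        # refine the crossing on the raw derivative near the detection — the
        # smoothing stencil leaks the upstroke a couple of samples early
        k = i
        for cand in range(max(i - 4, 1), min(i + 5, j, dvdt_raw.size)):
            if dvdt_raw[cand - 1] < dvdt_threshold <= dvdt_raw[cand]:
                k = cand
                break
        denom = dvdt_raw[k] - dvdt_raw[k - 1] if 0 < k < dvdt_raw.size else 0.0
        frac = (dvdt_threshold - dvdt_raw[k - 1]) / denom if denom else 0.0
        frac = float(np.clip(frac, 0.0, 1.0))
        thr_vm = float(raw[k] + frac * (raw[k + 1] - raw[k])) if k + 1 < raw.size else float(raw[k])
        peak_vm = float(raw[j])
        if peak_vm - thr_vm < min_prominence:
            continue
        events.append(
            APEvent(
                onset_time=trace.t0 + (k + frac) / trace.fs,
                peak_time=trace.t0 + j / trace.fs,
                peak_vm=peak_vm,
                threshold_vm=thr_vm,
                half_width=_ap_half_width(raw, k, j, thr_vm, peak_vm, trace.fs),
            )
        )
        last_peak = j
    return events


def _ap_half_width(
    x: np.ndarray, i_thr: int, i_peak: int, thr_vm: float, peak_vm: float, fs: float
) -> float | None:
    """Width (ms) at half amplitude between threshold and peak, interpolated."""
    level = thr_vm + (peak_vm - thr_vm) / 2.0
    # rising crossing between threshold and peak
    rise = None
    for k in range(i_peak, i_thr, -1):
        if x[k - 1] <= level < x[k] or x[k - 1] < level <= x[k]:
            frac = (level - x[k - 1]) / (x[k] - x[k - 1])
            rise = k - 1 + frac
            break
    # falling crossing after the peak
    fall = None
    for k in range(i_peak, min(i_peak + int(0.01 * fs), x.size - 1)):
        if x[k] >= level > x[k + 1]:
            frac = (x[k] - level) / (x[k] - x[k + 1])
            fall = k + frac
            break
    if rise is None or fall is None or fall <= rise:
        return None
    return float((fall - rise) * 1000.0 / fs)


def spontaneous_metrics(
    trace: VmTrace,
    window: float = SPONT_WINDOW_S,
    events: list[APEvent] | None = None,
) -> tuple[bool, float]:
    """Spontaneous activity over a stimulus-free window.

    A cell is active when it fires at least once within the window; the rate
    is the spike count over the window length. Silent cells return rate 0 and
    stay in population statistics.
    """
    if trace.duration < window:
        raise ValidationError(f"epoch shorter than the {window:g}-s spontaneous window")
    if events is None:
        events = detect_aps(trace)
    t_end = trace.t0 + window
    count = sum(1 for e in events if trace.t0 <= e.peak_time < t_end)
    return count >= 1, count / window


def evoked_counts(
    trialset: TrialSet, events: list[APEvent]
) -> tuple[np.ndarray, float | None, float | None, float | None]:
    """Per-trial evoked spike counts and their summary.

    evoked = post-stimulus count - pre-stimulus count (200-ms windows; negative
    values retained). The coefficient of variation is SD/mean of the evoked
    counts (undefined when the mean is 0); spikes per successful trial divides
    the total evoked count by the number of trials with at least one
    post-stimulus spike.
    """
    peaks = np.array([e.peak_time for e in events])
    evoked = np.empty(trialset.n_trials)
    successful = 0
    for i, t in enumerate(trialset.stim_times):
        pre = np.count_nonzero((peaks >= t - trialset.pre_window) & (peaks < t))
        post = np.count_nonzero((peaks >= t) & (peaks < t + trialset.post_window))
        evoked[i] = post - pre
        if post >= 1:
            successful += 1
    mean = float(np.mean(evoked))
    cv = float(np.std(evoked, ddof=1) / mean) if mean != 0 else None
    per_successful = float(np.sum(evoked) / successful) if successful else None
    return evoked, mean, cv, per_successful


def first_ap_jitter(
    trialset: TrialSet,
    events: list[APEvent],
    window: float = FIRST_AP_WINDOW_S,
) -> tuple[np.ndarray, float | None]:
    """First-spike onset latencies (ms) within ``window`` after each stimulus
    and their SD (the trial-by-trial onset jitter; None below 2 trials)."""
    onsets = np.array([e.onset_time for e in events])
    latencies = []
    for t in trialset.stim_times:
        inside = onsets[(onsets > t) & (onsets <= t + window)]
        if inside.size:
            latencies.append((inside[0] - t) * 1000.0)
    latencies = np.asarray(latencies)
    jitter = float(np.std(latencies, ddof=1)) if latencies.size >= 2 else None
    return latencies, jitter


def classify_cell(outcomes: list[str]) -> tuple[dict[str, float], str]:
    """Outcome fractions over the trial block and the response class.

    ``outcomes`` are per-trial labels from the EPSP analysis ("ap", "epsp",
    "failure"); a cell with at least one AP trial is AP-EPSP, otherwise
    EPSP-only. Fractions sum to 1 exactly.
    """
    if not outcomes:
        raise ValidationError("no trial outcomes")
    n = len(outcomes)
    fractions = {
        key: outcomes.count(key) / n for key in ("ap", "epsp", "failure")
    }
    cell_class = "AP-EPSP" if fractions["ap"] > 0 else "EPSP-only"
    return fractions, cell_class
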