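"""Two-state (up/down) segmentation of spontaneous membrane potential.

Every sample of a (drift-corrected) trace is labelled up or down, with no
intermediate state: a gliding threshold is computed once per second as the
median of all samples within 4 s before and after that second; each sample's
local median (50 ms before and after, truncated at the edges) is then compared
against the threshold of its containing second. Maximal same-label runs become
segments, and segments shorter than 100 ms are relabelled into their flanking
state (shortest first, until stable), so no sub-100-ms state survives.

Upstates lasting 100-150 ms are counted separately as "micro"-upstates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import ValidationError, VmTrace

__all__ = [
    "StateSegment",
    "StateSummary",
    "detrend_linear",
    "gliding_threshold",
    "segment_states",
    "summarize_states",
]

GLIDE_HALF_WINDOW_S = 4.0
LOCAL_MEDIAN_HALF_S = 0.05
MIN_STATE_DUR_S = 0.1
MICRO_UP_RANGE_S = (0.100, 0.150)


@dataclass
class StateSegment:
    label: str  # "up" | "down"
    start: float  # s, half-open [start, end)
    end: float
    mean_vm: float  # mV

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class StateSummary:
    up_dur_mean: float | None
    up_freq: float
    down_dur_mean: float | None
    down_freq: float
    dvm_updown: float | None  # undefined (None) when only one state present
    micro_count: int
    up_vm_norm: np.ndarray  # per-upstate mean Vm minus grand downstate mean


def segments_to_frame(segments: list[StateSegment]) -> pd.DataFrame:
    """Segmentation as a BED-like table (start_s, end_s, label, mean_vm_mv).

    Write with ``df.to_csv(path, sep="\\t", index=False)`` for the TSV form or
    ``df.to_json(path, orient="records")`` for JSON.
    """
    return pd.DataFrame(
        [
            {"start_s": s.start, "end_s": s.end, "label": s.label,
             "mean_vm_mv": s.mean_vm}
            for s in segments
        ]
    )


def detrend_linear(trace: VmTrace) -> VmTrace:
    """Remove the least-squares linear drift; the epoch mean is preserved."""
    if trace.n_samples < 2:
        raise ValidationError("detrending needs at least 2 samples")
    t = np.arange(trace.n_samples) / trace.fs
    slope, intercept = np.polyfit(t, trace.samples, 1)
    detrended = trace.samples - (slope * t + intercept) + np.mean(trace.samples)
    meta = dict(trace.meta)
    meta["drift_slope_removed_mv_per_s"] = float(slope)
    return VmTrace(samples=detrended, fs=trace.fs, t0=trace.t0, meta=meta)


def gliding_threshold(trace: VmTrace) -> np.ndarray:
    """Per-second thresholds: median over [t - 4 s, t + 4 s), edge-truncated.

    Returns one value per started second of the epoch, so every sample has a
    threshold for its containing second.
    """
    if trace.n_samples == 0:
        raise ValidationError("empty trace")
    if trace.duration < 1.0:
        raise ValidationError("gliding threshold needs at least 1 s of data")
    n_seconds = int(np.ceil(trace.duration))
    half = int(round(GLIDE_HALF_WINDOW_S * trace.fs))
    thresholds = np.empty(n_seconds)
    for t in range(n_seconds):
        center = int(round(t * trace.fs))
        lo = max(center - half, 0)
        hi = min(center + half, trace.n_samples)
        thresholds[t] = np.median(trace.samples[lo:hi])
    return thresholds


def _local_median(x: np.ndarray, half_samples: int) -> np.ndarray:
    win = 2 * half_samples + 1
    return (
        pd.Series(x).rolling(window=win, center=True, min_periods=1).median().to_numpy()
    )


def _runs(labels: np.ndarray) -> list[list]:
    """Maximal runs of a boolean label array as [label, i0, i1) triples."""
    change = np.flatnonzero(np.diff(labels.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [labels.size]))
    return [
        [bool(labels[bounds[k]]), int(bounds[k]), int(bounds[k + 1])]
        for k in range(bounds.size - 1)
    ]


def _remove_short(runs: list[list], fs: float, min_dur: float) -> list[list]:
    """Relabel sub-``min_dur`` runs into the flanking state, shortest first,
    merging until no short run remains."""
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        durations = [(r[2] - r[1]) / fs for r in runs]
        short = [i for i, d in enumerate(durations) if d < min_dur - 1e-12]
        if not short:
            break
        i = min(short, key=lambda k: (durations[k], k))
        # flanking neighbours carry the opposite label (runs alternate)
        runs[i][0] = not runs[i][0]
        merged: list[list] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged
    return runs


def segment_states(
    trace: VmTrace,
    detrend: bool = True,
    threshold_mode: str = "hold",
) -> list[StateSegment]:
    """Segment a spontaneous trace into alternating up/down states.

    ``threshold_mode`` selects how the per-second threshold applies between
    evaluation points: ``"hold"`` (each sample uses its containing second's
    value) or ``"interp"`` (linear interpolation between seconds). A sample
    whose local median exactly equals its threshold is labelled down.
    """
    if trace.duration < 1.0:
        raise ValidationError("segmentation needs at least 1 s of data")
    work = detrend_linear(trace) if detrend else trace
    x = work.samples
    fs = work.fs
    thresholds = gliding_threshold(work)

    local_med = _local_median(x, int(round(LOCAL_MEDIAN_HALF_S * fs)))
    sec_idx = np.minimum((np.arange(x.size) / fs).astype(int), thresholds.size - 1)
    if threshold_mode == "hold":
        thr = thresholds[sec_idx]
    elif threshold_mode == "interp":
        thr = np.interp(np.arange(x.size) / fs, np.arange(thresholds.size), thresholds)
    else:
        raise ValidationError(f"unknown threshold_mode {threshold_mode!r}")

    up = local_med > thr  # tie -> down
    runs = _remove_short(_runs(up), fs, MIN_STATE_DUR_S)

    segments = []
    for is_up, i0, i1 in runs:
        segments.append(
            StateSegment(
                label="up" if is_up else "down",
                start=trace.t0 + i0 / fs,
                end=trace.t0 + i1 / fs,
                mean_vm=float(np.mean(x[i0:i1])),
            )
        )
    return segments


def state_at(segments: list[StateSegment], t: float) -> str:
    """Label of the segment containing time ``t``."""
    for seg in segments:
        if seg.start <= t < seg.end:
            return seg.label
    raise ValidationError(f"time {t:g} s outside the segmented epoch")


def summarize_states(
    segments: list[StateSegment], trace: VmTrace | None = None
) -> StateSummary:
    """State statistics over an epoch: durations, frequencies, Vm contrast.

    Frequencies are counts per epoch duration; the up-down Vm difference is
    the duration-weighted mean upstate Vm minus the duration-weighted mean
    downstate Vm, undefined (``None``) when a state is absent. Micro-upstates
    are upstates lasting 100-150 ms inclusive.
    """
    if not segments:
        raise ValidationError("empty segmentation")
    epoch = segments[-1].end - segments[0].start
    ups = [s for s in segments if s.label == "up"]
    downs = [s for s in segments if s.label == "down"]

    def _wmean(segs: list[StateSegment]) -> float:
        w = np.array([s.duration for s in segs])
        v = np.array([s.mean_vm for s in segs])
        return float(np.sum(w * v) / np.sum(w))

    down_mean = _wmean(downs) if downs else None
    up_mean = _wmean(ups) if ups else None
    dvm = (up_mean - down_mean) if (ups and downs) else None
    lo, hi = MICRO_UP_RANGE_S
    micro = sum(1 for s in ups if lo - 1e-12 <= s.duration <= hi + 1e-12)
    up_vm_norm = (
        np.array([s.mean_vm - down_mean for s in ups])
        if (ups and downs)
        else np.array([])
    )
    return StateSummary(
        up_dur_mean=float(np.mean([s.duration for s in ups])) if ups else None,
        up_freq=len(ups) / epoch,
        down_dur_mean=float(np.mean([s.duration for s in downs])) if downs else None,
        down_freq=len(downs) / epoch,
        dvm_updown=dvm,
        micro_count=micro,
        up_vm_norm=up_vm_norm,
    )
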