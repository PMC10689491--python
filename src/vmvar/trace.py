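"""Core in-memory containers for membrane-potential recordings.

All times are in seconds, 0-based from trace start; every analysis window is
half-open ``[start, end)`` so that adjacent windows never double-count a
sample. Voltages are millivolts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "VmTrace",
    "TrialSet",
    "StepProtocol",
    "InclusionVerdict",
    "validate_recording",
    "ValidationError",
]

#: QC thresholds for including a recorded cell in the analysis.
MAX_ACCESS_RESISTANCE_MOHM = 50.0
MAX_RESTING_VM_MV = -50.0


class ValidationError(ValueError):
    """Raised when a container or recording violates its invariants."""


@dataclass
class VmTrace:
    """A uniformly sampled membrane-potential trace.

    Parameters
    ----------
    samples : ndarray
        Membrane potential in mV.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Epoch start time (s); sample ``i`` sits at ``t0 + i / fs``.
    meta : dict
        Free-form annotations (cell id, recording depth, group label, ...).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must be finite")
        if not (self.fs > 0):
            raise ValidationError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Epoch length in seconds."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_of(self, t: float) -> int:
        """Sample index containing time ``t`` (half-open sample bins)."""
        return int(np.floor((t - self.t0) * self.fs))

    def window(self, start: float, end: float) -> np.ndarray:
        """Samples in the half-open time window ``[start, end)``.

        The window is clipped to the epoch; requesting a window fully outside
        the epoch raises.
        """
        # sample i (at t0 + i/fs) belongs to [start, end) iff
        # ceil((start-t0)*fs) <= i < ceil((end-t0)*fs), with a tie guard for
        # times that land exactly on a sample
        eps = 1e-9
        i0 = max(int(np.ceil((start - self.t0) * self.fs - eps)), 0)
        i1 = min(int(np.ceil((end - self.t0) * self.fs - eps)), self.n_samples)
        if i1 <= i0:
            raise ValidationError(f"empty window [{start}, {end})")
        return self.samples[i0:i1]


@dataclass
class TrialSet:
    """A stimulation block: one trace plus aligned stimulus onsets.

    Default pre/post windows are 200 ms, the per-trial baseline and response
    windows used throughout the evoked-response analysis.
    """

    trace: VmTrace
    stim_times: np.ndarray
    pre_window: float = 0.2
    post_window: float = 0.2

    def __post_init__(self) -> None:
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.stim_times.ndim != 1 or self.stim_times.size < 1:
            raise ValidationError("stim_times must be a non-empty 1-D array")
        if np.any(np.diff(self.stim_times) <= 0):
            raise ValidationError("stim_times must be strictly ascending")
        t_end = self.trace.t0 + self.trace.duration
        if self.stim_times[0] - self.pre_window < self.trace.t0:
            raise ValidationError(
                f"stimulus at {self.stim_times[0]:g} s lacks a full "
                f"{self.pre_window:g}-s pre-window"
            )
        if self.stim_times[-1] + self.post_window > t_end:
            raise ValidationError(
                f"stimulus at {self.stim_times[-1]:g} s lacks a full "
                f"{self.post_window:g}-s post-window"
            )

    @property
    def n_trials(self) -> int:
        return self.stim_times.size

    def baseline(self, i: int) -> np.ndarray:
        """Samples of trial ``i``'s baseline window ``[stim - pre, stim)``."""
        t = self.stim_times[i]
        return self.trace.window(t - self.pre_window, t)

    def response(self, i: int) -> np.ndarray:
        """Samples of trial ``i``'s response window ``[stim, stim + post)``."""
        t = self.stim_times[i]
        return self.trace.window(t, t + self.post_window)


@dataclass
class StepProtocol:
    """Current-step protocol: one sweep per injected current amplitude.

    ``step_onset`` is the within-sweep time at which the step begins; the step
    lasts ``step_dur`` seconds.
    """

    currents: np.ndarray  # pA
    sweeps: list[VmTrace]
    step_dur: float = 0.5
    step_onset: float = 0.1

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        if len(self.sweeps) != self.currents.size:
            raise ValidationError("one sweep per current required")
        if self.currents.size >= 3:
            steps = np.diff(self.currents)
            if not np.allclose(steps, steps[0]):
                raise ValidationError("currents must form an arithmetic grid")

    def sweep_at(self, current: float) -> VmTrace:
        idx = np.flatnonzero(np.isclose(self.currents, current))
        if idx.size == 0:
            raise ValidationError(f"no sweep at {current:g} pA")
        return self.sweeps[int(idx[0])]


@dataclass
class InclusionVerdict:
    include: bool
    reasons: list[str] = field(default_factory=list)


def validate_recording(trace: VmTrace, meta: dict | None = None) -> InclusionVerdict:
    """Quality-control verdict for a recorded cell.

    A cell is excluded when pipette access resistance exceeds 50 MOhm or the
    resting membrane potential is depolarized above -50 mV. ``meta`` must
    carry ``access_resistance_mohm`` and ``resting_vm_mv``; by default the
    trace's own ``meta`` is used.
    """
    meta = trace.meta if meta is None else meta
    required = ("access_resistance_mohm", "resting_vm_mv")
    missing = [k for k in required if k not in meta]
    if missing:
        raise ValidationError(f"missing meta fields: {', '.join(missing)}")
    reasons: list[str] = []
    if meta["access_resistance_mohm"] > MAX_ACCESS_RESISTANCE_MOHM:
        reasons.append("access resistance")
    if meta["resting_vm_mv"] > MAX_RESTING_VM_MV:
        reasons.append("depolarized")
    return InclusionVerdict(include=not reasons, reasons=reasons)
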