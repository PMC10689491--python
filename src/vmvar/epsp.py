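"""Per-trial quantification of stimulus-evoked subthreshold responses.

For each stimulus trial the baseline window is the 200 ms just before onset
and the response window the 200 ms just after. The response amplitude is the
maximum post-stimulus Vm minus the baseline mean; trials whose amplitude is
below twice the baseline SD are failures. Kinetics are the width at
half-maximal amplitude and the 20-80% rise slope. Onset latency comes from a
Gaussian fit to the rising limb of the trial-averaged response; the SNR of a
trial is its amplitude divided by the across-trial (sample) amplitude
variance of the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .trace import TrialSet, ValidationError

__all__ = [
    "EPSPFeatures",
    "CellEPSPSummary",
    "baseline_stats",
    "detect_epsp",
    "analyze_trials",
    "onset_latency",
    "snr",
    "tbt_variability",
    "summarize_cell",
]

FAILURE_SD_FACTOR = 2.0
ONSET_TOLERANCE = 0.01  # fraction of fitted amplitude above baseline


@dataclass
class EPSPFeatures:
    trial: int
    outcome: str  # "epsp" | "failure" | "ap"
    baseline_vm: float  # mV
    baseline_sd: float  # mV
    amplitude: float | None = None  # mV, None for ap trials
    half_width: float | None = None  # ms
    rise_slope_2080: float | None = None  # mV/ms
    peak_time: float | None = None  # ms post-stimulus


@dataclass
class CellEPSPSummary:
    n_trials: int
    n_epsp: int
    n_failure: int
    n_ap: int
    mean_amplitude: float | None
    mean_half_width: float | None
    mean_slope: float | None
    onset_latency_ms: float | None
    peak_latency_ms: float | None
    tbt_sd_amplitude: float | None
    tbt_sd_halfwidth: float | None
    tbt_sd_slope: float | None
    snr_per_trial: np.ndarray | None
    snr_cell: float | None
    mean_baseline_sd: float | None
    sd_baseline_sd: float | None  # across-trial SD of the per-trial baseline SD
    flags: list[str] = field(default_factory=list)


def baseline_stats(trialset: TrialSet, trial_idx: int) -> tuple[float, float]:
    """Mean and sample SD of the 200-ms pre-stimulus window."""
    x = trialset.baseline(trial_idx)
    expected = int(round(trialset.pre_window * trialset.trace.fs))
    if x.size < expected:
        raise ValidationError("truncated baseline window")
    return float(np.mean(x)), float(np.std(x, ddof=1))


def _crossings(t: np.ndarray, y: np.ndarray, level: float) -> np.ndarray:
    """Linearly interpolated times where ``y`` crosses ``level``."""
    s = y - level
    idx = np.flatnonzero(np.signbit(s[:-1]) != np.signbit(s[1:]))
    if idx.size == 0:
        return np.array([])
    frac = s[idx] / (s[idx] - s[idx + 1])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def _half_width(t_ms: np.ndarray, y: np.ndarray, baseline: float, amp: float,
                i_peak: int) -> float | None:
    """Width (ms) of the response at half-maximal amplitude around the peak."""
    level = baseline + amp / 2.0
    s = y - level
    above = s > 0
    if not above[i_peak]:
        return None
    i0 = i_peak
    while i0 > 0 and above[i0 - 1]:
        i0 -= 1
    i1 = i_peak
    while i1 < y.size - 1 and above[i1 + 1]:
        i1 += 1
    # interpolate the two flank crossings where possible
    t_lo = t_ms[i0]
    if i0 > 0:
        c = _crossings(t_ms[i0 - 1 : i0 + 1], y[i0 - 1 : i0 + 1], level)
        if c.size:
            t_lo = c[0]
    t_hi = t_ms[i1]
    if i1 < y.size - 1:
        c = _crossings(t_ms[i1 : i1 + 2], y[i1 : i1 + 2], level)
        if c.size:
            t_hi = c[0]
    width = t_hi - t_lo
    return float(width) if width > 0 else None


def _rise_slope(t_ms: np.ndarray, y: np.ndarray, baseline: float, amp: float,
                i_peak: int) -> float | None:
    """Slope between the 20% and 80% amplitude points on the rising phase."""
    rise_t = t_ms[: i_peak + 1]
    rise_y = y[: i_peak + 1]
    t20 = _crossings(rise_t, rise_y, baseline + 0.2 * amp)
    t80 = _crossings(rise_t, rise_y, baseline + 0.8 * amp)
    if t20.size == 0 or t80.size == 0:
        return None
    # last crossings before the peak bound the final ascent
    dt = t80[-1] - t20[-1]
    if dt <= 0:
        return None
    return float(0.6 * amp / dt)


def detect_epsp(
    trialset: TrialSet,
    trial_idx: int,
    ap_times: np.ndarray | None = None,
) -> EPSPFeatures:
    """Extract one trial's response features, or label it failure/AP.

    ``ap_times`` are detected spike times for the whole trace (s); a spike
    inside the trial's post-window makes the outcome ``"ap"`` and suppresses
    the subthreshold fields.
    """
    baseline_vm, baseline_sd = baseline_stats(trialset, trial_idx)
    t_stim = trialset.stim_times[trial_idx]
    y = trialset.response(trial_idx)
    expected = int(round(trialset.post_window * trialset.trace.fs))
    if y.size < expected:
        raise ValidationError("truncated response window")
    if ap_times is not None and ap_times.size:
        in_post = (ap_times >= t_stim) & (ap_times < t_stim + trialset.post_window)
        if np.any(in_post):
            return EPSPFeatures(
                trial=trial_idx, outcome="ap",
                baseline_vm=baseline_vm, baseline_sd=baseline_sd,
            )
    t_ms = (np.arange(y.size) + 1) * 1000.0 / trialset.trace.fs
    i_peak = int(np.argmax(y))
    amp = float(y[i_peak] - baseline_vm)
    if amp < FAILURE_SD_FACTOR * baseline_sd:
        return EPSPFeatures(
            trial=trial_idx, outcome="failure",
            baseline_vm=baseline_vm, baseline_sd=baseline_sd,
            amplitude=max(amp, 0.0),
        )
    return EPSPFeatures(
        trial=trial_idx, outcome="epsp",
        baseline_vm=baseline_vm, baseline_sd=baseline_sd,
        amplitude=amp,
        half_width=_half_width(t_ms, y, baseline_vm, amp, i_peak),
        rise_slope_2080=_rise_slope(t_ms, y, baseline_vm, amp, i_peak),
        peak_time=float(t_ms[i_peak]),
    )


def analyze_trials(
    trialset: TrialSet, ap_times: np.ndarray | None = None
) -> list[EPSPFeatures]:
    """Feature extraction for every trial of a stimulation block."""
    return [detect_epsp(trialset, i, ap_times) for i in range(trialset.n_trials)]


def features_to_frame(features: list[EPSPFeatures], cell_id: str) -> "pd.DataFrame":
    """Per-trial feature table (one row per trial) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"cell_id": cell_id, "trial": f.trial, "outcome": f.outcome,
             "amplitude_mv": f.amplitude, "half_width_ms": f.half_width,
             "slope_mv_per_ms": f.rise_slope_2080,
             "baseline_vm_mv": f.baseline_vm, "baseline_sd_mv": f.baseline_sd}
            for f in features
        ]
    )


def _gaussian(t, a, mu, sigma):
    return a * np.exp(-((t - mu) ** 2) / (2 * sigma**2))


def onset_latency(
    trialset: TrialSet,
    features: list[EPSPFeatures],
    tolerance: float = ONSET_TOLERANCE,
) -> tuple[float, float, dict]:
    """Onset and peak latency (ms) from the averaged non-failure response.

    A Gaussian is fitted to the rising limb (baseline to peak) of the
    trial-averaged response; onset is the earliest time where the fit exceeds
    the baseline by ``tolerance`` of the fitted amplitude. Peak latency is the
    averaged response's peak time minus the onset. Returns
    ``(onset_ms, peak_latency_ms, info)``; ``info["fallback"]`` is True when
    the fit failed and a threshold-crossing estimate was used instead.
    """
    keep = [f.trial for f in features if f.outcome == "epsp"]
    if len(keep) < 2:
        raise ValidationError("no average response: fewer than 2 EPSP trials")
    fs = trialset.trace.fs
    avg = np.mean([trialset.response(i) for i in keep], axis=0)
    base = float(np.mean([trialset.baseline(i) for i in keep]))
    t_ms = (np.arange(avg.size) + 1) * 1000.0 / fs
    i_peak = int(np.argmax(avg))
    amp = avg[i_peak] - base
    if amp <= 0:
        raise ValidationError("averaged response has no positive deflection")
    # fit only the foot of the final ascent (between `tolerance` and 30% of
    # the amplitude): a free Gaussian fitted over the whole rise has a much
    # wider flank than the response foot and would bias the onset early
    def _ascent(hi_frac: float) -> tuple[np.ndarray, np.ndarray]:
        hi_level = base + hi_frac * amp
        lo_level = base + tolerance * amp
        i_hi = i_peak
        while i_hi > 0 and avg[i_hi - 1] > hi_level:
            i_hi -= 1
        # walk back through the foot, but never further than a few rise spans
        # (a pre-onset plateau sitting above lo_level must not be swallowed)
        floor = max(i_hi - max(3 * (i_peak - i_hi), 20), 0)
        i_lo = i_hi
        while i_lo > floor and avg[i_lo - 1] >= lo_level and avg[i_lo - 1] <= avg[i_lo]:
            i_lo -= 1
        return t_ms[i_lo : i_hi + 1], avg[i_lo : i_hi + 1]

    rise_t, rise_y = _ascent(0.3)
    if rise_t.size < 4:  # coarse sampling or degraded foot: widen the window
        rise_t, rise_y = _ascent(0.6)
    info: dict = {"fallback": False, "n_trials_averaged": len(keep)}
    onset = None
    if rise_t.size >= 4:
        span = max(rise_t[-1] - rise_t[0], 0.5)
        try:
            popt, _ = optimize.curve_fit(
                _gaussian, rise_t, rise_y - base,
                p0=[amp, rise_t[-1] + span, span],
                maxfev=10000,
            )
            a_fit, mu_fit, sig_fit = popt
            sig_fit = abs(sig_fit)
            if a_fit <= 0 or sig_fit <= 0:
                raise RuntimeError("degenerate fit")
            # earliest time the Gaussian exceeds tolerance * a above baseline
            onset = mu_fit - sig_fit * np.sqrt(2.0 * np.log(1.0 / tolerance))
            info["fit"] = {
                "a": float(a_fit), "mu": float(mu_fit), "sigma": float(sig_fit)
            }
        except RuntimeError:
            onset = None
    if onset is None:
        info["fallback"] = True
        level = base + tolerance * amp
        y = avg[: i_peak + 1]
        idx = np.flatnonzero((y[:-1] <= level) & (y[1:] > level))
        if idx.size == 0:
            # pre-onset drift can hold the whole average above the baseline
            # level; reference the tolerance to the pre-peak minimum instead
            level = float(np.min(y)) + tolerance * amp
            info["foot_referenced"] = True
            idx = np.flatnonzero((y[:-1] <= level) & (y[1:] > level))
        if idx.size == 0:
            raise ValidationError("onset fit failed and no threshold crossing found")
        k = idx[-1]
        frac = (level - y[k]) / (y[k + 1] - y[k])
        onset = float(t_ms[k] + frac * (t_ms[k + 1] - t_ms[k]))
    onset = float(max(onset, 0.0))
    peak_latency = float(t_ms[i_peak] - onset)
    return onset, peak_latency, info


def snr(amplitudes: np.ndarray) -> tuple[np.ndarray | None, float | None]:
    """Per-trial and cell SNR: each amplitude over the across-trial variance.

    Uses the sample (n-1) variance; undefined (``None``) when fewer than two
    amplitudes are available or their variance is zero.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size < 2:
        return None, None
    var = float(np.var(a, ddof=1))
    if var == 0:
        return None, None
    per_trial = a / var
    return per_trial, float(np.mean(per_trial))


def tbt_variability(values: np.ndarray) -> float | None:
    """Trial-by-trial variability: sample SD across trials (None if n < 2)."""
    v = np.asarray([x for x in np.ravel(values) if x is not None and np.isfinite(x)])
    if v.size < 2:
        return None
    return float(np.std(v, ddof=1))


def summarize_cell(
    trialset: TrialSet, features: list[EPSPFeatures]
) -> CellEPSPSummary:
    """Cell-level EPSP summary: means, latencies, trial-by-trial SDs, SNR.

    Failure trials are excluded from amplitude/kinetics statistics and from
    the SNR variance (their amplitudes are not imputed)."""
    flags: list[str] = []
    epsp = [f for f in features if f.outcome == "epsp"]
    amps = np.array([f.amplitude for f in epsp], dtype=float)
    hws = np.array([f.half_width for f in epsp if f.half_width is not None])
    slopes = np.array(
        [f.rise_slope_2080 for f in epsp if f.rise_slope_2080 is not None]
    )
    base_sds = np.array([f.baseline_sd for f in features])

    onset = peak_lat = None
    if len(epsp) >= 2:
        try:
            onset, peak_lat, _ = onset_latency(trialset, features)
        except ValidationError as err:
            flags.append(f"latency: {err}")
    else:
        flags.append("latency: fewer than 2 EPSP trials")

    snr_trials, snr_cell = (snr(amps) if amps.size >= 2 else (None, None))
    if snr_cell is None:
        flags.append("snr: undefined (needs >= 2 EPSP trials with variance)")

    return CellEPSPSummary(
        n_trials=len(features),
        n_epsp=len(epsp),
        n_failure=sum(f.outcome == "failure" for f in features),
        n_ap=sum(f.outcome == "ap" for f in features),
        mean_amplitude=float(np.mean(amps)) if amps.size else None,
        mean_half_width=float(np.mean(hws)) if hws.size else None,
        mean_slope=float(np.mean(slopes)) if slopes.size else None,
        onset_latency_ms=onset,
        peak_latency_ms=peak_lat,
        tbt_sd_amplitude=tbt_variability(amps),
        tbt_sd_halfwidth=tbt_variability(hws),
        tbt_sd_slope=tbt_variability(slopes),
        snr_per_trial=snr_trials,
        snr_cell=snr_cell,
        mean_baseline_sd=float(np.mean(base_sds)) if base_sds.size else None,
        sd_baseline_sd=tbt_variability(base_sds),
        flags=flags,
    )
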