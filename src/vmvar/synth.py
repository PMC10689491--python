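"""Ground-truthed synthetic membrane-potential generator.

Emulates the statistical structure of anesthetized in vivo whole-cell
recordings from cortical pyramidal neurons so that every analysis stage can be
tested against a known truth: two-state (up/down) slow dynamics with
gamma-distributed state durations, band-limited sinusoidal oscillations plus
white noise, optional linear drift, stimulus-evoked EPSPs with
double-exponential kinetics and trial-to-trial amplitude/latency jitter and
failures, spontaneous and evoked action potentials from a piecewise-linear
template with an analytically known 10 mV/ms threshold crossing, current-step
protocols, and acoustic-startle response tables.

Two presets bracket the study conditions: ``wt_like`` (quiet baseline, no
micro-upstates) and ``ko_like`` (roughly twofold baseline-Vm SD, larger
up-down Vm contrast, micro-upstates, higher upstate frequency, higher
spontaneous firing, larger EPSP amplitude dispersion).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trace import StepProtocol, TrialSet, ValidationError, VmTrace

__all__ = [
    "SynthParams",
    "GroundTruth",
    "EPSPEvent",
    "APTemplate",
    "genotype_presets",
    "generate_trace",
    "generate_trial_set",
    "generate_startle_table",
    "generate_step_protocol",
    "generate_adp_trials",
    "ap_template",
    "epsp_kernel",
]

#: Band-center frequencies (Hz) for the sinusoidal oscillation synthesis.
BAND_CENTERS: dict[str, float] = {
    "delta": 2.25,
    "theta": 5.5,
    "alpha": 10.0,
    "beta": 21.5,
    "gamma": 65.0,
}


@dataclass
class SynthParams:
    """Generator parameters; defaults describe a quiet wild-type-like cell."""

    fs: float = 20000.0  # Hz
    duration_spont: float = 180.0  # s
    v_down: float = -70.0  # mV, downstate mean
    dv_updown: float = 6.0  # mV, up minus down
    dur_up: float = 0.5  # s, mean upstate duration
    dur_down: float = 0.8  # s, mean downstate duration
    dur_shape: float = 2.0  # gamma shape for state durations
    # floor on ordinary state durations: keeps them well clear of both the
    # 100-ms removal rule and the 100-150 ms micro-upstate band, so the
    # ground truth for the micro counter is unambiguous
    min_state_dur: float = 0.3  # s
    micro_up_rate: float = 0.0  # Hz, inserted 100-150 ms upstates
    osc_amp: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 0.6,
            "theta": 0.4,
            "alpha": 0.3,
            "beta": 0.2,
            "gamma": 0.15,
        }
    )
    osc_mode: str = "sinusoid"  # "sinusoid" (closed-form band powers) | "filtered"
    noise_sd: float = 0.4  # mV white noise
    drift_slope: float = 0.0  # mV/s
    epsp_amp_mu: float = 6.0  # mV, mean of the lognormal amplitude
    epsp_amp_sd: float = 1.5  # mV, SD of the lognormal amplitude
    epsp_tau_rise: float = 2.0  # ms
    epsp_tau_decay: float = 15.0  # ms
    epsp_latency_mu: float = 8.0  # ms post-stimulus
    epsp_latency_jitter: float = 0.8  # ms SD
    p_fail: float = 0.1
    p_ap_given_epsp: float = 0.0
    spont_ap_rate: float = 0.005  # Hz
    n_trials: int = 40
    isi: float = 3.4  # s, > 1/0.3 Hz
    state_gain: float = 0.2  # EPSP amplitude coupling to instantaneous state
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 200.0:
            raise ValidationError("fs must exceed 200 Hz (gamma band resolvable)")
        for name in (
            "duration_spont", "dur_up", "dur_down", "dur_shape", "noise_sd",
            "epsp_amp_sd", "epsp_tau_rise", "epsp_tau_decay",
            "epsp_latency_jitter", "spont_ap_rate", "micro_up_rate",
            "min_state_dur",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("p_fail", "p_ap_given_epsp"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_trials > 1 and self.isi <= 1 / 0.3:
            raise ValidationError("isi must exceed 1/0.3 s for multi-trial blocks")
        if self.dv_updown <= 0:
            raise ValidationError("dv_updown must be positive")
        if self.osc_mode not in ("sinusoid", "filtered"):
            raise ValidationError("osc_mode must be 'sinusoid' or 'filtered'")


@dataclass
class EPSPEvent:
    trial: int
    amplitude: float  # mV (0 for failures)
    latency: float  # ms post-stimulus
    failed: bool
    has_ap: bool


@dataclass
class GroundTruth:
    state_intervals: list[tuple[str, float, float]] = field(default_factory=list)
    epsp_events: list[EPSPEvent] = field(default_factory=list)
    ap_times: np.ndarray = field(default_factory=lambda: np.array([]))
    drift: float = 0.0


_PRESETS: dict[str, dict] = {
    # wild-type-like: no micro-upstates, low noise, sparse spontaneous firing
    "wt_like": {},
    # knockout-like: every Vm-amplitude component (white noise, oscillation
    # amplitudes, up-down contrast) doubled, so the baseline-Vm SD is 2x the
    # wild-type value by construction; micro-upstates raise the upstate
    # frequency; spontaneous firing and EPSP amplitude dispersion larger
    "ko_like": dict(
        noise_sd=0.8,
        osc_amp={"delta": 1.2, "theta": 0.8, "alpha": 0.6, "beta": 0.4, "gamma": 0.3},
        dv_updown=12.0,
        micro_up_rate=0.1,
        spont_ap_rate=0.05,
        epsp_amp_mu=7.0,
        epsp_amp_sd=3.0,
        epsp_latency_jitter=1.5,
    ),
}


def genotype_presets(name: str, **overrides) -> SynthParams:
    """Fully populated parameter set for a named genotype-like preset."""
    if name not in _PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; valid presets: {sorted(_PRESETS)}"
        )
    return replace(SynthParams(**_PRESETS[name]), **overrides)


# ---------------------------------------------------------------------------
# state process


def _draw_state_intervals(
    rng: np.random.Generator, params: SynthParams, duration: float
) -> list[tuple[str, float, float]]:
    """Alternating up/down intervals tiling [0, duration), starting down.

    Durations are gamma-distributed (shape ``dur_shape``) with a floor at
    ``min_state_dur`` so the true segmentation contains no events the
    sub-100-ms removal rule would erase. Micro-upstates (uniform 100-150 ms)
    are then inserted into downstates that can host them without creating
    sub-100-ms fragments.
    """
    intervals: list[list] = []
    t = 0.0
    label = "down"
    while t < duration:
        mean = params.dur_down if label == "down" else params.dur_up
        d = rng.gamma(params.dur_shape, mean / params.dur_shape)
        d = max(d, params.min_state_dur)
        end = min(t + d, duration)
        intervals.append([label, t, end])
        t = end
        label = "up" if label == "down" else "down"

    n_micro = rng.poisson(params.micro_up_rate * duration)
    for _ in range(n_micro):
        dur = rng.uniform(0.100, 0.150)
        # candidate downstates with room for the micro-upstate plus margins
        margin = 0.12
        hosts = [
            i for i, (lab, a, b) in enumerate(intervals)
            if lab == "down" and (b - a) > dur + 2 * margin
        ]
        if not hosts:
            continue
        i = int(rng.choice(hosts))
        lab, a, b = intervals[i]
        s = rng.uniform(a + margin, b - margin - dur)
        intervals[i : i + 1] = [
            ["down", a, s],
            ["up", s, s + dur],
            ["down", s + dur, b],
        ]
    return [(lab, a, b) for lab, a, b in intervals]


def _state_waveform(
    intervals: list[tuple[str, float, float]], params: SynthParams, n: int
) -> np.ndarray:
    x = np.full(n, params.v_down)
    fs = params.fs
    for lab, a, b in intervals:
        if lab == "up":
            i0 = int(np.ceil(a * fs - 1e-9))
            i1 = min(int(np.ceil(b * fs - 1e-9)), n)
            x[i0:i1] += params.dv_updown
    return x


#: Band edges used by the filtered-noise oscillation mode (Hz).
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}


def _oscillations(
    rng: np.random.Generator, params: SynthParams, n: int
) -> np.ndarray:
    """Band-limited oscillations, matched in variance across both modes.

    ``sinusoid``: one fixed-amplitude sinusoid per band at the band-center
    frequency with random phase (variance A^2/2 exactly, so band powers have
    closed forms). ``filtered``: 4th-order Butterworth band-passed white
    noise rescaled to the same variance (no line spectrum, more realistic).
    """
    x = np.zeros(n)
    if params.osc_mode == "sinusoid":
        t = np.arange(n) / params.fs
        for band, amp in params.osc_amp.items():
            if amp == 0:
                continue
            f = BAND_CENTERS[band]
            phase = rng.uniform(0, 2 * np.pi)
            x += amp * np.sin(2 * np.pi * f * t + phase)
        return x
    from scipy import signal as _signal

    for band, amp in params.osc_amp.items():
        if amp == 0:
            continue
        lo, hi = BAND_EDGES[band]
        hi = min(hi, 0.45 * params.fs)
        sos = _signal.butter(4, [lo, hi], btype="bandpass", fs=params.fs, output="sos")
        y = _signal.sosfilt(sos, rng.normal(0.0, 1.0, n))
        sd = np.std(y)
        if sd > 0:
            x += y * (amp / np.sqrt(2.0)) / sd
    return x


# ---------------------------------------------------------------------------
# action-potential template


@dataclass
class APTemplate:
    """Piecewise-linear spike waveform (mV above the insertion baseline).

    The rising phase has two linear segments: a slow pre-potential below
    10 mV/ms followed by a fast upstroke far above it, so the 10 mV/ms
    threshold crossing sits exactly at the kink — ``threshold_offset`` mV above
    baseline — which detection tests can use analytically.
    """

    waveform: np.ndarray
    peak_index: int
    threshold_offset: float  # mV above insertion baseline at dV/dt = 10 mV/ms
    peak_offset: float  # mV above insertion baseline
    half_width_ms: float


def ap_template(
    fs: float,
    threshold_offset: float = 25.0,
    peak_offset: float = 100.0,
    half_width_ms: float = 1.0,
    prepot_slope: float = 8.0,  # mV/ms, below the 10 mV/ms criterion
    upstroke_slope: float = 400.0,  # mV/ms
) -> APTemplate:
    """Build the spike template at sampling rate ``fs``.

    With the default offsets a spike inserted on a -70 mV downstate crosses
    10 mV/ms at -45 mV and peaks at +30 mV. ``half_width_ms`` is the width at
    half amplitude between threshold and peak; the (linear) downstroke slope
    is solved from it.
    """
    if not 0 < threshold_offset < peak_offset:
        raise ValidationError("0 < threshold_offset < peak_offset required")
    half_level = threshold_offset + (peak_offset - threshold_offset) / 2.0
    t_up_half = (peak_offset - half_level) / upstroke_slope  # ms above half, rising
    if half_width_ms <= t_up_half:
        raise ValidationError("half_width too small for the upstroke slope")
    down_slope = (peak_offset - half_level) / (half_width_ms - t_up_half)

    dt_ms = 1000.0 / fs
    t_pre = threshold_offset / prepot_slope
    t_rise = (peak_offset - threshold_offset) / upstroke_slope
    t_fall = peak_offset / down_slope
    total_ms = t_pre + t_rise + t_fall
    n = int(np.ceil(total_ms / dt_ms)) + 1
    t = np.arange(n) * dt_ms
    v = np.where(
        t < t_pre,
        prepot_slope * t,
        np.where(
            t < t_pre + t_rise,
            threshold_offset + upstroke_slope * (t - t_pre),
            np.maximum(peak_offset - down_slope * (t - t_pre - t_rise), 0.0),
        ),
    )
    peak_index = int(np.argmin(np.abs(t - (t_pre + t_rise))))
    v[peak_index] = peak_offset
    return APTemplate(
        waveform=v,
        peak_index=peak_index,
        threshold_offset=threshold_offset,
        peak_offset=peak_offset,
        half_width_ms=half_width_ms,
    )


def _insert_ap(x: np.ndarray, template: APTemplate, peak_time: float, fs: float) -> None:
    """Add the template so its peak lands at ``peak_time`` (in place)."""
    start = int(round(peak_time * fs)) - template.peak_index
    w = template.waveform
    lo = max(start, 0)
    hi = min(start + w.size, x.size)
    if hi <= lo:
        return
    x[lo:hi] += w[lo - start : hi - start]


# ---------------------------------------------------------------------------
# EPSP kernel


def epsp_kernel(
    t_ms: np.ndarray, tau_rise: float, tau_decay: float
) -> np.ndarray:
    """Unit-peak double exponential ``exp(-t/tau_d) - exp(-t/tau_r)``."""
    if tau_decay <= tau_rise:
        raise ValidationError("tau_decay must exceed tau_rise")
    t_peak = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    out = np.where(
        t_ms >= 0, np.exp(-t_ms / tau_decay) - np.exp(-t_ms / tau_rise), 0.0
    )
    return out / peak


def epsp_peak_delay_ms(tau_rise: float, tau_decay: float) -> float:
    """Kernel onset-to-peak delay in ms."""
    return float(
        np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    )


# ---------------------------------------------------------------------------
# trace / trial-set generation


def _background(
    rng: np.random.Generator, params: SynthParams, duration: float
) -> tuple[np.ndarray, list[tuple[str, float, float]]]:
    n = int(round(duration * params.fs))
    intervals = _draw_state_intervals(rng, params, duration)
    x = _state_waveform(intervals, params, n)
    x += _oscillations(rng, params, n)
    if params.noise_sd > 0:
        x += rng.normal(0.0, params.noise_sd, n)
    if params.drift_slope != 0:
        x += params.drift_slope * np.arange(n) / params.fs
    return x, intervals


def _spont_aps(
    rng: np.random.Generator,
    params: SynthParams,
    x: np.ndarray,
    template: APTemplate,
    duration: float,
) -> np.ndarray:
    n_ap = rng.poisson(params.spont_ap_rate * duration)
    times = np.sort(rng.uniform(0.01, duration - 0.01, n_ap))
    for t_ap in times:
        _insert_ap(x, template, t_ap, params.fs)
    return times


def generate_trace(
    params: SynthParams, ap_waveform: APTemplate | None = None
) -> tuple[VmTrace, GroundTruth]:
    """Spontaneous-epoch trace of ``duration_spont`` seconds plus ground truth."""
    rng = np.random.default_rng(params.seed)
    x, intervals = _background(rng, params, params.duration_spont)
    template = ap_waveform or ap_template(params.fs)
    ap_times = _spont_aps(rng, params, x, template, params.duration_spont)
    trace = VmTrace(samples=x, fs=params.fs, meta={"kind": "spont"})
    truth = GroundTruth(
        state_intervals=intervals, ap_times=ap_times, drift=params.drift_slope
    )
    return trace, truth


def generate_trial_set(
    params: SynthParams,
    ap_waveform: APTemplate | None = None,
    pre_window: float = 0.2,
    post_window: float = 0.2,
) -> tuple[TrialSet, GroundTruth]:
    """Stimulation block: ``n_trials`` stimuli at ``isi`` spacing over the
    two-state background, each carrying a double-exponential EPSP unless it
    fails, with optional riding action potentials."""
    if params.n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    if params.isi < pre_window + post_window:
        raise ValidationError("isi too small for the pre+post analysis windows")
    rng = np.random.default_rng(params.seed)
    lead = max(pre_window + 0.3, 0.5)
    duration = lead + params.n_trials * params.isi + post_window + 0.3
    x, intervals = _background(rng, params, duration)
    template = ap_waveform or ap_template(params.fs)
    ap_times = list(_spont_aps(rng, params, x, template, duration))

    stim_times = lead + np.arange(params.n_trials) * params.isi
    state_vm = {  # instantaneous state level at each stimulus
        "down": params.v_down,
        "up": params.v_down + params.dv_updown,
    }

    def _state_at(t: float) -> str:
        for lab, a, b in intervals:
            if a <= t < b:
                return lab
        return "down"

    sigma2 = np.log(1.0 + (params.epsp_amp_sd / params.epsp_amp_mu) ** 2) if (
        params.epsp_amp_sd > 0 and params.epsp_amp_mu > 0
    ) else 0.0
    mu_log = np.log(params.epsp_amp_mu) - sigma2 / 2 if params.epsp_amp_mu > 0 else 0.0

    events: list[EPSPEvent] = []
    kernel_t = np.arange(int(round(0.3 * params.fs))) * 1000.0 / params.fs
    for i, t_stim in enumerate(stim_times):
        failed = rng.uniform() < params.p_fail
        amp = float(rng.lognormal(mu_log, np.sqrt(sigma2))) if sigma2 > 0 else params.epsp_amp_mu
        latency = float(
            max(rng.normal(params.epsp_latency_mu, params.epsp_latency_jitter), 0.5)
        )
        has_ap = (not failed) and (rng.uniform() < params.p_ap_given_epsp)
        if failed:
            events.append(EPSPEvent(i, 0.0, latency, True, False))
            continue
        vm_state = state_vm[_state_at(t_stim)]
        amp *= 1.0 + params.state_gain * (vm_state - params.v_down) / params.dv_updown
        onset = t_stim + latency / 1000.0
        i0 = int(round(onset * params.fs))
        wave = amp * epsp_kernel(kernel_t, params.epsp_tau_rise, params.epsp_tau_decay)
        hi = min(i0 + wave.size, x.size)
        x[i0:hi] += wave[: hi - i0]
        if has_ap:
            t_ap = onset + epsp_peak_delay_ms(
                params.epsp_tau_rise, params.epsp_tau_decay
            ) / 1000.0
            _insert_ap(x, template, t_ap, params.fs)
            ap_times.append(t_ap)
        events.append(EPSPEvent(i, amp, latency, False, has_ap))

    trace = VmTrace(samples=x, fs=params.fs, meta={"kind": "trials"})
    trialset = TrialSet(
        trace=trace, stim_times=stim_times, pre_window=pre_window,
        post_window=post_window,
    )
    truth = GroundTruth(
        state_intervals=intervals,
        epsp_events=events,
        ap_times=np.sort(np.asarray(ap_times)),
        drift=params.drift_slope,
    )
    return trialset, truth


# ---------------------------------------------------------------------------
# startle table


DEFAULT_INTENSITIES_DB = (71.0, 77.0, 83.0, 89.0)


def generate_startle_table(
    n_animals: int,
    group_params: dict[str, dict[str, float]],
    intensities: tuple[float, ...] = DEFAULT_INTENSITIES_DB,
    n_reps: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Acoustic-startle responses: animals x intensities x trials, long format.

    ``group_params`` maps group label to ``{"mean", "slope_per_db",
    "animal_sd", "trial_sd"}``: an animal's expected response grows linearly
    with intensity above the lowest level, each animal carries a random offset
    (``animal_sd``), and single trials scatter around the animal mean with
    ``trial_sd``. Columns: animal_id, group, intensity_db, trial, response.
    """
    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2")
    if not intensities:
        raise ValidationError("intensities must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for group, p in group_params.items():
        for key in ("animal_sd", "trial_sd"):
            if p[key] < 0:
                raise ValidationError(f"{key} must be >= 0")
        for a in range(n_animals):
            animal_id = f"{group}_{a:02d}"
            offset = rng.normal(0.0, p["animal_sd"])
            for db in intensities:
                mean = p["mean"] + p.get("slope_per_db", 0.0) * (db - intensities[0])
                for trial in range(n_reps):
                    resp = mean + offset + rng.normal(0.0, p["trial_sd"])
                    rows.append(
                        dict(
                            animal_id=animal_id, group=group, intensity_db=db,
                            trial=trial, response=resp,
                        )
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# current-step protocol and ADP trains


def generate_step_protocol(
    fs: float = 20000.0,
    v_rest: float = -70.0,
    r_input: float = 80.0,  # MOhm
    tau_m: float = 0.020,  # s, membrane time constant
    rheobase: float = 100.0,  # pA
    pa_per_extra_ap: float = 100.0,  # each extra `pa_per_extra_ap` adds one AP
    first_isi_ms: float = 12.0,
    isi_growth: float = 1.2,  # geometric inter-spike-interval growth
    currents: np.ndarray | None = None,
    step_dur: float = 0.5,
    step_onset: float = 0.1,
    ap_waveform: APTemplate | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[StepProtocol, dict]:
    """Current-step sweeps with known passive and spiking ground truth.

    Subthreshold responses follow a single-compartment RC charging curve
    (``dV = I * R * (1 - exp(-t/tau))``); sweeps at or above ``rheobase``
    additionally carry a regular-to-accommodating spike train whose count grows
    with the injected current and whose inter-spike intervals grow
    geometrically (``isi_growth``), so accommodation ratios have closed form.
    """
    if currents is None:
        currents = np.arange(-450.0, 550.0 + 1, 50.0)
    currents = np.asarray(currents, dtype=float)
    rng = np.random.default_rng(seed)
    template = ap_waveform or ap_template(fs, threshold_offset=25.0)
    n = int(round((step_onset + step_dur + 0.1) * fs))
    t = np.arange(n) / fs
    truth: dict = {"ap_counts": {}, "isis_ms": {}, "r_input": r_input, "tau_m": tau_m}
    sweeps = []
    for current in currents:
        x = np.full(n, v_rest)
        on = t >= step_onset
        dt = np.clip(t - step_onset, 0, None)
        charge = np.where(dt < step_dur, 1 - np.exp(-dt / tau_m),
                          (1 - np.exp(-step_dur / tau_m)) * np.exp(-(dt - step_dur) / tau_m))
        x += np.where(on, current * r_input * 1e-3 * charge, 0.0)
        n_aps = 0
        isis = []
        if current >= rheobase:
            n_aps = 1 + int((current - rheobase) // pa_per_extra_ap)
            t_ap = step_onset + 0.02
            ap_times = [t_ap]
            isi = first_isi_ms / 1000.0
            for _ in range(n_aps - 1):
                t_ap = t_ap + isi
                if t_ap > step_onset + step_dur - 0.005:
                    break
                ap_times.append(t_ap)
                isis.append(isi * 1000.0)
                isi *= isi_growth
            isis = isis[: len(ap_times) - 1]
            n_aps = len(ap_times)
            for t_ap in ap_times:
                _insert_ap(x, template, t_ap, fs)
        if noise_sd > 0:
            x += rng.normal(0, noise_sd, n)
        truth["ap_counts"][float(current)] = n_aps
        truth["isis_ms"][float(current)] = isis
        sweeps.append(VmTrace(samples=x, fs=fs, meta={"current_pa": float(current)}))
    protocol = StepProtocol(
        currents=currents, sweeps=sweeps, step_dur=step_dur, step_onset=step_onset
    )
    truth["rheobase"] = float(rheobase)
    truth["template"] = template
    return protocol, truth


def generate_adp_trials(
    params: SynthParams,
    n_trains: int = 5,
    train_freq: float = 100.0,  # Hz within the 3-AP train
    adp_amp: float = 2.0,  # mV at 5 ms after the last peak
    force_downstate: bool = True,
    ap_waveform: APTemplate | None = None,
) -> tuple[VmTrace, list[float], GroundTruth]:
    """Trace with 3-AP trains plus an after-depolarization of known amplitude.

    Returns the trace, the train onset times (time of the first AP peak per
    train), and the ground truth. The ADP is an alpha-shaped bump whose value
    exactly 5 ms after the last AP peak equals ``adp_amp``. Trains are placed
    inside downstates (or upstates when ``force_downstate`` is False).
    """
    rng = np.random.default_rng(params.seed)
    duration = params.duration_spont
    x, intervals = _background(rng, params, duration)
    template = ap_waveform or ap_template(params.fs)
    want = "down" if force_downstate else "up"
    hosts = [(a, b) for lab, a, b in intervals if lab == want and (b - a) > 0.5]
    if len(hosts) < n_trains:
        raise ValidationError("not enough host states for the requested trains")
    idx = rng.choice(len(hosts), size=n_trains, replace=False)
    train_times = []
    isi = 1.0 / train_freq
    tau_adp_ms = 5.0  # alpha bump peaking at +5 ms with value adp_amp
    for k in sorted(idx):
        a, b = hosts[k]
        t0 = a + 0.15
        peaks = [t0, t0 + isi, t0 + 2 * isi]
        for t_ap in peaks:
            _insert_ap(x, template, t_ap, params.fs)
        last = peaks[-1]
        i0 = int(round(last * params.fs))
        n_bump = int(round(0.05 * params.fs))
        tb = np.arange(n_bump) * 1000.0 / params.fs  # ms after last peak
        bump = adp_amp * (tb / tau_adp_ms) * np.exp(1 - tb / tau_adp_ms)
        hi = min(i0 + n_bump, x.size)
        x[i0:hi] += bump[: hi - i0]
        train_times.append(t0)
    trace = VmTrace(samples=x, fs=params.fs, meta={"kind": "adp_trains"})
    truth = GroundTruth(state_intervals=intervals)
    return trace, train_times, truth
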