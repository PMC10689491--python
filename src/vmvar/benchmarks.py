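"""Ground-truth validation benchmarks on synthetic recordings.

Each routine generates data from the synthetic model, runs the corresponding
analysis stage, and measures recovery against the known truth. They back the
acceptance checks and the reproduction script; problem sizes default to the
scales those checks run at.
"""

from __future__ import annotations

import numpy as np

from . import epsp as epsp_mod
from . import spectral as spectral_mod
from . import states as states_mod
from . import stats as stats_mod
from .pipeline import AnalysisConfig, run_cell, simulate_cell
from .synth import BAND_CENTERS, SynthParams, epsp_kernel, genotype_presets, generate_trace
from .trace import TrialSet, VmTrace

__all__ = [
    "segmentation_benchmark",
    "short_event_absorption",
    "spectral_benchmark",
    "epsp_benchmark",
    "failure_boundary_sweep",
    "type1_calibration",
    "recovery_benchmark",
]


def segmentation_benchmark(
    n_traces: int = 50,
    seed: int = 0,
    fs: float = 2000.0,
    duration: float = 180.0,
    dv_updown: float = 6.0,
    noise_sd: float = 1.2,
) -> dict:
    """Boundary recovery on two-state traces with known state intervals.

    Balanced up/down durations, state contrast over noise of 5 by default.
    Returns the pooled fraction of true boundaries detected within 25 ms, the
    shortest segment ever produced (ms), and the boundary count.
    """
    within = 0
    total = 0
    min_seg = np.inf
    for k in range(n_traces):
        p = genotype_presets(
            "wt_like", fs=fs, duration_spont=duration, seed=seed + k,
            dv_updown=dv_updown, noise_sd=noise_sd, dur_up=0.5, dur_down=0.5,
            osc_amp={b: 0.0 for b in BAND_CENTERS}, spont_ap_rate=0.0,
        )
        trace, truth = generate_trace(p)
        segs = states_mod.segment_states(trace)
        min_seg = min(min_seg, min(s.duration for s in segs))
        det = np.array([s.end for s in segs[:-1]])
        true_bounds = np.array([b for _, _, b in truth.state_intervals[:-1]])
        for tb in true_bounds:
            total += 1
            if det.size and np.min(np.abs(det - tb)) <= 0.025:
                within += 1
    return {
        "boundary_within_25ms_pct": 100.0 * within / total,
        "min_segment_ms": min_seg * 1000.0,
        "n_boundaries": total,
    }


def short_event_absorption(n_cases: int = 10, seed: int = 0, fs: float = 1000.0) -> dict:
    """80-ms up-excursions inserted into downstates must never count as states."""
    changed = 0
    min_seg = np.inf
    rng = np.random.default_rng(seed)
    half = int(0.5 * fs)
    cycle = np.concatenate([np.full(half, -70.0), np.full(half, -64.0)])
    for _ in range(n_cases):
        x = np.tile(cycle, 20) + rng.normal(0, 0.3, 20 * 2 * half)
        base = states_mod.segment_states(VmTrace(samples=x.copy(), fs=fs), detrend=False)
        n_up = sum(1 for s in base if s.label == "up")
        k = int(rng.integers(3, 17))
        i0 = int((k + 0.2) * fs)  # inside the downstate [k, k+0.5)
        x[i0 : i0 + int(0.08 * fs)] += 6.0
        segs = states_mod.segment_states(VmTrace(samples=x, fs=fs), detrend=False)
        min_seg = min(min_seg, min(s.duration for s in segs))
        if sum(1 for s in segs if s.label == "up") != n_up:
            changed += 1
    return {"excursions_miscounted": changed, "min_segment_ms": min_seg * 1000.0}


def spectral_benchmark(seed: int = 0, fs: float = 1000.0, duration: float = 180.0) -> dict:
    """Tone and white-noise closed forms for the Welch/band-power stage."""
    t = np.arange(int(duration * fs)) / fs
    amp = 2.0
    tone_errs = []
    bands_correct = 0
    tones = (2.0, 6.0, 10.0, 20.0, 60.0)
    for f0 in tones:
        trace = VmTrace(samples=amp * np.sin(2 * np.pi * f0 * t), fs=fs)
        psd = spectral_mod.welch_psd(trace)
        tone_errs.append(abs(psd.total_power() - amp**2 / 2) / (amp**2 / 2))
        own = spectral_mod.assign_band(f0)
        others = sum(v for k, v in psd.band_powers.items() if k != own)
        if own is not None and psd.band_powers[own] > 100 * max(others, 1e-300):
            bands_correct += 1
    rng = np.random.default_rng(seed)
    noise = VmTrace(samples=rng.normal(0, 1, int(duration * fs)), fs=fs)
    parseval = spectral_mod.welch_psd(noise).total_power()
    return {
        "tone_power_max_rel_err_pct": 100.0 * max(tone_errs),
        "tone_band_assignment_correct": bands_correct,
        "n_tones": len(tones),
        "white_noise_total_power": parseval,
    }


def epsp_benchmark(fs: float = 20000.0) -> dict:
    """Noiseless double-exponential recovery against dense closed forms."""
    amp_errs, hw_errs = [], []
    for amp, tr, td in [(5.0, 2.0, 15.0), (3.0, 1.0, 10.0), (8.0, 3.0, 25.0)]:
        n = int(0.2 * fs)
        t_ms = (np.arange(n) + 1) * 1000.0 / fs
        resp = -70.0 + amp * epsp_kernel(t_ms - 8.0, tr, td)
        lead = np.full(int(0.3 * fs), -70.0)
        x = np.concatenate([lead, resp, np.full(int(0.01 * fs), resp[-1])])
        ts = TrialSet(
            trace=VmTrace(samples=x, fs=fs), stim_times=np.array([lead.size / fs])
        )
        f = epsp_mod.detect_epsp(ts, 0)
        amp_errs.append(abs(f.amplitude - amp) / amp)
        tt = np.arange(0, 200, 1e-4)
        y = amp * epsp_kernel(tt, tr, td)
        span = tt[y >= amp / 2]
        fwhm = span[-1] - span[0]
        hw_errs.append(abs(f.half_width - fwhm) / fwhm)
    return {
        "amplitude_max_rel_err_pct": 100.0 * max(amp_errs),
        "half_width_max_rel_err_pct": 100.0 * max(hw_errs),
    }


def failure_boundary_sweep(fs: float = 20000.0) -> dict:
    """The failure rule must flip exactly at amplitude = 2 x baseline SD."""
    n = int(0.2 * fs)
    base = np.full(n, -70.0)
    base[::2] += 0.1
    base[1::2] -= 0.1
    sd = float(np.std(base, ddof=1))
    misclassified = 0
    checked = 0
    for rel in (0.5, 0.9, 0.99, 0.999, 1.001, 1.01, 1.1, 2.0):
        amp = rel * 2 * sd
        resp = np.full(n, -70.0)
        resp[n // 2 : n // 2 + 200] = -70.0 + amp
        lead = np.full(int(0.1 * fs), -70.0)
        x = np.concatenate([lead, base, resp, np.full(200, -70.0)])
        ts = TrialSet(
            trace=VmTrace(samples=x, fs=fs),
            stim_times=np.array([(lead.size + n) / fs]),
        )
        f = epsp_mod.detect_epsp(ts, 0)
        expected = "failure" if amp < 2 * sd else "epsp"
        checked += 1
        if f.outcome != expected:
            misclassified += 1
    return {"boundary_points_checked": checked, "boundary_misclassified": misclassified}


def type1_calibration(
    seed: int = 0, n_sims: int = 1000, n1: int = 16, n2: int = 17,
    n_perm: int = 999,
) -> dict:
    """False-positive rates of the three comparison paths under their nulls."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["a", "b"], [n1, n2])
    rej = {"compare": 0, "variance": 0, "permutation": 0}
    for k in range(n_sims):
        x = rng.normal(0, 1, n1 + n2)
        if stats_mod.compare_groups(x, groups).p < 0.05:
            rej["compare"] += 1
        if stats_mod.variance_test(x, groups).p < 0.05:
            rej["variance"] += 1
        if stats_mod.permutation_test(
            x, groups, n_perm=n_perm, seed=int(rng.integers(2**31))
        ).p < 0.05:
            rej["permutation"] += 1
    return {
        "type1_compare_groups": rej["compare"] / n_sims,
        "type1_variance_test": rej["variance"] / n_sims,
        "type1_permutation_test": rej["permutation"] / n_sims,
        "n_sims": n_sims,
    }


RECOVERY_METRICS = (
    "tbt_sd_amplitude", "baseline_sd", "up_freq", "micro_count", "spont_rate"
)


def recovery_benchmark(
    seed: int = 0,
    n_cohorts: int = 50,
    cells_per_group: int = 4,
    fs: float = 10000.0,
    duration_spont: float = 60.0,
) -> dict:
    """Directional genotype-contrast recovery over paired synthetic cohorts.

    Each cohort holds ``cells_per_group`` wild-type-like and knockout-like
    cells generated from paired seeds (identical background realizations, so
    the contrast isolates the parameter changes). Recovery in a cohort means
    the knockout-like group mean exceeds the wild-type-like one — except for
    micro-upstates, whose qualitative signature is a nonzero count in the
    knockout-like group (detected counts in either group also include
    fragmentation artifacts of the median threshold, so a strict inequality
    is not the method's claim). The baseline-SD ratio is pooled over all
    cohorts.
    """
    config = AnalysisConfig(seg_epoch=duration_spont, spont_window=duration_spont)
    wins = {m: 0 for m in RECOVERY_METRICS}
    wt_base, ko_base = [], []
    for c in range(n_cohorts):
        means: dict[str, dict[str, list[float]]] = {
            g: {m: [] for m in RECOVERY_METRICS} for g in ("wt", "ko")
        }
        for i in range(cells_per_group):
            cell_seed = seed + 997 * c + i
            for g, preset in (("wt", "wt_like"), ("ko", "ko_like")):
                params = genotype_presets(
                    preset, fs=fs, duration_spont=duration_spont, seed=cell_seed
                )
                summary = run_cell(
                    simulate_cell(params, f"{g}{c}_{i}", g), config
                )
                for m in RECOVERY_METRICS:
                    if m in summary.params:
                        means[g][m].append(summary.params[m])
                if "baseline_sd" in summary.params:
                    (wt_base if g == "wt" else ko_base).append(
                        summary.params["baseline_sd"]
                    )
        for m in RECOVERY_METRICS:
            wt_m = np.mean(means["wt"][m]) if means["wt"][m] else np.nan
            ko_m = np.mean(means["ko"][m]) if means["ko"][m] else np.nan
            if not (np.isfinite(wt_m) and np.isfinite(ko_m)):
                continue
            if m == "micro_count":
                if ko_m > 0:
                    wins[m] += 1
            elif ko_m > wt_m:
                wins[m] += 1
    out = {f"recovered_{m}_pct": 100.0 * wins[m] / n_cohorts for m in RECOVERY_METRICS}
    out["baseline_sd_ratio"] = float(np.mean(ko_base) / np.mean(wt_base))
    out["n_cohorts"] = n_cohorts
    return out
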