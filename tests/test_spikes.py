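"""Spike detection and spontaneous/evoked firing metrics."""

import numpy as np
import pytest

from vmvar import spikes, synth
from vmvar.trace import TrialSet, ValidationError, VmTrace

FS = 20000.0


def _trace_with_aps(times, fs=FS, dur=10.0, noise=0.0, seed=0, **tpl_kw):
    tpl = synth.ap_template(fs, **tpl_kw)
    x = np.full(int(dur * fs), -70.0)
    for t in times:
        synth._insert_ap(x, tpl, t, fs)
    if noise > 0:
        x += np.random.default_rng(seed).normal(0, noise, x.size)
    return VmTrace(samples=x, fs=fs)


def test_threshold_recovery_within_half_mv():
    """10 mV/ms crossing of the template sits 25 mV above baseline (-45 mV)."""
    for hw in (0.5, 1.0, 2.0):
        trace = _trace_with_aps([0.5], half_width_ms=hw)
        events = spikes.detect_aps(trace)
        assert len(events) == 1
        assert events[0].threshold_vm == pytest.approx(-45.0, abs=0.5)
        assert events[0].half_width == pytest.approx(hw, rel=0.05)


def test_subthreshold_epsp_not_detected():
    t = np.arange(int(2 * FS)) / FS * 1000.0
    x = -70.0 + 5.0 * synth.epsp_kernel(t - 500.0, 2.0, 15.0)
    assert spikes.detect_aps(VmTrace(samples=x, fs=FS)) == []


def test_doublet_refractory():
    trace = _trace_with_aps([0.5, 0.5015])  # peaks 1.5 ms apart
    assert len(spikes.detect_aps(trace)) == 1
    trace = _trace_with_aps([0.5, 0.503])  # 3 ms apart: two events
    assert len(spikes.detect_aps(trace)) == 2


def test_detection_recall_and_precision_noiseless():
    rng = np.random.default_rng(3)
    times = np.sort(rng.uniform(0.5, 9.5, 8))
    times = times[np.concatenate([[True], np.diff(times) > 0.02])]
    events = spikes.detect_aps(_trace_with_aps(times))
    det = np.array([e.peak_time for e in events])
    assert det.size == times.size
    assert np.all(np.abs(det - times) < 0.001)


def test_detection_recall_at_1mv_noise():
    rng = np.random.default_rng(4)
    hits = total = false_pos = 0
    for seed in range(10):
        times = np.sort(rng.uniform(0.5, 9.5, 5))
        times = times[np.concatenate([[True], np.diff(times) > 0.02])]
        events = spikes.detect_aps(_trace_with_aps(times, noise=1.0, seed=seed))
        det = np.array([e.peak_time for e in events])
        total += times.size
        hits += sum(1 for t in times if det.size and np.min(np.abs(det - t)) < 0.002)
        false_pos += sum(1 for d in det if np.min(np.abs(times - d)) > 0.002)
    assert hits / total >= 0.95
    assert false_pos <= 1


def test_requires_10khz():
    with pytest.raises(ValidationError, match="10 kHz"):
        spikes.detect_aps(VmTrace(samples=np.zeros(1000), fs=1000.0))


def test_spontaneous_metrics():
    silent = VmTrace(samples=np.full(int(120 * 10000), -70.0), fs=10000.0)
    active_flag, rate = spikes.spontaneous_metrics(silent, events=[])
    assert (active_flag, rate) == (False, 0.0)

    trace = _trace_with_aps(list(np.linspace(5, 115, 6)), dur=120.0)
    active_flag, rate = spikes.spontaneous_metrics(trace)
    assert active_flag is True
    assert rate == pytest.approx(6 / 120.0)

    with pytest.raises(ValidationError):
        spikes.spontaneous_metrics(VmTrace(samples=np.zeros(1000), fs=10000.0))


def test_spont_rate_poisson_recovery():
    rates = []
    for seed in range(40):
        p = synth.genotype_presets(
            "wt_like", fs=10000.0, duration_spont=120.0, seed=seed,
            spont_ap_rate=0.05, noise_sd=0.2,
        )
        trace, truth = synth.generate_trace(p)
        _, rate = spikes.spontaneous_metrics(trace)
        rates.append(rate)
    assert np.mean(rates) == pytest.approx(0.05, abs=0.01)


def _trialset(fs=FS, n_trials=4, isi=1.0):
    n = int((n_trials * isi + 1.0) * fs)
    trace = VmTrace(samples=np.full(n, -70.0), fs=fs)
    stims = 0.5 + np.arange(n_trials) * isi
    return TrialSet(trace=trace, stim_times=stims)


def test_evoked_counts_subtraction():
    ts = _trialset(n_trials=2)
    tpl = synth.ap_template(FS)
    x = ts.trace.samples
    t0 = ts.stim_times[0]
    for t in (t0 - 0.15, t0 + 0.02, t0 + 0.05, t0 + 0.12):  # 1 pre, 3 post
        synth._insert_ap(x, tpl, t, FS)
    events = spikes.detect_aps(ts.trace)
    evoked, mean, cv, per_success = spikes.evoked_counts(ts, events)
    assert evoked[0] == 2.0  # 3 post - 1 pre
    assert evoked[1] == 0.0
    assert per_success == pytest.approx(2.0)  # 2 evoked / 1 successful trial


def test_evoked_counts_constructed_ratio():
    """12 evoked APs over 10 successful trials -> 1.2 per successful trial."""
    ts = _trialset(n_trials=40)
    peaks = []
    for i in range(10):
        t = ts.stim_times[i]
        peaks.extend(t + 0.01 + 0.01 * np.arange(1 if i < 8 else 2))
    events = [spikes.APEvent(p, p, 30.0, -45.0, 1.0) for p in sorted(peaks)]
    evoked, mean, cv, per_success = spikes.evoked_counts(ts, events)
    assert np.sum(evoked) == 12
    assert per_success == pytest.approx(1.2)


def test_evoked_counts_no_aps_cv_undefined():
    ts = _trialset()
    evoked, mean, cv, per_success = spikes.evoked_counts(ts, [])
    assert np.all(evoked == 0)
    assert cv is None and per_success is None


def test_evoked_translation_invariance():
    ts = _trialset(n_trials=2)
    tpl = synth.ap_template(FS)
    synth._insert_ap(ts.trace.samples, tpl, ts.stim_times[0] + 0.02, FS)
    e1 = spikes.evoked_counts(ts, spikes.detect_aps(ts.trace))[0]
    shifted = TrialSet(
        trace=VmTrace(samples=ts.trace.samples + 12.0, fs=FS),
        stim_times=ts.stim_times,
    )
    e2 = spikes.evoked_counts(shifted, spikes.detect_aps(shifted.trace))[0]
    assert np.array_equal(e1, e2)


def test_first_ap_jitter():
    ts = _trialset(n_trials=4)
    onsets_ms = [12.0, 15.0, 18.0]
    events = [
        spikes.APEvent(ts.stim_times[i] + ms / 1000.0, ts.stim_times[i] + ms / 1000.0,
                       30.0, -45.0, 1.0)
        for i, ms in enumerate(onsets_ms)
    ]
    # fourth trial has its first AP at 75 ms: outside the 70-ms window
    events.append(spikes.APEvent(ts.stim_times[3] + 0.075, ts.stim_times[3] + 0.075,
                                 30.0, -45.0, 1.0))
    latencies, jitter = spikes.first_ap_jitter(ts, events)
    assert latencies.size == 3
    assert jitter == pytest.approx(3.0)


def test_first_ap_jitter_identical_zero():
    ts = _trialset(n_trials=3)
    events = [
        spikes.APEvent(t + 0.012, t + 0.012, 30.0, -45.0, 1.0) for t in ts.stim_times
    ]
    _, jitter = spikes.first_ap_jitter(ts, events)
    assert jitter == pytest.approx(0.0, abs=1e-12)


def test_classify_cell():
    outcomes = ["ap"] * 10 + ["epsp"] * 25 + ["failure"] * 5
    fractions, cls = spikes.classify_cell(outcomes)
    assert fractions == {"ap": 0.25, "epsp": 0.625, "failure": 0.125}
    assert sum(fractions.values()) == 1.0
    assert cls == "AP-EPSP"
    fractions, cls = spikes.classify_cell(["epsp"] * 30 + ["failure"] * 10)
    assert cls == "EPSP-only"


def test_class_separation_by_generator_probability():
    classes = {0.0: [], 0.3: []}
    for p_ap in classes:
        for seed in range(10):
            p = synth.genotype_presets(
                "wt_like", fs=10000.0, seed=seed, p_ap_given_epsp=p_ap, p_fail=0.0,
                spont_ap_rate=0.0,
            )
            _, truth = synth.generate_trial_set(p)
            has_ap = any(e.has_ap for e in truth.epsp_events)
            classes[p_ap].append(has_ap)
    assert not any(classes[0.0])
    assert all(classes[0.3])
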