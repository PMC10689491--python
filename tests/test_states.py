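"""Gliding-median segmentation: thresholds, labels, short-event removal."""

import numpy as np
import pytest

from conftest import two_state_square
from vmvar import states, synth
from vmvar.trace import ValidationError, VmTrace


def test_detrend_removes_ramp_exactly():
    fs = 1000.0
    n = int(180 * fs)
    ramp = np.linspace(0.0, 10.0, n)
    out = states.detrend_linear(VmTrace(samples=ramp, fs=fs))
    assert np.allclose(out.samples, 5.0, atol=1e-9)


def test_detrend_zero_slope_identity():
    fs = 1000.0
    rng = np.random.default_rng(0)
    x = -70 + rng.normal(0, 1, int(10 * fs))
    x -= np.polyfit(np.arange(x.size) / fs, x, 1)[0] * np.arange(x.size) / fs
    out = states.detrend_linear(VmTrace(samples=x, fs=fs))
    assert np.allclose(out.samples, x, atol=1e-9)


def test_detrend_recovers_slope_on_square_wave():
    fs = 1000.0
    x = two_state_square(fs, 1.0, 180).astype(float)
    t = np.arange(x.size) / fs
    trace = VmTrace(samples=x + 0.05 * t, fs=fs)
    out = states.detrend_linear(trace)
    assert out.meta["drift_slope_removed_mv_per_s"] == pytest.approx(0.05, abs=0.001)


def test_gliding_threshold_constant():
    trace = VmTrace(samples=np.full(5000, -70.0), fs=1000.0)
    thr = states.gliding_threshold(trace)
    assert np.all(thr == -70.0)
    assert thr.size == 5


def test_gliding_threshold_square_wave_midpoint():
    fs = 1000.0
    trace = VmTrace(samples=two_state_square(fs, 1.0, 20), fs=fs)
    thr = states.gliding_threshold(trace)
    # interior seconds see a perfectly balanced bimodal window
    assert np.all(thr[4:16] == -60.0)


def test_gliding_threshold_edge_truncation():
    fs = 1000.0
    # first 4 s at -70, rest at -50: threshold at t=0 is median over [0, 4 s)
    x = np.concatenate([np.full(int(4 * fs), -70.0), np.full(int(8 * fs), -50.0)])
    thr = states.gliding_threshold(VmTrace(samples=x, fs=fs))
    assert thr[0] == -70.0


def test_segment_constant_trace_is_single_downstate():
    trace = VmTrace(samples=np.full(3000, -70.0), fs=1000.0)
    segs = states.segment_states(trace, detrend=False)
    assert len(segs) == 1
    assert segs[0].label == "down"
    assert (segs[0].start, segs[0].end) == (0.0, 3.0)


def test_segment_alternating_plateaus():
    fs = 1000.0
    trace = VmTrace(samples=two_state_square(fs, 1.0, 20), fs=fs)
    segs = states.segment_states(trace, detrend=False)
    ups = [s for s in segs if s.label == "up"]
    downs = [s for s in segs if s.label == "down"]
    assert len(ups) == 20
    # true boundaries at k*0.5 s; detected within 25 ms
    for s in segs[1:-1]:
        assert min(abs(s.start - k * 0.5) for k in range(1, 41)) <= 0.025
    assert all(abs(s.mean_vm - -50.0) < 1e-6 for s in ups)
    assert all(abs(s.mean_vm - -70.0) < 1e-6 for s in downs)


def test_sub100ms_excursion_absorbed():
    # mild noise keeps the gliding median between the two modes (a perfectly
    # noise-free unbalanced square wave is degenerate for a median threshold)
    fs = 1000.0
    rng = np.random.default_rng(0)
    noise = rng.normal(0, 0.2, int(20 * fs))
    x = two_state_square(fs, 1.0, 20) + noise
    n_up_before = sum(
        1 for s in states.segment_states(VmTrace(samples=x.copy(), fs=fs), detrend=False)
        if s.label == "up"
    )
    # insert an 80-ms up-excursion mid-downstate (at 10.1 s, downstate 10.0-10.5)
    i0 = int(10.1 * fs)
    x[i0 : i0 + int(0.08 * fs)] += 20.0
    segs = states.segment_states(VmTrace(samples=x, fs=fs), detrend=False)
    n_up_after = sum(1 for s in segs if s.label == "up")
    assert n_up_after == n_up_before
    assert min(s.duration for s in segs) >= 0.1 - 1e-9


def test_segmentation_tiles_epoch():
    p = synth.genotype_presets("ko_like", fs=2000.0, duration_spont=30.0, seed=2)
    trace, _ = synth.generate_trace(p)
    segs = states.segment_states(trace)
    assert segs[0].start == 0.0
    assert segs[-1].end == pytest.approx(trace.duration)
    for a, b in zip(segs[:-1], segs[1:]):
        assert a.end == pytest.approx(b.start)
        assert a.label != b.label
    assert sum(s.duration for s in segs) == pytest.approx(trace.duration)
    assert min(s.duration for s in segs) >= 0.1 - 1e-9


def test_idempotent_on_reconstructed_plateaus():
    # balanced alternating plateaus with slightly heterogeneous levels: the
    # gliding median stays strictly between the two level clusters, the
    # regime in which re-segmenting a plateau reconstruction is stable
    fs = 1000.0
    rng = np.random.default_rng(4)
    levels = []
    for k in range(20):
        levels.append(-70.0 + rng.normal(0, 0.2))
        levels.append(-64.0 + rng.normal(0, 0.2))
    x = np.concatenate([np.full(int(0.5 * fs), lv) for lv in levels])
    trace = VmTrace(samples=x, fs=fs)
    segs1 = states.segment_states(trace, detrend=False)
    rebuilt = np.empty_like(x)
    for s in segs1:
        i0, i1 = int(round(s.start * fs)), int(round(s.end * fs))
        rebuilt[i0:i1] = s.mean_vm
    segs2 = states.segment_states(VmTrace(samples=rebuilt, fs=fs), detrend=False)
    assert len(segs1) == len(segs2)
    for a, b in zip(segs1, segs2):
        assert a.label == b.label
        assert a.start == pytest.approx(b.start, abs=0.01)


def test_monotone_dvm_with_generator_contrast():
    kw = dict(fs=2000.0, duration_spont=30.0, seed=6, micro_up_rate=0.0)
    lo = synth.genotype_presets("wt_like", dv_updown=4.0, **kw)
    hi = synth.genotype_presets("wt_like", dv_updown=8.0, **kw)
    out = []
    for p in (lo, hi):
        trace, _ = synth.generate_trace(p)
        summary = states.summarize_states(states.segment_states(trace), trace)
        out.append(summary.dvm_updown)
    assert out[1] > out[0]


def test_summary_statistics():
    segs = [
        states.StateSegment("down", 0.0, 10.0, -70.0),
        states.StateSegment("up", 10.0, 10.12, -50.0),
        states.StateSegment("down", 10.12, 100.0, -70.0),
        states.StateSegment("up", 100.0, 100.4, -50.0),
        states.StateSegment("down", 100.4, 150.0, -70.0),
        states.StateSegment("up", 150.0, 150.14, -50.0),
        states.StateSegment("down", 150.14, 180.0, -70.0),
    ]
    s = states.summarize_states(segs)
    assert s.up_freq == pytest.approx(3 / 180.0)  # 0.0167 Hz
    assert s.micro_count == 2  # 0.12 and 0.14 s; 0.4 s is not micro
    assert s.dvm_updown == pytest.approx(20.0)
    assert np.allclose(s.up_vm_norm, 20.0)


def test_summary_single_state_undefined_contrast():
    segs = [states.StateSegment("down", 0.0, 180.0, -70.0)]
    s = states.summarize_states(segs)
    assert s.dvm_updown is None
    assert s.up_freq == 0.0


def test_short_trace_errors():
    with pytest.raises(ValidationError):
        states.gliding_threshold(VmTrace(samples=np.zeros(100), fs=1000.0))
    with pytest.raises(ValidationError):
        states.detrend_linear(VmTrace(samples=np.zeros(1), fs=1000.0))
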