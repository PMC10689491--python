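"""Generator ground-truth guarantees: determinism, closed-form statistics."""

import numpy as np
import pytest

from vmvar import synth
from vmvar.trace import ValidationError


def test_presets():
    wt = synth.genotype_presets("wt_like")
    ko = synth.genotype_presets("ko_like")
    assert wt.micro_up_rate == 0.0
    assert ko.micro_up_rate > 0.0
    assert ko.noise_sd == pytest.approx(2 * wt.noise_sd)
    for band in wt.osc_amp:
        assert ko.osc_amp[band] == pytest.approx(2 * wt.osc_amp[band])
    assert ko.dv_updown > wt.dv_updown
    assert ko.spont_ap_rate > wt.spont_ap_rate
    assert ko.epsp_amp_sd > wt.epsp_amp_sd
    with pytest.raises(ValidationError, match="wt_like"):
        synth.genotype_presets("xx")


def test_seeded_determinism():
    p = synth.genotype_presets("ko_like", fs=2000.0, duration_spont=10.0, seed=42)
    a, _ = synth.generate_trace(p)
    b, _ = synth.generate_trace(p)
    assert np.array_equal(a.samples, b.samples)
    ts1, _ = synth.generate_trial_set(
        synth.genotype_presets("ko_like", fs=2000.0, seed=7, n_trials=5)
    )
    ts2, _ = synth.generate_trial_set(
        synth.genotype_presets("ko_like", fs=2000.0, seed=7, n_trials=5)
    )
    assert np.array_equal(ts1.trace.samples, ts2.trace.samples)


def test_noise_free_trace_is_pure_step_function():
    p = synth.genotype_presets(
        "wt_like", fs=2000.0, duration_spont=20.0, seed=3,
        noise_sd=0.0, osc_amp={k: 0.0 for k in synth.BAND_CENTERS},
        drift_slope=0.0, spont_ap_rate=0.0,
    )
    trace, truth = synth.generate_trace(p)
    levels = set(np.unique(trace.samples))
    assert levels <= {p.v_down, p.v_down + p.dv_updown}
    # trace equals the ground-truth state waveform sample by sample
    for lab, a, b in truth.state_intervals:
        seg = trace.window(a + 1e-9, b - 1e-9) if b - a > 1e-6 else []
        expect = p.v_down + (p.dv_updown if lab == "up" else 0.0)
        assert np.all(seg == expect)


def test_state_intervals_tile_epoch():
    p = synth.genotype_presets("ko_like", fs=2000.0, duration_spont=60.0, seed=11)
    _, truth = synth.generate_trace(p)
    iv = truth.state_intervals
    assert iv[0][1] == 0.0
    assert iv[-1][2] == pytest.approx(60.0)
    for (_, _, b), (_, a2, _) in zip(iv[:-1], iv[1:]):
        assert b == pytest.approx(a2)
    total = sum(b - a for _, a, b in iv)
    assert total == pytest.approx(60.0)


def test_ko_trace_has_larger_downstate_sd_same_seed():
    kw = dict(fs=2000.0, duration_spont=30.0, seed=5)
    wt_tr, wt_truth = synth.generate_trace(synth.genotype_presets("wt_like", **kw))
    ko_tr, _ = synth.generate_trace(synth.genotype_presets("ko_like", **kw))
    # any 200-ms window strictly inside a wt downstate
    downs = [(a, b) for lab, a, b in wt_truth.state_intervals if lab == "down" and b - a > 0.4]
    a, b = downs[0]
    mid = (a + b) / 2
    wt_sd = np.std(wt_tr.window(mid - 0.1, mid + 0.1), ddof=1)
    ko_sd = np.std(ko_tr.window(mid - 0.1, mid + 0.1), ddof=1)
    assert ko_sd > wt_sd


def test_oscillation_parseval():
    """Variance of an oscillation-only trace equals sum A^2/2 within 2%."""
    p = synth.genotype_presets(
        "wt_like", fs=2000.0, duration_spont=180.0, seed=1,
        noise_sd=0.0, dv_updown=1e-9, spont_ap_rate=0.0,
    )
    # suppress the state step by a negligible contrast
    trace, _ = synth.generate_trace(p)
    expected = sum(a**2 / 2 for a in p.osc_amp.values())
    assert np.var(trace.samples) == pytest.approx(expected, rel=0.02)


def test_filtered_oscillation_mode_matches_variance():
    """Filtered-noise oscillations carry the same total variance as the
    sinusoidal mode and spread energy across (not outside) the bands."""
    base = dict(fs=1000.0, duration_spont=120.0, seed=2, noise_sd=0.0,
                dv_updown=1e-9, spont_ap_rate=0.0)
    sin_tr, _ = synth.generate_trace(synth.genotype_presets("wt_like", **base))
    filt_tr, _ = synth.generate_trace(
        synth.genotype_presets("wt_like", osc_mode="filtered", **base)
    )
    assert np.var(filt_tr.samples) == pytest.approx(np.var(sin_tr.samples), rel=0.05)
    with pytest.raises(ValidationError):
        synth.genotype_presets("wt_like", osc_mode="wideband")


def test_epsp_amplitude_lognormal_moments():
    p = synth.genotype_presets("ko_like")
    mu, sd = p.epsp_amp_mu, p.epsp_amp_sd
    sigma2 = np.log(1 + (sd / mu) ** 2)
    rng = np.random.default_rng(0)
    draws = rng.lognormal(np.log(mu) - sigma2 / 2, np.sqrt(sigma2), 10_000)
    assert np.mean(draws) == pytest.approx(mu, rel=0.03)
    assert np.std(draws, ddof=1) == pytest.approx(sd, rel=0.03)


def test_trial_set_degenerate_probabilities():
    base = dict(fs=2000.0, n_trials=40, seed=9)
    all_fail = synth.genotype_presets("wt_like", p_fail=1.0, **base)
    _, truth = synth.generate_trial_set(all_fail)
    assert all(e.failed for e in truth.epsp_events)

    frozen = synth.genotype_presets(
        "wt_like", p_fail=0.0, epsp_amp_sd=0.0, noise_sd=0.0,
        epsp_latency_jitter=0.0, state_gain=0.0, spont_ap_rate=0.0,
        osc_amp={k: 0.0 for k in synth.BAND_CENTERS}, dur_down=500.0, **base,
    )
    ts, truth = synth.generate_trial_set(frozen)
    amps = [e.amplitude for e in truth.epsp_events]
    assert np.std(amps) == 0.0
    # every trial window is sample-identical
    r0 = ts.response(0)
    for i in range(1, ts.n_trials):
        assert np.array_equal(ts.response(i), r0)


def test_ap_trial_fraction_matches_ground_truth():
    p = synth.genotype_presets(
        "wt_like", fs=2000.0, p_ap_given_epsp=0.25, p_fail=0.0, n_trials=40, seed=21
    )
    _, truth = synth.generate_trial_set(p)
    n_ap = sum(e.has_ap for e in truth.epsp_events)
    # binomial(40, 0.25): generous band around 10
    assert 3 <= n_ap <= 18


def test_trial_set_isi_guard():
    with pytest.raises(ValidationError, match="isi"):
        p = synth.genotype_presets("wt_like", fs=2000.0, n_trials=1, isi=0.3)
        synth.generate_trial_set(p)


def test_param_validation():
    with pytest.raises(ValidationError):
        synth.SynthParams(p_fail=1.5)
    with pytest.raises(ValidationError):
        synth.SynthParams(noise_sd=-1.0)
    with pytest.raises(ValidationError):
        synth.SynthParams(fs=100.0)
    with pytest.raises(ValidationError):
        synth.SynthParams(isi=2.0, n_trials=40)


def test_startle_table_layout():
    gp = {
        "wt": dict(mean=100.0, slope_per_db=5.0, animal_sd=10.0, trial_sd=8.0),
        "ko": dict(mean=100.0, slope_per_db=5.0, animal_sd=10.0, trial_sd=16.0),
    }
    table = synth.generate_startle_table(10, gp, seed=0)
    assert sorted(table["intensity_db"].unique()) == [71.0, 77.0, 83.0, 89.0]
    assert table.groupby(["animal_id", "intensity_db"])["trial"].count().eq(8).all()
    assert table["animal_id"].nunique() == 20

    frozen = synth.generate_startle_table(
        2, {"wt": dict(mean=50.0, animal_sd=5.0, trial_sd=0.0)}, seed=1
    )
    sds = frozen.groupby(["animal_id", "intensity_db"])["response"].std()
    assert (sds == 0).all()

    with pytest.raises(ValidationError):
        synth.generate_startle_table(
            2, {"wt": dict(mean=50.0, animal_sd=5.0, trial_sd=-1.0)}
        )


def test_ap_template_geometry():
    tpl = synth.ap_template(20000.0, threshold_offset=25.0, peak_offset=100.0,
                            half_width_ms=1.0)
    assert tpl.waveform.max() == pytest.approx(100.0)
    assert tpl.waveform[0] == 0.0
    # width at the mid level between threshold and peak equals half_width_ms
    level = 25.0 + 75.0 / 2
    above = np.flatnonzero(tpl.waveform >= level)
    width_ms = (above[-1] - above[0]) / 20.0
    assert width_ms == pytest.approx(1.0, abs=0.1)
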