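# Methods

This note documents the models, operational definitions and numerical choices
behind `vmvar`, including every place where a published description leaves a
judgement call open and which call this package makes.

## Synthetic membrane-potential model

The generator emulates anesthetized in vivo whole-cell recordings as a sum of
independent components:

- **Two-state process.** Alternating down/up states starting in the
  downstate, with gamma-distributed durations (shape 2, means `dur_down`,
  `dur_up`) floored at `min_state_dur = 0.3 s`. The floor keeps ordinary
  states well clear of both the detector's 100-ms removal rule and the
  100–150-ms micro-upstate band, so the ground truth for the micro counter is
  unambiguous. Micro-upstates are inserted explicitly into downstates as
  uniform 100–150-ms events at rate `micro_up_rate` (Poisson count over the
  epoch), with ≥120-ms margins so no sub-100-ms fragment is created. The
  downstate sits at `v_down = −70 mV`; upstates add `dv_updown`.
- **Oscillations.** By default one sinusoid per canonical band at its center
  frequency (2.25, 5.5, 10, 21.5, 65 Hz) with random phase, so each band's
  power is exactly A²/2 and the spectral stage has closed-form expectations.
  `osc_mode="filtered"` substitutes variance-matched Butterworth-band-passed
  white noise for realism (no line spectrum); the two modes carry identical
  total variance by construction.
- **White noise** (`noise_sd`), optional **linear drift** (`drift_slope`),
  and **spontaneous APs** (Poisson at `spont_ap_rate`).
- **Evoked responses.** Stimulation blocks of `n_trials = 40` at
  `isi = 3.4 s` (the stimulation-rate constraint is isi > 1/0.3 s). Each
  non-failure trial adds a unit-peak double exponential
  `exp(−t/τ_decay) − exp(−t/τ_rise)` scaled by a lognormal amplitude
  (parameterized by its mean and SD in mV) at a Gaussian-jittered latency.
  Failures occur with probability `p_fail`; with probability
  `p_ap_given_epsp` an AP template rides the EPSP peak. EPSP–state coupling
  is linear: amplitude × (1 + state_gain · (Vm_state − v_down)/dv_updown).
  This is a stand-in for the observed correlation between EPSP amplitude and
  baseline Vm, not a mechanistic claim — no conductances are modelled.
- **AP template.** Piecewise linear: a slow pre-potential (8 mV/ms, below
  the 10 mV/ms detection criterion) to `threshold_offset` (25 mV above the
  insertion baseline), a fast upstroke (400 mV/ms) to `peak_offset`
  (100 mV above baseline, i.e. +30 mV on a −70 mV downstate), then a linear
  downstroke solved from the requested half-width. The 10 mV/ms crossing
  therefore sits exactly at the prepotential→upstroke kink, giving detection
  tests an analytic threshold.

The two presets are the study conditions. `wt_like` is the default parameter
set (no micro-upstates, noise SD 0.4 mV, dv 6 mV, spontaneous rate 0.005 Hz,
EPSP 6 ± 1.5 mV). `ko_like` doubles every Vm-amplitude component — white
noise, all oscillation amplitudes, and the up–down contrast — so the
baseline-Vm SD is exactly twice the wild-type value by construction, and
additionally sets `micro_up_rate = 0.1 Hz` (carrying the upstate-frequency
increase), spontaneous rate 0.05 Hz, and EPSP 7 ± 3 mV. State-duration means
are identical across presets; with paired seeds the two genotypes share their
background realization and the contrast isolates the parameter changes.

What the generator does **not** emulate: conductance-based dynamics,
anesthesia-depth drift of state statistics, electrode/access artifacts,
synaptic background bombardment with realistic autocorrelation (unless the
filtered mode is used), or receptive-field structure. Passing tests therefore
demonstrate correctness of the analysis operations and recoverability of
planted effects — not that real recordings satisfy the model.

## State detection

Operational choices, in order of application:

1. **Drift correction always runs** (it is a no-op at zero slope), removing
   the judgement call of deciding when it is "necessary". The epoch mean is
   re-added so absolute Vm is preserved.
2. **Gliding threshold**: for each started second t, the median of all
   samples in [t − 4 s, t + 4 s), truncated at the epoch edges. Between
   evaluation points the threshold is sample-and-hold (each sample uses its
   containing second's value); linear interpolation is available via
   `threshold_mode="interp"`.
3. **Labelling**: a sample is up iff its ±50-ms local median (edge-truncated)
   strictly exceeds its threshold; ties go to the downstate (deterministic,
   biased toward quiescence).
4. **Sub-100-ms removal** relabels short segments into the flanking state —
   shortest first, merging and repeating until stable — which makes the
   result order-independent and keeps the segmentation a tiling of the
   epoch. Removal means relabelling, not exclusion: the statistics afterwards
   see a gapless alternating segmentation.

Known behaviour worth stating: with a perfectly noise-free two-level signal
the 8-s median can land exactly on a mode and the comparison degenerates;
any realistic noise restores a threshold between the modes. When the local
duty cycle of upstates in an 8-s window drifts past 50%, the threshold moves
into the majority cluster and oscillation troughs can fragment genuine
upstates; some fragments land in the 100–150-ms band, so detected
micro-upstate counts include fragmentation artifacts in *both* groups. The
planted knockout contrast remains recoverable because its micro events add
on top of this common background.

## Spectral analysis

- Welch: 4-s Hann segments, 50% overlap, mean averaging, one-sided density
  scaling (so the integrated PSD equals the signal variance). Total
  integrated power uses the trapezoid rule — Simpson's alternating weights
  misweight a near-delta tone peak — while **band** powers use the composite
  Simpson rule over [f_lo, f_hi] as the area-under-the-curve definition.
- Band edges are delta 0.5–4, theta 4–7, alpha 8–12, beta 13–30, gamma
  30–100 Hz; shared edges belong to the upper band for band *assignment*
  (half-open, last band closed).
- The 200-ms per-trial baseline cannot hold a 4-s Welch segment; it is
  analyzed as a single Hann periodogram (5-Hz bins at 20 kHz) with band
  powers as binned rectangle sums, NaN for bands with no bin (delta cannot
  be estimated in 200 ms — this is reported honestly rather than
  extrapolated). Powers are also returned normalized by |mean baseline Vm|.
- Morlet widths follow `(w · Fs)/(2 · y · π)` exactly, `w = 4` Hz; power is
  the magnitude of the complex coefficients; the 0–3 display saturation is
  metadata only.

## EPSP quantification

Windows are half-open: baseline [−200, 0) ms, response [0, 200) ms around
each stimulus. Amplitude is max(post) − mean(baseline); the failure rule is
exactly `amplitude < 2 × SD(baseline)` with the sample (n−1) SD. The
"baseline Vm variance" of the field is operationally this SD and is named
`baseline_sd` throughout. Half-width and 20–80% slope use linear
interpolation at level crossings on the rising/falling flanks.

**Onset latency.** A Gaussian never literally crosses its asymptote, so the
onset is operationalized as the earliest time the fitted Gaussian exceeds the
baseline by 1% of the fitted amplitude (tolerance configurable). The fit is
restricted to the *foot* of the final ascent (between 1% and 30% of the
amplitude): a free Gaussian fitted over the whole rise has a much wider flank
than a double-exponential foot and would bias the onset several ms early;
the foot-restricted fit recovers planted onsets within 0.5 ms on noiseless
input. If the fit fails, a threshold-crossing estimate is used and flagged;
if pre-stimulus drift holds the averaged response above the 1% level
everywhere, the level is re-referenced to the pre-peak minimum and flagged.

SNR per trial is amplitude divided by the across-trial sample variance of
amplitudes; failures are excluded from that variance (not imputed as zeros —
the published definition is silent on this, and imputation would conflate
failure rate with amplitude dispersion). Zero-variance cells return an
explicit undefined flag, never a numeric sentinel.

## AP detection and metrics

Detection: dV/dt of a 0.1-ms boxcar-smoothed trace crosses +10 mV/ms; the
subsequent 5-ms peak must rise ≥30 mV above the Vm at the crossing; 2-ms
peak-to-peak refractory. The crossing is refined on the raw forward
difference near the detection (the smoothing stencil leaks the upstroke a
couple of samples early), recovering template thresholds within 0.1 mV at
20 kHz. The prominence and refractory guards, and the smoothing width, are
configuration, since no published detector is specified for spontaneous
spikes; they are chosen to reject EPSP peaks (≤ ~15 mV) while keeping
template spikes (75 mV above threshold). Negative evoked counts
(pre > post) are retained, as the subtraction definition permits.

## Intrinsic properties

Maximum AP frequency is count/step-duration of the sweep with the most
spikes (not 1/min ISI). Accommodation uses the *lowest*-current sweep with
≥5 spikes. ADP: only trains whose onset falls in a downstate (same
segmentation engine) qualify; the first six eligible trials in temporal
order are averaged; baseline is the 50 ms ending 5 ms before the first
injection (the guard keeps the first spike's foot out); the ADP is read a
single point 5 ms after the last spike's peak. Input resistance averages a
10-ms window centered 300 ms into the −100 pA step; mV/pA·10³ = MΩ.

## Statistical layer

- Grubbs: two-sided, single outlier, applied once per group per parameter
  (iteration is not specified in the field's descriptions; one pass is the
  conservative reading). Removed indices are returned for audit.
- Location comparisons: Shapiro–Wilk per group at α = 0.05 selects t test /
  one-way ANOVA (Bonferroni-corrected pairwise t) versus Mann–Whitney U /
  Kruskal–Wallis (Dunn's rank test with tie correction, Bonferroni-adjusted;
  a plain Bonferroni Mann–Whitney path is available).
- Variance homogeneity: F (2 groups) or Bartlett when all groups pass
  Shapiro–Wilk, else Levene centered on the mean; zero-spread groups route
  to Levene with a warning.
- Permutation test: statistic |mean difference|, exact enumeration when
  C(n, n₁) ≤ 20,000, otherwise seeded Monte-Carlo with the +1 correction.
  Spontaneous-rate comparisons use this path because silent cells make the
  distribution a zero-inflated mixture.
- Correlation graphs: pairwise-complete Pearson; constant columns yield NaN
  (flagged), never 0; edges kept at raw p < 0.05 with no multiplicity
  correction — that is the published filter — and node degree is recomputed
  from retained edges.
- Startle: trial-by-trial variability is the per-animal SD at each intensity,
  compared across groups with a mixed (between-group × within-intensity)
  repeated-measures ANOVA; inter-individual variability is the variance of
  per-animal means per intensity, compared with Bartlett. The published
  captions name both "mixed ANOVA" and "repeated-measures two-way ANOVA";
  both route to the single mixed-ANOVA implementation here.

## Validation problem sizes

The ground-truth benchmarks run at sizes chosen for statistical power of the
check itself: segmentation accuracy on 50 × 180-s two-state traces at 2 kHz
(balanced 0.5-s mean durations, contrast/noise = 5); spectral closed forms on
180-s traces at 1 kHz; type-I calibration with 1000 simulations at n = 16/17
per group; genotype recovery over 50 paired cohorts of 4 + 4 cells, each with
a 60-s spontaneous epoch at 10 kHz and a 40-trial block. The 60-s epoch gives
each cell ≈6 expected micro-upstates and ≈50 state cycles, enough for stable
per-cohort frequency estimates; spike detection requires ≥10 kHz.

## Limitations

- The segmentation inherits the median-threshold method's sensitivity to
  local duty cycle (see above); boundary accuracy is quantified only under
  the two-state synthetic model.
- Onset latencies on high-noise cells fall back to threshold crossings and
  should be treated as flagged estimates.
- Real-data ingestion (e.g. ABF) is out of scope; the HDF5/CSV layouts in
  `vmvar.io` are the supported interchange formats.
- The startle analysis assumes a balanced animals × intensities × trials
  design; unbalanced designs are handled only by dropping single-trial
  cells.
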