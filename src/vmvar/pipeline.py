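"""End-to-end per-cell and cohort orchestration.

``run_cell`` composes QC, state segmentation, spectral analysis, per-trial
EPSP/AP feature extraction and intrinsic-property analysis into one flat
parameter vector per neuron; ``run_cohort`` stacks those vectors into a
neurons-by-parameters table and applies the statistical layer (Grubbs screen,
normality-dispatched comparisons, variance tests, correlation matrix and node
graph per group). Everything is deterministic given the input bundles and the
configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import epsp as epsp_mod
from . import intrinsic as intrinsic_mod
from . import spikes as spikes_mod
from . import states as states_mod
from . import spectral as spectral_mod
from . import stats as stats_mod
from .synth import SynthParams, generate_step_protocol, generate_trace, generate_trial_set
from .trace import StepProtocol, TrialSet, ValidationError, VmTrace, validate_recording

__all__ = [
    "AnalysisConfig",
    "CellBundle",
    "NeuronSummary",
    "run_cell",
    "run_cohort",
    "simulate_cell",
    "load_config",
]


@dataclass
class AnalysisConfig:
    """Every window length, band edge and threshold used by the pipeline.

    Defaults are the operational values of the analysis: 200-ms pre/post trial
    windows, 180-s segmentation epoch, 120-s spontaneous-activity window,
    drift correction always on, p < 0.05 for correlation-graph edges.
    """

    pre_window: float = 0.2
    post_window: float = 0.2
    seg_epoch: float = 180.0
    spont_window: float = 120.0
    detrend: bool = True
    threshold_mode: str = "hold"
    alpha: float = 0.05
    failure_sd_factor: float = 2.0
    n_perm: int = 10_000
    permutation_params: tuple[str, ...] = ("spont_rate",)
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Configuration from a YAML file; defaults when ``path`` is None."""
    if path is None:
        return AnalysisConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "permutation_params" in data:
        data["permutation_params"] = tuple(data["permutation_params"])
    return AnalysisConfig(**data)


@dataclass
class CellBundle:
    """One cell's recordings: spontaneous epoch, trial block, step protocol."""

    cell_id: str
    group: str
    spont: VmTrace | None = None
    trials: TrialSet | None = None
    protocol: StepProtocol | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class NeuronSummary:
    cell_id: str
    group: str
    qc_include: bool
    qc_reasons: list[str]
    params: dict[str, float] = field(default_factory=dict)
    absent: list[str] = field(default_factory=list)
    trial_correlates: pd.DataFrame | None = None
    trial_correlations: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"cell_id": self.cell_id, "group": self.group}
        row.update(self.params)
        return row


def _put(params: dict, absent: list[str], name: str, value) -> None:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        absent.append(name)
    else:
        params[name] = float(value)


def run_cell(bundle: CellBundle, config: AnalysisConfig | None = None) -> NeuronSummary:
    """Analyze one cell end to end.

    QC-excluded cells carry a verdict only; missing protocol sections produce a
    partial summary with the absent fields listed explicitly.
    """
    config = config or AnalysisConfig()
    meta = dict(bundle.meta)
    if bundle.spont is not None:
        meta = {**bundle.spont.meta, **meta}
    if {"access_resistance_mohm", "resting_vm_mv"} <= set(meta):
        verdict = validate_recording(bundle.spont or bundle.trials.trace, meta)
        if not verdict.include:
            return NeuronSummary(
                bundle.cell_id, bundle.group, False, verdict.reasons
            )
    params: dict[str, float] = {}
    absent: list[str] = []

    if bundle.spont is not None:
        epoch = bundle.spont
        if epoch.duration > config.seg_epoch:
            epoch = VmTrace(
                samples=epoch.samples[: int(config.seg_epoch * epoch.fs)],
                fs=epoch.fs, t0=epoch.t0, meta=epoch.meta,
            )
        segments = states_mod.segment_states(
            epoch, detrend=config.detrend, threshold_mode=config.threshold_mode
        )
        summary = states_mod.summarize_states(segments, epoch)
        _put(params, absent, "up_dur_mean", summary.up_dur_mean)
        _put(params, absent, "up_freq", summary.up_freq)
        _put(params, absent, "down_dur_mean", summary.down_dur_mean)
        _put(params, absent, "down_freq", summary.down_freq)
        _put(params, absent, "dvm_updown", summary.dvm_updown)
        _put(params, absent, "micro_count", summary.micro_count)

        psd = spectral_mod.welch_psd(epoch)
        for band, power in psd.band_powers.items():
            _put(params, absent, f"power_{band}", power)

        try:
            events = spikes_mod.detect_aps(bundle.spont)
            is_active, rate = spikes_mod.spontaneous_metrics(
                bundle.spont, window=config.spont_window, events=events
            )
            _put(params, absent, "is_active", float(is_active))
            _put(params, absent, "spont_rate", rate)
        except ValidationError:
            absent.extend(["is_active", "spont_rate"])
    else:
        absent.extend(
            ["up_dur_mean", "up_freq", "down_dur_mean", "down_freq", "dvm_updown",
             "micro_count", "is_active", "spont_rate"]
            + [f"power_{b.name}" for b in spectral_mod.DEFAULT_BANDS]
        )

    trial_correlates = None
    trial_correlations: dict[str, float] = {}
    if bundle.trials is not None:
        ts = bundle.trials
        try:
            trial_events = spikes_mod.detect_aps(ts.trace)
        except ValidationError:
            trial_events = []
        ap_times = np.array([e.peak_time for e in trial_events])
        features = epsp_mod.analyze_trials(ts, ap_times)
        cell = epsp_mod.summarize_cell(ts, features)
        _put(params, absent, "epsp_amplitude", cell.mean_amplitude)
        _put(params, absent, "epsp_half_width", cell.mean_half_width)
        _put(params, absent, "epsp_slope", cell.mean_slope)
        _put(params, absent, "epsp_onset_latency", cell.onset_latency_ms)
        _put(params, absent, "epsp_peak_latency", cell.peak_latency_ms)
        _put(params, absent, "tbt_sd_amplitude", cell.tbt_sd_amplitude)
        _put(params, absent, "tbt_sd_halfwidth", cell.tbt_sd_halfwidth)
        _put(params, absent, "tbt_sd_slope", cell.tbt_sd_slope)
        _put(params, absent, "snr_cell", cell.snr_cell)
        _put(params, absent, "baseline_sd", cell.mean_baseline_sd)
        _put(params, absent, "sd_baseline_sd", cell.sd_baseline_sd)

        outcomes = [f.outcome for f in features]
        fractions, cell_class = spikes_mod.classify_cell(outcomes)
        _put(params, absent, "frac_ap_trials", fractions["ap"])
        _put(params, absent, "frac_failures", fractions["failure"])
        params["cell_class_ap"] = float(cell_class == "AP-EPSP")

        evoked, evoked_mean, evoked_cv, per_success = spikes_mod.evoked_counts(
            ts, trial_events
        )
        _put(params, absent, "evoked_ap_mean", evoked_mean)
        _put(params, absent, "evoked_ap_cv", evoked_cv)
        _put(params, absent, "ap_per_successful_trial", per_success)
        _, jitter = spikes_mod.first_ap_jitter(ts, trial_events)
        _put(params, absent, "ap_onset_jitter", jitter)

        trial_correlates = _trial_correlates(ts, features)
        trial_correlations = _trial_correlations(trial_correlates)
        for name, r in trial_correlations.items():
            _put(params, absent, name, r)

    if bundle.protocol is not None:
        summary = intrinsic_mod.analyze_protocol(bundle.protocol)
        _put(params, absent, "rheobase", summary.rheobase)
        _put(params, absent, "max_ap_freq", summary.max_ap_freq)
        _put(params, absent, "ap_threshold", summary.ap_threshold)
        _put(params, absent, "ap_half_width", summary.first_ap_half_width)
        _put(params, absent, "hw_ratio_3_1", summary.hw_ratio_3_1)
        _put(params, absent, "accommodation", summary.accommodation)
        _put(params, absent, "input_resistance", summary.input_resistance)
        _put(params, absent, "resting_vm", summary.resting_vm)
    else:
        absent.extend(
            ["rheobase", "max_ap_freq", "ap_threshold", "ap_half_width",
             "hw_ratio_3_1", "accommodation", "input_resistance", "resting_vm"]
        )

    return NeuronSummary(
        bundle.cell_id, bundle.group, True, [], params, absent,
        trial_correlates, trial_correlations,
    )


def _trial_correlates(ts: TrialSet, features) -> pd.DataFrame:
    """Per-trial baseline metrics next to per-trial response features.

    Baseline SD and band powers are also normalized by the magnitude of the
    baseline Vm, the form used for trial-wise correlation.
    """
    rows = []
    for f in features:
        row = {
            "trial": f.trial,
            "outcome": f.outcome,
            "baseline_vm": f.baseline_vm,
            "baseline_sd": f.baseline_sd,
            "baseline_sd_norm": f.baseline_sd / abs(f.baseline_vm)
            if f.baseline_vm != 0 else np.nan,
            "amplitude": f.amplitude if f.outcome == "epsp" else np.nan,
            "half_width": f.half_width if f.outcome == "epsp" else np.nan,
        }
        powers = spectral_mod.short_window_psd(ts, f.trial)
        for band, p in powers["band_powers_norm"].items():
            row[f"power_{band}_norm"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def _trial_correlations(tc: pd.DataFrame) -> dict[str, float]:
    """Pearson r between baseline metrics and EPSP features across trials."""
    from scipy import stats as sps

    out = {}
    pairs = [
        ("baseline_sd", "amplitude", "r_sd_amplitude"),
        ("baseline_sd", "half_width", "r_sd_halfwidth"),
        ("baseline_vm", "amplitude", "r_vm_amplitude"),
    ]
    for a, b, name in pairs:
        x, y = tc[a].to_numpy(), tc[b].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
            out[name] = float(sps.pearsonr(x[ok], y[ok]).statistic)
        else:
            out[name] = np.nan
    return out


# ---------------------------------------------------------------------------
# cohort level


def run_cohort(
    bundles: list[CellBundle], config: AnalysisConfig | None = None
) -> dict:
    """Analyze a cohort of cells and apply the group-statistics layer.

    Returns a dict with the neurons-by-parameters ``table``, per-parameter
    ``comparisons`` and ``variance_tests`` (2+ groups with n >= 3 each,
    otherwise skipped with a named reason), per-group correlation ``graphs``,
    and a reproducibility ``manifest``.
    """
    config = config or AnalysisConfig()
    summaries = [run_cell(b, config) for b in bundles]
    rows = [s.to_row() for s in summaries if s.qc_include]
    excluded = [
        {"cell_id": s.cell_id, "reasons": s.qc_reasons}
        for s in summaries if not s.qc_include
    ]
    table = pd.DataFrame(rows)
    result: dict = {
        "table": table,
        "summaries": summaries,
        "excluded": excluded,
        "comparisons": {},
        "variance_tests": {},
        "graphs": {},
        "skipped": {},
        "manifest": {
            "config": asdict(config),
            "config_digest": config.digest(),
            "n_cells": len(bundles),
        },
    }
    if table.empty:
        return result
    groups = table["group"]
    group_sizes = groups.value_counts()
    param_cols = [c for c in table.columns if c not in ("cell_id", "group")]

    if len(group_sizes) >= 2 and (group_sizes >= 3).all():
        for col in param_cols:
            vals, labs = [], []
            for g, sub in table.groupby("group"):
                x = sub[col].dropna().to_numpy(dtype=float)
                kept, _, _ = stats_mod.grubbs_filter(x, config.alpha)
                vals.append(kept)
                labs.append(np.repeat(g, kept.size))
            values = np.concatenate(vals)
            labels = np.concatenate(labs)
            sizes = pd.Series(labels).value_counts()
            if len(sizes) < 2 or (sizes < 3).any():
                result["skipped"][col] = "group n < 3 after missing/outlier removal"
                continue
            try:
                if col in config.permutation_params:
                    result["comparisons"][col] = stats_mod.permutation_test(
                        values, labels, n_perm=config.n_perm, seed=config.seed
                    )
                else:
                    result["comparisons"][col] = stats_mod.compare_groups(
                        values, labels, alpha=config.alpha
                    )
                result["variance_tests"][col] = stats_mod.variance_test(
                    values, labels, alpha=config.alpha
                )
            except ValidationError as err:
                result["skipped"][col] = str(err)
    else:
        result["skipped"]["__all__"] = "need >= 2 groups with n >= 3 cells each"

    for g, sub in table.groupby("group"):
        usable = [
            c for c in param_cols
            if sub[c].notna().sum() >= 3 and sub[c].std() > 0
        ]
        if len(usable) < 2:
            continue
        r, p = stats_mod.correlation_matrix(sub[usable])
        result["graphs"][g] = stats_mod.node_graph(r, p, alpha=config.alpha)
    return result


# ---------------------------------------------------------------------------
# synthetic cell bundles


def simulate_cell(
    params: SynthParams,
    cell_id: str,
    group: str,
    with_protocol: bool = False,
) -> CellBundle:
    """Generate one synthetic cell's bundle (spontaneous epoch + trial block,
    optional current-step protocol) from a single parameter set."""
    trace, _ = generate_trace(params)
    trial_params = SynthParams(**{**asdict_shallow(params), "seed": params.seed + 1})
    trials, _ = generate_trial_set(trial_params)
    protocol = None
    if with_protocol:
        protocol, _ = generate_step_protocol(fs=params.fs, seed=params.seed + 2)
    return CellBundle(
        cell_id=cell_id, group=group, spont=trace, trials=trials, protocol=protocol
    )


def asdict_shallow(params: SynthParams) -> dict:
    d = asdict(params)
    d["osc_amp"] = dict(params.osc_amp)
    return d
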