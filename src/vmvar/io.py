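"""Reading and writing traces, trial sets, step protocols, and cohort tables.

Native container is HDF5: dataset ``/vm`` (float mV, attribute ``units``),
root attributes ``fs`` (Hz), ``t0`` (s) and ``kind``; trial sets add
``/stim_times`` (s) plus window attributes; step protocols store one sweep per
current under ``/sweeps``. Readers never coerce units silently — ``units`` and
``fs`` are mandatory. A two-column CSV dialect (time_s, vm_mv) exists for tiny
text fixtures. Cohort tables are CSV with one row per neuron; correlation
graphs export as node-link JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .trace import StepProtocol, TrialSet, ValidationError, VmTrace

__all__ = [
    "FormatError",
    "write_bundle",
    "read_bundle",
    "write_trace_csv",
    "read_trace_csv",
    "write_graph_json",
    "read_graph_json",
]


class FormatError(ValueError):
    """Raised when a file does not conform to the documented layout."""


def _write_meta(group: h5py.Group, meta: dict) -> None:
    if meta:
        group.attrs["meta_json"] = json.dumps(meta, default=float)


def _read_meta(group: h5py.Group) -> dict:
    raw = group.attrs.get("meta_json")
    return json.loads(raw) if raw is not None else {}


def write_bundle(obj: VmTrace | TrialSet | StepProtocol, path: str | Path) -> Path:
    """Write a trace, trial set, or step protocol to an HDF5 bundle."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        if isinstance(obj, VmTrace):
            f.attrs["kind"] = "trace"
            _write_trace(f, obj)
        elif isinstance(obj, TrialSet):
            f.attrs["kind"] = "trialset"
            _write_trace(f, obj.trace)
            ds = f.create_dataset("stim_times", data=obj.stim_times)
            ds.attrs["units"] = "s"
            f.attrs["pre_window"] = obj.pre_window
            f.attrs["post_window"] = obj.post_window
        elif isinstance(obj, StepProtocol):
            f.attrs["kind"] = "protocol"
            f.attrs["step_dur"] = obj.step_dur
            f.attrs["step_onset"] = obj.step_onset
            f.attrs["fs"] = obj.sweeps[0].fs
            ds = f.create_dataset("currents", data=obj.currents)
            ds.attrs["units"] = "pA"
            grp = f.create_group("sweeps")
            for i, sweep in enumerate(obj.sweeps):
                d = grp.create_dataset(f"{i:03d}", data=sweep.samples)
                d.attrs["units"] = "mV"
                _write_meta_ds(d, sweep.meta)
        else:
            raise ValidationError(f"unsupported object type {type(obj).__name__}")
    return path


def _write_trace(f: h5py.File, trace: VmTrace) -> None:
    ds = f.create_dataset("vm", data=trace.samples)
    ds.attrs["units"] = "mV"
    f.attrs["fs"] = trace.fs
    f.attrs["t0"] = trace.t0
    _write_meta(f, trace.meta)


def _write_meta_ds(ds: h5py.Dataset, meta: dict) -> None:
    if meta:
        ds.attrs["meta_json"] = json.dumps(meta, default=float)


def _require_attr(obj, name: str):
    if name not in obj.attrs:
        raise FormatError(f"missing attribute: {name}")
    return obj.attrs[name]


def read_bundle(path: str | Path) -> VmTrace | TrialSet | StepProtocol:
    """Read an HDF5 bundle back; the round trip is bit-exact on samples."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        kind = _require_attr(f, "kind")
        if kind == "trace":
            return _read_trace(f)
        if kind == "trialset":
            trace = _read_trace(f)
            if "stim_times" not in f:
                raise FormatError("missing dataset: stim_times")
            return TrialSet(
                trace=trace,
                stim_times=f["stim_times"][()],
                pre_window=float(_require_attr(f, "pre_window")),
                post_window=float(_require_attr(f, "post_window")),
            )
        if kind == "protocol":
            fs = float(_require_attr(f, "fs"))
            currents = f["currents"][()]
            sweeps = []
            for key in sorted(f["sweeps"]):
                ds = f["sweeps"][key]
                _require_attr(ds, "units")
                meta = (
                    json.loads(ds.attrs["meta_json"])
                    if "meta_json" in ds.attrs else {}
                )
                sweeps.append(VmTrace(samples=ds[()], fs=fs, meta=meta))
            return StepProtocol(
                currents=currents,
                sweeps=sweeps,
                step_dur=float(_require_attr(f, "step_dur")),
                step_onset=float(_require_attr(f, "step_onset")),
            )
        raise FormatError(f"unknown bundle kind: {kind!r}")


def _read_trace(f: h5py.File) -> VmTrace:
    if "vm" not in f:
        raise FormatError("missing dataset: vm")
    ds = f["vm"]
    units = _require_attr(ds, "units")
    if units != "mV":
        raise FormatError(f"vm units must be mV, found {units!r}")
    fs = float(_require_attr(f, "fs"))
    t0 = float(f.attrs.get("t0", 0.0))
    return VmTrace(samples=ds[()], fs=fs, t0=t0, meta=_read_meta(f))


# ---------------------------------------------------------------------------
# CSV fixture dialect


def write_trace_csv(trace: VmTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times(), "vm_mv": trace.samples})
    df.to_csv(path, index=False)
    return path


def read_trace_csv(path: str | Path) -> VmTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "vm_mv"):
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise FormatError("CSV trace needs at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise FormatError("CSV trace must be uniformly sampled")
    return VmTrace(samples=df["vm_mv"].to_numpy(), fs=1.0 / dt[0], t0=float(t[0]))


# ---------------------------------------------------------------------------
# wavelet export


def write_wavelet_h5(wavelet, path: str | Path) -> Path:
    """Store a wavelet power matrix with its frequency/time axes."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "wavelet_power"
        f.attrs["w"] = wavelet.w
        f.attrs["display_saturation"] = wavelet.display_saturation
        f.create_dataset("power", data=wavelet.power)
        f.create_dataset("freqs", data=wavelet.freqs).attrs["units"] = "Hz"
        f.create_dataset("times", data=wavelet.times).attrs["units"] = "s"
        f.create_dataset("widths", data=wavelet.widths)
    return path


# ---------------------------------------------------------------------------
# graph export


def write_graph_json(graph: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    data = nx.node_link_data(graph, edges="links")
    path.write_text(json.dumps(data, indent=1, default=float))
    return path


def read_graph_json(path: str | Path) -> nx.Graph:
    data = json.loads(Path(path).read_text())
    return nx.node_link_graph(data, edges="links")
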