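"""File formats: manifests, trace containers, event tables, results.

Formats are deliberately plain: YAML manifests, HDF5 (or CSV) trace
containers, comma-separated event tables with a JSON provenance sidecar,
and versioned JSON results.  Every writer's output is readable by the
matching reader; numeric loss is limited to float64 round-off in the CSV
paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .biophysics import CircuitParams, FrequencyPanel, ShellMap
from .detect import EventTable
from .dna_math import SampleSpec
from .simulate import AcquisitionSettings, TraceSet

RESULTS_SCHEMA_VERSION = "1.0"

#: Minimal schema for the per-sample results document.
RESULTS_SCHEMA = {
    "version": str,
    "provenance": dict,
    "samples": list,  # items: see _validate_sample_result
}

_SAMPLE_RESULT_REQUIRED = {
    "label": str,
    "n_beads": int,
    "q_mean": float,
    "q_se": float,
    "spectrum_mean": list,
    "spectrum_sem": list,
}


class ManifestError(ValueError):
    """Raised when a manifest fails validation."""


def load_manifest(path: str | Path) -> dict:
    """Load and validate a sample manifest.

    Returns a dict with keys ``samples`` (list of :class:`SampleSpec`),
    ``circuit``, ``shell_map``, ``acquisition`` (settings overrides dict)
    and ``panel``.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "samples" not in raw:
        raise ManifestError(f"{path}: manifest must be a mapping with a 'samples' list")
    samples = []
    for i, entry in enumerate(raw["samples"]):
        try:
            samples.append(
                SampleSpec(
                    label=str(entry["label"]),
                    dna_length_bp=int(entry.get("dna_length_bp", 0)),
                    copies_per_bead=float(entry.get("copies_per_bead", 0.0)),
                    n_beads=int(entry["n_beads"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ManifestError(f"{path}: sample #{i}: {exc}") from exc
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise ManifestError(f"{path}: sample labels must be unique")

    circuit = CircuitParams(**raw.get("circuit", {}))
    shell_map = ShellMap(**raw.get("shell_map", {}))
    panel_cfg = raw.get("panel")
    panel = FrequencyPanel(tuple(float(f) for f in panel_cfg)) if panel_cfg else FrequencyPanel()
    return {
        "samples": samples,
        "circuit": circuit,
        "shell_map": shell_map,
        "acquisition": dict(raw.get("acquisition", {})),
        "panel": panel,
    }


def _settings_to_attrs(acq: AcquisitionSettings) -> dict:
    d = dataclasses.asdict(acq)
    d["noise_sd"] = np.atleast_1d(np.asarray(d["noise_sd"], dtype=float))
    return d


def write_traces_h5(traces: TraceSet, path: str | Path) -> None:
    """Write a trace set to an HDF5 container.

    Layout: datasets ``/time``, ``/channels`` (frequency x sample) and
    ``/panel``; acquisition settings as root attributes; the ground-truth
    event log (if any) under ``/ground_truth/<column>``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=traces.time)
        f.create_dataset("channels", data=traces.channels)
        f.create_dataset("panel", data=np.asarray(traces.panel.frequencies))
        f.attrs["source"] = traces.source
        for k, v in _settings_to_attrs(traces.settings).items():
            f.attrs[f"acq_{k}"] = v
        if traces.ground_truth is not None:
            grp = f.create_group("ground_truth")
            for col in traces.ground_truth.columns:
                grp.create_dataset(col, data=traces.ground_truth[col].to_numpy())
            grp.attrs["columns"] = list(traces.ground_truth.columns)


def read_traces_h5(path: str | Path) -> TraceSet:
    with h5py.File(path, "r") as f:
        time = f["time"][:]
        channels = f["channels"][:]
        panel = FrequencyPanel(tuple(float(x) for x in f["panel"][:]))
        kwargs = {}
        for k, v in f.attrs.items():
            if k.startswith("acq_"):
                kwargs[k[4:]] = v
        noise_sd = np.atleast_1d(kwargs.get("noise_sd", 1e-5))
        kwargs["noise_sd"] = (
            float(noise_sd[0]) if noise_sd.size == 1 else tuple(float(x) for x in noise_sd)
        )
        for int_key in ("seed",):
            if int_key in kwargs:
                kwargs[int_key] = int(kwargs[int_key])
        for float_key in (
            "sampling_rate", "duration", "mean_transit_time", "arrival_rate",
            "drift_amplitude", "drift_timescale", "doublet_probability",
        ):
            if float_key in kwargs:
                kwargs[float_key] = float(kwargs[float_key])
        settings = AcquisitionSettings(**kwargs)
        gt = None
        if "ground_truth" in f:
            grp = f["ground_truth"]
            cols = list(grp.attrs["columns"])
            gt = pd.DataFrame({c: grp[c][:] for c in cols})
        source = str(f.attrs.get("source", str(path)))
    return TraceSet(time, channels, panel, settings, gt, source=source)


def write_traces_csv(traces: TraceSet, path: str | Path) -> None:
    """Plain multi-column CSV export: time plus one column per frequency."""
    cols = {"time_s": traces.time}
    for j, f_hz in enumerate(traces.panel.frequencies):
        cols[f"channel_{f_hz:.0f}Hz"] = traces.channels[j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_traces_csv(path: str | Path, settings: AcquisitionSettings) -> TraceSet:
    """Read a CSV trace export; acquisition settings must be supplied."""
    df = pd.read_csv(path)
    time = df["time_s"].to_numpy()
    ch_cols = [c for c in df.columns if c.startswith("channel_")]
    freqs = tuple(float(c[len("channel_"):-2]) for c in ch_cols)
    channels = df[ch_cols].to_numpy().T
    return TraceSet(time, channels, FrequencyPanel(freqs), settings, None, source=str(path))


def write_events_csv(events: EventTable, path: str | Path) -> None:
    """One row per event plus a ``<path>.provenance.json`` sidecar."""
    path = Path(path)
    events.to_dataframe().to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    with open(sidecar, "w") as fh:
        json.dump(events.provenance, fh, indent=2, sort_keys=True, default=str)


def read_events_csv(path: str | Path) -> EventTable:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    provenance = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            provenance = json.load(fh)
    return EventTable.from_dataframe(df, provenance=provenance)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_results_json(results: dict, path: str | Path) -> None:
    validate_results(results)
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results_json(path: str | Path) -> dict:
    with open(path) as fh:
        results = json.load(fh)
    validate_results(results)
    return results


def validate_results(results: dict) -> None:
    """Check a results document against the shipped schema."""
    for key, typ in RESULTS_SCHEMA.items():
        if key not in results:
            raise ValueError(f"results document missing key '{key}'")
        if not isinstance(results[key], typ):
            raise ValueError(f"results['{key}'] must be {typ.__name__}")
    for i, sample in enumerate(results["samples"]):
        for key, typ in _SAMPLE_RESULT_REQUIRED.items():
            if key not in sample:
                raise ValueError(f"sample result #{i} missing '{key}'")
            if typ is float and isinstance(sample[key], int):
                continue
            if not isinstance(sample[key], typ):
                raise ValueError(f"sample result #{i}: '{key}' must be {typ.__name__}")
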